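"""Measurement protocol: accuracy, repeated runs, significance, confusion.

Decoding performance is reported as validation accuracy in percent, as the
mean +/- sample standard deviation over five repeated runs with identical
hyperparameters but different seeds.  Pairwise differences between methods
are assessed with Welch's two-sample t-test on the per-seed accuracies (the
one-sample variant when one method is deterministic and contributes a single
constant).  Confusion matrices are row-normalized: entry (i, j) estimates
P(predicted = j | true = i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METHOD_ORDER = (
    "decision_tree",
    "random_forest",
    "adaboost",
    "svm_linear",
    "svm_rbf",
    "nn",
    "lstm_forward",
    "lstm_backward",
    "brnn",
)


@dataclass
class RunResult:
    method: str
    label_level: str  # "coarse" | "mid" | "fine"
    seed: int
    val_accuracy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.val_accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class RepeatSummary:
    mean_pct: float
    std_pct: float
    accuracies: list[float]
    single_run: bool = False

    def __str__(self) -> str:
        return f"{self.mean_pct:.2f} ± {self.std_pct:.2f}"


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true labels must be nonempty and equal length")
    return float(np.mean(predicted == true))


def repeated_runs(train_fn, seed_list: list[int]) -> RepeatSummary:
    """Run ``train_fn(seed) -> accuracy`` per seed; mean +/- sample std in percent.

    A single run is reported with zero std and flagged as such.
    """
    if len(seed_list) < 1:
        raise ValueError("need at least one seed")
    if len(set(seed_list)) != len(seed_list):
        raise ValueError("seeds must be distinct")
    accs = []
    for seed in seed_list:
        try:
            accs.append(float(train_fn(seed)))
        except Exception as exc:  # surface the failing seed
            raise RuntimeError(f"run with seed {seed} failed: {exc}") from exc
    mean = float(np.mean(accs)) * 100.0
    std = float(np.std(accs, ddof=1)) * 100.0 if len(accs) > 1 else 0.0
    return RepeatSummary(mean, std, accs, single_run=len(accs) == 1)


def significance_test(
    accs_a: list[float], accs_b: list[float]
) -> tuple[float, bool]:
    """Two-sided Welch t-test between per-seed accuracies.

    When one side is a deterministic classifier (all repeats identical, or a
    single value), a one-sample t-test of the other side against that
    constant is used.  Returns ``(p, degenerate)``; ``degenerate`` is True
    when both sides are constant (then p = 1).
    """
    a = np.asarray(accs_a, dtype=float)
    b = np.asarray(accs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both accuracy lists must be nonempty")
    a_const = a.size < 2 or np.ptp(a) == 0.0
    b_const = b.size < 2 or np.ptp(b) == 0.0
    if a_const and b_const:
        return 1.0, True
    if a_const:
        p = stats.ttest_1samp(b, float(a[0])).pvalue
    elif b_const:
        p = stats.ttest_1samp(a, float(b[0])).pvalue
    else:
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return p, False


def normalized_confusion_matrix(
    predicted: np.ndarray, true: np.ndarray, n_classes: int
) -> np.ndarray:
    """Row-stochastic confusion matrix; rows without support are NaN."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.min(initial=0) < 0 or predicted.max(initial=0) >= n_classes:
        raise ValueError("predicted labels out of range")
    if true.min(initial=0) < 0 or true.max(initial=0) >= n_classes:
        raise ValueError("true labels out of range")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (true, predicted), 1.0)
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(support > 0, counts / support, np.nan)


@dataclass
class EvaluationReport:
    """Accuracy tables (per label level), significance table, confusion matrices."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    significance: pd.DataFrame | None = None
    confusion: dict[str, np.ndarray] = field(default_factory=dict)

    def to_text(self) -> str:
        parts = []
        for level, table in self.tables.items():
            parts.append(f"== accuracy ({level} labels, percent, mean ± std) ==")
            parts.append(table.to_string())
        if self.significance is not None and not self.significance.empty:
            parts.append("== pairwise Welch t-test p-values ==")
            parts.append(self.significance.to_string())
        for name, mat in self.confusion.items():
            parts.append(f"== normalized confusion matrix: {name} ==")
            parts.append(
                "\n".join(" ".join(f"{v:.4f}" for v in row) for row in mat)
            )
        return "\n".join(parts) + "\n"


def build_report(
    results: list[RunResult],
    comparisons: list[tuple[str, str]] | None = None,
    confusion: dict[str, np.ndarray] | None = None,
) -> EvaluationReport:
    """Aggregate per-seed run results into the standard report layout.

    One table per label level with methods as rows (classical methods first,
    then the NN baseline, the unidirectional ablations and the bidirectional
    decoder), plus an optional significance table over ``comparisons`` within
    each level.
    """
    if not results:
        raise ValueError("need at least one run result")
    df = pd.DataFrame(
        [
            {"method": r.method, "level": r.label_level, "seed": r.seed,
             "accuracy": r.val_accuracy}
            for r in results
        ]
    )
    order = {m: i for i, m in enumerate(METHOD_ORDER)}
    report = EvaluationReport(confusion=dict(confusion or {}))
    for level, level_df in df.groupby("level", sort=False):
        rows = []
        methods = sorted(level_df["method"].unique(),
                         key=lambda m: order.get(m, len(order)))
        for method in methods:
            accs = level_df.loc[level_df["method"] == method, "accuracy"]
            mean = accs.mean() * 100.0
            std = accs.std(ddof=1) * 100.0 if len(accs) > 1 else 0.0
            rows.append(
                {"method": method, "n_runs": len(accs),
                 "mean_pct": round(mean, 2), "std_pct": round(std, 2),
                 "summary": f"{mean:.2f} ± {std:.2f}"}
            )
        report.tables[level] = pd.DataFrame(rows).set_index("method")
    if comparisons:
        sig_rows = []
        for level, level_df in df.groupby("level", sort=False):
            have = set(level_df["method"])
            for a, b in comparisons:
                if a not in have or b not in have:
                    continue
                accs_a = list(level_df.loc[level_df["method"] == a, "accuracy"])
                accs_b = list(level_df.loc[level_df["method"] == b, "accuracy"])
                p, degenerate = significance_test(accs_a, accs_b)
                sig_rows.append({"level": level, "method_a": a, "method_b": b,
                                 "p_value": p, "degenerate": degenerate})
        report.significance = pd.DataFrame(sig_rows)
    return report
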