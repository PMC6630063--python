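"""Voxel-wise sparse linear encoding models and voxel selection.

A voxel's response vector ``y`` (one amplitude per stimulus) is modeled as a
sparse linear readout of a stimulus feature matrix ``X``: ``y = X w`` with
``||w||_0`` small.  The sparse fit uses Regularized Orthogonal Matching
Pursuit (ROMP): greedy selection of comparable-magnitude batches of columns
by residual correlation, followed by orthogonal least-squares refitting on
the accumulated support.  Fits are scored by held-out Pearson correlation;
the feature layer whose top voxels are best explained is chosen per visual
area, and the top-``k`` voxels of each area (default 100) form the nodes of
the downstream decoding sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SequenceSample, VoxelResponseSet

logger = logging.getLogger(__name__)


@dataclass
class EncodingProblem:
    """One voxel's regression problem: m-sample design X and response y."""

    X: np.ndarray  # (m, n)
    y: np.ndarray  # (m,)
    layer_id: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be m x n with y of length m")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in encoding problem")


@dataclass
class SparseWeights:
    """Sparse solution: support indices, their coefficients, and diagnostics."""

    support: np.ndarray  # sorted column indices
    values: np.ndarray  # coefficients aligned with support
    n_iterations: int
    residual_norm: float
    residual_history: list[float] = field(default_factory=list)

    def dense(self, n: int) -> np.ndarray:
        w = np.zeros(n)
        w[self.support] = self.values
        return w


@dataclass
class EncodingFit:
    voxel_id: str
    area: str
    layer_id: int
    weights: SparseWeights
    val_correlation: float  # NaN flags an undefined (constant-prediction) case


@dataclass
class AreaSelection:
    """Voxels chosen for one area, in descending held-out correlation order."""

    area: str
    chosen_layer: int
    voxel_ids: list[str]


def _comparable_window(abs_u: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Maximal-energy subset of candidates with pairwise comparable magnitudes.

    ``candidates`` are column indices sorted by descending |u|.  Scans every
    contiguous window of the sorted list in which the largest magnitude is at
    most twice the smallest, and returns the window with the largest energy
    sum(u^2).
    """
    mags = abs_u[candidates]
    best_energy = -1.0
    best: np.ndarray = candidates[:1]
    n = len(candidates)
    for start in range(n):
        end = start
        while end < n and mags[end] >= mags[start] / 2.0:
            end += 1
        energy = float(np.sum(mags[start:end] ** 2))
        if energy > best_energy:
            best_energy = energy
            best = candidates[start:end]
    return best


def fit_romp(
    problem: EncodingProblem,
    max_nonzeros: int | None = None,
    residual_tol: float = 1e-4,
) -> SparseWeights:
    """Regularized Orthogonal Matching Pursuit.

    Each iteration correlates the residual with all columns, keeps the
    ``max_nonzeros`` largest-magnitude candidates, regularizes them to the
    comparable-magnitude batch with maximal energy, adds that batch to the
    support (clipped to the sparsity budget) and refits by orthogonal least
    squares.  Stops when the relative residual falls below ``residual_tol``,
    the support reaches ``max_nonzeros``, or the residual stops decreasing.
    The residual norm is non-increasing across iterations.
    """
    X, y = problem.X, problem.y
    m, n = X.shape
    if max_nonzeros is None:
        max_nonzeros = max(1, min(m // 4, 100))
    if max_nonzeros < 1:
        raise ValueError("max_nonzeros must be >= 1")

    y_norm = float(np.linalg.norm(y))
    history = [y_norm]
    if y_norm == 0.0:
        return SparseWeights(np.array([], dtype=int), np.array([]), 0, 0.0, history)

    support: list[int] = []
    in_support = np.zeros(n, dtype=bool)
    r = y.copy()
    prev_norm = y_norm
    values = np.array([])
    n_iter = 0
    while len(support) < max_nonzeros:
        u = X.T @ r
        u[in_support] = 0.0
        abs_u = np.abs(u)
        live = np.flatnonzero(abs_u > 1e-13 * y_norm)
        if live.size == 0:
            break
        # top max_nonzeros by |u| (all live ones if fewer), descending
        order = live[np.argsort(-abs_u[live], kind="stable")]
        candidates = order[:max_nonzeros]
        batch = _comparable_window(abs_u, candidates)
        budget = max_nonzeros - len(support)
        if len(batch) > budget:
            batch = batch[:budget]  # batch is sorted by descending |u|
        support.extend(int(j) for j in batch)
        in_support[batch] = True
        cols = np.asarray(support, dtype=int)
        sol, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        r = y - X[:, cols] @ sol
        new_norm = float(np.linalg.norm(r))
        n_iter += 1
        # least squares on a superset cannot increase the residual; guard anyway
        new_norm = min(new_norm, prev_norm)
        history.append(new_norm)
        values = sol
        if new_norm <= residual_tol * y_norm:
            prev_norm = new_norm
            break
        if prev_norm - new_norm <= 1e-12 * y_norm:
            prev_norm = new_norm
            break
        prev_norm = new_norm

    cols = np.asarray(support, dtype=int)
    order = np.argsort(cols)
    return SparseWeights(
        support=cols[order],
        values=np.asarray(values)[order] if cols.size else np.array([]),
        n_iterations=n_iter,
        residual_norm=prev_norm,
        residual_history=history,
    )


def predict_voxel(problem: EncodingProblem, weights: SparseWeights) -> np.ndarray:
    """Predicted response X[:, support] @ values (zero vector for empty support)."""
    if weights.support.size == 0:
        return np.zeros(problem.X.shape[0])
    if weights.support.max() >= problem.X.shape[1] or weights.support.min() < 0:
        raise IndexError("support index out of range for design matrix")
    return problem.X[:, weights.support] @ weights.values


def pearson_correlation(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson r; NaN flags the undefined case of a constant input."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    pc = pred - pred.mean()
    oc = obs - obs.mean()
    denom = np.linalg.norm(pc) * np.linalg.norm(oc)
    if denom == 0.0:
        return float("nan")
    return float(np.clip(pc @ oc / denom, -1.0, 1.0))


def standardize_columns(
    X: np.ndarray, train_idx: np.ndarray
) -> np.ndarray:
    """Z-score columns with training-split statistics (constant columns -> 0)."""
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def fit_encoding_models(
    features: dict[int, np.ndarray],
    voxels: dict[str, VoxelResponseSet],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    max_nonzeros: int | None = None,
    residual_tol: float = 1e-4,
) -> pd.DataFrame:
    """Fit every (voxel, layer) pair on the training rows; score on validation.

    Feature columns are z-scored with training statistics so residual
    correlations are comparable across columns.  Voxels with non-finite
    responses are dropped (logged).  Returns one row per (voxel, layer) with
    the fitted :class:`SparseWeights` attached.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("empty split partition")
    std_features = {
        layer: standardize_columns(X, train_idx) for layer, X in features.items()
    }
    rows = []
    for area, vset in voxels.items():
        finite = np.isfinite(vset.data).all(axis=0)
        n_bad = int((~finite).sum())
        if n_bad:
            logger.warning("dropping %d non-finite voxels in area %s", n_bad, area)
        for v in np.flatnonzero(finite):
            vid = vset.voxel_ids[v]
            y = vset.data[:, v]
            for layer, X in std_features.items():
                problem = EncodingProblem(X[train_idx], y[train_idx], layer)
                w = fit_romp(problem, max_nonzeros=max_nonzeros,
                             residual_tol=residual_tol)
                pred = predict_voxel(EncodingProblem(X[val_idx], y[val_idx], layer), w)
                r = pearson_correlation(pred, y[val_idx])
                rows.append(
                    {
                        "voxel_id": vid,
                        "area": area,
                        "layer": layer,
                        "support_size": int(w.support.size),
                        "val_correlation": r,
                        "weights": w,
                    }
                )
    return pd.DataFrame(rows)


def select_layer_per_area(fits: pd.DataFrame, top_n: int = 200) -> dict[str, int]:
    """Choose, per area, the layer with the best mean top-``top_n`` correlation.

    The mean is over the ``top_n`` best-explained voxels of that area/layer
    (clipped to the available count); ties break toward the lower layer index.
    """
    if fits.empty:
        raise ValueError("empty fit table")
    chosen: dict[str, int] = {}
    for area, area_df in fits.groupby("area", sort=False):
        best_layer, best_score = None, -np.inf
        for layer in sorted(area_df["layer"].unique()):
            rs = area_df.loc[area_df["layer"] == layer, "val_correlation"]
            rs = rs.fillna(-1.0).sort_values(ascending=False)
            score = float(rs.head(top_n).mean())
            if score > best_score:
                best_layer, best_score = int(layer), score
        chosen[area] = best_layer
    return chosen


def select_voxels(
    fits: pd.DataFrame, area: str, chosen_layer: int, k: int = 100
) -> AreaSelection:
    """Top-``k`` voxels of an area by held-out correlation on the chosen layer.

    Descending correlation; ties (and only ties) break by ascending voxel id.
    Requests beyond the available voxel count clip with a warning.
    """
    sub = fits[(fits["area"] == area) & (fits["layer"] == chosen_layer)].copy()
    if sub.empty:
        raise ValueError(f"no fits for area {area!r} on layer {chosen_layer}")
    sub["val_correlation"] = sub["val_correlation"].fillna(-np.inf)
    sub = sub.sort_values(
        ["val_correlation", "voxel_id"], ascending=[False, True], kind="stable"
    )
    if k > len(sub):
        warnings.warn(
            f"requested {k} voxels for area {area} but only {len(sub)} available; clipping",
            stacklevel=2,
        )
        k = len(sub)
    return AreaSelection(
        area=area, chosen_layer=chosen_layer, voxel_ids=list(sub["voxel_id"].head(k))
    )


def assemble_sequences(
    selections: dict[str, AreaSelection],
    voxels: dict[str, VoxelResponseSet],
    labels: dict[str, np.ndarray],
    area_order: tuple[str, ...] = ("V1", "V2", "V3", "V4", "LO"),
) -> list[SequenceSample]:
    """Build the 5-node space sequence per sample from the selected voxels.

    Node order is fixed low-to-high (V1, V2, V3, V4, LO); each node is the
    selected-voxel vector of one area, in selection order.
    """
    missing = [a for a in area_order if a not in selections]
    if missing:
        raise KeyError(f"missing area selections: {missing}")
    per_area = []
    for area in area_order:
        sel = selections[area]
        vset = voxels[area]
        col_of = {vid: i for i, vid in enumerate(vset.voxel_ids)}
        cols = [col_of[vid] for vid in sel.voxel_ids]
        per_area.append(vset.data[:, cols])
    n = per_area[0].shape[0]
    samples = []
    for s in range(n):
        areas = np.stack([mat[s] for mat in per_area])
        samples.append(
            SequenceSample(
                areas=areas,
                coarse=int(labels["coarse"][s]),
                mid=int(labels["mid"][s]),
                fine=int(labels["fine"][s]),
            )
        )
    return samples
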