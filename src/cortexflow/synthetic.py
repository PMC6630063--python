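"""Synthetic stand-ins for natural-image fMRI decoding data.

Generates statistically structured data that mimics the situation the real
pipeline faces: five ventral visual areas (V1, V2, V3, V4, LO) each providing
one standardized response amplitude per voxel per stimulus, a nested
5/10/23-way category hierarchy over stimuli, sparse linear voxel <- feature
relationships for the encoding stage, and -- for the decoding stage -- two
distinct kinds of category signal:

* a *marginal* per-area signal (a category-specific mean pattern whose
  strength grows from V1 to LO, emulating the hierarchy of semantic content
  in the ventral stream), and
* a *relational* signal (label-dependent coupling between area patterns via a
  shared latent vector, so that category information lives in the relation
  between areas rather than in any single area's mean).

All generators are deterministic functions of their seed: one dataset seed
fans out to per-component child streams by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AREA_ORDER: tuple[str, ...] = ("V1", "V2", "V3", "V4", "LO")

N_FINE = 23
N_MID = 10
N_COARSE = 5

# fixed offsets for per-component child RNG streams
_SEED_HIERARCHY = 11
_SEED_FEATURES = 23
_SEED_VOXELS = 37
_SEED_SEQUENCES = 53
_SEED_SHUFFLE = 71


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, int(seed)])


@dataclass(frozen=True)
class LabelHierarchy:
    """Nested partition of 23 fine categories into 10 mid and 5 coarse groups."""

    coarse_of_mid: tuple[int, ...]  # length 10, values in 0..4
    mid_of_fine: tuple[int, ...]  # length 23, values in 0..9

    def __post_init__(self) -> None:
        if len(self.mid_of_fine) != N_FINE or len(self.coarse_of_mid) != N_MID:
            raise ValueError("hierarchy must map 23 fine -> 10 mid -> 5 coarse")
        if set(self.mid_of_fine) != set(range(N_MID)):
            raise ValueError("mid labels must be surjective onto 0..9")
        if set(self.coarse_of_mid) != set(range(N_COARSE)):
            raise ValueError("coarse labels must be surjective onto 0..4")

    def coarse_of_fine(self, fine: np.ndarray) -> np.ndarray:
        mid = np.asarray(self.mid_of_fine)[fine]
        return np.asarray(self.coarse_of_mid)[mid]

    def mid_of(self, fine: np.ndarray) -> np.ndarray:
        return np.asarray(self.mid_of_fine)[np.asarray(fine)]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the real dataset's scale where it has one: a 1750/120
    train/validation split, five areas, 100 voxels per area.  ``snr`` is the
    signal-to-noise variance ratio of the voxel-from-feature generative model.
    ``beta_marginal`` grows linearly from V1 to LO (per-area category mean
    strength); ``beta_relational`` scales the label-dependent cross-area
    coupling.  Sequence noise is unit Gaussian.
    """

    n_train: int = 1750
    n_val: int = 120
    areas: tuple[str, ...] = AREA_ORDER
    voxels_per_area: int = 100
    feature_dims: tuple[int, ...] = (64, 128)
    sparsity_k: int = 3
    snr: float = 10.0
    beta_marginal: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2, 1.4)
    beta_relational: float = 0.5
    area_layers: tuple[int, ...] | None = None  # planted layer per area
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_val <= 0 or self.voxels_per_area <= 0:
            raise ValueError("all counts must be positive")
        if len(self.areas) != 5:
            raise ValueError("exactly 5 areas expected")
        if len(self.beta_marginal) != 5:
            raise ValueError("beta_marginal must have length 5")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if any(d <= 0 for d in self.feature_dims):
            raise ValueError("feature dims must be positive")
        if self.sparsity_k <= 0:
            raise ValueError("sparsity_k must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_train + self.n_val

    def layer_of_area(self) -> tuple[int, ...]:
        """Planted feature layer per area; default spreads layers low->high."""
        if self.area_layers is not None:
            if len(self.area_layers) != len(self.areas):
                raise ValueError("area_layers must have one entry per area")
            return tuple(self.area_layers)
        n_layers = len(self.feature_dims)
        return tuple(min(i * n_layers // len(self.areas), n_layers - 1)
                     for i in range(len(self.areas)))


@dataclass
class VoxelResponseSet:
    """samples x voxels response matrix for one visual area."""

    area: str
    data: np.ndarray  # (n_samples, n_voxels)
    voxel_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.voxel_ids):
            raise ValueError("data must be samples x voxels with matching ids")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    true_supports: dict[str, np.ndarray]  # voxel_id -> sorted support indices
    true_weights: dict[str, np.ndarray]  # voxel_id -> dense weight vector
    voxel_layer: dict[str, int]  # voxel_id -> layer index
    area_layers: tuple[int, ...] = ()
    class_means: np.ndarray | None = None  # (n_fine, 5, K)
    mixing_matrices: np.ndarray | None = None  # (n_fine, 5, K, K)


@dataclass
class SequenceSample:
    """One stimulus: five ordered area vectors plus the three-level label."""

    areas: np.ndarray  # (5, K), ordered V1..LO
    coarse: int
    mid: int
    fine: int

    @property
    def labels(self) -> tuple[int, int, int]:
        return (self.coarse, self.mid, self.fine)


def make_label_hierarchy(seed: int = 0) -> LabelHierarchy:
    """Random balanced nested partition: 23 fine -> 10 mid -> 5 coarse.

    Group sizes are as even as 23/10/5 allows (mid groups hold 2-3 fine
    labels; every coarse group holds 2 mid groups, 4-5 fine labels), so that
    label marginals stay near-uniform at every level and chance accuracy is
    ~1/5, 1/10, 1/23.  Which labels land in which group is random but
    deterministic per seed.
    """
    rng = _rng(seed, _SEED_HIERARCHY)
    # two mids per coarse; spread the three size-3 mids over distinct coarse
    # groups so coarse fine-counts are 5,5,5,4,4
    coarse_perm = rng.permutation(N_COARSE)
    mid_sizes = np.full(N_MID, 2)
    coarse_of_mid = np.empty(N_MID, dtype=int)
    for slot, coarse in enumerate(coarse_perm):
        coarse_of_mid[2 * slot] = coarse
        coarse_of_mid[2 * slot + 1] = coarse
        if slot < N_FINE - 2 * N_MID:  # first three slots get a size-3 mid
            mid_sizes[2 * slot] = 3
    mid_perm = rng.permutation(N_MID)
    fine_perm = rng.permutation(N_FINE)
    mid_of_fine = np.empty(N_FINE, dtype=int)
    pos = 0
    for mid in mid_perm:
        for _ in range(mid_sizes[mid]):
            mid_of_fine[fine_perm[pos]] = mid
            pos += 1
    return LabelHierarchy(tuple(int(v) for v in coarse_of_mid),
                          tuple(int(v) for v in mid_of_fine))


def simulate_features(config: SimConfig) -> dict[int, np.ndarray]:
    """Per-layer stimulus feature matrices, entries i.i.d. standard normal.

    Returns a mapping layer index -> (n_train + n_val, dim) array.
    """
    rng = _rng(config.seed, _SEED_FEATURES)
    return {
        layer: rng.standard_normal((config.n_samples, dim))
        for layer, dim in enumerate(config.feature_dims)
    }


def simulate_voxels_from_features(
    features: dict[int, np.ndarray], config: SimConfig
) -> tuple[dict[str, VoxelResponseSet], SimTruth]:
    """Voxel responses as sparse linear readouts of their area's planted layer.

    Each voxel response is ``X @ w_true + noise`` where ``w_true`` has exactly
    ``sparsity_k`` nonzeros in the area's feature layer; the noise variance is
    the signal variance divided by ``snr`` (``snr=inf`` gives noiseless
    responses).  Responses are standardized per voxel with training-split
    statistics, matching how amplitudes arrive from real preprocessing.
    """
    area_layers = config.layer_of_area()
    for layer in area_layers:
        if config.sparsity_k > config.feature_dims[layer]:
            raise ValueError("sparsity_k exceeds feature dimension of a planted layer")
    rng = _rng(config.seed, _SEED_VOXELS)
    responses: dict[str, VoxelResponseSet] = {}
    truth = SimTruth(true_supports={}, true_weights={}, voxel_layer={},
                     area_layers=area_layers)
    for area, layer in zip(config.areas, area_layers):
        X = features[layer]
        dim = X.shape[1]
        data = np.empty((config.n_samples, config.voxels_per_area))
        ids = []
        for v in range(config.voxels_per_area):
            vid = f"{area}_{v:04d}"
            support = np.sort(rng.choice(dim, size=config.sparsity_k, replace=False))
            w = np.zeros(dim)
            # magnitudes bounded away from zero so the support is well defined
            w[support] = rng.uniform(0.5, 1.5, config.sparsity_k) * rng.choice(
                [-1.0, 1.0], config.sparsity_k
            )
            signal = X @ w
            if np.isfinite(config.snr):
                sig_var = signal[: config.n_train].var()
                noise = rng.standard_normal(config.n_samples) * np.sqrt(
                    sig_var / config.snr
                )
            else:
                noise = 0.0
            y = signal + noise
            mu = y[: config.n_train].mean()
            sd = y[: config.n_train].std()
            data[:, v] = (y - mu) / sd
            ids.append(vid)
            truth.true_supports[vid] = support
            truth.true_weights[vid] = w
            truth.voxel_layer[vid] = layer
        responses[area] = VoxelResponseSet(area=area, data=data, voxel_ids=ids)
    return responses, truth


def _balanced_fine_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fine labels balanced within +/-1 sample per class, in random order."""
    reps = np.tile(np.arange(N_FINE), n // N_FINE + 1)[:n]
    rng.shuffle(reps)
    return reps


def simulate_area_sequences(
    config: SimConfig, hierarchy: LabelHierarchy
) -> tuple[list[SequenceSample], list[SequenceSample], SimTruth]:
    """Labeled 5-node area sequences carrying marginal and relational signal.

    Area ``a`` of a sample with fine label ``l`` is

        beta_marginal[a] * mu(l, a)
        + beta_relational * M(l, a) @ z / sqrt(K)
        + N(0, I)

    where ``mu(l, a)`` is a fixed unit mean pattern, ``z`` is a per-sample
    shared latent and ``M(l, a)`` a fixed label-dependent mixing matrix, so
    category information is also carried by how areas co-vary, not only by
    each area's mean.
    """
    rng = _rng(config.seed, _SEED_SEQUENCES)
    K = config.voxels_per_area
    n_areas = len(config.areas)
    class_means = rng.standard_normal((N_FINE, n_areas, K))
    class_means /= np.linalg.norm(class_means, axis=2, keepdims=True)
    mixing = rng.standard_normal((N_FINE, n_areas, K, K))
    truth = SimTruth(true_supports={}, true_weights={}, voxel_layer={},
                     class_means=class_means, mixing_matrices=mixing)
    beta_m = np.asarray(config.beta_marginal)

    def _make(n: int) -> list[SequenceSample]:
        fine = _balanced_fine_labels(n, rng)
        mid = hierarchy.mid_of(fine)
        coarse = hierarchy.coarse_of_fine(fine)
        samples = []
        for s in range(n):
            l = fine[s]
            z = rng.standard_normal(K)
            noise = rng.standard_normal((n_areas, K))
            areas = (
                beta_m[:, None] * class_means[l]
                + config.beta_relational * (mixing[l] @ z) / np.sqrt(K)
                + noise
            )
            samples.append(
                SequenceSample(areas=areas, coarse=int(coarse[s]),
                               mid=int(mid[s]), fine=int(l))
            )
        return samples

    return _make(config.n_train), _make(config.n_val), truth


def shuffle_labels(dataset: list[SequenceSample], seed: int) -> list[SequenceSample]:
    """Null control: permute the label tuples, leaving voxel data untouched."""
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = _rng(seed, _SEED_SHUFFLE)
    perm = rng.permutation(len(dataset))
    return [
        SequenceSample(
            areas=s.areas,
            coarse=dataset[j].coarse,
            mid=dataset[j].mid,
            fine=dataset[j].fine,
        )
        for s, j in zip(dataset, perm)
    ]


def simulate_dataset(
    config: SimConfig, hierarchy: LabelHierarchy | None = None
) -> tuple[dict[int, np.ndarray], dict[str, VoxelResponseSet], dict[str, np.ndarray], SimTruth]:
    """Full synthetic dataset carrying both encoding and decoding structure.

    Each voxel response is the standardized sparse feature readout (so the
    encoding stage has supports to recover) plus the label-dependent marginal
    and relational category components (so the decoding stage has categories
    to decode; the feature-driven part is label-independent and plays the
    role of the decoder's noise).  Returns (features, per-area voxel sets,
    label arrays over all samples, ground truth).
    """
    if hierarchy is None:
        hierarchy = make_label_hierarchy(config.seed)
    features = simulate_features(config)
    voxels, truth = simulate_voxels_from_features(features, config)
    rng = _rng(config.seed, _SEED_SEQUENCES)
    K = config.voxels_per_area
    n_areas = len(config.areas)
    class_means = rng.standard_normal((N_FINE, n_areas, K))
    class_means /= np.linalg.norm(class_means, axis=2, keepdims=True)
    mixing = rng.standard_normal((N_FINE, n_areas, K, K))
    truth.class_means = class_means
    truth.mixing_matrices = mixing
    fine = np.concatenate(
        [_balanced_fine_labels(config.n_train, rng),
         _balanced_fine_labels(config.n_val, rng)]
    )
    labels = {
        "fine": fine,
        "mid": hierarchy.mid_of(fine),
        "coarse": hierarchy.coarse_of_fine(fine),
    }
    beta_m = np.asarray(config.beta_marginal)
    for s in range(config.n_samples):
        l = fine[s]
        z = rng.standard_normal(K)
        extra = beta_m[:, None] * class_means[l] + (
            config.beta_relational * (mixing[l] @ z) / np.sqrt(K)
        )
        for a, area in enumerate(config.areas):
            voxels[area].data[s] += extra[a]
    return features, voxels, labels, truth


def stack_sequences(samples: list[SequenceSample]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Pack a list of sequence samples into (n, 5, K) plus label arrays."""
    X = np.stack([s.areas for s in samples])
    labels = {
        "coarse": np.array([s.coarse for s in samples]),
        "mid": np.array([s.mid for s in samples]),
        "fine": np.array([s.fine for s in samples]),
    }
    return X, labels
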