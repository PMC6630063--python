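"""Dataset containers, HDF5/delimited readers and writers, pipeline config.

The on-disk HDF5 layout is::

    /areas/<name>     (n_samples, n_voxels) float64, voxel ids as an attribute
    /labels/coarse    (n_samples,) int
    /labels/mid       (n_samples,) int
    /labels/fine      (n_samples,) int
    /meta             attrs: n_train, n_val, area_order, config_hash

The delimited layout (for small text fixtures) is a directory with one
``area_<name>.tsv`` per area (header row = voxel ids), a ``labels.tsv`` with
coarse/mid/fine columns, and a ``meta.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import AREA_ORDER, SimConfig, VoxelResponseSet

logger = logging.getLogger(__name__)

LABEL_LEVELS = ("coarse", "mid", "fine")


@dataclass
class Dataset:
    """In-memory dataset: per-area voxel responses, labels, fixed split."""

    voxels: dict[str, VoxelResponseSet]
    labels: dict[str, np.ndarray]
    n_train: int
    n_val: int
    area_order: tuple[str, ...] = AREA_ORDER
    meta: dict = field(default_factory=dict)

    @property
    def train_idx(self) -> np.ndarray:
        return np.arange(self.n_train)

    @property
    def val_idx(self) -> np.ndarray:
        return np.arange(self.n_train, self.n_train + self.n_val)

    def validate(self) -> None:
        n = self.n_train + self.n_val
        for area in self.area_order:
            if area not in self.voxels:
                raise ValueError(f"missing area {area!r}")
            if self.voxels[area].data.shape[0] != n:
                raise ValueError(f"area {area!r} has wrong sample count")
        for level in LABEL_LEVELS:
            if level not in self.labels or len(self.labels[level]) != n:
                raise ValueError(f"missing or malformed label level {level!r}")


def _drop_nonfinite(data: np.ndarray, ids: list[str], area: str):
    finite = np.isfinite(data).all(axis=0)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("dropping %d non-finite voxel(s) in area %s", n_bad, area)
    return data[:, finite], [i for i, ok in zip(ids, finite) if ok]


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.validate()
    with h5py.File(path, "w") as f:
        areas = f.create_group("areas")
        for area in dataset.area_order:
            vset = dataset.voxels[area]
            ds = areas.create_dataset(area, data=vset.data)
            ds.attrs["voxel_ids"] = [s.encode() for s in vset.voxel_ids]
        labels = f.create_group("labels")
        for level in LABEL_LEVELS:
            labels.create_dataset(level, data=np.asarray(dataset.labels[level], dtype=np.int64))
        meta = f.create_group("meta")
        meta.attrs["n_train"] = dataset.n_train
        meta.attrs["n_val"] = dataset.n_val
        meta.attrs["area_order"] = [a.encode() for a in dataset.area_order]
        for k, v in dataset.meta.items():
            meta.attrs[k] = v


def _load_hdf5(path: Path) -> Dataset:
    with h5py.File(path, "r") as f:
        for group in ("areas", "labels", "meta"):
            if group not in f:
                raise ValueError(f"malformed dataset {path}: missing group '/{group}'")
        meta = dict(f["meta"].attrs)
        area_order = tuple(
            a.decode() if isinstance(a, bytes) else str(a)
            for a in meta.pop("area_order")
        )
        voxels = {}
        for area in area_order:
            if area not in f["areas"]:
                raise ValueError(f"malformed dataset {path}: missing '/areas/{area}'")
            ds = f["areas"][area]
            ids = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in ds.attrs["voxel_ids"]
            ]
            data, ids = _drop_nonfinite(ds[()], ids, area)
            voxels[area] = VoxelResponseSet(area=area, data=data, voxel_ids=ids)
        labels = {}
        for level in LABEL_LEVELS:
            if level not in f["labels"]:
                raise ValueError(f"malformed dataset {path}: missing '/labels/{level}'")
            labels[level] = f["labels"][level][()]
        out = Dataset(
            voxels=voxels,
            labels=labels,
            n_train=int(meta.pop("n_train")),
            n_val=int(meta.pop("n_val")),
            area_order=area_order,
            meta=meta,
        )
    out.validate()
    return out


def save_dataset_delimited(dataset: Dataset, directory: str | Path) -> None:
    dataset.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for area in dataset.area_order:
        vset = dataset.voxels[area]
        pd.DataFrame(vset.data, columns=vset.voxel_ids).to_csv(
            directory / f"area_{area}.tsv", sep="\t", index=False
        )
    pd.DataFrame({lv: dataset.labels[lv] for lv in LABEL_LEVELS}).to_csv(
        directory / "labels.tsv", sep="\t", index=False
    )
    meta = {"n_train": dataset.n_train, "n_val": dataset.n_val,
            "area_order": list(dataset.area_order), **dataset.meta}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, default=str))


def _load_delimited(directory: Path) -> Dataset:
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"malformed dataset {directory}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    area_order = tuple(meta.pop("area_order"))
    voxels = {}
    for area in area_order:
        p = directory / f"area_{area}.tsv"
        if not p.exists():
            raise ValueError(f"malformed dataset {directory}: missing {p.name}")
        df = pd.read_csv(p, sep="\t")
        data, ids = _drop_nonfinite(df.to_numpy(float), list(df.columns), area)
        voxels[area] = VoxelResponseSet(area=area, data=data, voxel_ids=ids)
    labels_path = directory / "labels.tsv"
    if not labels_path.exists():
        raise ValueError(f"malformed dataset {directory}: missing labels.tsv")
    ldf = pd.read_csv(labels_path, sep="\t")
    for level in LABEL_LEVELS:
        if level not in ldf.columns:
            raise ValueError(f"malformed dataset {directory}: labels.tsv lacks column {level!r}")
    out = Dataset(
        voxels=voxels,
        labels={lv: ldf[lv].to_numpy() for lv in LABEL_LEVELS},
        n_train=int(meta.pop("n_train")),
        n_val=int(meta.pop("n_val")),
        area_order=area_order,
        meta=meta,
    )
    out.validate()
    return out


def load_dataset(path: str | Path, format: str = "hdf5") -> Dataset:
    """Load a dataset written by :func:`save_dataset` or its delimited twin.

    Voxel columns containing non-finite values are dropped with a logged
    count, mirroring how invalid voxels in real recordings are handled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "delimited":
        return _load_delimited(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class EncodingSettings:
    top_n: int = 200  # voxels averaged for layer selection
    n_select: int = 100  # voxels kept per area
    max_nonzeros: int | None = None
    residual_tol: float = 1e-4


@dataclass
class DecoderSettings:
    hidden_dim: int = 16
    dropout_rate: float = 0.5
    gamma: float = 5.0
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 200


@dataclass
class PipelineConfig:
    """Declarative configuration for the end-to-end pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    dataset_path: str | None = None  # overrides simulation when set
    dataset_format: str = "hdf5"
    encoding: EncodingSettings = field(default_factory=EncodingSettings)
    decoder: DecoderSettings = field(default_factory=DecoderSettings)
    methods: tuple[str, ...] = ("svm_linear", "nn", "brnn")
    levels: tuple[str, ...] = ("coarse",)
    repeat_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    output_dir: str = "cortexflow_output"

    def __post_init__(self) -> None:
        for level in self.levels:
            if level not in LABEL_LEVELS:
                raise ValueError(f"unknown label level {level!r}")
        if len(set(self.repeat_seeds)) != len(self.repeat_seeds):
            raise ValueError("repeat seeds must be distinct")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _from_mapping(cls, mapping: dict, where: str):
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**kwargs)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    sections = {}
    for name, cls in (("sim", SimConfig), ("encoding", EncodingSettings),
                      ("decoder", DecoderSettings)):
        if name in raw:
            sections[name] = _from_mapping(cls, raw.pop(name), name)
    return _from_mapping(
        PipelineConfig, {**raw, **sections}, "pipeline config"
    )
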