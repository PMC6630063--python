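"""Optional adapter for the public vim-1 natural-image fMRI release.

The vim-1 dataset (1750 training and 120 validation natural-image stimuli,
two subjects, voxel response amplitudes for areas V1-LO) must be downloaded
by the user from http://crcns.org/data-sets/vc/vim-1 after registration; it
is distributed as MATLAB containers and is never downloaded here.

Expected variables (per subject), following the release's EstimatedResponses
container:

* ``dataTrnS{1,2}``: (voxels, 1750) training response amplitudes
* ``dataValS{1,2}``: (voxels, 120) validation response amplitudes
* ``roiS{1,2}``: per-voxel ROI assignment (1..7; V1, V2, V3, V3A, V3B, V4, LO)

Mirrors differ in variable naming; the loader fails loudly when the expected
variables are absent.  vim-1 ships no category labels (labels were produced
by manual annotation), so labels must be supplied separately; by default the
loader fills the label arrays with -1 placeholders.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import Dataset
from .synthetic import AREA_ORDER, VoxelResponseSet

VIM1_URL = "http://crcns.org/data-sets/vc/vim-1"

# ROI codes in the release; V3A/V3B are not part of the five-area sequence
ROI_NAMES = {1: "V1", 2: "V2", 3: "V3", 4: "V3A", 5: "V3B", 6: "V4", 7: "LO"}

N_TRAIN = 1750
N_VAL = 120


def _read_container(path: Path) -> dict[str, np.ndarray]:
    """Read a MATLAB container (v7 via scipy, v7.3 via h5py)."""
    try:
        from scipy.io import loadmat

        raw = loadmat(path)
        return {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in f:
                out[k] = np.asarray(f[k])
        return out


def load_vim1(path: str | Path, subject: int = 1,
              labels: dict[str, np.ndarray] | None = None) -> Dataset:
    """Map a user-downloaded vim-1 response container to the internal dataset.

    ``path`` points at the EstimatedResponses MATLAB file.  Voxels with
    non-finite responses are dropped; the 1750/120 partition and the presence
    of all five areas are asserted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. Download the vim-1 release from {VIM1_URL} "
            "(registration required) and point at its EstimatedResponses file."
        )
    raw = _read_container(path)
    trn_key, val_key, roi_key = (f"dataTrnS{subject}", f"dataValS{subject}",
                                 f"roiS{subject}")
    missing = [k for k in (trn_key, val_key, roi_key) if k not in raw]
    if missing:
        raise KeyError(
            f"expected variables {missing} not present in {path.name}; "
            f"found {sorted(raw)}. Mirrors vary -- see {VIM1_URL}."
        )
    trn = np.asarray(raw[trn_key], dtype=float)
    val = np.asarray(raw[val_key], dtype=float)
    roi = np.asarray(raw[roi_key]).ravel()
    if trn.shape[0] != roi.size:  # stored voxels x samples
        trn, val = trn.T, val.T
    if trn.shape[1] != N_TRAIN or val.shape[1] != N_VAL:
        raise ValueError(
            f"expected {N_TRAIN}/{N_VAL} train/validation samples, got "
            f"{trn.shape[1]}/{val.shape[1]}"
        )
    voxels = {}
    for area in AREA_ORDER:
        code = next(c for c, n in ROI_NAMES.items() if n == area)
        sel = np.flatnonzero(roi == code)
        if sel.size == 0:
            raise ValueError(f"area {area} absent from ROI assignment")
        data = np.concatenate([trn[sel].T, val[sel].T], axis=0)
        finite = np.isfinite(data).all(axis=0)
        sel = sel[finite]
        voxels[area] = VoxelResponseSet(
            area=area,
            data=data[:, finite],
            voxel_ids=[f"{area}_{int(i):06d}" for i in sel],
        )
    n = N_TRAIN + N_VAL
    if labels is None:
        labels = {lv: np.full(n, -1, dtype=int) for lv in ("coarse", "mid", "fine")}
    return Dataset(voxels=voxels, labels=labels, n_train=N_TRAIN, n_val=N_VAL,
                   meta={"source": "vim-1", "subject": subject})
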