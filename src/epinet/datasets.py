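"""In-memory containers for BOLD and diffusion-weighted datasets, plus NIfTI I/O.

Tissue/ROI labels are coded in a single integer volume.  The default code
scheme distinguishes left/right gray matter, the left/right sensorimotor
seed ROIs (which are themselves gray matter), white matter and CSF:

====================  ====
name                  code
====================  ====
background            0
gm_left               1
gm_right              2
sm_left               3
sm_right              4
wm                    5
csf                   6
====================  ====
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_LABEL_CODES: dict[str, int] = {
    "gm_left": 1,
    "gm_right": 2,
    "sm_left": 3,
    "sm_right": 4,
    "wm": 5,
    "csf": 6,
}

#: label names per hemisphere (gray matter only; used for hemisphere masks)
HEMISPHERE_LABELS: dict[str, tuple[str, ...]] = {
    "left": ("gm_left", "sm_left"),
    "right": ("gm_right", "sm_right"),
}

GRAY_MATTER_LABELS: tuple[str, ...] = ("gm_left", "gm_right", "sm_left", "sm_right")


@dataclass
class BoldDataset:
    """Masked 4D BOLD time series with geometry and tissue labels.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal in arbitrary units.
    tr : float
        Repetition time in seconds.
    brain_mask : ndarray of bool, shape (x, y, z)
        Voxels that belong to the brain (any tissue class).
    labels : ndarray of int, shape (x, y, z)
        Tissue/ROI code per voxel; nonzero only inside ``brain_mask``.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    motion_params : ndarray, shape (t, 6), optional
        Three rotation and three translation parameters per frame.
    label_codes : dict
        Mapping from label name to integer code.
    meta : dict
        Free-form provenance (generation parameters, processing history).
    """

    data: np.ndarray
    tr: float
    brain_mask: np.ndarray
    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.5)
    motion_params: np.ndarray | None = None
    label_codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least two frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape does not match data")
        if not self.brain_mask.any():
            raise ValueError("empty brain mask")
        if np.any(self.labels[~self.brain_mask] != 0):
            raise ValueError("labels defined outside the brain mask")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.n_frames, 6):
                raise ValueError("motion_params must have shape (t, 6)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def mask_for(self, *names: str) -> np.ndarray:
        """Boolean volume selecting voxels whose label is any of `names`."""
        codes = [self.label_codes[n] for n in names]
        return np.isin(self.labels, codes) & self.brain_mask

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Gray-matter mask of one hemisphere ('left' or 'right')."""
        return self.mask_for(*HEMISPHERE_LABELS[side])

    def gray_matter_mask(self) -> np.ndarray:
        return self.mask_for(*GRAY_MATTER_LABELS)

    def series(self, mask: np.ndarray) -> np.ndarray:
        """Time-by-voxel matrix of the series under `mask` (C-order of voxels)."""
        return self.data[mask].T

    def mean_series(self, mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            raise ValueError("mask selects no voxels")
        return self.data[mask].mean(axis=0)

    def copy_with(self, data: np.ndarray, **meta_updates) -> "BoldDataset":
        """New dataset sharing geometry/labels, with replaced data and extended meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return BoldDataset(
            data=data,
            tr=self.tr,
            brain_mask=self.brain_mask,
            labels=self.labels,
            voxel_size=self.voxel_size,
            motion_params=self.motion_params,
            label_codes=dict(self.label_codes),
            meta=meta,
        )

    # ------------------------------------------------------------------ I/O
    def _affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def save(self, prefix: str | Path) -> None:
        """Write `<prefix>.nii.gz` (4D BOLD), `<prefix>_mask.nii.gz`,
        `<prefix>_labels.nii.gz`, optional `<prefix>_motion.txt`, and a JSON
        sidecar `<prefix>.json` echoing tr, voxel size, label codes and meta."""
        prefix = Path(prefix)
        aff = self._affine()
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), aff), str(prefix) + ".nii.gz")
        nib.save(
            nib.Nifti1Image(self.brain_mask.astype(np.uint8), aff),
            str(prefix) + "_mask.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), aff),
            str(prefix) + "_labels.nii.gz",
        )
        if self.motion_params is not None:
            np.savetxt(str(prefix) + "_motion.txt", self.motion_params)
        sidecar = {
            "tr": self.tr,
            "voxel_size": list(self.voxel_size),
            "label_codes": self.label_codes,
            "meta": _jsonable(self.meta),
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "BoldDataset":
        prefix = Path(prefix)
        img = nib.load(str(prefix) + ".nii.gz")
        mask = nib.load(str(prefix) + "_mask.nii.gz")
        labels = nib.load(str(prefix) + "_labels.nii.gz")
        sidecar = json.loads(Path(str(prefix) + ".json").read_text())
        motion = None
        motion_path = Path(str(prefix) + "_motion.txt")
        if motion_path.exists():
            motion = np.loadtxt(motion_path)
        return cls(
            data=np.asanyarray(img.dataobj, dtype=float),
            tr=float(sidecar["tr"]),
            brain_mask=np.asanyarray(mask.dataobj).astype(bool),
            labels=np.asanyarray(labels.dataobj).astype(int),
            voxel_size=tuple(sidecar["voxel_size"]),
            motion_params=motion,
            label_codes={k: int(v) for k, v in sidecar["label_codes"].items()},
            meta=sidecar.get("meta", {}),
        )


@dataclass
class DiffusionDataset:
    """Diffusion-weighted volumes with their gradient scheme.

    `signals` stacks all volumes (diffusion-weighted and b=0) along the last
    axis; `bvecs[i]` / `bvals[i]` describe volume i.  b=0 volumes carry a zero
    b-value (their direction is ignored).
    """

    signals: np.ndarray
    bvecs: np.ndarray
    bvals: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4D (x, y, z, volumes)")
        n = self.signals.shape[3]
        if self.bvecs.shape != (n, 3) or self.bvals.shape != (n,):
            raise ValueError("bvecs/bvals do not match the number of volumes")
        if self.mask.shape != self.signals.shape[:3]:
            raise ValueError("mask shape does not match signals")
        if np.any(self.signals < 0):
            raise ValueError("signals must be nonnegative")
        if not np.any(self.bvals == 0):
            raise ValueError("need at least one b=0 volume")
        dw = self.bvals > 0
        if _n_noncollinear(self.bvecs[dw]) < 6:
            raise ValueError("need >= 6 unique non-collinear diffusion directions")

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[3]

    def save(self, prefix: str | Path) -> None:
        """Write `<prefix>.nii.gz`, `<prefix>_mask.nii.gz` and FSL-style
        `<prefix>.bvec` / `<prefix>.bval` (3 rows / 1 row of n columns)."""
        prefix = Path(prefix)
        aff = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.signals.astype(np.float32), aff), str(prefix) + ".nii.gz")
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff), str(prefix) + "_mask.nii.gz")
        np.savetxt(str(prefix) + ".bvec", self.bvecs.T, fmt="%.8f")
        np.savetxt(str(prefix) + ".bval", self.bvals[None, :], fmt="%.4f")
        if self.meta:
            Path(str(prefix) + ".json").write_text(json.dumps(_jsonable(self.meta), indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "DiffusionDataset":
        prefix = Path(prefix)
        img = nib.load(str(prefix) + ".nii.gz")
        mask = nib.load(str(prefix) + "_mask.nii.gz")
        bvecs = np.loadtxt(str(prefix) + ".bvec").T
        bvals = np.atleast_1d(np.loadtxt(str(prefix) + ".bval")).ravel()
        meta = {}
        sidecar = Path(str(prefix) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        zooms = img.header.get_zooms()[:3]
        return cls(
            signals=np.asanyarray(img.dataobj, dtype=float),
            bvecs=bvecs,
            bvals=bvals,
            mask=np.asanyarray(mask.dataobj).astype(bool),
            voxel_size=tuple(float(z) for z in zooms),
            meta=meta,
        )


def _n_noncollinear(vecs: np.ndarray, tol: float = 1e-6) -> int:
    """Count directions that are pairwise distinct up to sign."""
    kept: list[np.ndarray] = []
    for v in vecs:
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        u = v / nv
        if all(abs(u @ k) < 1 - tol for k in kept):
            kept.append(u)
    return len(kept)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
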