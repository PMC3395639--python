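"""Diffusion tensor estimation and scalar maps (FA, ADC trace, axial/radial).

The tensor is estimated per voxel by log-linear least squares on the
monoexponential model ``ln S = ln S0 - b g^T D g`` over the six unique
tensor elements plus ln S0.  Scalar maps follow from the eigensystem with
eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3):

* FA       = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||
* ADC trace = lambda1 + lambda2 + lambda3 (the trace, not mean diffusivity)
* axial    = lambda1
* radial   = (lambda2 + lambda3) / 2
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epinet.datasets import DiffusionDataset

logger = logging.getLogger(__name__)

#: nonpositive signals are clamped to this fraction of S0 before the log
SIGNAL_FLOOR_FRACTION = 1e-6


@dataclass
class TensorFit:
    """Per-voxel fitted diffusion tensors inside the mask."""

    tensors: np.ndarray  # (x, y, z, 3, 3), mm^2/s
    s0: np.ndarray  # fitted S0 per voxel
    mask: np.ndarray
    invalid: np.ndarray  # voxels where the fit is unusable
    clamped: np.ndarray  # voxels where nonpositive signals were floored
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)


@dataclass
class TensorScalarMaps:
    """Scalar maps derived from the tensor eigensystem."""

    fa: np.ndarray
    adc_trace: np.ndarray
    axial: np.ndarray
    radial: np.ndarray
    eigenvalues: np.ndarray  # (..., 3) sorted descending
    mask: np.ndarray
    invalid: np.ndarray
    negative_clipped: np.ndarray = field(default=None)

    @property
    def mean_diffusivity(self) -> np.ndarray:
        """Trace / 3, for consumers who prefer MD over the plain trace."""
        return self.adc_trace / 3.0


def _design_matrix(bvecs: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    g = bvecs
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _elements_to_tensors(el: np.ndarray) -> np.ndarray:
    """(..., 6) ordering (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) -> (..., 3, 3)."""
    out = np.empty(el.shape[:-1] + (3, 3))
    out[..., 0, 0] = el[..., 0]
    out[..., 1, 1] = el[..., 1]
    out[..., 2, 2] = el[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = el[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = el[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = el[..., 5]
    return out


def fit_tensor(ds: DiffusionDataset) -> TensorFit:
    """Log-linear least-squares tensor fit per masked voxel.

    Nonpositive signals are clamped to ``1e-6 * S0`` before the log and the
    voxel flagged; voxels with nonpositive S0 (mean of the b=0 volumes) are
    flagged invalid and get a zero tensor.
    """
    if ds.n_volumes < 7:
        raise ValueError("need at least 7 volumes (6 directions + b0) to fit a tensor")
    if not np.any(ds.bvals > 0):
        raise ValueError("no diffusion encoding: all volumes are b=0")
    design = _design_matrix(ds.bvecs, ds.bvals)
    pinv = np.linalg.pinv(design)

    sig = ds.signals[ds.mask]  # V x n_volumes
    s0 = ds.signals[..., ds.bvals == 0].mean(axis=-1)
    s0_masked = s0[ds.mask]
    invalid_flat = ~(s0_masked > 0) | ~np.isfinite(sig).all(axis=1)

    floor = SIGNAL_FLOOR_FRACTION * np.where(s0_masked > 0, s0_masked, 1.0)
    clamped_flat = (sig <= 0).any(axis=1) & ~invalid_flat
    sig_safe = np.maximum(sig, floor[:, None])
    coeffs = np.log(sig_safe) @ pinv.T  # V x 7
    tensors_flat = _elements_to_tensors(coeffs[:, 1:])
    tensors_flat[invalid_flat] = 0.0

    shape = ds.signals.shape[:3]
    tensors = np.zeros(shape + (3, 3))
    tensors[ds.mask] = tensors_flat
    invalid = np.zeros(shape, dtype=bool)
    invalid[ds.mask] = invalid_flat
    clamped = np.zeros(shape, dtype=bool)
    clamped[ds.mask] = clamped_flat
    if invalid_flat.any():
        logger.warning("%d voxel(s) with unusable signal flagged invalid", invalid_flat.sum())
    s0_fit = np.zeros(shape)
    s0_fit[ds.mask] = np.exp(coeffs[:, 0])
    return TensorFit(
        tensors=tensors,
        s0=s0_fit,
        mask=ds.mask,
        invalid=invalid,
        clamped=clamped,
        voxel_size=ds.voxel_size,
    )


def scalar_maps(fit: "TensorFit | np.ndarray", mask: np.ndarray | None = None) -> TensorScalarMaps:
    """FA, ADC trace, axial and radial diffusivity from fitted tensors.

    Negative eigenvalues (noise artifacts) are clipped to zero before the
    FA computation, with a per-voxel flag.  All-zero tensors get FA = 0.
    """
    if isinstance(fit, TensorFit):
        tensors = fit.tensors
        mask = fit.mask
        invalid = fit.invalid
    else:
        tensors = np.asarray(fit, dtype=float)
        if mask is None:
            mask = np.ones(tensors.shape[:-2], dtype=bool)
        invalid = np.zeros(tensors.shape[:-2], dtype=bool)

    evals = np.linalg.eigvalsh(tensors)[..., ::-1]  # sorted descending
    negative = (evals < 0).any(axis=-1) & mask
    evals_clipped = np.clip(evals, 0.0, None)

    lam_bar = evals_clipped.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals_clipped - lam_bar) ** 2).sum(axis=-1))
    den = np.sqrt((evals_clipped**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(np.nan_to_num(fa, nan=0.0), 0.0, 1.0)

    adc_trace = evals_clipped.sum(axis=-1)
    axial = evals_clipped[..., 0]
    radial = evals_clipped[..., 1:].mean(axis=-1)
    outside = ~mask
    for arr in (fa, adc_trace, axial, radial):
        arr[outside] = 0.0
    return TensorScalarMaps(
        fa=fa,
        adc_trace=adc_trace,
        axial=axial,
        radial=radial,
        eigenvalues=evals_clipped,
        mask=mask,
        invalid=invalid,
        negative_clipped=negative,
    )


def roi_summary(maps: TensorScalarMaps, roi_mask: np.ndarray) -> pd.Series:
    """Mean FA / ADC trace / axial / radial over valid ROI voxels.

    Invalid voxels are excluded and counted.  Raises on an empty ROI.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    usable = roi_mask & maps.mask & ~maps.invalid
    n_total = int(np.count_nonzero(roi_mask & maps.mask))
    if n_total == 0:
        raise ValueError("empty ROI (no voxels inside the mask)")
    if not usable.any():
        raise ValueError("no valid voxels in ROI")
    return pd.Series(
        {
            "fa": float(maps.fa[usable].mean()),
            "adc_trace": float(maps.adc_trace[usable].mean()),
            "axial": float(maps.axial[usable].mean()),
            "radial": float(maps.radial[usable].mean()),
            "n_voxels": n_total,
            "n_excluded": n_total - int(np.count_nonzero(usable)),
        }
    )


def fa_from_eigenvalues(eigenvalues) -> float:
    """Closed-form FA of a single eigenvalue triple (convenience)."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam_bar = lam.mean()
    den = np.sqrt((lam**2).sum())
    if den == 0:
        return 0.0
    return float(np.sqrt(1.5) * np.sqrt(((lam - lam_bar) ** 2).sum()) / den)


def radial_for_fa(fa: float, axial: float) -> float:
    """Radial diffusivity r such that eigenvalues (axial, r, r) have the given FA."""
    from scipy.optimize import brentq

    if not 0 <= fa < 1:
        raise ValueError("fa must lie in [0, 1)")
    if fa == 0:
        return axial
    return float(brentq(lambda r: fa_from_eigenvalues((axial, r, r)) - fa, 0.0, axial))
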