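"""BOLD denoising chain: spatial smoothing, temporal band-pass, nuisance regression.

The canonical order is smooth -> bandpass -> nuisance regression; the
convenience wrapper :func:`run_preprocess` applies it and records every
stage's parameters in the dataset's ``meta``.  Nuisance regressors are
band-pass filtered with the same filter as the data before regression, so
the regression cannot reintroduce out-of-band variance.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage, signal

from epinet.datasets import BoldDataset

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def smooth(ds: BoldDataset, fwhm_mm: float) -> BoldDataset:
    """Per-frame Gaussian spatial smoothing within the brain mask.

    The kernel standard deviation is ``fwhm / (2 sqrt(2 ln 2))`` converted to
    voxel units per axis.  Outside-mask voxels do not leak into the mask:
    the data are smoothed mask-weighted and renormalized by the smoothed
    mask, so edge voxels are not diluted by zeros.  ``fwhm_mm = 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return ds.copy_with(ds.data.copy(), smooth_fwhm_mm=0.0)
    sigma_vox = tuple(fwhm_mm * FWHM_TO_SIGMA / vs for vs in ds.voxel_size)
    mask = ds.brain_mask.astype(float)
    sm_mask = ndimage.gaussian_filter(mask, sigma=sigma_vox)
    # single 4D pass (sigma 0 along time) instead of one call per frame
    weighted = ndimage.gaussian_filter(
        ds.data * mask[..., None], sigma=sigma_vox + (0.0,)
    )
    out = np.zeros_like(ds.data)
    inside = ds.brain_mask
    out[inside] = weighted[inside] / sm_mask[inside, None]
    return ds.copy_with(out, smooth_fwhm_mm=float(fwhm_mm))


def bandpass(ds: BoldDataset, low_hz: float, high_hz: float, order: int = 2) -> BoldDataset:
    """Voxel-wise zero-phase Butterworth band-pass filtering.

    Forward-backward (filtfilt) application avoids phase lag that would
    distort correlations.  ``low_hz = 0`` degenerates to a low-pass filter.
    """
    nyquist = 0.5 / ds.tr
    if not 0 <= low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 <= low < high < Nyquist {nyquist:g} Hz"
        )
    sos = _design_filter(low_hz, high_hz, ds.tr, order)
    out = np.zeros_like(ds.data)
    series = ds.data[ds.brain_mask]
    out[ds.brain_mask] = signal.sosfiltfilt(sos, series, axis=-1)
    return ds.copy_with(out, bandpass_hz=(float(low_hz), float(high_hz)), filter_order=order)


def _design_filter(low_hz: float, high_hz: float, tr: float, order: int):
    nyquist = 0.5 / tr
    if low_hz == 0:
        return signal.butter(order, high_hz / nyquist, btype="lowpass", output="sos")
    return signal.butter(
        order, [low_hz / nyquist, high_hz / nyquist], btype="bandpass", output="sos"
    )


def _drop_dependent_columns(x: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (rank-revealing QR), warn when any go."""
    if x.shape[1] == 0:
        return x
    _, r, piv = _qr_pivoted(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < x.shape[1]:
        keep = np.sort(piv[:rank])
        logger.warning(
            "nuisance design rank-deficient: dropping %d dependent column(s)",
            x.shape[1] - rank,
        )
        return x[:, keep]
    return x


def _qr_pivoted(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def nuisance_regress(ds: BoldDataset, regressors: np.ndarray) -> BoldDataset:
    """Remove nuisance signals from every voxel by ordinary least squares.

    An intercept column is always included, so the output is mean-centered;
    residuals are orthogonal to every (retained) regressor column.  Linearly
    dependent columns are dropped with a warning.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ds.n_frames:
        raise ValueError("regressors must have one row per frame")
    if regressors.shape[1] < 1:
        raise ValueError("need at least one regressor column")
    design = np.column_stack([np.ones(ds.n_frames), regressors])
    design = _drop_dependent_columns(design)
    series = ds.data[ds.brain_mask].T  # t x V
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    resid = series - design @ beta
    out = np.zeros_like(ds.data)
    out[ds.brain_mask] = resid.T
    return ds.copy_with(out, nuisance_columns=design.shape[1])


def build_nuisance(ds: BoldDataset, include_global: bool = True) -> np.ndarray:
    """Standard nuisance design: global, WM and CSF mean series + motion.

    Column order: [global whole-brain mean (optional), WM mean, CSF mean,
    motion params (t x 6) when present].  A missing WM or CSF label omits
    that column with a warning.  Global-signal regression is standard but
    is known to induce anti-correlations when the signal of interest
    dominates the global mean; hence the switch.
    """
    cols = [ds.mean_series(ds.brain_mask)] if include_global else []
    for name in ("wm", "csf"):
        m = ds.mask_for(name)
        if m.any():
            cols.append(ds.mean_series(m))
        else:
            logger.warning("no %s voxels labelled; omitting its nuisance column", name)
    if not cols:
        raise ValueError("no nuisance columns available")
    design = np.column_stack(cols)
    if ds.motion_params is not None:
        design = np.column_stack([design, ds.motion_params])
    return design


def run_preprocess(
    ds: BoldDataset,
    fwhm_mm: float = 1.0,
    band_hz: tuple[float, float] = (0.01, 0.1),
    regress_nuisance: bool = True,
    filter_regressors: bool = True,
    global_regressor: bool = True,
) -> BoldDataset:
    """Full chain smooth -> bandpass -> nuisance regression.

    Nuisance regressors are built from the smoothed, filtered data; motion
    parameters (if present) are band-pass filtered with the same filter
    when ``filter_regressors`` is set.
    """
    out = smooth(ds, fwhm_mm)
    out = bandpass(out, *band_hz)
    if regress_nuisance:
        design = build_nuisance(out, include_global=global_regressor)
        if filter_regressors and ds.motion_params is not None:
            sos = _design_filter(band_hz[0], band_hz[1], ds.tr, 2)
            n_motion = ds.motion_params.shape[1]
            design[:, -n_motion:] = signal.sosfiltfilt(
                sos, design[:, -n_motion:], axis=0
            )
        out = nuisance_regress(out, design)
    out.meta["preprocess_order"] = ["smooth", "bandpass", "nuisance_regress"][
        : 3 if regress_nuisance else 2
    ]
    return out
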