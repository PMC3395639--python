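"""Voxel-level weight matrices and ROI-based functional-connectivity measures.

Functional connectivity is the Pearson correlation between BOLD series,
variance-stabilized by the Fisher z' transform (``z' = arctanh r``).  For
the graph analysis, negative correlations are set to zero and the diagonal
is zero; ROI-level measures (interhemispheric z', seed maps) keep the sign,
since anti-correlations are themselves of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from epinet.datasets import GRAY_MATTER_LABELS, BoldDataset

logger = logging.getLogger(__name__)

#: correlations of magnitude 1 are clamped to +/- arctanh(1 - CLAMP_EPS)
CLAMP_EPS = 1e-7
Z_CLAMP = float(np.arctanh(1.0 - CLAMP_EPS))


def fisher_z(r):
    """Fisher z' transform of a correlation: ``z' = arctanh(r)``.

    Values with ``|r| = 1`` (within 1e-12) are clamped to
    ``+/- arctanh(1 - 1e-7)`` with a warning, so coherent noiseless series
    yield a large finite weight instead of infinity.  No degrees-of-freedom
    scaling is applied: thresholds like z' > 0.15 are on the plain arctanh
    scale.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    clipped = np.clip(r, -1.0, 1.0)
    n_clamped = int(np.sum(np.abs(clipped) > 1 - CLAMP_EPS))
    if n_clamped:
        logger.warning("clamping %d correlation(s) at |r| ~ 1", n_clamped)
        clipped = np.clip(clipped, -(1 - CLAMP_EPS), 1 - CLAMP_EPS)
    z = np.arctanh(clipped)
    return float(z) if z.ndim == 0 else z


@dataclass
class WeightMatrix:
    """Symmetric nonnegative V x V functional-connection weights (z' scale).

    ``w[i, i] = 0``; negative correlations have been zeroed.  Row order is
    the C-order of voxels under the selecting mask.
    """

    w: np.ndarray
    voxel_index: np.ndarray  # (V, 3) voxel coordinates per row
    source_labels: np.ndarray  # label code per row
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("w must be square")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("w must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, k=1)))

    def save_edgelist(self, path) -> None:
        """Plain-text edge list: `i j weight` per line (upper triangle)."""
        ii, jj = np.nonzero(np.triu(self.w, k=1))
        with open(path, "w") as fh:
            fh.write(f"# nodes {self.n_nodes}\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i} {j} {self.w[i, j]:.10g}\n")


@dataclass
class ConnectivityMap:
    """Per-voxel Fisher-z map against a seed ROI's mean signal."""

    z: np.ndarray  # volume, defined on mask voxels (NaN elsewhere)
    seed_label: str
    threshold: float = 0.15
    mask: np.ndarray | None = None

    def suprathreshold(self) -> np.ndarray:
        """Boolean volume of voxels with z' strictly above the threshold."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.z, nan=-np.inf) > self.threshold


def build_weight_matrix(
    ds: BoldDataset,
    include_labels: tuple[str, ...] = GRAY_MATTER_LABELS,
    max_nodes: int | None = None,
) -> WeightMatrix:
    """Weighted functional network over the selected (gray-matter) voxels.

    ``w_ij = max(0, arctanh(pearson(series_i, series_j)))`` for i != j,
    with the diagonal at zero.  Zero-variance voxel series get a zero
    row/column (with a warning) rather than being dropped, so V stays
    comparable across scans.  ``max_nodes`` keeps every k-th voxel (evenly
    spaced in C-order, hence balanced across hemisphere blocks) when the
    full voxel count would be too expensive downstream.
    """
    mask = ds.mask_for(*include_labels)
    keep = np.ones(int(mask.sum()), dtype=bool)
    if max_nodes is not None and mask.sum() > max_nodes:
        sel = np.unique(np.linspace(0, mask.sum() - 1, max_nodes).round().astype(int))
        keep[:] = False
        keep[sel] = True
    series = ds.data[mask][keep]  # V x t
    v = series.shape[0]
    if v < 2:
        raise ValueError("need at least two voxels to build a network")
    sd = series.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance voxel series; zeroing their edges", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(series)
    r[np.isnan(r)] = 0.0  # rows for zero-variance series
    np.fill_diagonal(r, 0.0)
    w = fisher_z(r)
    w[w < 0] = 0.0
    w[degenerate, :] = 0.0
    w[:, degenerate] = 0.0
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)  # exact symmetry against fp asymmetry in corrcoef
    return WeightMatrix(
        w=w,
        voxel_index=np.argwhere(mask)[keep],
        source_labels=ds.labels[mask][keep],
        meta={"include_labels": list(include_labels), "clamp": Z_CLAMP},
    )


def seed_map(ds: BoldDataset, seed_label: str, threshold: float = 0.15) -> ConnectivityMap:
    """Fisher-z map of every brain voxel against the seed ROI mean signal.

    Seed voxels are included in the map.  The map carries the display /
    volume threshold (strict ``z' > threshold``).
    """
    seed_mask = ds.mask_for(seed_label)
    if not seed_mask.any():
        raise ValueError(f"seed label {seed_label!r} selects no voxels")
    seed = ds.mean_series(seed_mask)
    series = ds.data[ds.brain_mask]
    r = _corr_with(seed, series)
    zvol = np.full(ds.brain_mask.shape, np.nan)
    zvol[ds.brain_mask] = fisher_z(r)
    return ConnectivityMap(z=zvol, seed_label=seed_label, threshold=threshold, mask=ds.brain_mask)


def interhemispheric_fc(ds: BoldDataset, left_label: str = "sm_left", right_label: str = "sm_right") -> float:
    """Fisher z' between the left and right ROI mean time series.

    May be negative: interhemispheric anti-correlations are meaningful and
    are not zeroed here (unlike graph edges).
    """
    left = ds.mask_for(left_label)
    right = ds.mask_for(right_label)
    if not left.any() or not right.any():
        raise ValueError("both ROIs must be nonempty")
    r = _corr_with(ds.mean_series(left), ds.mean_series(right)[None, :])[0]
    return float(fisher_z(r))


def intrahemispheric_volume(
    ds: BoldDataset,
    seed_label: str,
    hemisphere: str,
    threshold: float = 0.15,
    include_seed: bool = True,
) -> float:
    """Volume (mm^3) of same-hemisphere voxels correlating with the seed.

    Counts gray-matter voxels of the given hemisphere whose Fisher z'
    against the seed ROI mean exceeds ``threshold`` (strict), multiplied by
    the voxel volume.  The seed's own voxels are counted by default.
    """
    hemi_mask = ds.hemisphere_mask(hemisphere)
    if not hemi_mask.any():
        raise ValueError(f"hemisphere {hemisphere!r} is empty")
    cmap = seed_map(ds, seed_label, threshold)
    supra = cmap.suprathreshold() & hemi_mask
    if not include_seed:
        supra &= ~ds.mask_for(seed_label)
    return float(np.count_nonzero(supra)) * ds.voxel_volume


def _corr_with(ref: np.ndarray, series: np.ndarray) -> np.ndarray:
    """Pearson r of each row of `series` (V x t) with the 1D `ref`."""
    ref_c = ref - ref.mean()
    s_c = series - series.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(s_c, axis=1) * np.linalg.norm(ref_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s_c @ ref_c) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)
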