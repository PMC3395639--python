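"""Synthetic BOLD and DWI generators with known, planted statistical structure.

The BOLD generator emulates a rodent resting-state acquisition: two
hemisphere blocks of gray matter, each containing a sensorimotor seed ROI,
plus white-matter and CSF compartments.  Coherent low-frequency
(0.01-0.1 Hz by default) fluctuations are planted via shared band-limited
latent signals:

* every sensorimotor voxel in hemisphere ``h`` is
  ``sqrt(intra) * u_h + sqrt(1 - intra) * e_v`` with ``corr(u_L, u_R) =
  inter_corr``, so the within-ROI voxel-pair correlation is ``intra_corr``
  and the cross-hemisphere ROI correlation is ``intra * inter`` per voxel
  pair (the ROI *mean* correlation approaches ``inter_corr`` as the ROI
  grows and noise averages out);
* background gray matter couples to its hemisphere's seed latent with a
  reduced loading ``bg_coupling * intra_corr``, so seed-based connectivity
  spreads beyond the ROI in a way that scales with the planted
  intra-hemispheric coupling;
* white matter and CSF are driven by their own independent latents, giving
  nuisance regression real structure to remove;
* independent white Gaussian noise of standard deviation ``noise_sd`` is
  added on top.

Latents are random mixtures of the exactly orthonormal Fourier basis of
the passband.  When the number of latent components does not exceed the
dimension of that band-limited subspace (twice the number of passband
frequency bins) the mixtures are taken orthonormal, so for
``noise_sd = 0`` the *sample* voxel-pair correlation matrix equals the
planted one exactly (see :func:`planted_correlation`), not merely in
expectation; beyond that dimension the latents are independent draws and
planted correlations hold in expectation only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from epinet.datasets import DEFAULT_LABEL_CODES, BoldDataset, DiffusionDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- BOLD
@dataclass
class BoldSimConfig:
    """Parameters of the planted BOLD model.

    Defaults follow the emulated acquisition: 1200 frames at TR 0.5 s
    (10 min), ~2000 gray-matter voxels across both hemispheres, coherent
    fluctuations restricted to 0.01-0.1 Hz.
    """

    n_voxels_per_hemisphere: int = 1000
    n_frames: int = 1200
    tr: float = 0.5
    roi_fraction: float = 0.3
    inter_corr: float = 0.6
    intra_corr: float = 0.6
    noise_sd: float = 1.0
    osc_band: tuple[float, float] = (0.01, 0.1)
    seed: int = 0
    #: loading of background gray matter on the hemisphere seed latent,
    #: as a fraction of intra_corr
    bg_coupling: float = 0.5
    n_wm_voxels: int | None = None
    n_csf_voxels: int | None = None
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.5)
    with_motion: bool = True

    def validate(self) -> None:
        if self.n_voxels_per_hemisphere < 1:
            raise ValueError("need at least one voxel per hemisphere")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.roi_fraction <= 1:
            raise ValueError("roi_fraction must lie in (0, 1]")
        if abs(self.inter_corr) > 1:
            raise ValueError("|inter_corr| must be <= 1")
        if not 0 <= self.intra_corr <= 1:
            raise ValueError("intra_corr must lie in [0, 1]")
        if not 0 <= self.bg_coupling <= 1:
            raise ValueError("bg_coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        low, high = self.osc_band
        nyquist = 0.5 / self.tr
        if not 0 < low < high < nyquist:
            raise ValueError(
                f"osc_band must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
            )
        # latent covariance [[1, rho], [rho, 1]] must be positive semidefinite;
        # with |rho| <= 1 the mixing construction below guarantees it
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def wm_voxels(self) -> int:
        if self.n_wm_voxels is not None:
            return self.n_wm_voxels
        return max(8, self.n_voxels_per_hemisphere // 8)

    @property
    def csf_voxels(self) -> int:
        if self.n_csf_voxels is not None:
            return self.n_csf_voxels
        return max(8, self.n_voxels_per_hemisphere // 8)


def _bandlimited_components(
    rng: np.random.Generator,
    n_components: int,
    n_frames: int,
    tr: float,
    band: tuple[float, float],
) -> np.ndarray:
    """(n_frames, n_components) zero-mean band-limited series.

    White Gaussian series are restricted to the band in the frequency
    domain.  If the number of components fits into the time dimension the
    set is orthonormalized so sample correlations between components are
    exactly zero; otherwise each column is only standardized.
    """
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    nyq_bin = n_frames // 2 if n_frames % 2 == 0 else None
    keep = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0))
    if nyq_bin is not None:
        keep = keep[keep != nyq_bin]
    if keep.size == 0:
        # too few frames to resolve the band: fall back to the nearest
        # usable nonzero-frequency bin so the latent is still oscillatory
        center = 0.5 * (band[0] + band[1])
        usable = np.arange(1, (n_frames - 1) // 2 + 1)
        keep = np.array([usable[np.argmin(np.abs(freqs[usable] - center))]])
        logger.warning("osc_band unresolvable at n_frames=%d; using nearest bin", n_frames)

    # exactly orthonormal, exactly zero-mean Fourier basis of the passband
    t_idx = np.arange(n_frames)
    phase = 2 * np.pi * np.outer(t_idx, keep) / n_frames
    basis = np.empty((n_frames, 2 * keep.size))
    basis[:, 0::2] = np.cos(phase) * math.sqrt(2.0 / n_frames)
    basis[:, 1::2] = np.sin(phase) * math.sqrt(2.0 / n_frames)

    m = basis.shape[1]
    if n_components <= m:
        # random orthonormal mixtures: sample correlations are exactly zero
        g = rng.standard_normal((m, n_components))
        q, r = np.linalg.qr(g)
        q = q * np.sign(np.diag(r))
        return basis @ q * math.sqrt(n_frames)
    # more components than the band subspace can hold orthogonally:
    # independent random mixtures, standardized (correlations ~ O(1/sqrt(m)))
    logger.debug(
        "band subspace dim %d < %d components; latents only approximately orthogonal",
        m,
        n_components,
    )
    sig = basis @ rng.standard_normal((m, n_components))
    return sig / sig.std(axis=0)


def _hemisphere_layout(config: BoldSimConfig) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Label volume for both hemisphere blocks; left block at low x."""
    n_vox = config.n_voxels_per_hemisphere
    n_roi = max(1, round(config.roi_fraction * n_vox))
    wm_l = config.wm_voxels // 2
    wm_r = config.wm_voxels - wm_l
    csf_l = config.csf_voxels // 2
    csf_r = config.csf_voxels - csf_l
    total_l = n_vox + wm_l + csf_l
    total_r = n_vox + wm_r + csf_r
    total = max(total_l, total_r)
    nz = max(1, round(total ** (1 / 3)))
    ny = max(1, math.ceil(math.sqrt(total / nz)))
    nx_h = math.ceil(total / (ny * nz))

    c = DEFAULT_LABEL_CODES
    left_codes = np.concatenate(
        [
            np.full(n_roi, c["sm_left"]),
            np.full(n_vox - n_roi, c["gm_left"]),
            np.full(wm_l, c["wm"]),
            np.full(csf_l, c["csf"]),
        ]
    )
    right_codes = np.concatenate(
        [
            np.full(n_roi, c["sm_right"]),
            np.full(n_vox - n_roi, c["gm_right"]),
            np.full(wm_r, c["wm"]),
            np.full(csf_r, c["csf"]),
        ]
    )
    labels = np.zeros((2 * nx_h, ny, nz), dtype=np.int16)
    left = np.zeros(nx_h * ny * nz, dtype=np.int16)
    left[: left_codes.size] = left_codes
    right = np.zeros(nx_h * ny * nz, dtype=np.int16)
    right[: right_codes.size] = right_codes
    labels[:nx_h] = left.reshape(nx_h, ny, nz)
    # mirror the right block in x so the two ROIs sit homotopically
    labels[nx_h:] = right.reshape(nx_h, ny, nz)[::-1]
    return labels, (2 * nx_h, ny, nz)


def generate_bold(config: BoldSimConfig) -> BoldDataset:
    """Simulate a masked 4D BOLD dataset with planted connectivity.

    Deterministic for a fixed ``config.seed``.  The full configuration is
    echoed into ``dataset.meta`` (and hence into the JSON sidecar on save).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, shape = _hemisphere_layout(config)
    mask = labels > 0
    c = DEFAULT_LABEL_CODES

    flat_labels = labels[mask]  # C-order of masked voxels
    n_masked = flat_labels.size
    # per-voxel loading on its hemisphere seed latent
    loading = np.zeros(n_masked)
    a_bg = config.bg_coupling * config.intra_corr
    loading[flat_labels == c["sm_left"]] = math.sqrt(config.intra_corr)
    loading[flat_labels == c["sm_right"]] = math.sqrt(config.intra_corr)
    loading[flat_labels == c["gm_left"]] = math.sqrt(a_bg)
    loading[flat_labels == c["gm_right"]] = math.sqrt(a_bg)
    is_left = np.isin(flat_labels, [c["sm_left"], c["gm_left"]])
    is_right = np.isin(flat_labels, [c["sm_right"], c["gm_right"]])
    is_wm = flat_labels == c["wm"]
    is_csf = flat_labels == c["csf"]

    # latent components: 2 seed drivers, 2 tissue drivers, 1 deviation per voxel
    n_components = 4 + n_masked
    latents = _bandlimited_components(
        rng, n_components, config.n_frames, config.tr, config.osc_band
    )
    z1, z2, g_wm, g_csf = latents[:, 0], latents[:, 1], latents[:, 2], latents[:, 3]
    deviations = latents[:, 4:]
    rho = config.inter_corr
    u_left = z1
    u_right = rho * z1 + math.sqrt(max(0.0, 1 - rho**2)) * z2

    t = config.n_frames
    shared = np.zeros((n_masked, t))
    shared[is_left] = u_left
    shared[is_right] = u_right
    shared[is_wm] = g_wm
    shared[is_csf] = g_csf
    load = loading.copy()
    load[is_wm | is_csf] = math.sqrt(0.5)
    series = load[:, None] * shared + np.sqrt(1 - load**2)[:, None] * deviations.T
    if config.noise_sd > 0:
        series += config.noise_sd * rng.standard_normal((n_masked, t))

    data = np.zeros(shape + (t,))
    data[mask] = series

    motion = None
    if config.with_motion:
        steps = rng.standard_normal((t, 6))
        motion = np.cumsum(steps, axis=0)
        motion[:, :3] *= 2e-3  # radians
        motion[:, 3:] *= 2e-2  # mm

    return BoldDataset(
        data=data,
        tr=config.tr,
        brain_mask=mask,
        labels=labels,
        voxel_size=config.voxel_size,
        motion_params=motion,
        meta={"generator": "epinet.synthetic.generate_bold", "config": _config_dict(config)},
    )


def planted_correlation(ds: BoldDataset) -> np.ndarray:
    """Planted gray-matter voxel-pair correlation matrix of a generated dataset.

    Rows/columns follow the C-order of voxels under ``ds.gray_matter_mask()``,
    i.e. the ordering of ``ds.series(ds.gray_matter_mask())``.  Valid in the
    noise-free limit; with noise the observed correlations are attenuated by
    ``1 / (1 + noise_sd**2)``.
    """
    cfg = ds.meta.get("config")
    if cfg is None:
        raise ValueError("dataset carries no generator configuration")
    gm = ds.gray_matter_mask()
    flat = ds.labels[gm]
    c = ds.label_codes
    intra = cfg["intra_corr"]
    a_bg = cfg["bg_coupling"] * intra
    loading = np.where(np.isin(flat, [c["sm_left"], c["sm_right"]]), math.sqrt(intra), math.sqrt(a_bg))
    left = np.isin(flat, [c["sm_left"], c["gm_left"]])
    hemi = np.where(left[:, None] == left[None, :], 1.0, cfg["inter_corr"])
    corr = np.outer(loading, loading) * hemi
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------- DWI
@dataclass
class DwiSimConfig:
    """Parameters of the monoexponential tensor-model DWI simulation.

    The noiseless signal follows ``S = S0 * exp(-b * g^T D g)`` per voxel
    and gradient direction, with a spherical scheme of ``n_directions``
    unique directions (electrostatic repulsion) at the default
    b = 1184.33 s/mm^2, plus ``n_b0`` non-diffusion-weighted volumes.
    """

    grid_shape: tuple[int, int, int]
    tensors: np.ndarray = None  # (x, y, z, 3, 3), mm^2/s
    s0: float | np.ndarray = 1000.0
    b_value: float = 1184.33
    n_directions: int = 50
    n_b0: int = 2
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    bvecs: np.ndarray | None = None
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(self.grid_shape)
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape != shape + (3, 3):
            raise ValueError("tensors must have shape grid_shape + (3, 3)")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2), atol=1e-12):
            raise ValueError("tensors must be symmetric")
        evals = np.linalg.eigvalsh(self.tensors.reshape(-1, 3, 3))
        if np.any(evals < -1e-12):
            raise ValueError("tensors must have nonnegative eigenvalues")
        s0 = np.asarray(self.s0, dtype=float)
        if np.any(s0 <= 0):
            raise ValueError("s0 must be positive")
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 volume")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def generate_dwi(config: DwiSimConfig) -> DiffusionDataset:
    """Simulate a DWI dataset from known per-voxel diffusion tensors."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    if config.bvecs is not None:
        dirs = np.asarray(config.bvecs, dtype=float)
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1) > 1e-8):
            raise ValueError("provided bvecs must be unit-norm")
    else:
        dirs = electrostatic_directions(config.n_directions, seed=config.seed)

    s0 = np.broadcast_to(np.asarray(config.s0, dtype=float), shape)
    # apparent diffusion coefficient along each direction: g^T D g
    adc = np.einsum("...ij,dj,di->...d", config.tensors, dirs, dirs)
    dw = s0[..., None] * np.exp(-config.b_value * adc)
    b0 = np.repeat(s0[..., None], config.n_b0, axis=-1)
    signals = np.concatenate([b0, dw], axis=-1)

    if config.noise_sd > 0:
        if config.noise_model == "rician":
            n1 = config.noise_sd * rng.standard_normal(signals.shape)
            n2 = config.noise_sd * rng.standard_normal(signals.shape)
            signals = np.sqrt((signals + n1) ** 2 + n2**2)
        else:
            signals = signals + config.noise_sd * rng.standard_normal(signals.shape)
            signals = np.clip(signals, 0.0, None)

    bvecs = np.vstack([np.zeros((config.n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(config.n_b0), np.full(len(dirs), config.b_value)])
    mask = config.mask if config.mask is not None else np.ones(shape, dtype=bool)
    return DiffusionDataset(
        signals=signals,
        bvecs=bvecs,
        bvals=bvals,
        mask=mask,
        voxel_size=config.voxel_size,
        meta={"generator": "epinet.synthetic.generate_dwi", "config": _config_dict(config)},
    )


def tensor_from_eigenvalues(
    eigenvalues: tuple[float, float, float],
    principal_axis: np.ndarray | tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """3x3 symmetric tensor with given eigenvalues, largest along `principal_axis`."""
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.stack([e1, e2, e3], axis=1)
    lam = np.asarray(sorted(eigenvalues, reverse=True), dtype=float)
    return basis @ np.diag(lam) @ basis.T


# ------------------------------------------------- gradient-direction design
def _coulomb_energy_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """Antipodally-symmetric Coulomb energy and gradient w.r.t. free vectors."""
    pts = x.reshape(n, 3)
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    u = pts / norms
    dminus = u[:, None, :] - u[None, :, :]
    dplus = u[:, None, :] + u[None, :, :]
    rm = np.linalg.norm(dminus, axis=2)
    rp = np.linalg.norm(dplus, axis=2)
    iu = np.triu_indices(n, k=1)
    energy = float(np.sum(1.0 / rm[iu]) + np.sum(1.0 / rp[iu]))
    np.fill_diagonal(rm, np.inf)
    np.fill_diagonal(rp, np.inf)
    # dE/du_i over all pairs (the i==j antipodal self-term is constant: |2u|=2)
    g_u = -np.sum(dminus / rm[..., None] ** 3, axis=1) - np.sum(
        dplus / rp[..., None] ** 3, axis=1
    )
    # project onto the tangent of the sphere and undo the normalization
    g_x = (g_u - u * np.sum(g_u * u, axis=1, keepdims=True)) / norms
    return energy, g_x.ravel()


def electrostatic_directions(n: int, iters: int = 500, seed: int = 0) -> np.ndarray:
    """`n` unit vectors locally minimizing antipodal Coulomb repulsion energy.

    Charges interact as the pair set {+g, -g} (the standard DWI convention,
    since diffusion encoding is symmetric under gradient sign).  The result
    is deterministic for a fixed seed.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    res = minimize(
        _coulomb_energy_grad,
        x0.ravel(),
        args=(n,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": iters},
    )
    pts = res.x.reshape(n, 3)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def coulomb_energy(directions: np.ndarray) -> float:
    """Antipodally-symmetric Coulomb energy of a unit-vector set."""
    n = len(directions)
    e, _ = _coulomb_energy_grad(np.asarray(directions, dtype=float).ravel(), n)
    return e


def _config_dict(config) -> dict:
    out = {}
    for k, v in vars(config).items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist() if v.size <= 64 else f"array{v.shape}"
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out
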