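"""Weighted graph metrics with surrogate normalization.

Segregation is measured by the Onnela weighted clustering coefficient and
integration by the harmonic-mean characteristic path length (the inverse of
global efficiency, so disconnected pairs contribute zero rather than
infinity).  Both are normalized by their means over degree-preserving
Maslov-Sneppen surrogate networks, yielding gamma = C / <C_surr> and
lambda = L / <L_surr>; gamma, lambda ~ 1 indicates random-like topology,
both >> 1 a regular, lattice-like one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from epinet.connectivity import WeightMatrix

logger = logging.getLogger(__name__)


@dataclass
class NetworkSummary:
    """Clustering, path length, surrogate means and normalized metrics for one scan."""

    C: float
    L: float
    C_surr_mean: float
    L_surr_mean: float
    gamma: float
    lambda_: float
    n_surrogates: int
    seed: int
    C_surr: np.ndarray = field(default_factory=lambda: np.array([]))
    L_surr: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self.L,
            "C_surr_mean": self.C_surr_mean,
            "L_surr_mean": self.L_surr_mean,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "n_surrogates": self.n_surrogates,
            "seed": self.seed,
            "C_surr_sd": float(np.std(self.C_surr, ddof=1)) if len(self.C_surr) > 1 else None,
            "L_surr_sd": float(np.std(self.L_surr, ddof=1)) if len(self.L_surr) > 1 else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_weight_array(w) -> np.ndarray:
    if isinstance(w, WeightMatrix):
        return w.w
    return np.asarray(w, dtype=float)


def clustering_weighted(w, include_all_nodes: bool = False) -> tuple[float, np.ndarray]:
    """Onnela weighted clustering coefficient.

    Weights are first normalized by the network maximum, ``w_hat = w /
    max(w)``; then

        C_i = 1 / (k_i (k_i - 1)) * sum_{j != h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3)

    with binary degree ``k_i``.  Nodes with ``k_i < 2`` get ``C_i = 0``.
    The scalar C averages C_i over nodes with ``k_i >= 2`` (nodes that can
    participate in a triangle); set ``include_all_nodes`` to average over
    every node, zeros included.

    Returns ``(C, C_i)``.
    """
    w = _as_weight_array(w)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        logger.warning("all-zero weight matrix: clustering defined as 0")
        return 0.0, np.zeros(n)
    w_hat = w / wmax
    cube = np.cbrt(w_hat)
    # number of closed triangles (weighted, geometric-mean) through each node
    triangles = np.einsum("ij,jk,ki->i", cube, cube, cube)
    k = np.count_nonzero(w > 0, axis=1)
    c_i = np.zeros(n)
    can = k >= 2
    c_i[can] = triangles[can] / (k[can] * (k[can] - 1))
    if include_all_nodes:
        c = float(c_i.mean())
    else:
        c = float(c_i[can].mean()) if can.any() else 0.0
    return c, c_i


def path_length_harmonic(
    w, length_transform: str = "inverse"
) -> tuple[float, np.ndarray]:
    """Harmonic-mean characteristic path length over weighted geodesics.

    Edge lengths are ``1 / w_ij`` (strong connections are short; the
    convention of the global-efficiency literature), or ``1 - w / max(w)``
    with ``length_transform='one_minus'``.  Geodesic distances d_ij come
    from Dijkstra per source; then

        L = [ 1 / (N (N - 1)) * sum_{i != j} 1 / d_ij ]^(-1)

    with ``1 / inf -> 0``, so disconnected pairs lower, rather than
    destroy, the average.  L is infinite only when every pair is
    disconnected.

    Returns ``(L, d)`` with the full V x V distance matrix.
    """
    w = _as_weight_array(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("path length needs at least two nodes")
    ii, jj = np.nonzero(np.triu(w, k=1))
    if length_transform == "inverse":
        lengths = 1.0 / w[ii, jj]
    elif length_transform == "one_minus":
        wmax = w.max()
        if wmax == 0:
            lengths = np.array([])
        else:
            lengths = 1.0 - w[ii, jj] / wmax
    else:
        raise ValueError("length_transform must be 'inverse' or 'one_minus'")
    graph = csr_matrix((lengths, (ii, jj)), shape=(n, n))
    d = dijkstra(graph, directed=False)
    off = ~np.eye(n, dtype=bool)
    d_off = d[off]
    inv = np.where(np.isinf(d_off), 0.0, 1.0 / np.maximum(d_off, 1e-300))
    mean_inv = inv.mean()
    length = float(1.0 / mean_inv) if mean_inv > 0 else float("inf")
    return length, d


def rewire_surrogate(
    w,
    n_swaps: int | None = None,
    seed: int = 0,
    shuffle_weights: bool = False,
) -> "WeightMatrix | np.ndarray":
    """Degree-preserving Maslov-Sneppen surrogate of a weighted network.

    Performs double-edge swaps on the binary topology: edges (a, b) and
    (c, d) become (a, d) and (c, b) when no self-loop or multi-edge would
    arise.  Each rewired edge carries its original weight, so the binary
    degree sequence and the weight multiset are both preserved exactly.
    With ``shuffle_weights`` the topology is kept and only the weights are
    permuted over the existing edges instead.

    ``n_swaps`` accepted swaps are attempted (default ``10 * n_edges``);
    if no valid swap exists (e.g. a star graph) the input is returned
    unchanged with a warning.
    """
    arr = _as_weight_array(w)
    n = arr.shape[0]
    ii, jj = np.nonzero(np.triu(arr, k=1))
    n_edges = len(ii)
    if n_edges < 2:
        logger.warning("fewer than two edges: surrogate equals input")
        return _rewrap(w, arr.copy())
    rng = np.random.default_rng(seed)

    if shuffle_weights:
        weights = arr[ii, jj]
        perm = rng.permutation(n_edges)
        out = np.zeros_like(arr)
        out[ii, jj] = weights[perm]
        out[jj, ii] = weights[perm]
        return _rewrap(w, out)

    if n_swaps is None:
        n_swaps = 10 * n_edges
    if n_edges == n * (n - 1) // 2:
        logger.warning("complete graph: no degree-preserving swap exists; "
                       "surrogate equals input")
        return _rewrap(w, arr.copy())
    edges = [tuple(e) for e in np.stack([ii, jj], axis=1)]
    weights = arr[ii, jj].copy()
    present = set(edges)
    accepted = 0
    attempts = 0
    max_attempts = max(20 * n_swaps, 1000)
    # draw randomness in chunks; the swap loop itself must stay sequential
    chunk = max(1024, min(n_swaps, 1 << 16))
    buf_e = np.empty((0, 2), dtype=np.int64)
    buf_o = np.empty(0, dtype=np.int64)
    pos = 0
    while accepted < n_swaps and attempts < max_attempts:
        if pos >= len(buf_o):
            buf_e = rng.integers(0, n_edges, size=(chunk, 2))
            buf_o = rng.integers(0, 2, size=chunk)
            pos = 0
        e1, e2 = buf_e[pos]
        orient = buf_o[pos]
        pos += 1
        attempts += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if orient:
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if a == c or a == d or b == c or b == d:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in present or new2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        accepted += 1
    if accepted == 0:
        logger.warning("no valid degree-preserving swap exists; surrogate equals input")
        return _rewrap(w, arr.copy())
    if accepted < n_swaps:
        logger.debug("accepted %d of %d requested swaps (dense graph)", accepted, n_swaps)
    earr = np.asarray(edges)
    out = np.zeros_like(arr)
    out[earr[:, 0], earr[:, 1]] = weights
    out[earr[:, 1], earr[:, 0]] = weights
    return _rewrap(w, out)


def _rewrap(original, arr: np.ndarray):
    if isinstance(original, WeightMatrix):
        return WeightMatrix(
            w=arr,
            voxel_index=original.voxel_index,
            source_labels=original.source_labels,
            meta=dict(original.meta, surrogate=True),
        )
    return arr


def normalize(
    w,
    n_surrogates: int = 100,
    seed: int = 0,
    length_transform: str = "inverse",
    include_all_nodes: bool = False,
    shuffle_weights: bool = False,
    n_swaps: int | None = None,
) -> NetworkSummary:
    """Surrogate-normalized clustering and path length for one network.

    gamma = C / mean_s C(surrogate_s), lambda = L / mean_s L(surrogate_s)
    over ``n_surrogates`` independent Maslov-Sneppen rewirings (default
    100).  Per-surrogate values are retained for dispersion reporting.
    Deterministic for a fixed seed (one spawned seed per surrogate).
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    c, _ = clustering_weighted(w, include_all_nodes=include_all_nodes)
    length, _ = path_length_harmonic(w, length_transform=length_transform)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_surrogates)
    c_surr = np.empty(n_surrogates)
    l_surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        surr = rewire_surrogate(w, n_swaps=n_swaps, seed=int(child_seeds[s]),
                                shuffle_weights=shuffle_weights)
        c_surr[s], _ = clustering_weighted(surr, include_all_nodes=include_all_nodes)
        l_surr[s], _ = path_length_harmonic(surr, length_transform=length_transform)
    c_mean = float(c_surr.mean())
    l_mean = float(l_surr.mean())
    if c_mean == 0 or l_mean == 0 or not np.isfinite(l_mean):
        raise ValueError("degenerate surrogate mean; cannot normalize")
    return NetworkSummary(
        C=c,
        L=length,
        C_surr_mean=c_mean,
        L_surr_mean=l_mean,
        gamma=c / c_mean,
        lambda_=length / l_mean,
        n_surrogates=n_surrogates,
        seed=seed,
        C_surr=c_surr,
        L_surr=l_surr,
    )
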