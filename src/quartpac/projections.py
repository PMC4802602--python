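"""The two R³→R remappings that feed the linear clustering test.

The global route embeds all Cα positions on a line by minimizing the
normalized stress

    σ₁ = sqrt( Σ_{i≠j} (δ_ij − d_ij(X))² / Σ_{i≠j} d_ij(X)² )

with δ the 3D distances and d the 1D distances; the induced rank order is
the residue arrangement.  The local route instead orders residues along a
heuristic shortest open Hamiltonian path through the Cα graph (min_π Σ
d(i, π(i))), so only nearby residues influence each other's placement.
Both arrangements are mutation-blind: they depend only on the distance
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmc import (
    BlankStructureError,
    ClusterRecord,
    find_linear_clusters,
    order_statistics,
)

__all__ = [
    "Embedding1D",
    "TourOrder",
    "stress",
    "mds_embed",
    "tsp_order",
    "run_ipac",
    "run_graphpac",
    "LinearScanResult",
]


@dataclass
class Embedding1D:
    coords: np.ndarray  # one real per residue, global-index order
    stress: float
    rank_order: np.ndarray  # permutation of 0..N-1: residue index at each slot


@dataclass
class TourOrder:
    path: np.ndarray  # permutation of 0..N-1, visit order
    path_length: float


@dataclass
class LinearScanResult:
    method: str
    clusters: list[ClusterRecord]
    min_p: float | None
    n: int
    N: int
    outcome: str  # "clustering" | "no_clustering" | "blank"
    arrangement: np.ndarray | None = None


def stress(coords: np.ndarray, dm: np.ndarray) -> float:
    """Normalized 1D embedding stress σ₁ (sums over ordered pairs i≠j)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != dm.shape[0]:
        raise ValueError("coords length must match distance matrix dimension")
    d1 = np.abs(coords[:, None] - coords[None, :])
    denom = (d1 ** 2).sum()
    if denom == 0.0:
        raise ValueError("all 1D coordinates identical: stress undefined")
    num = ((dm - d1) ** 2).sum() - np.trace((dm - d1) ** 2)  # exclude i == j
    # diagonal of both matrices is zero, so the trace term vanishes; keep the
    # subtraction for clarity with non-validated input
    return float(np.sqrt(num / denom))


def _classical_start(dm: np.ndarray) -> np.ndarray:
    """First principal coordinate of classical (Torgerson) scaling."""
    d2 = dm ** 2
    n = dm.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    lead = np.argmax(vals)
    return vecs[:, lead] * np.sqrt(max(vals[lead], 0.0))


def _majorize_1d(dm: np.ndarray, x0: np.ndarray, max_iter: int,
                 tol: float) -> np.ndarray:
    """SMACOF-style Guttman updates for a 1D configuration (unit weights)."""
    n = dm.shape[0]
    x = x0 - x0.mean()
    d1 = np.abs(x[:, None] - x[None, :])
    raw = ((dm - d1) ** 2).sum() / 2.0
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d1 > 0, dm / d1, 0.0)
        np.fill_diagonal(ratio, 0.0)
        # Guttman transform: x_new_i = (1/n) Σ_j ratio_ij (x_i - x_j) + mean
        row = ratio.sum(axis=1)
        x_new = (row * x - ratio @ x) / n
        x_new -= x_new.mean()
        d1 = np.abs(x_new[:, None] - x_new[None, :])
        raw_new = ((dm - d1) ** 2).sum() / 2.0
        if raw > 0 and abs(raw - raw_new) / max(raw, 1e-300) < tol:
            x = x_new
            break
        x = x_new
        raw = raw_new
    return x


def _sigma1_rescale(x: np.ndarray, dm: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale the configuration to minimize σ₁ (optimal c = Σδ²/Σδd)."""
    d1 = np.abs(x[:, None] - x[None, :])
    a = (dm ** 2).sum()
    b = (dm * d1).sum()
    c2 = (d1 ** 2).sum()
    if b <= 0 or c2 <= 0:
        return x, float("inf")
    scale = a / b
    xs = x * scale
    s1 = float(np.sqrt(max(0.0, 1.0 - b * b / (a * c2))))
    return xs, s1


def mds_embed(dm: np.ndarray, seed: int = 0, restarts: int = 5,
              max_iter: int = 300, tol: float = 1e-6) -> Embedding1D:
    """Best-of-restarts 1D metric MDS by stress majorization.

    One classical-scaling start plus ``restarts - 1`` seeded random starts;
    the returned configuration is rescaled to its σ₁-optimal scale.  Rank
    ties are broken by the original global index, so the induced arrangement
    is always a strict order.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least two residues to embed")
    rng = np.random.default_rng(seed)
    scale = dm.max() if dm.max() > 0 else 1.0
    starts = [_classical_start(dm)]
    for _ in range(max(0, restarts - 1)):
        starts.append(rng.normal(0.0, scale / 4.0, size=n))
    best_x, best_s = None, np.inf
    for x0 in starts:
        if np.allclose(x0, x0[0]):
            x0 = x0 + rng.normal(0.0, 1e-6, size=n)
        x = _majorize_1d(dm, x0, max_iter=max_iter, tol=tol)
        if np.allclose(x, x[0]):
            continue
        xs, s1 = _sigma1_rescale(x, dm)
        if s1 < best_s:
            best_x, best_s = xs, s1
    if best_x is None:
        raise ValueError("stress majorization degenerated on every start")
    order = np.lexsort((np.arange(n), best_x))  # stable: ties by index
    return Embedding1D(coords=best_x, stress=best_s, rank_order=order)


def _nearest_neighbor_path(dm: np.ndarray, start: int = 0) -> np.ndarray:
    n = dm.shape[0]
    visited = np.zeros(n, dtype=bool)
    path = np.empty(n, dtype=int)
    path[0] = start
    visited[start] = True
    cur = start
    for t in range(1, n):
        d = dm[cur].copy()
        d[visited] = np.inf
        cur = int(np.argmin(d))  # ties -> lowest index
        path[t] = cur
        visited[cur] = True
    return path


def _cheapest_insertion_path(dm: np.ndarray) -> np.ndarray:
    n = dm.shape[0]
    if n == 2:
        return np.array([0, 1])
    # start from the globally closest pair (lowest-index tie-break)
    masked = dm + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    i0, j0 = np.unravel_index(np.argmin(masked), dm.shape)
    path = [min(i0, j0), max(i0, j0)]
    remaining = [v for v in range(n) if v not in path]
    while remaining:
        best = None  # (cost, vertex, slot)
        for v in remaining:
            # insertion at either end
            cand = [(dm[v, path[0]], v, 0), (dm[v, path[-1]], v, len(path))]
            seg = dm[v, path[:-1]] + dm[v, path[1:]] - dm[path[:-1], path[1:]]
            s = int(np.argmin(seg))
            cand.append((float(seg[s]), v, s + 1))
            c = min(cand, key=lambda t: (t[0], t[1], t[2]))
            if best is None or (c[0], c[1]) < (best[0], best[1]):
                best = c
        path.insert(best[2], best[1])
        remaining.remove(best[1])
    return np.array(path)


def _path_length(dm: np.ndarray, path: np.ndarray) -> float:
    return float(dm[path[:-1], path[1:]].sum())


def _two_opt(dm: np.ndarray, path: np.ndarray,
             max_moves: int | None = None) -> np.ndarray:
    """Best-improvement 2-opt refinement of an open path.

    Reversing path[i..j] only swaps the two boundary edges, so the gain of
    every (i, j) move is evaluated as one vectorized n×n computation.
    """
    path = path.copy()
    n = len(path)
    if max_moves is None:
        max_moves = 20 * n
    big = dm.max() * (n + 1) + 1.0
    for _ in range(max_moves):
        p = path
        # prev[i] = d(path[i-1], path[i]) with a free (zero-cost) virtual
        # endpoint before the first and after the last vertex
        d_prev = np.concatenate(([0.0], dm[p[:-1], p[1:]]))  # edge into slot i
        d_next = np.concatenate((dm[p[:-1], p[1:]], [0.0]))  # edge out of slot j
        # new left edge: d(path[i-1], path[j]); new right: d(path[i], path[j+1])
        left = np.zeros((n, n))
        left[1:, :] = dm[p[:-1]][:, p]  # left[i, j] = d(path[i-1], path[j])
        right = np.zeros((n, n))
        right[:, :-1] = dm[p][:, p[1:]]  # right[i, j] = d(path[i], path[j+1])
        delta = (left + right) - (d_prev[:, None] + d_next[None, :])
        iu = np.triu_indices(n, k=1)
        deltas = np.full((n, n), big)
        deltas[iu] = delta[iu]
        i, j = np.unravel_index(np.argmin(deltas), deltas.shape)
        if deltas[i, j] >= -1e-9:
            break
        path[i:j + 1] = path[i:j + 1][::-1]
    return path


def tsp_order(dm: np.ndarray, heuristic: str = "two_opt_refined",
              seed: int = 0) -> TourOrder:
    """Heuristic shortest open Hamiltonian path through the Cα graph.

    Heuristics: ``nearest_neighbor`` (start at residue 1),
    ``cheapest_insertion``, and the default ``two_opt_refined``
    (nearest-neighbor start + 2-opt segment reversal; never longer than the
    unrefined start).  Deterministic for a given heuristic and seed.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least two residues")
    if heuristic == "nearest_neighbor":
        path = _nearest_neighbor_path(dm)
    elif heuristic == "cheapest_insertion":
        path = _cheapest_insertion_path(dm)
    elif heuristic == "two_opt_refined":
        path = _two_opt(dm, _nearest_neighbor_path(dm))
    else:
        raise ValueError(f"unknown TSP heuristic {heuristic!r}")
    return TourOrder(path=path, path_length=_path_length(dm, path))


def _scan_arrangement(
    arrangement: np.ndarray,
    structure,
    mapped,
    alpha: float,
    method_tag: str,
    pvalue_method: str = "auto",
) -> LinearScanResult:
    """Run the linear span test on residues rearranged by `arrangement`
    (array of 0-based residue indices in slot order)."""
    N = structure.n_residues
    residues = structure.residues
    slot_of = np.empty(N, dtype=int)
    slot_of[arrangement] = np.arange(1, N + 1)
    if mapped.is_blank:
        return LinearScanResult(method=method_tag, clusters=[], min_p=None,
                                n=mapped.n, N=N, outcome="blank")
    slots = [int(slot_of[p - 1]) for p in mapped.positions]
    om = order_statistics(slots, N_eff=N)

    def serial_of(slot: int) -> int:
        return residues[int(arrangement[slot - 1])].atom_serial

    clusters, min_p = find_linear_clusters(om, serial_of, alpha=alpha,
                                           method=pvalue_method, tag=method_tag)
    outcome = "clustering" if min_p <= alpha else "no_clustering"
    return LinearScanResult(method=method_tag, clusters=clusters, min_p=min_p,
                            n=om.n, N=N, outcome=outcome,
                            arrangement=arrangement)


def run_ipac(structure, mapped, alpha: float = 0.05, seed: int = 0,
             dm: np.ndarray | None = None, restarts: int = 5,
             pvalue_method: str = "auto",
             embedding: Embedding1D | None = None) -> LinearScanResult:
    """Global-MDS arrangement followed by the linear clustering scan.

    A precomputed ``embedding`` (mutation-blind) may be passed to amortize
    the MDS cost over many mutation draws on the same structure.
    """
    from .structures import distance_matrix

    if dm is None:
        dm = distance_matrix(structure)
    if embedding is None:
        embedding = mds_embed(dm, seed=seed, restarts=restarts)
    return _scan_arrangement(embedding.rank_order, structure, mapped, alpha,
                             "ipac", pvalue_method)


def run_graphpac(structure, mapped, alpha: float = 0.05, seed: int = 0,
                 dm: np.ndarray | None = None,
                 heuristic: str = "two_opt_refined",
                 pvalue_method: str = "auto",
                 tour: TourOrder | None = None) -> LinearScanResult:
    """TSP-path arrangement followed by the linear clustering scan."""
    from .structures import distance_matrix

    if dm is None:
        dm = distance_matrix(structure)
    if tour is None:
        tour = tsp_order(dm, heuristic=heuristic, seed=seed)
    return _scan_arrangement(tour.path, structure, mapped, alpha,
                             "graphpac", pvalue_method)
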