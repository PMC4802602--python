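"""Direct 3D hotspot detection by optimal sphere covering.

For sphere counts s ∈ {1,2,3} and radii r ∈ {1..10} Å, find the s spheres
(centered on mutated Cα positions) with pairwise-disjoint covered-mutation
sets that jointly cover the most mutations.  The observed coverages X_0,s,r
are compared against T Monte-Carlo replicates in which the n mutations are
re-assigned iid-uniformly over all N residues:

    μ_s,r = mean_i X_i,s,r ,  σ_s,r = sd_i X_i,s,r      (i = 1..T)
    Z_i   = max_{s,r} (X_i,s,r − μ_s,r) / σ_s,r
    p     = 1 − #{i : Z_0 > Z_i} / T

One p-value is produced per structure run regardless of how many (s, r)
cells exist.  Cells with σ = 0 (saturated coverage) are excluded from the
max; when every cell is excluded the p-value is 1.

Two optimizers coexist: an exhaustive search over distinct covered sets
(used for the observed data, with deterministic tie-breaks) and a pruned
bitset engine compiled with numba for the simulation inner loop.  Both are
globally optimal; tests cross-check them against brute force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit

__all__ = [
    "SphereHotspot",
    "NullSimulation",
    "SpacePacResult",
    "sphere_coverage",
    "best_spheres",
    "simulate_null",
    "spacepac_pvalue",
    "run_spacepac",
]

DEFAULT_RADII = tuple(range(1, 11))
DEFAULT_SPHERES = (1, 2, 3)


@dataclass
class SphereHotspot:
    center_serial: int
    center_global_index: int
    radius: float
    mutation_count: int


@dataclass
class NullSimulation:
    X: np.ndarray          # (T+1, |S|, |R|); row 0 = observed
    mu: np.ndarray         # (|S|, |R|) over rows 1..T
    sigma: np.ndarray      # (|S|, |R|) sample sd over rows 1..T
    Z: np.ndarray          # (T+1,)
    T: int
    seed: int
    spheres: tuple[int, ...]
    radii: tuple[float, ...]
    n: int
    N: int
    observed_positions: np.ndarray


@dataclass
class SpacePacResult:
    p_value: float
    p_label: str            # e.g. "<1.00E-03" when Z0 beats every replicate
    hotspots: list[SphereHotspot]
    best_s: int
    best_radius: float
    outcome: str            # "clustering" | "no_clustering" | "blank"
    min_p: float | None
    sim: NullSimulation | None = None


def sphere_coverage(dm: np.ndarray, center: int, radius: float,
                    mapped) -> int:
    """Mutations (with multiplicity) on residues within `radius` Å of the
    center residue's Cα; the center's own mutations count."""
    if not (1 <= center <= dm.shape[0]):
        raise ValueError(f"center {center} outside 1..{dm.shape[0]}")
    pos = np.asarray(mapped.positions, dtype=int)
    if pos.size == 0:
        return 0
    return int((dm[center - 1, pos - 1] <= radius).sum())


def _covered_sets(dm: np.ndarray, positions: np.ndarray, radius: float,
                  candidates: np.ndarray):
    """Distinct covered-mutation index sets per candidate center.

    Returns (sets, counts, representative-centers); representative is the
    lowest candidate global index realizing the set.
    """
    cover = dm[np.ix_(candidates - 1, positions - 1)] <= radius  # (u, n)
    sets: dict[bytes, int] = {}
    reps: list[int] = []
    masks: list[np.ndarray] = []
    for row, center in zip(cover, candidates):
        key = row.tobytes()
        if key not in sets:
            sets[key] = len(reps)
            reps.append(int(center))
            masks.append(row)
    return masks, [int(m.sum()) for m in masks], reps


def best_spheres(
    dm: np.ndarray,
    mapped,
    s: int,
    radius: float,
    candidates: str = "mutated",
) -> tuple[list[SphereHotspot], int, bool]:
    """Optimal s non-overlapping spheres of the given radius.

    "Non-overlapping" means disjoint covered-mutation sets (the summed
    quantity).  Candidate centers default to mutated residues; pass
    ``candidates="all"`` to scan every residue.  Exhaustive over distinct
    covered sets, hence globally optimal; ties broken by (total coverage
    desc, center tuple asc).  Returns (hotspots, total_coverage,
    achieved_fewer) where the flag marks the degenerate case of fewer than
    s mutually disjoint nonempty sets.
    """
    if s not in (1, 2, 3):
        raise ValueError("sphere count s must be 1, 2 or 3")
    positions = np.asarray(sorted(mapped.positions), dtype=int)
    serial_by_gidx = getattr(mapped, "serial_by_gidx", None)
    if positions.size == 0:
        return [], 0, s > 0
    if candidates == "mutated":
        cand = np.unique(positions)
    elif candidates == "all":
        cand = np.arange(1, dm.shape[0] + 1)
    else:
        raise ValueError("candidates must be 'mutated' or 'all'")
    masks, counts, reps = _covered_sets(dm, positions, radius, cand)
    k = len(masks)
    nonempty = [i for i in range(k) if counts[i] > 0]

    best_total = -1
    best_combo: tuple[int, ...] | None = None
    achieved_fewer = False
    # order candidates by (coverage desc, center asc) so the first optimal
    # combination encountered is the canonical tie-break winner
    order = sorted(nonempty, key=lambda i: (-counts[i], reps[i]))
    for m in range(s, 0, -1):
        for combo in combinations(order, m):
            union = masks[combo[0]].copy()
            total = counts[combo[0]]
            ok = True
            for idx in combo[1:]:
                if (union & masks[idx]).any():
                    ok = False
                    break
                union |= masks[idx]
                total += counts[idx]
            if not ok:
                continue
            centers = tuple(sorted(reps[i] for i in combo))
            if total > best_total or (
                    total == best_total and best_combo is not None
                    and centers < best_combo):
                best_total = total
                best_combo = centers
        if best_combo is not None:
            achieved_fewer = m < s
            break
    if best_combo is None:
        return [], 0, True
    hotspots = []
    rep_count = {reps[i]: counts[i] for i in nonempty}
    for center in best_combo:
        serial = serial_by_gidx[center] if serial_by_gidx else center
        hotspots.append(SphereHotspot(center_serial=int(serial),
                                      center_global_index=int(center),
                                      radius=float(radius),
                                      mutation_count=rep_count[center]))
    return hotspots, int(best_total), achieved_fewer


@njit(cache=False)
def _best123(bits, pops):  # pragma: no cover - compiled
    """Max total coverage of 1, 2 and 3 pairwise-disjoint bitset rows.

    bits: (k, w) uint64 packed covered sets sorted by pop desc; pops: (k,).
    Returns (best1, best2, best3).
    """
    k, w = bits.shape
    best1 = 0
    for i in range(k):
        if pops[i] > best1:
            best1 = pops[i]
    best2 = 0
    for i in range(k - 1):
        if pops[i] + pops[i + 1] <= best2:
            break  # sorted: no later pair can beat it
        for j in range(i + 1, k):
            t = pops[i] + pops[j]
            if t <= best2:
                break
            disjoint = True
            for q in range(w):
                if bits[i, q] & bits[j, q]:
                    disjoint = False
                    break
            if disjoint:
                best2 = t
    best3 = 0
    for i in range(k - 2):
        if pops[i] + pops[i + 1] + pops[i + 2] <= best3:
            break
        for j in range(i + 1, k - 1):
            if pops[i] + pops[j] + pops[j + 1] <= best3:
                break
            dij = True
            for q in range(w):
                if bits[i, q] & bits[j, q]:
                    dij = False
                    break
            if not dij:
                continue
            for l in range(j + 1, k):
                t = pops[i] + pops[j] + pops[l]
                if t <= best3:
                    break
                disjoint = True
                for q in range(w):
                    if (bits[i, q] | bits[j, q]) & bits[l, q]:
                        disjoint = False
                        break
                if disjoint:
                    best3 = t
    return best1, best2, best3


def _pack_rows(cover: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dedupe boolean rows and pack into uint64 words sorted by pop desc."""
    uniq = np.unique(cover, axis=0)
    pops = uniq.sum(axis=1).astype(np.int64)
    keep = pops > 0
    uniq, pops = uniq[keep], pops[keep]
    order = np.argsort(-pops, kind="stable")
    uniq, pops = uniq[order], pops[order]
    packed8 = np.packbits(uniq, axis=1)
    w8 = packed8.shape[1]
    pad = (-w8) % 8
    if pad:
        packed8 = np.pad(packed8, ((0, 0), (0, pad)))
    bits = packed8.view(np.uint64).reshape(len(uniq), -1) if len(uniq) else \
        np.zeros((0, 1), dtype=np.uint64)
    return np.ascontiguousarray(bits), pops


def _coverage_row(dm: np.ndarray, positions: np.ndarray,
                  radii, spheres) -> np.ndarray:
    """X[s, r] best coverages for one mutation assignment (any s in 1..3)."""
    cand = np.unique(positions)
    sub = dm[np.ix_(cand - 1, positions - 1)]
    out = np.zeros((len(spheres), len(radii)), dtype=np.int64)
    for ri, r in enumerate(radii):
        bits, pops = _pack_rows(sub <= r)
        if len(pops) == 0:
            continue
        b1, b2, b3 = _best123(bits, pops)
        by_s = {1: b1, 2: max(b1, b2), 3: max(b1, b2, b3)}
        # s spheres may use fewer when no s disjoint sets exist, so the
        # statistic is monotone in s
        for si, s in enumerate(spheres):
            out[si, ri] = by_s[s]
    return out


def simulate_null(
    dm: np.ndarray,
    mapped,
    radii=DEFAULT_RADII,
    spheres=DEFAULT_SPHERES,
    T: int = 1000,
    seed: int = 0,
) -> NullSimulation:
    """T uniform re-assignments of the n mutations over all N residues.

    Row 0 of X holds the observed coverages; rows 1..T the replicates.  The
    moments μ, σ are computed over rows 1..T only (sample sd).  Identical
    seed gives a bit-identical simulation.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    N = dm.shape[0]
    positions = np.asarray(sorted(mapped.positions), dtype=int)
    n = positions.size
    radii = tuple(float(r) for r in radii)
    spheres = tuple(int(s) for s in spheres)
    X = np.zeros((T + 1, len(spheres), len(radii)), dtype=np.int64)
    X[0] = _coverage_row(dm, positions, radii, spheres)
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, N + 1, size=(T, n))
    for t in range(T):
        X[t + 1] = _coverage_row(dm, draws[t], radii, spheres)
    mu = X[1:].mean(axis=0)
    sigma = X[1:].std(axis=0, ddof=1) if T > 1 else np.zeros_like(mu, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        znorm = (X - mu) / sigma
    znorm[:, sigma == 0] = -np.inf  # saturated cells excluded from the max
    Z = znorm.reshape(T + 1, -1).max(axis=1)
    return NullSimulation(X=X, mu=mu, sigma=sigma, Z=Z, T=T, seed=seed,
                          spheres=spheres, radii=radii, n=n, N=N,
                          observed_positions=positions)


def spacepac_pvalue(sim: NullSimulation, dm: np.ndarray | None = None,
                    mapped=None, alpha: float = 0.05) -> SpacePacResult:
    """Single p-value per run: p = 1 − #{i : Z₀ > Z_i}/T, plus the observed
    hotspots at the argmax (s, r) cell of row 0."""
    T = sim.T
    if np.isneginf(sim.Z).all():
        warnings.warn("all (s, r) cells saturated (σ = 0); p = 1")
        return SpacePacResult(p_value=1.0, p_label="1", hotspots=[],
                              best_s=0, best_radius=0.0,
                              outcome="no_clustering", min_p=1.0, sim=sim)
    z0 = sim.Z[0]
    beats = int((z0 > sim.Z[1:]).sum())
    p = 1.0 - beats / T
    label = f"<{1.0 / T:.2E}" if beats == T else f"{p:.6g}"

    # argmax cell of the observed row among unsaturated cells
    obs = (sim.X[0] - sim.mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_norm = obs / sim.sigma
    obs_norm[sim.sigma == 0] = -np.inf
    si, ri = np.unravel_index(np.argmax(obs_norm), obs_norm.shape)
    best_s, best_r = sim.spheres[si], sim.radii[ri]
    hotspots: list[SphereHotspot] = []
    if dm is not None and mapped is not None:
        hotspots, _, _ = best_spheres(dm, mapped, best_s, best_r)
    outcome = "clustering" if p <= alpha else "no_clustering"
    return SpacePacResult(p_value=p, p_label=label, hotspots=hotspots,
                          best_s=int(best_s), best_radius=float(best_r),
                          outcome=outcome, min_p=p, sim=sim)


def run_spacepac(structure, mapped, alpha: float = 0.05, seed: int = 0,
                 dm: np.ndarray | None = None, radii=DEFAULT_RADII,
                 spheres=DEFAULT_SPHERES, T: int = 1000,
                 keep_sim: bool = False) -> SpacePacResult:
    """Whole sphere-covering procedure on one structure."""
    from .structures import distance_matrix

    if dm is None:
        dm = distance_matrix(structure)
    if mapped.is_blank:
        return SpacePacResult(p_value=1.0, p_label="blank", hotspots=[],
                              best_s=0, best_radius=0.0, outcome="blank",
                              min_p=None, sim=None)
    serial_by_gidx = {r.global_index: r.atom_serial
                      for r in structure.residues}
    mapped.serial_by_gidx = serial_by_gidx  # used for hotspot reporting
    sim = simulate_null(dm, mapped, radii=radii, spheres=spheres, T=T,
                        seed=seed)
    result = spacepac_pvalue(sim, dm=dm, mapped=mapped, alpha=alpha)
    if not keep_sim:
        result.sim = None
    return result
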