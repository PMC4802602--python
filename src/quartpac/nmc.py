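"""Linear (1D) non-random clustering test shared by the two projection
methods.

Under the null hypothesis the n mutations fall independently and uniformly
on the N_eff slots of a 1D arrangement of residues.  Writing X_(1) <= ... <=
X_(n) for the sorted mutation positions, a candidate cluster between the
i-th and k-th order statistics is scored by

    p = P( X_(k) - X_(i) <= c )            with c the observed span.

Small p means the k-i+1 mutations sit in an improbably short stretch.  All
n(n-1)/2 ordered pairs are tested and a Bonferroni factor m = n(n-1)/2 is
applied within the structure.

Two evaluation routes are provided:

* ``exact`` — the exact discrete distribution, obtained by conditioning on
  the value a of X_(i) and the counts of draws below a / inside the window,
  which reduces to O(N·n) vectorized binomial tail sums.  Verified against
  full N^n enumeration.
* ``midpoint`` / ``plus_one`` / ``none`` — the continuous order-statistic
  approximation: the spacing U_(k) - U_(i) of n iid Uniform(0,1) draws is
  Beta(k-i, n-(k-i)+1); the CDF is evaluated at (c+offset)/N_eff.  The
  midpoint offset 0.5 splits the discretization bracket
  [F(c/N), F((c+1)/N)] that contains the exact value.

The default ``auto`` uses the exact route whenever it is cheap and the
midpoint approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "OrderedMutations",
    "ClusterRecord",
    "order_statistics",
    "pair_span_pvalue",
    "find_linear_clusters",
]

# above this cost bound the exact route gives way to the Beta approximation
_EXACT_COST_LIMIT = 2_000_000  # ~ N * n elementary terms


class BlankStructureError(ValueError):
    """Raised when fewer than two mutations are available (blank outcome)."""


@dataclass
class OrderedMutations:
    sorted_positions: np.ndarray  # nondecreasing ints in 1..N_eff
    n: int
    N_eff: int


@dataclass
class ClusterRecord:
    method: str  # "ipac" | "graphpac"
    i: int
    k: int
    start_serial: int
    end_serial: int
    residues_in_cluster: int
    num_mutations: int
    p_raw: float
    p_bonferroni: float


def order_statistics(positions, N_eff: int | None = None) -> OrderedMutations:
    """Sort the mutation position multiset into order statistics."""
    pos = np.asarray(sorted(positions), dtype=int)
    if pos.size < 2:
        raise BlankStructureError(
            f"{pos.size} mutation(s): blank, no clustering test possible")
    N = int(N_eff) if N_eff is not None else int(pos.max())
    if pos.min() < 1 or pos.max() > N:
        raise ValueError("positions must lie in 1..N_eff")
    return OrderedMutations(sorted_positions=pos, n=int(pos.size), N_eff=N)


def _exact_span_pvalue(n: int, N: int, i: int, k: int, c: int) -> float:
    """Exact P(X_(k) - X_(i) <= c) for i.i.d. uniform draws on {1..N}.

    Decomposes over the value a of X_(i): with B = min(a+c, N),

        P(X_(i) = a, X_(k) <= B) = J(a, B) - J(a+1, B),
        J(a, B) = sum_{n1 <= i-1} C(n, n1) ((a-1)/N)^n1 (1-(a-1)/N)^(n-n1)
                    * P(Binom(n - n1, (B-a+1)/(N-a+1)) >= k - n1)

    where n1 counts draws strictly below a and J(a, B) = P(X_(i) >= a,
    X_(k) <= B).  Cost O(N * i) with vectorized binomial tails.
    """
    if c >= N - 1:
        return 1.0
    if c < 0:
        return 0.0
    a = np.arange(1, N + 1, dtype=float)
    b = np.minimum(a + c, N)

    def joint(a_vec: np.ndarray) -> np.ndarray:
        """P(X_(i) >= a, X_(k) <= b) elementwise (b fixed from outer scope)."""
        p_low = (a_vec - 1.0) / N
        valid = a_vec <= b  # empty window -> probability 0 of X_(k)<=b<X_(i)
        width = np.where(valid, (b - a_vec + 1.0), 0.0)
        denom = np.maximum(N - (a_vec - 1.0), 1.0)
        q = np.clip(width / denom, 0.0, 1.0)
        total = np.zeros_like(a_vec, dtype=float)
        for n1 in range(0, i):
            rest = n - n1
            need = k - n1
            tail = stats.binom.sf(need - 1, rest, q) if need > 0 else 1.0
            total += stats.binom.pmf(n1, n, p_low) * tail
        return np.where(valid, total, 0.0)

    term = joint(a) - joint(a + 1.0)
    return float(min(1.0, max(0.0, term.sum())))


@lru_cache(maxsize=500_000)
def _exact_cached(n: int, N: int, i: int, k: int, c: int) -> float:
    return _exact_span_pvalue(n, N, i, k, c)


def _beta_span_pvalue(n: int, N: int, i: int, k: int, c: int,
                      offset: float) -> float:
    if c >= N - 1:
        return 1.0
    if c < 0:
        return 0.0
    gap = k - i
    x = min(1.0, max(0.0, (c + offset) / N))
    return float(stats.beta.cdf(x, gap, n - gap + 1))


_OFFSETS = {"midpoint": 0.5, "plus_one": 1.0, "none": 0.0}


def pair_span_pvalue(i: int, k: int, span: int, n: int, N_eff: int,
                     method: str = "auto") -> float:
    """P(X_(k) - X_(i) <= span) under iid-uniform placement on {1..N_eff}.

    ``method``: "auto" (exact when affordable, else midpoint Beta),
    "exact", "midpoint", "plus_one", or "none".
    """
    if not (1 <= i < k <= n):
        raise ValueError(f"need 1 <= i < k <= n, got i={i}, k={k}, n={n}")
    if span < 0 or span > N_eff - 1:
        raise ValueError(f"span must be in 0..N_eff-1, got {span}")
    if method == "auto":
        method = "exact" if N_eff * n <= _EXACT_COST_LIMIT else "midpoint"
    if method == "exact":
        # the joint law of (X_(i), X_(k)) depends on (i, k) jointly; cache
        return _exact_cached(n, N_eff, i, k, span)
    if method in _OFFSETS:
        return _beta_span_pvalue(n, N_eff, i, k, span, _OFFSETS[method])
    raise ValueError(f"unknown p-value method {method!r}")


def find_linear_clusters(
    om: OrderedMutations,
    serial_of,
    alpha: float = 0.05,
    method: str = "auto",
    tag: str = "linear",
    screen_factor: float = 50.0,
) -> tuple[list[ClusterRecord], float]:
    """Test all n(n-1)/2 order-statistic pairs; Bonferroni-correct within the
    structure; return records with corrected p <= alpha (ascending p) and the
    minimum corrected p over all pairs.

    ``serial_of`` maps an arrangement slot (1..N_eff) to the atom serial
    reported for that residue.  When the exact route is active, a vectorized
    midpoint-Beta screen decides which pairs are worth evaluating exactly
    (those within ``screen_factor`` of significance, plus the screen minimum);
    the rest inherit the screen value, which is accurate far from the tail.
    """
    n, N = om.n, om.N_eff
    pos = om.sorted_positions
    m = n * (n - 1) // 2
    ii, kk = np.triu_indices(n, k=1)
    ii += 1
    kk += 1
    spans = pos[kk - 1] - pos[ii - 1]
    gaps = kk - ii
    # vectorized midpoint-Beta values for every pair
    x = np.clip((spans + 0.5) / N, 0.0, 1.0)
    p_screen = stats.beta.cdf(x, gaps, n - gaps + 1)
    p_screen[spans >= N - 1] = 1.0

    resolved = method if method != "auto" else (
        "exact" if N * n <= _EXACT_COST_LIMIT else "midpoint")
    if resolved == "exact":
        p_raw = p_screen.copy()
        thresh = min(1.0, alpha * screen_factor / m)
        candidates = set(np.nonzero(p_screen <= thresh)[0].tolist())
        candidates.add(int(np.argmin(p_screen)))
        for idx in candidates:
            p_raw[idx] = _exact_cached(n, N, int(ii[idx]), int(kk[idx]),
                                       int(spans[idx]))
    elif resolved in _OFFSETS:
        off = _OFFSETS[resolved]
        x2 = np.clip((spans + off) / N, 0.0, 1.0)
        p_raw = stats.beta.cdf(x2, gaps, n - gaps + 1)
        p_raw[spans >= N - 1] = 1.0
    else:
        raise ValueError(f"unknown p-value method {method!r}")

    p_bonf = np.minimum(1.0, p_raw * m)
    min_p = float(p_bonf.min())
    order = np.argsort(p_raw, kind="stable")
    records: list[ClusterRecord] = []
    for idx in order:
        if p_bonf[idx] > alpha:
            break
        i_, k_ = int(ii[idx]), int(kk[idx])
        lo, hi = int(pos[i_ - 1]), int(pos[k_ - 1])
        records.append(
            ClusterRecord(
                method=tag,
                i=i_,
                k=k_,
                start_serial=int(serial_of(lo)),
                end_serial=int(serial_of(hi)),
                residues_in_cluster=hi - lo + 1,
                num_mutations=k_ - i_ + 1,
                p_raw=float(p_raw[idx]),
                p_bonferroni=float(p_bonf[idx]),
            )
        )
    return records, min_p
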