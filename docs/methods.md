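# Methods

## Model and null hypothesis

Every residue of every polymer chain in the first model of a structure
file is represented by its Cα coordinate and given a single global index
1..N running over chains in file order. All statistics test the same null:
the n mapped missense mutations are placed independently and uniformly on
the N residues of the assembly, with replacement (recurrent mutations are
repeated draws on one residue). The alternative of interest is spatial
concentration — possibly spanning several chains.

Restricting every computation to one chain recovers the tertiary
(single-chain) version of each test exactly: the quaternary distance
matrix restricted to a chain's indices *is* that chain's distance matrix
(a tested invariant), so tertiary-vs-quaternary comparisons differ only in
the data, never in the machinery.

## Input handling

**Structure parsing** (gemmi, PDB and mmCIF): model 1 only; waters and
non-polymer HETATM excluded; modified amino acids with a Cα (MSE, SEC,
PYL) kept and mapped to the nearest standard letter, anything else to X;
residues without a Cα skipped; alternate locations resolved to the
highest-occupancy conformer, ties to the first in file; insertion-coded
residues kept as distinct residues in file order. No crystallographic or
biological-assembly expansion is performed: the quaternary structure is
the set of chains present in the file.

**Mutation filtering** mirrors a somatic-mutation-database query: keep
nonsynonymous missense records whose somatic status is "confirmed somatic
variant" or "Reported in another sample as somatic", from whole-genome or
whole-gene screens, carrying a UniProt accession; then deduplicate on
(sample, accession, position, mutant AA) keeping first occurrence, so the
same substitution in different samples — genuine recurrence — survives.

**Reconciliation**: canonical sequences are aligned to each chain's
ATOM-derived sequence with global Needleman–Wunsch (BLOSUM62, gap open 10,
extend 0.5 — configurable); identity is counted over aligned columns so
truncated termini do not penalize; maps below 0.90 identity are rejected
and the chain excluded. Wild-type mismatches at mapped sites are kept with
a warning by default (database/structure version skew), or dropped.

**Homo-oligomer assignment**: when one protein appears as several
identical chains, canonical positions are ambiguous. The default
`round_robin` policy cycles successive mutations over the copies: it
preserves the total count n and, under the uniform null, spreads mass the
way the null itself does. `first_chain` concentrates everything on one
copy (conservative for interface detection); `replicate_all` duplicates
each mutation onto every copy and inflates n — it is provided for
comparison but warned against.

## The span test

With X₍₁₎ ≤ … ≤ X₍ₙ₎ the sorted mutation positions on a 1D arrangement of
N slots, a pair (i, k) with observed span c = X₍ₖ₎ − X₍ᵢ₎ is scored by
P(X₍ₖ₎ − X₍ᵢ₎ ≤ c). Evaluation routes (`pvalue_method`):

- `exact` — the exact discrete probability, by conditioning on the value a
  of X₍ᵢ₎ and the count of draws below a; the inner sums are vectorized
  binomial tails, cost O(N·i) per pair. Verified identical (≤ 1e-9) to
  full N^n enumeration for all n ≤ 4, N ≤ 8.
- `midpoint` / `plus_one` / `none` — the continuous approximation: the
  spacing U₍ₖ₎ − U₍ᵢ₎ of n uniform(0,1) draws is Beta(k−i, n−(k−i)+1),
  evaluated at (c + offset)/N. The exact value always lies in the bracket
  [F(c/N), F((c+1)/N)]; the midpoint offset 0.5 sits inside that bracket
  and is the accurate default among the three (worst error 0.11 over all
  n ≤ 4, N ≤ 8, and within Monte-Carlo error at n=20, N=500, where the +1
  offset is measurably biased upward). The offset is exposed because
  different published implementations made different choices.
- `auto` (default) — exact while N·n ≤ 2·10⁶, midpoint beyond. In
  `find_linear_clusters` the exact route is applied to the pairs a
  vectorized midpoint screen places within a factor 50 of significance
  (plus the screen minimum); screened-out pairs keep the midpoint value,
  which is accurate away from the tail where no decision depends on it.

All n(n−1)/2 pairs are tested and multiplied by m = n(n−1)/2 (capped at
1); records at or below α (default 0.05) are reported with the residue
count between the endpoints inclusive and the boundary Cα serial numbers.
Ties (c = 0) are handled by the same formulas. Structures with n < 2 are
"blank" — no test is possible.

## Projections

**Global (MDS) route.** 1D metric MDS by SMACOF-style majorization of the
raw stress, one classical-scaling start plus four seeded random starts,
convergence at relative stress change < 1e-6 or 300 iterations; the best
configuration is rescaled to its σ₁-optimal scale (closed form c = Σδ²/Σδd)
and σ₁ reported. The residue arrangement is the rank order of the 1D
coordinates, ties broken by global index so the order is always strict.
Only the rank order feeds the span test, so the scale choice affects
reported stress, not inference.

**Local (TSP) route.** Open Hamiltonian path (not a cycle) through the
complete Cα graph. Heuristics: nearest neighbor (start at residue 1,
lowest-index tie-breaks), cheapest insertion (seeded from the closest
pair), and the default nearest-neighbor + best-improvement 2-opt, whose
moves only swap the two boundary edges of a reversed segment and are
evaluated as one vectorized n×n computation per move. The refined path is
never longer than its start. Paths are deterministic given heuristic and
seed.

Both arrangements depend only on the distance matrix — never on the
mutations — so they are computed once per structure and reused across
mutation draws.

## Sphere covering

Candidate centers are the mutated residues: any sphere can be recentered
on a covered mutated residue at no more than doubled radius, and the
exhaustive-oracle tests quantify the (empirically zero, on all tested
fixtures) gap; `candidates="all"` scans every residue instead.
"Non-overlapping" means disjoint covered-mutation sets — the quantity
being summed — rather than geometric disjointness (a config alternative).
The search deduplicates candidate spheres by covered-set equality and is
exhaustive over distinct sets, hence globally optimal; observed-data
searches use deterministic tie-breaks (coverage descending, then center
index ascending). The null simulation draws T × n uniform residue
assignments from one seeded generator and evaluates every (s, r) cell with
a pruned bitset search compiled with numba (rows sorted by coverage allow
early termination); identical seeds give bit-identical simulations.

Moments μ, σ are computed over replicates 1..T only (the observed row 0 is
excluded, following the estimator's definition; sample standard deviation,
ddof 1). Cells with σ = 0 — saturated coverage, e.g. a radius exceeding
the assembly diameter — are excluded from the max in Z; if every cell is
excluded the p-value is 1 with a warning. When Z₀ exceeds all T null
values the numeric p is 0 and the label "<1/T" is attached (at T=1000,
"<1.00E-03"). The strict inequality in 1 − #{Z₀ > Zᵢ}/T makes the
estimator conservative in the presence of ties between Z₀ and null Z
values, which are common because coverages are small integers; the null
calibration test documents this (the same p-values with midpoint tie
handling are indistinguishable from uniform).

## Multiple testing across structures

Scanning k structures, the rough-FDR cutoff α(k+1)/(2k) approximates
step-up FDR control under many positively correlated tests (structures
sharing subunits); the applied cutoff is rounded *down* to three decimals
to stay conservative. At α=0.05 and k=2156 this gives 0.025012 → 0.025.
Per-structure outcomes are trinary: blank (n < 2), clustering (minimum
reported p ≤ cutoff), else no clustering. The tertiary side of the 3D/4D
cross-classification counts as clustering when any chain clusters.

Method agreement is summarized by Cramér's V = √((χ²/n)/min(r−1, c−1))
with uncorrected Pearson χ². The one-sided comparison of two proportions
defaults to the pooled z-test with continuity correction (equivalently the
one-sided Yates χ², as in R's `prop.test`) — the variant that reproduces
the published disease-database overlap values to printed precision; the
exact Fisher/hypergeometric tail and the uncorrected score test are
selectable.

## Synthetic fixtures

The generator emits idealized assemblies (line, ideal α-helix with 3.8 Å
Cα spacing / 1.5 Å rise / 100° twist, cubic grid) with deterministic
seeded sequences, valid minimal PDB ATOM records, and mutation tables in
the pipeline's own dialect, plus ground-truth labels (residues within the
declared spread of each hotspot center). Background mutations are drawn
uniformly over all residues — exactly the null. Hotspot draws are
"balanced" by default: counts over the eligible residues differ by at most
one, and interface hotspots draw evenly from each participating subunit;
iid draws (`balanced=False`) are available but concentrate recurrences on
single residues, which changes the character of the planted signal.

The canonical interface fixture is a 300-residue dimer: two parallel
150-residue chains 5 Å apart, with a 6-mutation recurrent core straddling
the distal tip of the interface (3 per subunit over the two terminal
residue pairs), a 14-mutation enrichment spread over the whole interface
region, and 10 uniform background mutations. This composition was designed
so the assembly-level signal is decisive for all three statistics while
each chain alone carries only an undersized share — the regime the
quaternary scan exists for. A single tight 20-mutation interface patch
does not show this contrast: its 10-mutation per-chain share is
overwhelming for any per-chain test, a constraint that follows directly
from the power of the span test at n≈15, N=150.

What the fixtures do *not* emulate: real fold geometry, side chains,
crystallographic disorder, non-uniform background mutation rates (CpG
context, transcription-coupled repair), or database noise in annotations.
Passing tests therefore demonstrate correctness and calibration of the
statistics under their stated null and power under a geometrically clean
interface signal — not robustness to the biological confounders above,
which the uniform-null model explicitly assumes away.

## Problem sizes and numerical choices

The test suite runs the null calibration at N=300, n=25 over 400 draws
with T=200 Monte-Carlo replicates per sphere-covering run, and the
interface power property over 50 seeds — sizes chosen so the full suite
completes in minutes while keeping binomial standard errors small enough
for the stated bounds. Exact span probabilities are cached across pairs
and runs (keyed on n, N, i, k, c). Degenerate inputs are handled
explicitly: single-residue structures (zero distance matrix), all-σ-zero
simulations (p = 1), fewer disjoint spheres than requested (flagged,
smaller optimum returned), identical 1D coordinates (stress undefined,
error), blank structures (short-circuit outcome).

## Known limitations

- The uniform null ignores sequence-context mutation-rate variation; an
  enriched mutational context inside a compact domain can mimic spatial
  clustering.
- Candidate sphere centers restricted to mutated residues make the search
  exact for the maximum-coverage objective in all tested configurations,
  but a pathological geometry could in principle favor a non-mutated
  center at small radii; the `candidates="all"` flag covers that case at
  higher cost.
- The homo-oligomer assignment is a modeling choice, not data; results for
  heavily recurrent positions on high-copy assemblies depend on it, and
  all three policies are exposed deliberately.
- TSP and MDS arrangements are heuristic optima; different heuristics can
  reorder residues, though the significant/not-significant call is stable
  across heuristics on planted fixtures (tested ≥ 90% agreement).
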