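"""Mutation-table handling: COSMIC-style filtering, deduplication, and the
pairwise-alignment reconciliation of canonical residue numbering with the
numbering actually present in a structure file.

The filtering rules mirror a somatic-mutation database query: keep missense
substitutions with confirmed somatic status, drawn from unbiased (whole
genome / whole gene) screens, and annotated with a UniProt accession.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

log = logging.getLogger("quartpac.mutations")

__all__ = [
    "MutationRecord",
    "PositionMap",
    "MappedMutations",
    "read_mutation_table",
    "filter_mutations",
    "deduplicate",
    "align_canonical_to_chain",
    "map_mutations",
]

SOMATIC_STATUSES = {
    "confirmed somatic variant",
    "reported in another sample as somatic",
}
ACCEPTED_SCREENS = {"whole genome", "whole gene"}


@dataclass(frozen=True)
class MutationRecord:
    uniprot_accession: str
    gene: str
    canonical_position: int
    wt_aa: str
    mut_aa: str
    sample_id: str
    somatic_status: str
    screen_type: str
    mutation_class: str


@dataclass
class PositionMap:
    """Partial map canonical position -> global residue index for one chain."""

    chain_id: str
    mapping: dict[int, int]
    alignment_identity: float
    ok: bool  # False when the alignment identity fell below threshold


@dataclass
class MappedMutations:
    """Mutation multiset expressed as global residue indices."""

    positions: list[int]
    n_total_input: int
    N: int
    dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def is_blank(self) -> bool:
        """Fewer than two mapped mutations: no clustering test is possible."""
        return self.n < 2


_COLUMNS = ["uniprot", "gene", "position", "wt", "mut",
            "sample", "status", "screen", "class"]


def read_mutation_table(source: str, sep: str | None = None) -> list[MutationRecord]:
    """Read the TSV/CSV mutation dialect (header: uniprot, gene, position,
    wt, mut, sample, status, screen, class).  `source` is a path or raw text.
    """
    if "\n" in source:
        buf = io.StringIO(source)
    else:
        buf = source  # type: ignore[assignment]
    df = pd.read_csv(buf, sep=sep or "\t", dtype=str).fillna("")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return [
        MutationRecord(
            uniprot_accession=row["uniprot"],
            gene=row["gene"],
            canonical_position=int(row["position"]),
            wt_aa=row["wt"],
            mut_aa=row["mut"],
            sample_id=row["sample"],
            somatic_status=row["status"],
            screen_type=row["screen"],
            mutation_class=row["class"],
        )
        for _, row in df.iterrows()
    ]


def filter_mutations(records: list[MutationRecord]) -> list[MutationRecord]:
    """Apply the somatic-database inclusion criteria, preserving order.

    Kept records are (a) nonsynonymous missense, (b) confirmed somatic or
    reported-in-another-sample-as-somatic, (c) from whole-genome/whole-gene
    screens, (d) annotated with a UniProt accession.
    """
    out = []
    for r in records:
        if "missense" not in r.mutation_class.lower():
            log.debug("drop %s: not missense", r)
            continue
        if r.wt_aa == r.mut_aa:
            log.debug("drop %s: synonymous", r)
            continue
        if r.somatic_status.strip().lower() not in SOMATIC_STATUSES:
            log.debug("drop %s: somatic status", r)
            continue
        if r.screen_type.strip().lower() not in ACCEPTED_SCREENS:
            log.debug("drop %s: screen type", r)
            continue
        if not r.uniprot_accession.strip():
            log.debug("drop %s: no accession", r)
            continue
        out.append(r)
    return out


def deduplicate(records: list[MutationRecord]) -> list[MutationRecord]:
    """Keep the first record per (sample, accession, position, mutant AA).

    The same substitution observed in two different samples is genuine
    recurrence and both records survive.
    """
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.sample_id, r.uniprot_accession, r.canonical_position, r.mut_aa)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_canonical_to_chain(
    canonical_seq: str,
    chain_residues,
    chain_id: str = "",
    identity_threshold: float = 0.90,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    warn_on_failure: bool = True,
) -> PositionMap:
    """Global Needleman–Wunsch alignment of the canonical sequence against the
    chain's ATOM-derived sequence; aligned non-gap columns become map entries.

    Identity is counted over aligned (non-gap) columns, so a chain that is
    merely truncated (disordered termini) still aligns with identity 1.
    Maps below `identity_threshold` are flagged not-ok and should be excluded.
    """
    chain_seq = "".join(r.amino_acid for r in chain_residues)
    if not canonical_seq or not chain_seq:
        raise ValueError("both sequences must be nonempty")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(canonical_seq, chain_seq)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            a_i = a_start + off  # 0-based canonical
            b_i = b_start + off  # 0-based chain residue
            aligned_cols += 1
            if canonical_seq[a_i] == chain_seq[b_i]:
                matches += 1
            mapping[a_i + 1] = chain_residues[b_i].global_index
    identity = matches / aligned_cols if aligned_cols else 0.0
    ok = identity >= identity_threshold
    if not ok:
        if warn_on_failure:
            log.warning("chain %s alignment failed (identity %.3f)",
                        chain_id, identity)
        mapping = {}
    return PositionMap(chain_id=chain_id, mapping=mapping,
                       alignment_identity=identity, ok=ok)


def map_mutations(
    muts: list[MutationRecord],
    structure,
    maps: dict[str, PositionMap],
    policy: str = "round_robin",
    canonical_seqs: dict[str, str] | None = None,
    wt_mismatch: str = "warn",
) -> MappedMutations:
    """Place filtered mutations onto global residue indices.

    When one protein is present as several identical chains, the default
    ``round_robin`` policy distributes successive mutations cyclically over
    the copies, preserving the total count n while spreading it over the
    assembly the way the uniform null does.  ``first_chain`` puts everything
    on the first copy; ``replicate_all`` duplicates each mutation onto every
    copy (count-inflating — use with care).
    """
    if policy not in {"round_robin", "first_chain", "replicate_all"}:
        raise ValueError(f"unknown assignment policy {policy!r}")
    if policy == "replicate_all":
        log.warning("replicate_all inflates the mutation count n")

    by_accession: dict[str, list[str]] = {}
    for c in structure.chains:
        if c.uniprot_accession and maps.get(c.chain_id) and maps[c.chain_id].ok:
            by_accession.setdefault(c.uniprot_accession, []).append(c.chain_id)

    residues_by_gidx = {r.global_index: r for r in structure.residues}
    positions: list[int] = []
    dropped = 0
    rr_counter: dict[str, int] = {}
    for rec in muts:
        chain_ids = by_accession.get(rec.uniprot_accession, [])
        if not chain_ids:
            dropped += 1
            log.info("drop %s@%d: no aligned chain", rec.uniprot_accession,
                     rec.canonical_position)
            continue
        if policy == "replicate_all":
            targets = list(chain_ids)
        elif policy == "first_chain":
            targets = [chain_ids[0]]
        else:  # round_robin: try the next copy in the cycle, then the rest
            start = rr_counter.get(rec.uniprot_accession, 0) % len(chain_ids)
            targets = [chain_ids[(start + j) % len(chain_ids)]
                       for j in range(len(chain_ids))]
        placed = False
        for chain_id in targets:
            gidx = maps[chain_id].mapping.get(rec.canonical_position)
            if gidx is None:
                continue
            res = residues_by_gidx[gidx]
            if res.amino_acid != rec.wt_aa:
                if wt_mismatch == "drop":
                    continue
                log.warning("wild-type mismatch at %s %d: structure %s, record %s",
                            chain_id, rec.canonical_position, res.amino_acid,
                            rec.wt_aa)
            positions.append(gidx)
            placed = True
            if policy != "replicate_all":
                break
        if placed and policy == "round_robin":
            rr_counter[rec.uniprot_accession] = rr_counter.get(
                rec.uniprot_accession, 0) + 1
        if not placed:
            dropped += 1
            log.info("drop %s@%d: position unresolved", rec.uniprot_accession,
                     rec.canonical_position)
    return MappedMutations(
        positions=positions,
        n_total_input=len(muts),
        N=structure.n_residues,
        dropped=dropped,
    )
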