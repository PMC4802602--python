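"""Model/Results interface tying the pipeline together.

``QuartPac`` is constructed from a parsed structure plus raw mutation
records and canonical sequences; construction performs the COSMIC-style
filtering, deduplication and alignment-based reconciliation.  ``fit()``
runs the requested clustering statistics on the quaternary assembly (and
optionally per chain) and returns a ``QuartPacResults`` carrying cluster
and hotspot tables, per-method outcomes and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mutations as mut
from . import projections, reporting, spacepac
from .structures import QuaternaryStructure, distance_matrix, parse_structure

__all__ = ["QuartPac", "QuartPacResults", "read_fasta"]

METHODS = ("ipac", "graphpac", "spacepac")


def read_fasta(source: str) -> dict[str, str]:
    """Accession -> sequence from FASTA text or a path."""
    from Bio import SeqIO
    import io

    handle = io.StringIO(source) if source.lstrip().startswith(">") \
        else open(source)
    with handle:
        return {rec.id.split("|")[0]: str(rec.seq)
                for rec in SeqIO.parse(handle, "fasta")}


class QuartPac:
    """Mutational-clustering model for one quaternary structure.

    Parameters
    ----------
    structure : QuaternaryStructure
    records : list of MutationRecord (raw; filtering applied here)
    sequences : dict accession -> canonical sequence
    methods : subset of {"ipac", "graphpac", "spacepac"}
    alpha : per-structure significance level for the trinary outcome
    assignment : homo-oligomer mutation assignment policy
    radii, spheres, sims : sphere-covering grid and replicate count
    pvalue_method : span-test evaluation route ("auto"/"exact"/...)
    """

    def __init__(
        self,
        structure: QuaternaryStructure,
        records,
        sequences: dict[str, str],
        methods=METHODS,
        alpha: float = 0.05,
        assignment: str = "round_robin",
        radii=spacepac.DEFAULT_RADII,
        spheres=spacepac.DEFAULT_SPHERES,
        sims: int = 1000,
        pvalue_method: str = "auto",
        identity_threshold: float = 0.90,
        prefiltered: bool = False,
    ) -> None:
        self.structure = structure
        self.sequences = sequences
        self.methods = tuple(methods)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.alpha = alpha
        self.assignment = assignment
        self.radii = tuple(radii)
        self.spheres = tuple(spheres)
        self.sims = sims
        self.pvalue_method = pvalue_method
        self.identity_threshold = identity_threshold

        if prefiltered:
            self.filtered = list(records)
        else:
            self.filtered = mut.deduplicate(mut.filter_mutations(list(records)))
        self._assign_accessions()
        self.position_maps = self._align_chains()
        self.mapped = mut.map_mutations(
            [r for r in self.filtered
             if r.uniprot_accession in self._aligned_accessions()],
            structure, self.position_maps, policy=assignment)
        self.dm = distance_matrix(structure)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_files(cls, structure_path, mutations_path, fasta_path,
                   format: str | None = None, **kwargs) -> "QuartPac":
        structure_path = Path(structure_path)
        fmt = format or ("mmcif" if structure_path.suffix in {".cif", ".mmcif"}
                         else "pdb")
        structure = parse_structure(structure_path.read_text(), format=fmt,
                                    structure_id=structure_path.stem)
        records = mut.read_mutation_table(str(mutations_path))
        sequences = read_fasta(str(fasta_path))
        return cls(structure, records, sequences, **kwargs)

    def _assign_accessions(self) -> None:
        """Give each chain the accession whose canonical sequence aligns
        best, unless accessions were attached upstream."""
        for chain in self.structure.chains:
            if chain.uniprot_accession:
                continue
            best_acc, best_id = None, 0.0
            for acc, seq in self.sequences.items():
                pm = mut.align_canonical_to_chain(
                    seq, chain.residues, chain_id=chain.chain_id,
                    identity_threshold=self.identity_threshold,
                    warn_on_failure=False)
                if pm.ok and pm.alignment_identity > best_id:
                    best_acc, best_id = acc, pm.alignment_identity
            chain.uniprot_accession = best_acc

    def _align_chains(self) -> dict[str, mut.PositionMap]:
        maps = {}
        for chain in self.structure.chains:
            acc = chain.uniprot_accession
            if acc and acc in self.sequences:
                maps[chain.chain_id] = mut.align_canonical_to_chain(
                    self.sequences[acc], chain.residues,
                    chain_id=chain.chain_id,
                    identity_threshold=self.identity_threshold)
        return maps

    def _aligned_accessions(self) -> set[str]:
        return {c.uniprot_accession for c in self.structure.chains
                if c.uniprot_accession
                and self.position_maps.get(c.chain_id)
                and self.position_maps[c.chain_id].ok}

    # -- fitting --------------------------------------------------------------

    def fit(self, seed: int = 0, tertiary: bool = False) -> "QuartPacResults":
        """Run the selected statistics; `tertiary=True` additionally scans
        every chain on its own (for the 3D-vs-4D cross-classification)."""
        scans = self._scan(self.structure, self.dm, self.mapped, seed)
        tert: dict[str, dict[str, object]] = {}
        if tertiary:
            for chain in self.structure.chains:
                sub = self.structure.subset_chain(chain.chain_id)
                sub_mapped = self._chain_mapped(chain.chain_id)
                sub_dm = distance_matrix(sub)
                tert[chain.chain_id] = self._scan(sub, sub_dm, sub_mapped,
                                                  seed)
        return QuartPacResults(model=self, seed=seed, quaternary=scans,
                               tertiary=tert)

    def _chain_mapped(self, chain_id: str) -> mut.MappedMutations:
        """Mutations of one chain's protein mapped onto that chain alone
        (canonical positions resolved against the single chain)."""
        chain = self.structure.chain(chain_id)
        sub = self.structure.subset_chain(chain_id)
        pm = self.position_maps.get(chain_id)
        if pm is None or not pm.ok or not chain.uniprot_accession:
            return mut.MappedMutations(positions=[], n_total_input=0,
                                       N=len(chain.residues))
        # renumber the quaternary map onto the chain-local indexing
        offset = chain.residues[0].global_index - 1
        local_map = {cpos: g - offset for cpos, g in pm.mapping.items()}
        positions = []
        dropped = 0
        recs = [r for r in self.filtered
                if r.uniprot_accession == chain.uniprot_accession]
        for r in recs:
            loc = local_map.get(r.canonical_position)
            if loc is None:
                dropped += 1
            else:
                positions.append(loc)
        return mut.MappedMutations(positions=positions,
                                   n_total_input=len(recs),
                                   N=len(chain.residues), dropped=dropped)

    def _scan(self, structure, dm, mapped, seed: int) -> dict[str, object]:
        out: dict[str, object] = {}
        rng = np.random.default_rng(seed)
        subseeds = {m: int(rng.integers(0, 2 ** 31 - 1)) for m in METHODS}
        for method in self.methods:
            if method == "ipac":
                out[method] = projections.run_ipac(
                    structure, mapped, alpha=self.alpha, dm=dm,
                    seed=subseeds[method], pvalue_method=self.pvalue_method)
            elif method == "graphpac":
                out[method] = projections.run_graphpac(
                    structure, mapped, alpha=self.alpha, dm=dm,
                    seed=subseeds[method], pvalue_method=self.pvalue_method)
            else:
                out[method] = spacepac.run_spacepac(
                    structure, mapped, alpha=self.alpha, dm=dm,
                    seed=subseeds[method], radii=self.radii,
                    spheres=self.spheres, T=self.sims)
        return out


@dataclass
class QuartPacResults:
    """Fitted clustering results for one structure."""

    model: QuartPac
    seed: int
    quaternary: dict[str, object]
    tertiary: dict[str, dict[str, object]] = field(default_factory=dict)

    # -- outcome access -------------------------------------------------------

    def outcome(self, method: str) -> str:
        return self.quaternary[method].outcome

    def min_p(self, method: str) -> float | None:
        return self.quaternary[method].min_p

    def structure_results(self) -> list[reporting.StructureResult]:
        out = []
        for method, scan in self.quaternary.items():
            clusters = getattr(scan, "clusters", [])
            hotspots = getattr(scan, "hotspots", [])
            out.append(reporting.StructureResult(
                structure_id=self.model.structure.structure_id,
                method=method, outcome=scan.outcome, min_p=scan.min_p,
                n_mutations=self.model.mapped.n, clusters=clusters,
                hotspots=hotspots))
        return out

    def cross_classification(self) -> dict[str, str]:
        """Per-method tertiary-vs-quaternary call (requires fit(tertiary=True))."""
        if not self.tertiary:
            raise ValueError("fit with tertiary=True first")
        out = {}
        for method in self.model.methods:
            tert = [scans[method].outcome for scans in self.tertiary.values()]
            out[method] = reporting.cross_classify(tert, self.outcome(method))
        return out

    # -- tables ---------------------------------------------------------------

    def clusters_frame(self) -> pd.DataFrame:
        rows = []
        for method in ("ipac", "graphpac"):
            if method not in self.quaternary:
                continue
            for idx, c in enumerate(self.quaternary[method].clusters, 1):
                rows.append({
                    "Method": method,
                    "Cluster": idx,
                    "Residues in cluster": c.residues_in_cluster,
                    "Start serial": c.start_serial,
                    "End serial": c.end_serial,
                    "Num. Muts": c.num_mutations,
                    "p-value": c.p_bonferroni,
                })
        return pd.DataFrame(rows, columns=["Method", "Cluster",
                                           "Residues in cluster",
                                           "Start serial", "End serial",
                                           "Num. Muts", "p-value"])

    def hotspots_frame(self) -> pd.DataFrame:
        rows = []
        if "spacepac" in self.quaternary:
            scan = self.quaternary["spacepac"]
            for label, h in zip("ABC", scan.hotspots):
                rows.append({
                    "HotSpot": label,
                    "Sphere center serial": h.center_serial,
                    "Sphere radius (Å)": h.radius,
                    "# Mutations": h.mutation_count,
                })
        return pd.DataFrame(rows, columns=["HotSpot", "Sphere center serial",
                                           "Sphere radius (Å)", "# Mutations"])

    def summary(self) -> str:
        s = self.model.structure
        lines = [
            "Quaternary mutational-clustering scan",
            "=" * 53,
            f"Structure: {s.structure_id}   chains: "
            f"{','.join(c.chain_id for c in s.chains)}   N={s.n_residues}",
            f"Mapped mutations: n={self.model.mapped.n} "
            f"(dropped {self.model.mapped.dropped})   "
            f"alpha={self.model.alpha}",
            "-" * 53,
            f"{'method':<10}{'outcome':<15}{'min p':<12}{'clusters':<9}",
        ]
        for method in self.model.methods:
            scan = self.quaternary[method]
            k = len(getattr(scan, "clusters", [])) or len(
                getattr(scan, "hotspots", []))
            p = "NA" if scan.min_p is None else f"{scan.min_p:.3g}"
            lines.append(f"{method:<10}{scan.outcome:<15}{p:<12}{k:<9}")
        lines.append("=" * 53)
        return "\n".join(lines)

    # -- output files ---------------------------------------------------------

    def to_files(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sid = self.model.structure.structure_id
        cf = self.clusters_frame()
        hf = self.hotspots_frame()
        cf.to_csv(outdir / f"{sid}_clusters.tsv", sep="\t", index=False)
        hf.to_csv(outdir / f"{sid}_hotspots.tsv", sep="\t", index=False)
        summary_rows = [{
            "structure": sid,
            "method": m,
            "outcome": self.quaternary[m].outcome,
            "min_p": "" if self.quaternary[m].min_p is None
            else repr(self.quaternary[m].min_p),
        } for m in self.model.methods]
        pd.DataFrame(summary_rows).to_csv(outdir / f"{sid}_summary.tsv",
                                          sep="\t", index=False)
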