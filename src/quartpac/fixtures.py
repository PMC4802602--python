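"""Deterministic synthetic assemblies and mutation tables.

Real inputs to this package are crystal structures plus a somatic-mutation
table; the generator builds idealized stand-ins for both so the whole
pipeline is testable offline.  Chains are placed on simple geometries
(line, ideal α-helix, grid) at 3.8 Å Cα–Cα spacing, hotspots plant
mutations within a declared spatial spread (possibly straddling a chain
interface), and the remaining background mutations are drawn uniformly
over all residues — exactly the null the clustering statistics assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mutations import MutationRecord
from .structures import Chain, QuaternaryStructure, Residue, write_pdb

__all__ = [
    "ChainSpec",
    "HotspotSpec",
    "FixtureSpec",
    "Fixture",
    "make_structure",
    "plant_mutations",
    "make_fixture",
    "interface_fixture_spec",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8          # Å between consecutive Cα
HELIX_RISE = 1.5          # Å rise per residue of an ideal α-helix
HELIX_TWIST = 100.0       # degrees per residue


@dataclass
class ChainSpec:
    length: int
    geometry: str = "line"              # line | ideal_helix | grid
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # about x,y,z
    reverse: bool = False               # traverse the geometry backwards
    accession: str = "P00001"
    chain_id: str = "A"


@dataclass
class HotspotSpec:
    where: str            # a chain_id, or "interface"
    center: int           # residue index (1-based along the named chain;
                          # along the first chain for "interface")
    spread: float         # Å around the hotspot center
    count: int
    balanced: bool = True  # spread counts evenly over eligible residues
                           # (recurrence lands on neighboring sites rather
                           # than piling on one); False = iid draws


@dataclass
class FixtureSpec:
    chains: list[ChainSpec]
    hotspots: list[HotspotSpec] = field(default_factory=list)
    background_mutations: int = 0
    seed: int = 0
    structure_id: str = "FIX1"


@dataclass
class Fixture:
    spec: FixtureSpec
    structure: QuaternaryStructure
    pdb_text: str
    mutation_tsv: str
    fasta_text: str
    records: list[MutationRecord]
    truth: dict


def _rotation_matrix(deg: tuple[float, float, float]) -> np.ndarray:
    ax, ay, az = (math.radians(v) for v in deg)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def _geometry_coords(geometry: str, length: int) -> np.ndarray:
    if geometry == "line":
        return np.column_stack([CA_SPACING * np.arange(length),
                                np.zeros(length), np.zeros(length)])
    if geometry == "ideal_helix":
        # radius chosen so consecutive Cα sit 3.8 Å apart with 1.5 Å rise
        chord = math.sqrt(CA_SPACING ** 2 - HELIX_RISE ** 2)
        radius = chord / (2.0 * math.sin(math.radians(HELIX_TWIST / 2)))
        t = np.radians(HELIX_TWIST) * np.arange(length)
        return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                                HELIX_RISE * np.arange(length)])
    if geometry == "grid":
        side = math.ceil(length ** (1.0 / 3.0))
        idx = np.arange(length)
        x = idx % side
        y = (idx // side) % side
        z = idx // (side * side)
        return CA_SPACING * np.column_stack([x, y, z]).astype(float)
    raise ValueError(f"unknown geometry {geometry!r}")


def _sequence_for(accession: str, length: int, seed: int) -> str:
    # deterministic per (fixture seed, accession); independent of chain order
    h = int.from_bytes(accession.encode(), "big") % (2 ** 31)
    rng = np.random.default_rng((seed * 1_000_003 + h) % (2 ** 31))
    return "".join(rng.choice(list(_AA), size=length))


def make_structure(spec: FixtureSpec) -> tuple[QuaternaryStructure, str]:
    """Build the assembly and its PDB text; same spec → identical bytes."""
    if not spec.chains:
        raise ValueError("fixture needs at least one chain")
    lengths: dict[str, int] = {}
    for cs in spec.chains:
        if lengths.setdefault(cs.accession, cs.length) != cs.length:
            raise ValueError(f"chains sharing accession {cs.accession} must "
                             "have equal lengths")
    chains: list[Chain] = []
    gidx = 0
    serial = 0
    all_xyz: list[np.ndarray] = []
    for cs in spec.chains:
        xyz = _geometry_coords(cs.geometry, cs.length)
        if cs.reverse:
            xyz = xyz[::-1].copy()
        xyz = xyz @ _rotation_matrix(cs.rotation_deg).T + np.asarray(cs.offset)
        seq = _sequence_for(cs.accession, cs.length, spec.seed)
        residues = []
        for i in range(cs.length):
            gidx += 1
            serial += 1
            residues.append(Residue(
                chain_id=cs.chain_id,
                author_seq_number=i + 1,
                insertion_code=None,
                amino_acid=seq[i],
                calpha_xyz=tuple(np.round(xyz[i], 3)),
                atom_serial=serial,
                global_index=gidx,
            ))
        chains.append(Chain(cs.chain_id, cs.accession, residues))
        all_xyz.append(xyz)
    # clash check between different chains
    for a in range(len(all_xyz)):
        for b in range(a + 1, len(all_xyz)):
            diff = all_xyz[a][:, None, :] - all_xyz[b][None, :, :]
            dmin = np.sqrt((diff ** 2).sum(axis=2)).min()
            if dmin < 1.0:
                raise ValueError(
                    f"chains {spec.chains[a].chain_id} and "
                    f"{spec.chains[b].chain_id} clash ({dmin:.2f} Å)")
    structure = QuaternaryStructure(structure_id=spec.structure_id,
                                    chains=chains)
    return structure, write_pdb(structure)


def _hotspot_point(spec: FixtureSpec, structure: QuaternaryStructure,
                   hs: HotspotSpec) -> np.ndarray:
    if hs.where == "interface":
        first = structure.chains[0]
        anchor = np.asarray(first.residues[hs.center - 1].calpha_xyz)
        # midpoint to the closest residue on any other chain
        best, best_d = anchor, np.inf
        for ch in structure.chains[1:]:
            xyz = np.array([r.calpha_xyz for r in ch.residues])
            d = np.sqrt(((xyz - anchor) ** 2).sum(axis=1))
            j = int(np.argmin(d))
            if d[j] < best_d:
                best_d, best = d[j], xyz[j]
        return (anchor + best) / 2.0
    chain = structure.chain(hs.where)
    return np.asarray(chain.residues[hs.center - 1].calpha_xyz)


def plant_mutations(
    spec: FixtureSpec,
    structure: QuaternaryStructure,
) -> tuple[str, dict, list[MutationRecord]]:
    """Draw hotspot + background mutations and emit the mutation TSV.

    Returns (tsv_text, truth, records); truth maps each hotspot to the set
    of global residue indices within its spread (the positive-label set)
    and lists the planted global indices.
    """
    rng = np.random.default_rng(spec.seed)
    residues = structure.residues
    xyz = structure.coordinates()
    chosen: list[int] = []     # 0-based residue indices
    truth: dict = {"hotspots": [], "background": []}
    for hs in spec.hotspots:
        if hs.count == 0:
            raise ValueError("declared hotspot with mutation count 0")
        point = _hotspot_point(spec, structure, hs)
        d = np.sqrt(((xyz - point) ** 2).sum(axis=1))
        eligible = np.nonzero(d <= hs.spread)[0]
        if eligible.size == 0:
            raise ValueError(f"no residue within {hs.spread} Å of hotspot "
                             f"{hs.where}:{hs.center}")
        if hs.balanced:
            # recurrence spreads over neighboring sites instead of piling on
            # one; an interface hotspot additionally draws evenly from every
            # participating subunit (that is what makes it an interface site)
            chain_of = {r.global_index - 1: r.chain_id for r in residues}
            if hs.where == "interface":
                groups = {}
                for e in eligible:
                    groups.setdefault(chain_of[int(e)], []).append(int(e))
                group_list = [np.asarray(groups[c])
                              for c in sorted(groups)]
            else:
                group_list = [eligible]
            share = [hs.count // len(group_list)] * len(group_list)
            for extra in range(hs.count % len(group_list)):
                share[extra] += 1
            picks = []
            for grp, cnt in zip(group_list, share):
                reps = -(-cnt // grp.size)
                pool = np.concatenate([rng.permutation(grp)
                                       for _ in range(reps)])
                picks.extend(int(p) for p in pool[:cnt])
            picks = np.asarray(picks)
        else:
            picks = rng.choice(eligible, size=hs.count, replace=True)
        chosen.extend(int(p) for p in picks)
        truth["hotspots"].append({
            "where": hs.where,
            "center": hs.center,
            "spread": hs.spread,
            "residues": [int(i) + 1 for i in eligible],
            "planted": [int(p) + 1 for p in picks],
        })
    if spec.background_mutations:
        picks = rng.integers(0, len(residues), size=spec.background_mutations)
        chosen.extend(int(p) for p in picks)
        truth["background"] = [int(p) + 1 for p in picks]

    records: list[MutationRecord] = []
    chain_pos: dict[int, tuple[str, int, str]] = {}
    for ch in structure.chains:
        for i, r in enumerate(ch.residues):
            acc = ch.uniprot_accession or "P00000"
            chain_pos[r.global_index] = (acc, i + 1, r.amino_acid)
    for j, idx0 in enumerate(chosen):
        gidx = residues[idx0].global_index
        acc, pos, wt = chain_pos[gidx]
        mut = rng.choice([a for a in _AA if a != wt])
        records.append(MutationRecord(
            uniprot_accession=acc,
            gene=f"GENE_{acc}",
            canonical_position=pos,
            wt_aa=wt,
            mut_aa=str(mut),
            sample_id=f"S{j + 1:04d}",
            somatic_status="Confirmed somatic variant",
            screen_type="whole genome",
            mutation_class="Substitution - Missense",
        ))
    header = "uniprot\tgene\tposition\twt\tmut\tsample\tstatus\tscreen\tclass"
    lines = [header] + [
        "\t".join([r.uniprot_accession, r.gene, str(r.canonical_position),
                   r.wt_aa, r.mut_aa, r.sample_id, r.somatic_status,
                   r.screen_type, r.mutation_class])
        for r in records
    ]
    return "\n".join(lines) + "\n", truth, records


def fixture_fasta(spec: FixtureSpec) -> str:
    seen: dict[str, str] = {}
    for cs in spec.chains:
        if cs.accession not in seen:
            seen[cs.accession] = _sequence_for(cs.accession, cs.length,
                                               spec.seed)
    out = []
    for acc, seq in seen.items():
        out.append(f">{acc}")
        out.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


def make_fixture(spec: FixtureSpec) -> Fixture:
    structure, pdb_text = make_structure(spec)
    tsv, truth, records = plant_mutations(spec, structure)
    return Fixture(spec=spec, structure=structure, pdb_text=pdb_text,
                   mutation_tsv=tsv, fasta_text=fixture_fasta(spec),
                   records=records, truth=truth)


def interface_fixture_spec(
    seed: int = 0,
    chain_length: int = 150,
    core_mutations: int = 6,
    region_mutations: int = 14,
    background_mutations: int = 10,
    core_spread: float = 5.0,
    region_spread: float = 150.0,
) -> FixtureSpec:
    """Canonical two-chain interface-hotspot fixture.

    Two parallel 150-residue chains run 5 Å apart (every station is an
    interface contact).  The planted signal has two parts, both straddling
    the interface: a tight core of recurrent mutations at the distal tip of
    the dimer (a few residues of *each* subunit), and a broad mutation-
    enriched interface region mid-chain.  Each single chain carries only
    half of either signal — a handful of core mutations and a diffuse
    region share — which is the regime where the assembly-level scan has
    power that no per-chain scan matches.
    """
    chains = [
        ChainSpec(length=chain_length, geometry="line", accession="P10001",
                  chain_id="A"),
        ChainSpec(length=chain_length, geometry="line", accession="P10002",
                  chain_id="B", offset=(0.0, 5.0, 0.0)),
    ]
    hotspots = [
        HotspotSpec(where="interface", center=chain_length,
                    spread=core_spread, count=core_mutations),
        HotspotSpec(where="interface", center=chain_length // 2,
                    spread=region_spread, count=region_mutations),
    ]
    return FixtureSpec(chains=chains, hotspots=hotspots,
                       background_mutations=background_mutations, seed=seed,
                       structure_id="IFACE")
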