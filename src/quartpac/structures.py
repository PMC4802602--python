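"""Quaternary-structure input: multi-chain Cα parsing and distance geometry.

Every residue of every polymer chain in the first model is reduced to the
coordinates of its alpha carbon.  Residues are numbered with a single global
index 1..N running over chains in file order, so that downstream statistics
can treat the whole assembly as one arrangement of N sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Residue",
    "Chain",
    "QuaternaryStructure",
    "parse_structure",
    "distance_matrix",
    "write_pdb",
]


@dataclass(frozen=True)
class Residue:
    """One amino acid represented by its Cα atom."""

    chain_id: str
    author_seq_number: int
    insertion_code: str | None
    amino_acid: str
    calpha_xyz: tuple[float, float, float]
    atom_serial: int
    global_index: int  # 1-based over the whole assembly


@dataclass
class Chain:
    chain_id: str
    uniprot_accession: str | None
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclass
class QuaternaryStructure:
    """All polymer chains of one structure file, flattened to Cα residues."""

    structure_id: str
    chains: list[Chain]

    @property
    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in global-index order."""
        return np.array([r.calpha_xyz for r in self.residues], dtype=float)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")

    def set_accessions(self, mapping: dict[str, str]) -> None:
        """Attach UniProt accessions to chains by chain id."""
        for c in self.chains:
            if c.chain_id in mapping:
                c.uniprot_accession = mapping[c.chain_id]

    def subset_chain(self, chain_id: str) -> "QuaternaryStructure":
        """Single-chain (tertiary) view with global indices renumbered 1..len."""
        src = self.chain(chain_id)
        residues = [
            Residue(
                chain_id=r.chain_id,
                author_seq_number=r.author_seq_number,
                insertion_code=r.insertion_code,
                amino_acid=r.amino_acid,
                calpha_xyz=r.calpha_xyz,
                atom_serial=r.atom_serial,
                global_index=i + 1,
            )
            for i, r in enumerate(src.residues)
        ]
        return QuaternaryStructure(
            structure_id=f"{self.structure_id}:{chain_id}",
            chains=[Chain(chain_id, src.uniprot_accession, residues)],
        )


class StructureParseError(ValueError):
    pass


_AA3_TO_1_EXTRA = {
    # common modified residues mapped to the nearest standard letter
    "MSE": "M",
    "SEC": "C",
    "PYL": "K",
}


def _one_letter(resname: str) -> str:
    if resname in _AA3_TO_1_EXTRA:
        return _AA3_TO_1_EXTRA[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _pick_calpha(res: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy Cα conformer; ties resolved to the first in file."""
    best = None
    for atom in res:
        if atom.name == "CA" and atom.element.name != "Ca":
            if best is None or atom.occ > best.occ:
                best = atom
    return best


def parse_structure(
    file_text: str,
    format: str = "pdb",
    structure_id: str | None = None,
) -> QuaternaryStructure:
    """Parse the first model of a PDB or mmCIF file into Cα residues.

    HETATM ligands and waters are excluded, but modified amino acids that are
    part of the polymer (e.g. MSE) are kept with their letter mapped to the
    nearest standard residue.  Residues without a Cα are skipped; alternate
    locations resolve to the highest-occupancy conformer.
    """
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(file_text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(file_text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"malformed structure file: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError("structure contains no models")
    model = st[0]  # first model only (NMR ensembles take model 1)

    chains: list[Chain] = []
    gidx = 0
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if not _is_amino_acid(res.name):
                continue
            atom = _pick_calpha(res)
            if atom is None:
                continue
            gidx += 1
            icode = res.seqid.icode.strip() or None
            residues.append(
                Residue(
                    chain_id=ch.name,
                    author_seq_number=res.seqid.num,
                    insertion_code=icode,
                    amino_acid=_one_letter(res.name),
                    calpha_xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    atom_serial=atom.serial,
                    global_index=gidx,
                )
            )
        if residues:
            chains.append(Chain(ch.name, None, residues))

    if gidx == 0:
        raise StructureParseError("no Cα atoms found in any polymer chain")
    sid = structure_id or (st.name.strip() if st.name.strip() else "structure")
    return QuaternaryStructure(structure_id=sid, chains=chains)


def distance_matrix(structure: QuaternaryStructure) -> np.ndarray:
    """N×N Euclidean Cα–Cα distances (Å) across all chains."""
    xyz = structure.coordinates()
    if xyz.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(xyz))


def write_pdb(structure: QuaternaryStructure) -> str:
    """Emit minimal wwPDB v3.3 ATOM records (Cα only) plus TER/END."""
    lines = []
    serial_check: set[int] = set()
    for chain in structure.chains:
        for r in chain.residues:
            if r.atom_serial in serial_check:
                raise ValueError(f"duplicate atom serial {r.atom_serial}")
            serial_check.add(r.atom_serial)
            x, y, z = r.calpha_xyz
            resname = _three_letter(r.amino_acid)
            icode = r.insertion_code or ""
            lines.append(
                f"ATOM  {r.atom_serial:5d}  CA  {resname:>3s} {r.chain_id[:1]}"
                f"{r.author_seq_number:4d}{icode:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


_AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _three_letter(aa: str) -> str:
    return _AA1_TO_3.get(aa.upper(), "UNK")
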