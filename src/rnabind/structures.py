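"""Protein–RNA complex parsing and binding-residue labelling.

A residue of the protein is an RNA-binding residue when at least one of its
atoms lies strictly within a distance cutoff (default 5.0 Å) of any atom of
the bound RNA.  Labels use the ±1 convention: +1 binding, −1 non-binding.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tables import RNA_RESNAMES, THREE_TO_ONE

DEFAULT_BINDING_CUTOFF = 5.0


class StructureError(ValueError):
    """Raised for unparsable or inconsistent structure input."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: non-finite or malformed position")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_index: int            # 1-based consecutive position within the chain
    aa_code: str              # one-letter amino acid, or A/U/G/C for RNA
    atoms: list[Atom]
    pdb_resseq: int | None = None  # author residue number, for reporting

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.chain_id}:{self.seq_index} has no atoms")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        if not atoms:  # hydrogen-only residue: fall back to all atoms
            atoms = self.atoms
        return np.array([a.position for a in atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


Chain = list[Residue]


@dataclass
class Complex:
    """A protein–RNA complex: ≥1 protein chain and (for labelling) ≥1 RNA chain."""

    id: str
    protein_chains: list[Chain]
    rna_chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_chains or not any(self.protein_chains):
            raise StructureError(f"complex {self.id}: no protein residues")

    def protein_residues(self) -> list[Residue]:
        return [r for chain in self.protein_chains for r in chain]

    def rna_residues(self) -> list[Residue]:
        return [r for chain in self.rna_chains for r in chain]

    def rna_atom_coords(self) -> np.ndarray:
        coords = [a.position for r in self.rna_residues() for a in r.atoms]
        return np.array(coords, dtype=float)


@dataclass
class BindingAnnotation:
    """Per-residue binding labels, y ∈ {−1, +1}, keyed by (chain_id, seq_index)."""

    labels: dict[tuple[str, int], int]

    def label(self, residue: Residue) -> int:
        return self.labels[residue.key]

    def array(self, chain: Chain) -> np.ndarray:
        return np.array([self.labels[r.key] for r in chain], dtype=int)

    def positives(self) -> int:
        return sum(1 for v in self.labels.values() if v == 1)

    def to_tsv(self) -> str:
        lines = ["residue\tlabel"]
        for (cid, idx), y in sorted(self.labels.items()):
            lines.append(f"{cid}:{idx}\t{y:+d}")
        return "\n".join(lines) + "\n"


def _convert_chain(bio_chain, chain_id: str, is_rna: bool) -> Chain:
    residues: Chain = []
    for res in bio_chain:
        hetfield = res.id[0]
        if hetfield != " ":  # waters and heteroatoms excluded
            continue
        resname = res.get_resname().strip()
        if is_rna:
            code = RNA_RESNAMES.get(resname)
        else:
            code = THREE_TO_ONE.get(resname)
        if code is None:
            warnings.warn(
                f"skipping non-standard residue {resname} in chain {chain_id}",
                stacklevel=3)
            continue
        atoms = []
        for atom in res.get_atoms():  # disordered atoms yield the selected
            # altLoc (highest occupancy) only
            pos = np.asarray(atom.get_coord(), dtype=float)
            element = (atom.element or atom.get_name()[0]).strip() or "C"
            atoms.append(Atom(atom.get_name(), element, pos))
        if not atoms:
            continue
        residues.append(Residue(chain_id, len(residues) + 1, code, atoms,
                                pdb_resseq=res.id[1]))
    return residues


def parse_structure(pdb_text: str,
                    protein_chain_ids: list[str] | tuple[str, ...],
                    rna_chain_ids: list[str] | tuple[str, ...] = (),
                    structure_id: str = "complex") -> Complex:
    """Parse PDB-format text into a :class:`Complex`.

    Only ATOM records of the named chains are used; waters/heteroatoms are
    excluded and alternate locations are collapsed to the highest-occupancy
    conformer.  Non-standard residues are skipped with a warning.

    Raises
    ------
    StructureError
        If nothing parses or a named chain is absent.
    """
    from Bio.PDB import PDBParser

    if not pdb_text.strip():
        raise StructureError("empty PDB text: nothing to parse")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except Exception as exc:  # malformed beyond recovery
        raise StructureError(f"unparsable PDB text: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError("no models in PDB text")
    model = models[0]
    present = {c.id for c in model}

    protein_chains: list[Chain] = []
    for cid in protein_chain_ids:
        if cid not in present:
            raise StructureError(f"protein chain {cid!r} not found in structure")
        chain = _convert_chain(model[cid], cid, is_rna=False)
        if not chain:
            raise StructureError(f"protein chain {cid!r} has no parsable residues")
        protein_chains.append(chain)

    rna_chains: list[Chain] = []
    for cid in rna_chain_ids:
        if cid not in present:
            raise StructureError(f"RNA chain {cid!r} not found in structure")
        chain = _convert_chain(model[cid], cid, is_rna=True)
        if not chain:
            raise StructureError(f"RNA chain {cid!r} has no parsable residues")
        rna_chains.append(chain)

    return Complex(structure_id, protein_chains, rna_chains)


def label_binding(complex_: Complex,
                  cutoff: float = DEFAULT_BINDING_CUTOFF) -> BindingAnnotation:
    """Label every protein residue +1 iff its minimum atom distance to any
    RNA atom is strictly below ``cutoff`` (Å); −1 otherwise."""
    rna_coords = complex_.rna_atom_coords()
    if rna_coords.size == 0:
        raise StructureError(
            f"complex {complex_.id}: no RNA atoms — cannot label binding residues")
    tree = cKDTree(rna_coords)
    labels: dict[tuple[str, int], int] = {}
    for res in complex_.protein_residues():
        dmin = tree.query(res.coords())[0].min()
        labels[res.key] = 1 if dmin < cutoff else -1
    return BindingAnnotation(labels)


def binding_events(complex_: Complex,
                   cutoff: float = DEFAULT_BINDING_CUTOFF
                   ) -> list[tuple[Residue, str]]:
    """Enumerate (protein residue, nucleotide code) contacts under the
    distance rule.  Each distinct (residue, RNA nucleotide) pair with any
    atom–atom distance strictly below ``cutoff`` counts once.  Used to count
    triplet–nucleotide interactions for the interaction-propensity table."""
    events: list[tuple[Residue, str]] = []
    rna = complex_.rna_residues()
    if not rna:
        return events
    trees = [(nres, cKDTree(nres.coords())) for nres in rna]
    for res in complex_.protein_residues():
        pc = res.coords()
        for nres, tree in trees:
            if tree.query(pc)[0].min() < cutoff:
                events.append((res, nres.aa_code))
    return events
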