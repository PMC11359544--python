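"""Molecular-graph parsing, validation and the structural screening criteria.

SMILES strings are parsed and sanitized with RDKit.  A parsed molecule is
exposed as a light-weight :class:`MoleculeGraph` carrying atoms, bonds and the
smallest set of smallest rings, which is all the downstream structural
criteria need.  Malformed SMILES never raise: they come back as an
:class:`InvalidSmiles` marker so generation statistics (valid fraction) can be
computed over raw model output.

The three structural criteria identify molecules expected to absorb at longer
wavelengths:

1. the molecule contains a polyatomic ring (any cycle of >= 3 atoms);
2. the ring system contains more than one unsaturated bond (double, triple
   or aromatic bonds between ring atoms);
3. at least one ring member is a non-carbon atom (N, O, S, ...).

A molecule *weakly passes* when at least two of the three hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from rdkit import Chem
from rdkit import RDLogger

# RDKit parse warnings are noise when scoring raw generator output.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "MoleculeGraph",
    "InvalidSmiles",
    "CriterionVerdict",
    "parse_smiles",
    "has_heteroatom",
    "evaluate_criteria",
    "read_smiles_file",
]

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class MoleculeGraph:
    """A sanitized molecule: atoms, bonds, SSSR rings and canonical SMILES."""

    atoms: tuple  # (element symbol, formal charge, aromatic flag)
    bonds: tuple  # (i, j, order) with order in {single, double, triple, aromatic}
    rings: tuple  # tuples of atom indices (SSSR)
    source_smiles: str
    canonical_smiles: str
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    def ring_atom_indices(self) -> set:
        return {i for ring in self.rings for i in ring}

    def ring_bonds(self) -> list:
        """Bonds whose endpoints are joined inside some ring."""
        ring_bonds = []
        ri = self.mol.GetRingInfo()
        seen = {b for ring in ri.BondRings() for b in ring}
        for bidx in sorted(seen):
            bond = self.mol.GetBondWithIdx(bidx)
            ring_bonds.append(
                (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), _BOND_ORDER[bond.GetBondType()])
            )
        return ring_bonds


@dataclass(frozen=True)
class InvalidSmiles:
    """Marker returned for unparseable or unsanitizable input."""

    smiles: str
    reason: str

    def __bool__(self) -> bool:  # allows `if not graph: ...`
        return False


@dataclass(frozen=True)
class CriterionVerdict:
    """Outcome of the three structural judgments for one molecule."""

    has_polyatomic_ring: bool
    ring_multi_unsaturation: bool
    ring_has_heteroatom: bool

    @property
    def n_satisfied(self) -> int:
        return sum(
            (self.has_polyatomic_ring, self.ring_multi_unsaturation, self.ring_has_heteroatom)
        )

    @property
    def weakened_pass(self) -> bool:
        """At least two of the three judgments hold."""
        return self.n_satisfied >= 2

    @property
    def full_pass(self) -> bool:
        return self.n_satisfied == 3


def parse_smiles(text: str) -> Union[MoleculeGraph, InvalidSmiles]:
    """Parse and sanitize a SMILES string.

    Returns a :class:`MoleculeGraph` for chemically valid input and an
    :class:`InvalidSmiles` marker otherwise.  Raises only on empty input,
    which indicates a caller bug rather than a bad molecule.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty SMILES input")
    text = text.strip()
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        return InvalidSmiles(text, "unparseable SMILES syntax")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # valence errors, kekulization failures, ...
        return InvalidSmiles(text, f"sanitization failed: {exc}")
    if any(b.GetBondType() not in _BOND_ORDER for b in mol.GetBonds()):
        # query/dative bonds (e.g. from '~' in raw generator output) are not
        # real covalent structures
        return InvalidSmiles(text, "unsupported bond type")
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic()) for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in mol.GetBonds()
    )
    rings = tuple(tuple(r) for r in mol.GetRingInfo().AtomRings())
    return MoleculeGraph(
        atoms=atoms,
        bonds=bonds,
        rings=rings,
        source_smiles=text,
        canonical_smiles=Chem.MolToSmiles(mol),
        mol=mol,
    )


def _require_valid(graph) -> MoleculeGraph:
    if isinstance(graph, InvalidSmiles):
        raise ValueError(f"invalid molecule: {graph.smiles!r} ({graph.reason})")
    if not isinstance(graph, MoleculeGraph):
        raise TypeError(f"expected MoleculeGraph, got {type(graph).__name__}")
    return graph


def has_heteroatom(graph: MoleculeGraph) -> bool:
    """True iff any atom is neither carbon nor hydrogen."""
    graph = _require_valid(graph)
    return any(symbol not in ("C", "H") for symbol, _, _ in graph.atoms)


def evaluate_criteria(graph: MoleculeGraph) -> CriterionVerdict:
    """Apply the three structural judgments to a valid molecule.

    Judgment 2 counts unsaturated bonds over the union of all ring bonds
    (the ring *system*), so fused rings pool their unsaturation.  Aromatic
    bonds count as unsaturated.
    """
    graph = _require_valid(graph)
    has_ring = len(graph.rings) > 0
    ring_bonds = graph.ring_bonds() if has_ring else []
    n_unsat = sum(1 for _, _, order in ring_bonds if order != "single")
    ring_atoms = graph.ring_atom_indices()
    has_het = any(graph.atoms[i][0] != "C" for i in ring_atoms)
    return CriterionVerdict(
        has_polyatomic_ring=has_ring,
        ring_multi_unsaturation=n_unsat >= 2,
        ring_has_heteroatom=has_het,
    )


def read_smiles_file(path) -> list:
    """Read a .smi / plain-text file: one SMILES per line, optional
    tab-separated name; blank lines and '#' comments are skipped."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        records.append(line.split("\t")[0].split()[0])
    return records


def write_smiles_file(path, smiles: Iterable[str], header: str | None = None) -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.extend(smiles)
    Path(path).write_text("\n".join(lines) + "\n")
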