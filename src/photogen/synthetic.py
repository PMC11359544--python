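"""Synthetic small-molecule corpora with planted structure–energy signal.

Real training data pairs small organic molecules (<= 23 atoms; H/C/N/O/S/Cl)
with first-excitation energies spanning 4.13–12.41 eV, where conjugated /
heteroatom-bearing rings sit at the low-energy (long-wavelength) end.  The
generator emulates exactly that: molecules are assembled from three template
families chosen to cover every branch of the structural-criteria engine —

* positives: 5/6-membered heteroaromatics with randomized substituents
  (all three criteria hold);
* ring-only cases: saturated carbocycles (criterion 1 only);
* negatives: acyclic amines/alcohols/chains (no criterion holds);

and the planted energy is a deterministic function of structure,

    E = 12.0 - 0.55 * (# unsaturated ring bonds) - 0.45 * (# ring heteroatoms)
        - 0.12 * (# heavy atoms) + noise,   clipped to the 4.13–12.41 eV range,

so criterion-positive molecules have strictly lower noiseless energies than
negatives and a regression model has recoverable signal.  3D coordinates for
featurization come from seeded distance-geometry embedding followed by MMFF
force-field relaxation.

A reader for the QM7b container (a MATLAB file with Coulomb matrices ``X``
and a property matrix ``T``) is included so the real dataset can be dropped
in; tests use a miniature synthetic file in the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_graph import MoleculeGraph, parse_smiles, evaluate_criteria

__all__ = [
    "FixtureSpec",
    "generate_corpus",
    "coordinates_for",
    "read_qm7b",
    "POSITIVE_TEMPLATES",
    "RING_ONLY_TEMPLATES",
    "NEGATIVE_TEMPLATES",
    "KCAL_PER_MOL_PER_EV",
]

KCAL_PER_MOL_PER_EV = 23.0605

# Heteroaromatic cores: ring + >=2 unsaturated ring bonds + ring heteroatom.
POSITIVE_TEMPLATES = [
    "c1ccncc1",   # pyridine
    "c1cc[nH]c1", # pyrrole
    "c1ccoc1",    # furan
    "c1ccsc1",    # thiophene
    "c1cnc[nH]1", # imidazole
    "c1cncnc1",   # pyrimidine
    "c1cscn1",    # thiazole
    "c1conc1",    # isoxazole
]
# Saturated all-carbon rings: criterion 1 only.
RING_ONLY_TEMPLATES = ["C1CCCCC1", "C1CCCC1", "C1CCC1", "C1CC1"]
# Acyclic molecules: no criterion holds.
NEGATIVE_TEMPLATES = [
    "CCO", "CCN", "CCC", "CCOC", "CCS", "CC(C)O", "CC(N)C", "CCCO",
    "CC(C)CO", "CCNC", "CC(C)N", "CCCCl", "CC(O)CC", "NCCO", "CCC(C)N",
]
_SUBSTITUENTS = ["", "C", "CC", "OC", "NC", "CO", "C(C)C", "ClC", "SC", "OCC"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic corpus draw."""

    n_molecules: int = 200
    positive_fraction: float = 0.5
    ring_only_fraction: float = 0.0
    energy_range: tuple = (4.13, 12.41)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.positive_fraction + self.ring_only_fraction <= 1.0:
            raise ValueError("fractions must sum to at most 1")


def _decorate(template: str, sub: str) -> str:
    """Prefix a substituent onto a ring/chain template; validated downstream."""
    return sub + template if sub else template


def planted_energy(graph: MoleculeGraph) -> float:
    """Noiseless structure-determined energy (eV), before clipping."""
    verdict_bonds = sum(1 for _, _, o in graph.ring_bonds() if o != "single")
    ring_het = sum(1 for i in graph.ring_atom_indices() if graph.atoms[i][0] != "C")
    return 12.0 - 0.55 * verdict_bonds - 0.45 * ring_het - 0.12 * graph.n_heavy_atoms


def generate_corpus(spec: FixtureSpec) -> list:
    """Draw (SMILES, energy_eV) pairs; deterministic under the spec's seed.

    All emitted SMILES are chemically valid by construction (each candidate
    is parsed before acceptance) and every template family exercises a
    distinct branch of the criteria engine.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_molecules * spec.positive_fraction))
    n_ring = int(round(spec.n_molecules * spec.ring_only_fraction))
    n_neg = spec.n_molecules - n_pos - n_ring

    def draw(templates, want, n):
        out = []
        while len(out) < n:
            t = templates[int(rng.integers(len(templates)))]
            sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            g = parse_smiles(_decorate(t, sub))
            if not isinstance(g, MoleculeGraph):
                continue
            v = evaluate_criteria(g)
            if want == "pos" and not v.full_pass:
                continue
            if want == "ring" and not (v.has_polyatomic_ring and v.n_satisfied == 1):
                continue
            if want == "neg" and v.n_satisfied != 0:
                continue
            out.append(g)
        return out

    graphs = draw(POSITIVE_TEMPLATES, "pos", n_pos) + \
        draw(RING_ONLY_TEMPLATES, "ring", n_ring) + \
        draw(NEGATIVE_TEMPLATES, "neg", n_neg)
    lo, hi = spec.energy_range
    records = []
    for g in graphs:
        e = planted_energy(g) + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        records.append((g.source_smiles, float(np.clip(e, lo, hi))))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def coordinates_for(graph: MoleculeGraph, seed: int = 0):
    """Seeded 3D geometry: distance-geometry embedding + MMFF relaxation.

    Returns an (n_atoms_with_H, 3) array in Angstrom and the matching atomic
    numbers, or None when embedding fails (caller skips and counts).
    """
    mol = Chem.AddHs(Chem.Mol(graph.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # unrelaxed DG geometry is still usable
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    numbers = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
    return numbers, coords


def read_qm7b(path, excitation_column: int, energy_unit: str = "eV") -> list:
    """Read a QM7b-layout container: ``X`` (n, 23, 23) Coulomb matrices and
    ``T`` (n, n_properties); returns (CoulombMatrix, energy_eV) pairs.

    ``excitation_column`` selects which property column holds the
    first-excitation energy; ``energy_unit`` converts kcal/mol to eV when
    the stored unit differs.
    """
    from scipy.io import loadmat

    from .excitation import CoulombMatrix

    try:
        data = loadmat(path)
        X, T = data["X"], data["T"]
    except Exception as exc:
        raise ValueError(
            "malformed QM7b container: expected a MATLAB file with keys "
            "'X' (n x 23 x 23 Coulomb matrices) and 'T' (n x p properties)"
        ) from exc
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("malformed QM7b container: X must be (n, a, a)")
    if not 0 <= excitation_column < T.shape[1]:
        raise ValueError(
            f"excitation_column {excitation_column} out of range for "
            f"{T.shape[1]} properties"
        )
    if energy_unit == "eV":
        factor = 1.0
    elif energy_unit in ("kcal/mol", "kcal"):
        factor = 1.0 / KCAL_PER_MOL_PER_EV
    else:
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    records = []
    for i in range(X.shape[0]):
        m = np.asarray(X[i], dtype=float)
        n_atoms = int((np.abs(m).sum(axis=1) > 0).sum())
        records.append(
            (CoulombMatrix(matrix=m, n_atoms=n_atoms), float(T[i, excitation_column]) * factor)
        )
    return records


def featurized_dataset(spec: FixtureSpec, max_atoms: int = 23):
    """Corpus -> (features, energies, smiles) for regression experiments.

    Embeds each molecule (seeded per record), builds the sorted Coulomb
    matrix and flattens it; embedding failures and molecules exceeding
    ``max_atoms`` (with hydrogens) are skipped and counted in the returned
    stats dict.
    """
    from .excitation import coulomb_matrix, featurize

    rng = np.random.default_rng(spec.seed + 1)
    feats, energies, smiles = [], [], []
    n_skipped = 0
    for smi, e in generate_corpus(spec):
        g = parse_smiles(smi)
        got = coordinates_for(g, seed=int(rng.integers(2**31 - 1)))
        if got is None:
            n_skipped += 1
            continue
        numbers, coords = got
        if len(numbers) > max_atoms:
            n_skipped += 1
            continue
        feats.append(featurize(coulomb_matrix(numbers, coords, max_atoms)))
        energies.append(e)
        smiles.append(smi)
    return (np.array(feats), np.array(energies), smiles,
            {"n_skipped": n_skipped})
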