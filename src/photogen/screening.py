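"""Drug-likeness, synthesizability and wavelength-band triage.

* QED — quantitative estimate of drug-likeness: the weighted geometric mean
  of the eight published desirability functions (MW, ALOGP, HBA, HBD, PSA,
  ROTB, AROM, ALERTS), in [0, 1]; computed with RDKit's reference
  implementation using the published mean weights (its default variant).
* SAscore — Ertl–Schuffenhauer synthetic accessibility: fragment
  contributions from the published PubChem-derived score table minus a
  complexity penalty, mapped to [1, 10] (higher = harder to make).  Uses the
  published implementation and fragment table distributed with RDKit, so
  results are version-pinned to the installed distribution.
* Band classification of an absorption wavelength into far-UV (< 200 nm),
  UV [200, 400), visible [400, 750) and NIR [750, 2000); intervals are
  left-closed/right-open.
"""

from __future__ import annotations

import functools
import os
import sys
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from rdkit.Chem import QED as _QED

from .chem_graph import MoleculeGraph, parse_smiles, _require_valid

__all__ = [
    "qed",
    "sascore",
    "classify_band",
    "rank_select",
    "ScreeningScores",
    "score_molecules",
    "load_reference_table",
    "BAND_EDGES",
]

# (name, lower-inclusive, upper-exclusive) in nm
BAND_EDGES = (
    ("far-UV", 0.0, 200.0),
    ("UV", 200.0, 400.0),
    ("visible", 400.0, 750.0),
    ("NIR", 750.0, 2000.0),
)


@functools.lru_cache(maxsize=1)
def _sascorer():
    """The published synthetic-accessibility scorer shipped with RDKit."""
    from rdkit.Chem import RDConfig

    path = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if not os.path.isdir(path):
        raise RuntimeError(
            "RDKit SA_Score contrib (published fragment table) not found at "
            f"{path}"
        )
    if path not in sys.path:
        sys.path.append(path)
    import sascorer  # noqa: deferred, lives in the RDKit distribution

    return sascorer


def qed(graph: MoleculeGraph) -> float:
    """Drug-likeness in [0, 1]; weighted geometric mean of the eight
    desirability functions with the published mean weights (the reference
    implementation's default)."""
    graph = _require_valid(graph)
    return float(_QED.qed(graph.mol))


def sascore(graph: MoleculeGraph) -> float:
    """Synthetic accessibility on the published 1 (easy) .. 10 (hard) scale."""
    graph = _require_valid(graph)
    return float(_sascorer().calculateScore(graph.mol))


def classify_band(wavelength_nm: float) -> str:
    """Assign an absorption wavelength to its spectral band."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    for name, lo, hi in BAND_EDGES:
        if lo <= wavelength_nm < hi:
            return name
    return "beyond-NIR"


@dataclass(frozen=True)
class ScreeningScores:
    smiles: str
    qed: float
    sascore: float
    predicted_nm: float | None = None

    @property
    def band(self) -> str | None:
        return classify_band(self.predicted_nm) if self.predicted_nm is not None else None


def score_molecules(smiles: Iterable[str], predicted_nm: Sequence[float] | None = None) -> pd.DataFrame:
    """Score a batch; invalid SMILES are dropped (their count is reported
    in the ``attrs`` of the returned frame)."""
    rows, n_invalid = [], 0
    nm_list = list(predicted_nm) if predicted_nm is not None else None
    for i, s in enumerate(smiles):
        g = parse_smiles(s)
        if not isinstance(g, MoleculeGraph):
            n_invalid += 1
            continue
        nm = nm_list[i] if nm_list is not None else None
        rows.append(
            {
                "smiles": g.canonical_smiles,
                "qed": qed(g),
                "sascore": sascore(g),
                "predicted_nm": nm,
                "band": classify_band(nm) if nm is not None else None,
            }
        )
    df = pd.DataFrame(rows, columns=["smiles", "qed", "sascore", "predicted_nm", "band"])
    df.attrs["n_invalid"] = n_invalid
    return df


def rank_select(scored: pd.DataFrame, key: str = "qed", k: int | None = None,
                sascore_window: tuple | None = None) -> pd.DataFrame:
    """Deterministic triage of a scored table.

    ``key="qed"`` sorts by QED descending (ties broken by canonical SMILES)
    and returns the top ``k``.  ``sascore_window=(lo, hi)`` instead keeps the
    molecules whose SAscore falls in the closed window — the mechanism used
    to pull the "interestingly hard" synthesis candidates out of the bulk.
    """
    df = scored.copy()
    if sascore_window is not None:
        lo, hi = sascore_window
        df = df[(df["sascore"] >= lo) & (df["sascore"] <= hi)]
        return df.sort_values(["sascore", "smiles"], ascending=[False, True]).reset_index(drop=True)
    if key != "qed":
        raise ValueError("key must be 'qed' or use sascore_window")
    df = df.sort_values(["qed", "smiles"], ascending=[False, True]).reset_index(drop=True)
    if k is None:
        return df
    if k > len(df):
        import warnings

        warnings.warn(f"k={k} exceeds {len(df)} records; returning all")
        k = len(df)
    return df.head(k)


def load_reference_table() -> pd.DataFrame:
    """The 17 validated candidate molecules with their first-excitation
    wavelengths (nm) in gas phase, water and organic solvent."""
    from importlib import resources

    with resources.files("photogen.data").joinpath("uv_candidates.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
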