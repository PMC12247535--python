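"""Protein physicochemical property calculators.

Implements the standard suite used to characterise a TF family after
identification: molecular weight, theoretical isoelectric point (pI),
Guruprasad instability index, Ikai aliphatic index and Kyte–Doolittle GRAVY.

GRAVY, the instability index and average molecular weight are delegated to
Biopython (which carries the published Kyte–Doolittle and DIWV tables); the
aliphatic index and the pI bisection are implemented here.  The pI depends on
the pKa set used, so the set is a named, swappable table (see PKA_TABLES).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bp_molecular_weight
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .exceptions import ParameterError, ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte–Doolittle hydropathy values (J Mol Biol 1982), used for validation and
#: as the documented reference for the GRAVY range invariant.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Side-chain and terminal pKa sets.  "expasy" is the Bjellqvist-compatible
#: set used by ProtParam-style tools; "emboss" is the EMBOSS iep default.
PKA_TABLES: dict[str, dict[str, float]] = {
    "expasy": {
        "Nterm": 7.5, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
}

_ALIPHATIC_A = 2.9  # Ikai (1980) relative volume coefficient for Val
_ALIPHATIC_B = 3.9  # ... for Ile and Leu


@dataclass
class ProteinProperties:
    """Per-protein property record; ``unstable`` iff instability index > 40."""

    protein_id: str
    length: int
    molecular_weight: float
    pI: float
    instability_index: float
    aliphatic_index: float
    gravy: float

    @property
    def unstable(self) -> bool:
        return self.instability_index > 40.0


def _check_sequence(sequence: str, min_length: int = 1) -> str:
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise ValidationError("empty protein sequence")
    seq = sequence.upper()
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValidationError(
            f"non-standard residue(s) {sorted(bad)}; only the 20 standard "
            "amino acids are accepted"
        )
    if len(seq) < min_length:
        raise ValidationError(f"sequence shorter than {min_length} residues")
    return seq


def compute_gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle score per residue."""
    seq = _check_sequence(sequence)
    return ProteinAnalysis(seq).gravy()


def compute_aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index.

    AI = X(Ala) + a*X(Val) + b*(X(Ile) + X(Leu)) with mole percents X and
    a = 2.9, b = 3.9.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + _ALIPHATIC_A * x["V"] + _ALIPHATIC_B * (x["I"] + x["L"])


def compute_instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights."""
    seq = _check_sequence(sequence, min_length=2)
    return ProteinAnalysis(seq).instability_index()


def compute_molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (residue masses + one water)."""
    seq = _check_sequence(sequence)
    return _bp_molecular_weight(seq, seq_type="protein")


def net_charge(sequence: str, pH: float, pka_table: str = "expasy") -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Positive contributions from the N-terminus and K/R/H side chains,
    negative from the C-terminus and D/E/C/Y side chains.
    """
    seq = _check_sequence(sequence)
    try:
        pka = PKA_TABLES[pka_table]
    except KeyError:
        raise ParameterError(
            f"unknown pKa table {pka_table!r}; available: {sorted(PKA_TABLES)}"
        ) from None

    def pos(pk: float, count: float) -> float:
        return count * 10 ** pk / (10 ** pk + 10 ** pH)

    def neg(pk: float, count: float) -> float:
        return -count * 10 ** pH / (10 ** pk + 10 ** pH)

    charge = pos(pka["Nterm"], 1) + neg(pka["Cterm"], 1)
    for aa in "KRH":
        charge += pos(pka[aa], seq.count(aa))
    for aa in "DECY":
        charge += neg(pka[aa], seq.count(aa))
    return charge


def compute_pI(sequence: str, tol: float = 1e-3, pka_table: str = "expasy") -> float:
    """Isoelectric point by bisection of the net charge on pH in [0, 14].

    The charge is strictly decreasing in pH, so bisection converges; the
    returned pH satisfies |interval| < tol around the zero crossing.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    seq = _check_sequence(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_properties(
    sequences: dict[str, str], tol: float = 1e-3, pka_table: str = "expasy"
) -> pd.DataFrame:
    """All properties for a {protein_id: sequence} mapping, one row each."""
    rows = []
    for pid, seq in sequences.items():
        rec = ProteinProperties(
            protein_id=pid,
            length=len(seq),
            molecular_weight=compute_molecular_weight(seq),
            pI=compute_pI(seq, tol=tol, pka_table=pka_table),
            instability_index=compute_instability_index(seq),
            aliphatic_index=compute_aliphatic_index(seq),
            gravy=compute_gravy(seq),
        )
        rows.append(asdict(rec))
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "length", "molecular_weight", "pI",
            "instability_index", "aliphatic_index", "gravy",
        ],
    )
    df["unstable"] = df["instability_index"] > 40.0
    return df
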