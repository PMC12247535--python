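"""TPM expression matrix handling over the NaCl concentration gradient.

The design is 6 treatments (T0, T30, T60, T90, T120, T150 mM NaCl) with
replicated samples.  Operations: low-expression filtering (TPM < 1 in all
samples), per-treatment replicate means, classification of each gene's
concentration-response shape into four classes, and qPCR relative expression
by the 2^-ddCt method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ValidationError

TREATMENTS = ["T0", "T30", "T60", "T90", "T120", "T150"]

PATTERN_LABELS = (
    "continuous_up", "continuous_down", "biphasic", "reverse_biphasic", "other"
)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM values plus a sample -> treatment map.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; every sample must map to one of the ordered treatments.
    """

    values: pd.DataFrame
    sample_treatments: dict[str, str]
    treatments: list[str] = field(default_factory=lambda: list(TREATMENTS))

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValidationError("TPM values must be nonnegative")
        missing = set(self.values.columns) - set(self.sample_treatments)
        if missing:
            raise ValidationError(f"samples without treatment mapping: {sorted(missing)}")
        bad = set(self.sample_treatments.values()) - set(self.treatments)
        if bad:
            raise ValidationError(f"unknown treatments: {sorted(bad)}")
        present = {self.sample_treatments[s] for s in self.values.columns}
        empty = set(self.treatments) - present
        if empty:
            raise ValidationError(f"treatments with no samples: {sorted(empty)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, matrix_path: str | Path, sample_map_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        with open(sample_map_path, "w") as fh:
            fh.write("sample_id\ttreatment\n")
            for s in self.values.columns:
                fh.write(f"{s}\t{self.sample_treatments[s]}\n")

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, sample_map_path: str | Path
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        smap = pd.read_csv(sample_map_path, sep="\t")
        if list(smap.columns) != ["sample_id", "treatment"]:
            raise FormatError(
                f"sample map must have columns sample_id, treatment; got {list(smap.columns)}"
            )
        return cls(values=values, sample_treatments=dict(zip(smap.sample_id, smap.treatment)))


def filter_low_expression(matrix: ExpressionMatrix, tpm_min: float = 1.0) -> ExpressionMatrix:
    """Drop genes with TPM < tpm_min in every sample; order preserved."""
    keep = (matrix.values >= tpm_min).any(axis=1)
    return ExpressionMatrix(
        values=matrix.values.loc[keep].copy(),
        sample_treatments=dict(matrix.sample_treatments),
        treatments=list(matrix.treatments),
    )


def treatment_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean of replicate TPM per treatment, gradient-ordered columns."""
    groups = pd.Series(
        {s: matrix.sample_treatments[s] for s in matrix.values.columns}
    )
    means = matrix.values.T.groupby(groups).mean().T
    return means[matrix.treatments]


def classify_pattern(profile, rel_tol: float = 0.1) -> str:
    """Classify a 6-point treatment-mean profile into a response shape.

    A tolerance band tau = rel_tol * (max - min) absorbs replicate noise.
    Monotone classes are checked first: continuous_down requires every step
    to fall or rise by at most tau AND the last mean below the first by more
    than tau (continuous_up is symmetric).  Then biphasic: interior maximum
    exceeding both endpoints by more than tau; reverse_biphasic: interior
    minimum below both endpoints by more than tau.  Flat profiles and
    everything else are "other".
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (len(TREATMENTS),):
        raise ParameterError(f"profile must have {len(TREATMENTS)} treatment means, got {p.shape}")
    if rel_tol < 0:
        raise ParameterError("rel_tol must be nonnegative")
    rng = p.max() - p.min()
    if rng == 0:
        return "other"
    tau = rel_tol * rng
    steps = np.diff(p)
    if (steps <= tau).all() and p[-1] < p[0] - tau:
        return "continuous_down"
    if (steps >= -tau).all() and p[-1] > p[0] + tau:
        return "continuous_up"
    imax = int(p.argmax())
    if 0 < imax < len(p) - 1 and p[imax] > p[0] + tau and p[imax] > p[-1] + tau:
        return "biphasic"
    imin = int(p.argmin())
    if 0 < imin < len(p) - 1 and p[imin] < p[0] - tau and p[imin] < p[-1] - tau:
        return "reverse_biphasic"
    return "other"


def classify_patterns(means: pd.DataFrame, rel_tol: float = 0.1) -> pd.Series:
    """Pattern label per gene from a gene x treatment mean table."""
    return pd.Series(
        {g: classify_pattern(means.loc[g].values, rel_tol=rel_tol) for g in means.index},
        name="pattern",
    )


def delta_delta_ct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target - Ct_ref)_treatment - (Ct_target - Ct_ref)_control.
    """
    vals = (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
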