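"""Hypergeometric over-representation analysis with BH correction.

Given a study set (e.g. genes co-expressed with the TF family), a background
set (genes with TPM >= 1 in at least one sample) and a gene -> term map,
each term with at least one study hit is tested with the hypergeometric
upper tail P(X >= k), and p-values are adjusted by the Benjamini–Hochberg
step-up procedure over the tested terms.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ValidationError


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Summed in log space (logsumexp over log-pmf terms) for numerical
    stability at large N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ParameterError(f"need 0 <= K,n <= N; got k={k} n={n} K={K} N={N}")
    if not 0 <= k <= min(n, K):
        raise ParameterError(f"need 0 <= k <= min(n, K); got k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    with np.errstate(divide="ignore"):
        logp = hypergeom.logpmf(support, N, K, n)
    logp = logp[np.isfinite(logp)]
    if logp.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def load_term_map(path: str | Path) -> pd.DataFrame:
    """gene -> term TSV with columns gene_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name"}
    if not required <= set(df.columns):
        raise ValidationError(f"term map needs columns {sorted(required)}")
    return df


def enrich(
    study: set[str],
    background: set[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each term in the study set vs the background.

    Study genes outside the background are dropped with a warning.  Only
    terms with >= 1 study hit enter the test family (so the BH family size
    equals the number of tested terms).  Significance uses the strict rule
    adjusted_p < alpha.  Result sorted by adjusted_p, then term_id.
    """
    if not background:
        raise ParameterError("background set is empty")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    stray = study - background
    if stray:
        warnings.warn(
            f"{len(stray)} study gene(s) absent from background were dropped",
            stacklevel=2,
        )
    study = study & background

    tmap = term_map[term_map.gene_id.isin(background)]
    names = tmap.drop_duplicates("term_id").set_index("term_id")["term_name"]
    by_term = tmap.groupby("term_id")["gene_id"].agg(set)

    N = len(background)
    n = len(study)
    rows = []
    for term_id, genes in by_term.items():
        k = len(genes & study)
        if k == 0:
            continue
        K = len(genes)
        rows.append({
            "term_id": term_id,
            "term_name": names[term_id],
            "k": k, "n": n, "K": K, "N": N,
            "p_value": hypergeom_upper_tail(k, n, K, N),
        })
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    if len(result):
        result["adjusted_p"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["adjusted_p"] < alpha
        result = result.sort_values(["adjusted_p", "term_id"]).reset_index(drop=True)
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
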