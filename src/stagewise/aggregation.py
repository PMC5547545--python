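"""Gene-level aggregation of transcript-level p-values.

A gene's screening evidence is the minimum of its transcript p-values,
converted to a gene-level p-value by the Sidak correction
``1 - (1 - min_p) ** n_g`` (exact under independence of the transcript
tests).  Gene-level q-values then control the FDR of the rule "reject every
gene whose minimum transcript p-value falls below a threshold theta" at

    q*(theta) = sum_g [1 - (1 - theta) ** n_g] / R(theta),

where ``R(theta)`` counts the genes whose minimum p-value is at or below
``theta``.  When every gene has a single transcript this reduces exactly to
Benjamini-Hochberg on the per-gene p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    GENE_COL,
    PVALUE_COL,
    ValidationError,
    validate_hypothesis_table,
)


def sidak_gene_pvalue(min_p: float, n_g: int) -> float:
    """Gene-level p-value ``1 - (1 - min_p) ** n_g`` for the min over ``n_g`` tests."""
    if n_g < 1:
        raise ValidationError("n_g must be >= 1")
    if not 0 <= min_p <= 1:
        raise ValidationError("min_p must lie in [0, 1]")
    if min_p == 1.0:
        return 1.0
    # -expm1(n*log1p(-p)) is 1-(1-p)^n without cancellation for small p
    return float(-np.expm1(n_g * np.log1p(-min_p)))


def per_gene_qvalue(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate transcript-level p-values to gene-level q-values.

    Parameters
    ----------
    table
        Long format with columns ``gene``, ``hypothesis``, ``pvalue``
        (one row per transcript test).

    Returns
    -------
    DataFrame with one row per gene: ``gene``, ``n_g``, ``theta`` (the
    minimum transcript p-value) and ``qvalue``.  ``qvalue <= alpha``
    reproduces gene discovery with FDR controlled at ``alpha``.
    """
    table = validate_hypothesis_table(table)
    per_gene = table.groupby(GENE_COL, sort=False)[PVALUE_COL].agg(["size", "min"])
    per_gene.columns = ["n_g", "theta"]
    n_g = per_gene["n_g"].to_numpy(dtype=float)
    theta_g = per_gene["theta"].to_numpy()

    # candidate thresholds: the observed minima; between them R(theta) is
    # constant and the numerator only grows, so no other theta can improve q*
    thetas = np.unique(theta_g)
    with np.errstate(divide="ignore"):
        log1m = np.log1p(-thetas)  # -inf at theta == 1 is fine under expm1
    numer = (-np.expm1(np.outer(log1m, n_g))).sum(axis=1)
    R = np.searchsorted(np.sort(theta_g), thetas, side="right")
    q_star = numer / R
    # monotonicity: running minimum from the largest threshold downward
    q_monotone = np.minimum(1.0, np.minimum.accumulate(q_star[::-1])[::-1])

    idx = np.searchsorted(thetas, theta_g)
    out = per_gene.reset_index()
    out["qvalue"] = q_monotone[idx]
    return out
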