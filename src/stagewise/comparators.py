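"""Reference procedures the stage-wise method is benchmarked against.

* ``conventional_analysis``: the field's default — BH FDR control applied
  separately within each contrast, with no gene-level guarantee.  A gene is
  flagged when any of its hypotheses is rejected in any contrast, so the
  gene-level FDR inflates with the number of contrasts tested.
* ``jiang_doerge``: the generic two-stage procedure that splits the FDR
  budget between the stages — BH screening at 4/5 of the target level, then
  one pooled BH pass over all confirmation p-values of the passing genes at
  the remaining 1/5.  Only the confirmation p-values enter the pooled family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GENE_COL,
    HYPOTHESIS_COL,
    PVALUE_COL,
    ScreeningResult,
    ValidationError,
    bh_adjust,
    screen,
    validate_hypothesis_table,
)

CONTRAST_COL = "contrast"


@dataclass
class ComparatorResult:
    method: str
    #: per-hypothesis table: gene, hypothesis, pvalue, p_adj, rejected
    table: pd.DataFrame
    #: per-gene table: gene, any_rejected (plus passed_screening for jiang)
    gene_table: pd.DataFrame
    screening: ScreeningResult | None = None


def conventional_analysis(
    table: pd.DataFrame,
    alpha: float = 0.05,
    contrast_col: str | None = None,
) -> ComparatorResult:
    """Per-contrast BH at level ``alpha``; gene flagged on any rejection.

    ``contrast_col`` names the column that partitions hypotheses into
    contrast families; by default the hypothesis id itself is the contrast
    label (as in a DGE design where every gene contributes one p-value per
    contrast).
    """
    table = validate_hypothesis_table(table)
    col = contrast_col or HYPOTHESIS_COL
    if col not in table.columns:
        raise ValidationError(f"unknown contrast column {col!r}")
    if table[col].isna().any():
        raise ValidationError("missing contrast labels")
    df = table.copy()
    df["p_adj"] = (
        df.groupby(col, sort=False)[PVALUE_COL]
        .transform(lambda p: bh_adjust(p.to_numpy()))
    )
    df["rejected"] = df["p_adj"] <= alpha
    gene_table = (
        df.groupby(GENE_COL)["rejected"].any().rename("any_rejected").reset_index()
    )
    return ComparatorResult("conventional", df.reset_index(drop=True), gene_table)


def jiang_doerge(
    table: pd.DataFrame,
    screening_pvalues: pd.DataFrame | pd.Series,
    alpha: float = 0.05,
    split: tuple[float, float] = (0.8, 0.2),
) -> ComparatorResult:
    """Two-stage procedure with the FDR budget split across stages.

    Stage 1 applies BH to the per-gene screening p-values at
    ``split[0] * alpha``; stage 2 pools the confirmation p-values of all
    passing genes into a single family and applies BH at
    ``split[1] * alpha``.  The default 4/5-1/5 split follows the original
    recommendation.
    """
    if len(split) != 2 or min(split) <= 0 or abs(sum(split) - 1.0) > 1e-12:
        raise ValidationError("split must be two positive fractions summing to 1")
    table = validate_hypothesis_table(table)
    screening = screen(screening_pvalues, alpha_I=split[0] * alpha)
    passing = set(screening.rejected_genes)

    df = table[[GENE_COL, HYPOTHESIS_COL, PVALUE_COL]].copy()
    df["passed_screening"] = df[GENE_COL].isin(passing)
    df["p_adj"] = 1.0
    df["rejected"] = False
    mask = df["passed_screening"].to_numpy()
    if mask.any():
        pooled_adj = bh_adjust(df.loc[mask, PVALUE_COL].to_numpy())
        df.loc[mask, "p_adj"] = pooled_adj
        df.loc[mask, "rejected"] = pooled_adj <= split[1] * alpha
    gene_table = (
        df.groupby(GENE_COL)
        .agg(any_rejected=("rejected", "any"), passed_screening=("passed_screening", "any"))
        .reset_index()
    )
    return ComparatorResult("jiang_doerge", df.reset_index(drop=True), gene_table, screening)
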