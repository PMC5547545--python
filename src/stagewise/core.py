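"""Two-stage (screening + confirmation) testing with gene-level FDR control.

The screening stage tests, for each gene, the aggregated null hypothesis that
none of the gene's individual hypotheses is false, and controls the FDR across
genes with the Benjamini-Hochberg (BH) step-up procedure at a target level
``alpha_I``.  Genes that pass are carried to a confirmation stage, where every
individual hypothesis is tested while controlling the within-gene family-wise
error rate (FWER) at the BH-adjusted significance level
``alpha_II = R * alpha_I / G`` (``R`` screening rejections out of ``G`` genes
screened).  Together the two stages bound the overall FDR (OFDR): the expected
proportion of discovered genes that carry at least one false rejection,
counting the screening rejection itself.

Within-gene FWER control uses Holm's step-down procedure or Shaffer's
modified sequentially rejective Bonferroni (MSRB) procedure.  MSRB compares
the j-th smallest p-value of a gene to ``alpha_II / t(j)``, where ``t(j)`` is
the maximum number of hypotheses that can still be jointly true given that
the j-1 smaller ones are false.  Logical relations between a gene's
hypotheses (e.g. a 2x2 treatment-by-time design, or transcript usage
proportions that must compensate each other) shrink ``t(j)`` below the Holm
divisor ``n_g - j + 1``, and a ``t(j)`` of zero encodes a vacuous threshold:
the hypothesis is rejected outright once its gene passes screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COL = "gene"
HYPOTHESIS_COL = "hypothesis"
PVALUE_COL = "pvalue"

#: Valid confirmation-stage contexts and the logical constraint they encode.
CONTEXTS = (
    "dge_2x2",      # 2x2 treatment x time: 3 contrasts, t = (1, 1, 1)
    "dge_2x2_avg",  # same + average-fold-change contrast: 4 contrasts, all t = 1
    "dte",          # per-transcript expression: t(1) = n-1, then Holm
    "dtu",          # transcript usage: t(1) = t(2) = n-2, then Holm
    "holm",         # no logical constraints: t(j) = n - j + 1
    "screened_free",  # only "at least one effect" known: t(1) = n-1, then Holm
)


class ValidationError(ValueError):
    """Raised when an input table or parameter violates a contract."""


def _as_pvalue_array(pvalues: Sequence[float], name: str = "pvalues") -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError(f"{name} must lie in [0, 1] with no missing values")
    return p


def validate_hypothesis_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format (gene, hypothesis, pvalue) table.

    Missing p-values are dropped (they must not inflate the within-gene
    correction burden), with a warning naming how many rows were removed.
    """
    required = {GENE_COL, HYPOTHESIS_COL, PVALUE_COL}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"hypothesis table lacks columns: {sorted(missing)}")
    table = table.copy()
    na = table[PVALUE_COL].isna()
    if na.any():
        logger.warning(
            "dropping %d hypotheses with missing p-values; they do not count "
            "towards the within-gene correction burden", int(na.sum()),
        )
        table = table[~na]
    if table.empty:
        raise ValidationError("hypothesis table is empty")
    _as_pvalue_array(table[PVALUE_COL].to_numpy(), PVALUE_COL)
    if table.duplicated([GENE_COL, HYPOTHESIS_COL]).any():
        raise ValidationError("duplicate (gene, hypothesis) pairs in table")
    return table


# ---------------------------------------------------------------------------
# Screening stage
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted[i] <= alpha`` reproduces the BH rejection decision at FDR
    level ``alpha``.
    """
    p = _as_pvalue_array(pvalues)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank enforces step-up monotonicity
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def compute_alpha_II(R: int, G: int, alpha_I: float) -> float:
    """BH-adjusted confirmation significance level ``alpha_II = R*alpha_I/G``."""
    if G < 1:
        raise ValidationError("G must be >= 1")
    if not 0 <= R <= G:
        raise ValidationError(f"R={R} must satisfy 0 <= R <= G={G}")
    if not 0 < alpha_I < 1:
        raise ValidationError("alpha_I must lie strictly between 0 and 1")
    return R * alpha_I / G


@dataclass
class ScreeningResult:
    """Per-gene screening decisions plus the stage-I/II significance levels."""

    table: pd.DataFrame  # columns: gene, pvalue, p_adj, rejected
    G: int
    R: int
    alpha_I: float
    alpha_II: float

    @property
    def rejected_genes(self) -> pd.Index:
        return pd.Index(self.table.loc[self.table["rejected"], GENE_COL])


def screen(
    screening_pvalues: pd.DataFrame | Mapping[str, float] | pd.Series,
    alpha_I: float = 0.05,
) -> ScreeningResult:
    """BH screening of per-gene omnibus p-values at FDR level ``alpha_I``.

    Parameters
    ----------
    screening_pvalues
        One p-value per gene: a DataFrame with columns ``gene`` and
        ``pvalue``, or a Series/mapping keyed by gene.
    alpha_I
        Target OFDR level for the whole two-stage procedure.
    """
    if isinstance(screening_pvalues, pd.DataFrame):
        df = screening_pvalues[[GENE_COL, PVALUE_COL]].copy()
    else:
        s = pd.Series(screening_pvalues)
        df = pd.DataFrame({GENE_COL: s.index, PVALUE_COL: s.to_numpy()})
    if df[GENE_COL].duplicated().any():
        raise ValidationError("duplicate gene ids in screening table")
    if not 0 < alpha_I < 1:
        raise ValidationError("alpha_I must lie strictly between 0 and 1")
    df["p_adj"] = bh_adjust(df[PVALUE_COL].to_numpy())
    df["rejected"] = df["p_adj"] <= alpha_I
    G = len(df)
    R = int(df["rejected"].sum())
    return ScreeningResult(
        table=df.reset_index(drop=True),
        G=G,
        R=R,
        alpha_I=alpha_I,
        alpha_II=compute_alpha_II(R, G, alpha_I),
    )


# ---------------------------------------------------------------------------
# Confirmation stage: t-sequences and the MSRB step-down adjustment
# ---------------------------------------------------------------------------

def shaffer_t_sequence(n_g: int, context: str) -> np.ndarray:
    """Shaffer MSRB divisor sequence t(1..n_g) for a given logical context.

    A value of 0 marks a vacuous threshold (the hypothesis is always rejected
    once the gene passes screening).  Every context satisfies
    ``t(j) <= n_g - j + 1``, so MSRB is uniformly at least as powerful as
    Holm.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    if n_g < 1:
        raise ValidationError("n_g must be >= 1")
    holm = np.arange(n_g, 0, -1)
    if context == "holm":
        return holm
    if context == "dge_2x2":
        # Passing screening means at most one of the three contrasts (effect
        # at either timepoint, interaction) can still be null, so each
        # p-value meets the unadjusted alpha_II.
        if n_g != 3:
            raise ValidationError("context 'dge_2x2' requires exactly 3 hypotheses per gene")
        return np.ones(3, dtype=int)
    if context == "dge_2x2_avg":
        # Adding the average-fold-change contrast leaves the logical bound at
        # one possibly-true null, so no extra FWER correction is needed.
        if n_g != 4:
            raise ValidationError("context 'dge_2x2_avg' requires exactly 4 hypotheses per gene")
        return np.ones(4, dtype=int)
    if context in ("dte", "screened_free"):
        # At least one effect must be real, so at most n_g - 1 nulls remain
        # for the most significant hypothesis; afterwards plain Holm.
        if n_g == 1:
            return np.array([0])
        t = holm.copy()
        t[0] = n_g - 1
        return t
    # context == "dtu": a usage change must be compensated by another
    # transcript, so at least two hypotheses are false.
    if n_g == 1:
        raise ValidationError("context 'dtu' requires at least 2 transcripts per gene")
    if n_g == 2:
        return np.array([0, 0])
    t = holm.copy()
    t[0] = t[1] = n_g - 2
    return t


def msrb_adjust(
    pvalues: Sequence[float],
    t: Sequence[int],
    tie_break: Sequence | None = None,
) -> np.ndarray:
    """Within-gene adjusted p-values for the MSRB step-down procedure.

    Sorting is stable with an optional deterministic tie-break key (the
    hypothesis id in :func:`confirm`).  The adjusted value at sorted position
    j is ``max_{k<=j} min(1, p_(k) * t(k))`` so that ``adjusted <= alpha_II``
    reproduces the sequential rejection decisions; ``t(k) == 0`` contributes
    0 (auto-rejection).  Returned in input order.
    """
    p = _as_pvalue_array(pvalues)
    t = np.asarray(t, dtype=int)
    if t.shape != p.shape:
        raise ValidationError("t sequence length must match the number of p-values")
    if (t < 0).any() or (t > np.arange(p.size, 0, -1)).any():
        raise ValidationError("invalid t sequence: need 0 <= t(j) <= n - j + 1")
    if tie_break is not None:
        order = np.lexsort((np.asarray(tie_break), p))
    else:
        order = np.argsort(p, kind="stable")
    stepwise = np.minimum(1.0, p[order] * t)
    adjusted = np.maximum.accumulate(stepwise)
    out = np.empty(p.size)
    out[order] = adjusted
    return out


@dataclass
class StageWiseResult:
    """Per-hypothesis confirmation decisions for a two-stage analysis.

    ``table`` columns: gene, hypothesis, pvalue, p_within (within-gene
    FWER-adjusted), p_stagewise (rescaled to the alpha_I scale so that
    ``p_stagewise <= alpha_I`` reproduces the two-stage decision), rejected,
    passed_screening.
    """

    table: pd.DataFrame
    screening: ScreeningResult
    context: str

    @property
    def rejected(self) -> pd.DataFrame:
        return self.table[self.table["rejected"]]


def confirm(
    table: pd.DataFrame,
    screening: ScreeningResult,
    context: str = "holm",
) -> StageWiseResult:
    """Confirmation stage: within-gene FWER control at ``alpha_II``.

    Only genes rejected at screening are eligible; all hypotheses of other
    genes are reported unrejected with a stage-wise adjusted p-value of 1.
    """
    table = validate_hypothesis_table(table)
    known = set(screening.table[GENE_COL])
    unknown = set(table[GENE_COL]) - known
    if unknown:
        raise ValidationError(
            f"{len(unknown)} gene(s) in the confirmation table were never screened, "
            f"e.g. {sorted(map(str, unknown))[:3]}"
        )

    df = table[[GENE_COL, HYPOTHESIS_COL, PVALUE_COL]].copy()
    passed = df[GENE_COL].isin(set(screening.rejected_genes)).to_numpy()
    df["passed_screening"] = passed
    df["p_within"] = 1.0
    df["p_stagewise"] = 1.0
    df["rejected"] = False

    if screening.R == 0:
        logger.info("no gene passed screening (R=0); confirmation stage skipped")
        return StageWiseResult(df.reset_index(drop=True), screening, context)

    sub = df[passed].sort_values(
        [GENE_COL, PVALUE_COL, HYPOTHESIS_COL], kind="mergesort"
    )
    grp = sub.groupby(GENE_COL, sort=False)
    n_g = grp[PVALUE_COL].transform("size").to_numpy()
    rank = grp.cumcount().to_numpy()
    # one t-sequence per distinct gene size; indexing avoids a per-gene loop
    t_by_n = {int(n): shaffer_t_sequence(int(n), context) for n in np.unique(n_g)}
    width = max(t_by_n)
    t_table = np.zeros((width + 1, width), dtype=int)
    for n, t in t_by_n.items():
        t_table[n, : n] = t
    t = t_table[n_g, rank]
    stepwise = np.minimum(1.0, sub[PVALUE_COL].to_numpy() * t)
    sub = sub.assign(_step=stepwise)
    p_within = sub.groupby(GENE_COL, sort=False)["_step"].cummax().to_numpy()

    scale = screening.G / screening.R
    p_stagewise = np.minimum(1.0, p_within * scale)
    df.loc[sub.index, "p_within"] = p_within
    df.loc[sub.index, "p_stagewise"] = p_stagewise
    df.loc[sub.index, "rejected"] = p_within <= screening.alpha_II
    return StageWiseResult(df.reset_index(drop=True), screening, context)


# ---------------------------------------------------------------------------
# Gene-level false discovery proportion
# ---------------------------------------------------------------------------

def gene_level_fdp(result: StageWiseResult, truth: pd.DataFrame) -> float:
    """Observed gene-level FDP, the quantity whose expectation is the OFDR.

    A false positive gene is a screening-rejected gene that is either fully
    null (every individual hypothesis true) or carries at least one falsely
    rejected individual hypothesis.

    Parameters
    ----------
    truth
        Long format with columns ``gene``, ``hypothesis`` and boolean
        ``is_null`` (True when the null hypothesis holds).
    """
    discovered = set(result.screening.rejected_genes)
    if not discovered:
        return 0.0
    merged = result.table.merge(
        truth[[GENE_COL, HYPOTHESIS_COL, "is_null"]],
        on=[GENE_COL, HYPOTHESIS_COL],
        how="left",
    )
    if merged["is_null"].isna().any():
        missing = merged.loc[merged["is_null"].isna(), GENE_COL].unique()
        raise ValidationError(
            f"truth table lacks records for {len(missing)} gene(s), "
            f"e.g. {list(map(str, missing[:3]))}"
        )
    merged["false_rejection"] = merged["is_null"] & merged["rejected"]
    per_gene = merged.groupby(GENE_COL).agg(
        fully_null=("is_null", "all"),
        any_false_rejection=("false_rejection", "any"),
    )
    disc = per_gene.loc[per_gene.index.intersection(pd.Index(discovered))]
    false_genes = int((disc["fully_null"] | disc["any_false_rejection"]).sum())
    return false_genes / len(discovered)
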