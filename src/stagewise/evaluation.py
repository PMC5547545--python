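"""Performance metrics over replicated simulations.

FDP-TPR curves rank units (hypotheses or genes) by an adjusted p-value and
trace the false discovery proportion against the true positive rate; working
points mark the rejection sets at nominal FDR cut-offs and are flagged
"achieved" when the empirical FDP is at or below the nominal level.  The
OFDR is estimated as the mean gene-level FDP over replicate simulations,
and its false-positive genes decompose into fully-null genes versus genes
with a real effect but a falsely rejected individual hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENE_COL, StageWiseResult, ValidationError, gene_level_fdp

DEFAULT_NOMINAL = (0.01, 0.05, 0.10)


@dataclass
class PerformanceCurve:
    """Cumulative (FDP, TPR) along a ranking, with nominal working points."""

    curve: pd.DataFrame  # columns: k, score, fdp, tpr
    working_points: pd.DataFrame  # columns: nominal, n_rejected, fdp, tpr, achieved
    no_alternatives: bool = False

    def tpr_at_fdp(self, fdp: float) -> float:
        """Best TPR attainable with cumulative FDP <= ``fdp`` along the ranking."""
        ok = self.curve["fdp"].to_numpy() <= fdp
        return float(self.curve["tpr"].to_numpy()[ok].max()) if ok.any() else 0.0


def fdp_tpr_curve(
    scores: pd.DataFrame,
    nominal: tuple[float, ...] = DEFAULT_NOMINAL,
    score_col: str = "score",
    null_col: str = "is_null",
) -> PerformanceCurve:
    """FDP-TPR curve from adjusted p-value scores (smaller = more significant).

    ``scores`` needs one row per unit with the ranking score and the truth
    flag ``is_null``.  Working points use the rejection set
    ``score <= nominal`` and are flagged achieved when FDP <= nominal.
    When no unit is a true alternative, TPR is reported as 0 and
    ``no_alternatives`` is set.
    """
    for col in (score_col, null_col):
        if col not in scores.columns:
            raise ValidationError(f"scores table lacks column {col!r}")
    if scores[null_col].isna().any():
        raise ValidationError("missing truth flags")
    df = scores.sort_values(score_col, kind="mergesort")
    is_null = df[null_col].to_numpy(dtype=bool)
    s = df[score_col].to_numpy(dtype=float)
    n_alt = int((~is_null).sum())
    no_alt = n_alt == 0

    k = np.arange(1, len(df) + 1)
    cum_fp = np.cumsum(is_null)
    cum_tp = k - cum_fp
    fdp = cum_fp / k
    tpr = cum_tp / n_alt if not no_alt else np.zeros(len(df))
    curve = pd.DataFrame({"k": k, "score": s, "fdp": fdp, "tpr": tpr})

    wp_rows = []
    for a in nominal:
        n_rej = int(np.searchsorted(s, a, side="right"))
        wp_fdp = float(fdp[n_rej - 1]) if n_rej else 0.0
        wp_tpr = float(tpr[n_rej - 1]) if n_rej else 0.0
        wp_rows.append(
            {
                "nominal": a,
                "n_rejected": n_rej,
                "fdp": wp_fdp,
                "tpr": wp_tpr,
                "achieved": wp_fdp <= a,
            }
        )
    return PerformanceCurve(curve, pd.DataFrame(wp_rows), no_alternatives=no_alt)


def ofdr_over_replicates(
    results: list[StageWiseResult], truths: list[pd.DataFrame]
) -> tuple[float, float]:
    """Mean gene-level FDP and its Monte-Carlo standard error across replicates."""
    if not results:
        raise ValidationError("need at least one replicate")
    if len(results) != len(truths):
        raise ValidationError("results and truths must align")
    fdps = np.array([gene_level_fdp(r, t) for r, t in zip(results, truths)])
    mean = float(fdps.mean())
    se = float(fdps.std(ddof=1) / np.sqrt(len(fdps))) if len(fdps) > 1 else 0.0
    return mean, se


def decompose_false_positive_genes(
    result: StageWiseResult, truth: pd.DataFrame
) -> tuple[int, int]:
    """Split gene-level false positives into (fully-null, partly-true) genes.

    The two counts sum to the numerator of :func:`gene_level_fdp`: genes
    with no real effect at all versus genes with a real effect but at least
    one falsely rejected individual hypothesis.
    """
    discovered = set(result.screening.rejected_genes)
    if not discovered:
        return (0, 0)
    merged = result.table.merge(
        truth[[GENE_COL, "hypothesis", "is_null"]],
        on=[GENE_COL, "hypothesis"],
        how="left",
    )
    if merged["is_null"].isna().any():
        raise ValidationError("truth table does not cover all result hypotheses")
    merged["false_rejection"] = merged["is_null"] & merged["rejected"]
    per_gene = merged.groupby(GENE_COL).agg(
        fully_null=("is_null", "all"),
        any_false_rejection=("false_rejection", "any"),
    )
    disc = per_gene.loc[per_gene.index.intersection(pd.Index(list(discovered)))]
    n_null = int(disc["fully_null"].sum())
    n_partly = int((~disc["fully_null"] & disc["any_false_rejection"]).sum())
    return (n_null, n_partly)


def plot_curves(curves: dict[str, PerformanceCurve], path=None, title: str | None = None):
    """Render FDP-TPR curves with their nominal working points (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, pc in curves.items():
        ax.plot(pc.curve["fdp"], pc.curve["tpr"], label=label)
        wp = pc.working_points
        ax.scatter(
            wp["fdp"], wp["tpr"],
            marker="o",
            facecolors=np.where(wp["achieved"], "black", "none"),
            edgecolors="black", zorder=3,
        )
    ax.set_xlabel("FDP")
    ax.set_ylabel("TPR")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
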