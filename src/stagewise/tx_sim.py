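"""Transcript-level count simulator for DTU and DTE evaluation.

Each gene carries one or more transcripts.  A gene's total expected count is
log-normal; its baseline isoform usage is a point on the simplex, and every
sample draws its own usage proportions from a Dirichlet centred on that
baseline (concentration controls biological usage variability).  Counts are
negative binomial at the transcript level with a mean-dispersion trend, which
preserves the statistical structure seen by downstream tests without read
simulation or quantification.

Differential transcript usage (DTU) is introduced by permuting the baseline
proportions of k selected transcripts in the second condition (a swap when
k = 2), which changes usage while conserving the gene's expected total
output.  Differential transcript expression (DTE) scales every transcript of
a selected gene by a fold change drawn from a truncated exponential law,
direction balanced across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENE_COL, ValidationError
from .dge_sim import _nb_draw, _rng

TRANSCRIPT_COL = "transcript"


@dataclass
class TranscriptomeModel:
    """Parametric model for genes, transcripts and abundances.

    Transcripts per gene follow ``1 + NegativeBinomial`` (a shifted discrete
    law with mean ``1 + tx_extra_mean``); gene expected counts are
    log-normal; baseline usage is Dirichlet(``base_alpha``) with proportions
    below ``min_expressed_prop`` zeroed and renormalised (those isoforms are
    unexpressed); per-sample usage is Dirichlet(``concentration`` x baseline)
    over the expressed isoforms.  Transcript NB dispersion follows
    ``a0 + a1/(mean+1)`` with log-normal noise.
    """

    gene_meanlog: float = 4.0
    gene_sdlog: float = 1.5
    tx_extra_mean: float = 2.0     # mean number of transcripts beyond the first
    tx_extra_shape: float = 1.5    # NB shape of the extra-transcript count
    base_alpha: float = 1.0
    min_expressed_prop: float = 0.01
    concentration: float = 100.0
    disp_a0: float = 0.05
    disp_a1: float = 2.0
    disp_sdlog: float = 0.3

    def validate(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("Dirichlet concentration must be positive")
        if self.tx_extra_mean < 0 or self.tx_extra_shape <= 0:
            raise ValidationError("invalid transcripts-per-gene parameters")
        if not 0 <= self.min_expressed_prop < 0.5:
            raise ValidationError("min_expressed_prop must lie in [0, 0.5)")


@dataclass
class TruncatedExponentialFC:
    """Fold-change law for DTE: Exp(rate) truncated to [lower, upper].

    Draws are fold-change magnitudes (> 1 by default); the per-gene
    direction decides whether the magnitude or its reciprocal is applied.
    """

    rate: float = 1.0
    lower: float = 1.5
    upper: float = 4.0

    def validate(self) -> None:
        if self.rate <= 0 or not 0 < self.lower <= self.upper:
            raise ValidationError("need rate > 0 and 0 < lower <= upper")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        if self.lower == self.upper:
            return np.full(n, self.lower)
        u = rng.uniform(size=n)
        lo, hi = np.exp(-self.rate * self.lower), np.exp(-self.rate * self.upper)
        return -np.log(lo - u * (lo - hi)) / self.rate


@dataclass
class TranscriptomeStructure:
    """Baseline transcriptome: per-gene totals and per-transcript usage."""

    genes: pd.DataFrame  # gene, expected_count, n_tx, n_expressed
    transcripts: pd.DataFrame  # gene, transcript, base_prop, dispersion


def simulate_structure(
    n_genes: int,
    model: TranscriptomeModel | None = None,
    seed=None,
) -> TranscriptomeStructure:
    """Draw the baseline transcriptome structure (deterministic given seed)."""
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    model = model or TranscriptomeModel()
    model.validate()
    rng = _rng(seed)

    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    p_nb = model.tx_extra_shape / (model.tx_extra_shape + model.tx_extra_mean)
    n_tx = 1 + rng.negative_binomial(model.tx_extra_shape, p_nb, size=n_genes)
    expected = rng.lognormal(model.gene_meanlog, model.gene_sdlog, size=n_genes)

    tx_rows = []
    for g, ntx, total in zip(gene_ids, n_tx, expected):
        props = rng.dirichlet(np.full(ntx, model.base_alpha))
        props[props < model.min_expressed_prop] = 0.0
        if props.sum() == 0:  # degenerate draw: keep the largest isoform
            props = np.zeros(ntx)
            props[0] = 1.0
        props = props / props.sum()
        mean_tx = total * props
        disp = (model.disp_a0 + model.disp_a1 / (mean_tx + 1.0)) * rng.lognormal(
            0.0, model.disp_sdlog, size=ntx
        )
        for k in range(ntx):
            tx_rows.append((g, f"{g}.tx{k + 1}", props[k], disp[k]))
    transcripts = pd.DataFrame(
        tx_rows, columns=[GENE_COL, TRANSCRIPT_COL, "base_prop", "dispersion"]
    )
    n_expressed = (
        transcripts.assign(expr=transcripts["base_prop"] > 0)
        .groupby(GENE_COL, sort=False)["expr"]
        .sum()
        .to_numpy()
    )
    genes = pd.DataFrame(
        {
            GENE_COL: gene_ids,
            "expected_count": expected,
            "n_tx": n_tx,
            "n_expressed": n_expressed,
        }
    )
    return TranscriptomeStructure(genes, transcripts)


def _non_identity_permutation(k: int, rng: np.random.Generator) -> np.ndarray:
    if k == 2:
        return np.array([1, 0])
    while True:
        perm = rng.permutation(k)
        if (perm != np.arange(k)).any():
            return perm


def assign_dtu_truth(
    structure: TranscriptomeStructure, n_dtu: int, seed=None
) -> pd.DataFrame:
    """Select DTU genes and build the transcript-level truth table.

    Eligibility requires an expected gene count above 5 and at least two
    expressed isoforms.  Per selected gene, k = max(2, Binomial(n_tx, 1/3))
    transcripts are flipped: their condition-2 baseline proportions are a
    random non-identity permutation (a swap for k = 2) of the condition-1
    proportions, confined to expressed isoforms so the usage change is real.

    Returns a transcript-level truth table with columns gene, transcript,
    is_dtu, is_dte, differentially_used, fold_change, prop_c1, prop_c2.
    """
    rng = _rng(seed)
    genes = structure.genes
    eligible = genes[(genes["expected_count"] > 5) & (genes["n_expressed"] >= 2)]
    if len(eligible) < n_dtu:
        raise ValidationError(
            f"only {len(eligible)} genes pass the DTU eligibility filter "
            f"(expected count > 5 and >= 2 expressed isoforms); requested {n_dtu}"
        )
    chosen = rng.choice(eligible[GENE_COL].to_numpy(), size=n_dtu, replace=False)
    chosen_set = set(chosen)

    truth = structure.transcripts[[GENE_COL, TRANSCRIPT_COL, "base_prop"]].copy()
    truth = truth.rename(columns={"base_prop": "prop_c1"})
    truth["prop_c2"] = truth["prop_c1"]
    truth["is_dtu"] = truth[GENE_COL].isin(chosen_set)
    truth["is_dte"] = False
    truth["differentially_used"] = False
    truth["fold_change"] = 1.0

    n_tx_by_gene = structure.genes.set_index(GENE_COL)["n_tx"]
    for g, sub in truth[truth["is_dtu"]].groupby(GENE_COL, sort=False):
        n_tx = int(n_tx_by_gene[g])
        k = max(2, int(rng.binomial(n_tx, 1.0 / 3.0)))
        expressed_idx = sub.index[sub["prop_c1"] > 0].to_numpy()
        k = min(k, expressed_idx.size)
        sel = rng.choice(expressed_idx, size=k, replace=False)
        perm = _non_identity_permutation(k, rng)
        truth.loc[sel, "prop_c2"] = truth.loc[sel, "prop_c1"].to_numpy()[perm]
        truth.loc[sel, "differentially_used"] = True
    return truth


def assign_dte_truth(
    truth: pd.DataFrame,
    n_dte: int,
    fc_model: TruncatedExponentialFC | None = None,
    seed=None,
) -> pd.DataFrame:
    """Select DTE genes (disjoint from DTU) and assign transcript fold changes.

    Every transcript of a selected gene receives a fold-change magnitude
    drawn from the truncated exponential law; the gene's direction (up or
    down) is balanced exactly across the selected genes.
    """
    rng = _rng(seed)
    fc_model = fc_model or TruncatedExponentialFC()
    fc_model.validate()
    out = truth.copy()
    free = out.loc[~out["is_dtu"], GENE_COL].unique()
    if n_dte > free.size:
        raise ValidationError(
            f"only {free.size} non-DTU genes available; requested {n_dte} DTE genes"
        )
    chosen = rng.choice(free, size=n_dte, replace=False)
    n_up = (n_dte + 1) // 2
    up = dict(zip(chosen, np.concatenate([np.ones(n_up), np.zeros(n_dte - n_up)]) > 0))
    chosen_set = set(chosen)
    mask = out[GENE_COL].isin(chosen_set)
    mags = fc_model.sample(int(mask.sum()), rng)
    direction_up = out.loc[mask, GENE_COL].map(up).to_numpy(dtype=bool)
    out.loc[mask, "fold_change"] = np.where(direction_up, mags, 1.0 / mags)
    out.loc[mask, "is_dte"] = True
    return out


def simulate_transcript_counts(
    structure: TranscriptomeStructure,
    truth: pd.DataFrame,
    n_per_condition: int = 5,
    model: TranscriptomeModel | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate transcript-level NB counts for two conditions.

    Per sample, each gene's usage is drawn from a Dirichlet centred on its
    condition-appropriate baseline proportions; the transcript mean is the
    gene's expected count times usage times the DTE fold change (condition 2
    only); counts are NB with the transcript's dispersion.

    Returns ``(counts, design)`` where ``counts`` has transcript rows (with
    a gene map column) and one integer column per sample.
    """
    if n_per_condition < 2:
        raise ValidationError("need at least 2 samples per condition")
    model = model or TranscriptomeModel()
    model.validate()
    rng = _rng(seed)

    merged = truth.merge(
        structure.transcripts[[GENE_COL, TRANSCRIPT_COL, "dispersion"]],
        on=[GENE_COL, TRANSCRIPT_COL],
    )
    if len(merged) != len(truth):
        raise ValidationError("truth table does not match the structure's transcripts")
    gene_total = structure.genes.set_index(GENE_COL)["expected_count"]

    samples, conds = [], []
    for cond in (1, 2):
        for r in range(1, n_per_condition + 1):
            samples.append(f"c{cond}_r{r}")
            conds.append(cond)
    counts = np.zeros((len(merged), len(samples)), dtype=np.int64)

    grouped = list(merged.groupby(GENE_COL, sort=False))
    for j, cond in enumerate(conds):
        prop_col = "prop_c1" if cond == 1 else "prop_c2"
        for g, sub in grouped:
            base = sub[prop_col].to_numpy()
            expressed = base > 0
            usage = np.zeros(base.size)
            if expressed.sum() == 1:
                usage[expressed] = 1.0
            else:
                usage[expressed] = rng.dirichlet(model.concentration * base[expressed])
            mean = gene_total[g] * usage
            if cond == 2:
                mean = mean * sub["fold_change"].to_numpy()
            if (mean < 0).any():
                raise ValidationError("negative transcript means")
            counts[sub.index.to_numpy(), j] = _nb_draw(
                rng, mean, sub["dispersion"].to_numpy()
            )

    counts_df = pd.concat(
        [
            merged[[GENE_COL, TRANSCRIPT_COL]].reset_index(drop=True),
            pd.DataFrame(counts, columns=samples),
        ],
        axis=1,
    )
    design = pd.DataFrame({"sample": samples, "condition": conds})
    return counts_df, design
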