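# Methods

## The two-stage procedure

Let genes *g = 1…G* each carry *n_g* null hypotheses. The screening stage
tests, per gene, the aggregated null that all *n_g* hypotheses hold, and
applies Benjamini–Hochberg (BH) across the *G* screening p-values at the
target level α_I. With *R* rejections, the confirmation stage tests every
individual hypothesis of each passing gene while controlling the within-gene
family-wise error rate at α_II = R·α_I/G. Under independence (or positive
regression dependence) across genes, this bounds the OFDR — the expected
proportion of discovered genes with at least one false rejection, where a
gene whose screening null was falsely rejected counts as false regardless of
its confirmation outcomes.

`G` in α_II = R·α_I/G is the number of genes actually screened; when
expression filtering precedes testing, filtered genes are simply absent from
both stages.

### Within-gene FWER: Holm and Shaffer MSRB

Sorting a gene's confirmation p-values ascending (stable, ties broken by
hypothesis id), the MSRB procedure compares p₍j₎ to α_II/t(j), with t(j) the
maximum number of hypotheses that can still be jointly true after j−1
rejections; t(j) ≤ n_g − j + 1, so Holm (t(j) = n_g − j + 1) is the weakest
valid choice. Built-in contexts:

| context | t-sequence | logic |
|---|---|---|
| `holm` | (n, n−1, …, 1) | no logical constraints |
| `screened_free` | (n−1, n−1, n−2, …, 1) | screening pass ⇒ ≥1 effect |
| `dte` | (n−1, n−1, n−2, …, 1); n=1 → (0) | as above; a single transcript is logically forced |
| `dtu` | (n−2, n−2, n−2, n−3, …, 1); n=2 → (0, 0) | a usage change must be compensated, ⇒ ≥2 effects |
| `dge_2x2` | (1, 1, 1) | at most one of {effect at t1, at t2, interaction} can be null |
| `dge_2x2_avg` | (1, 1, 1, 1) | adding the average-fold-change contrast leaves that bound |

t(j) = 0 encodes a vacuous threshold: the hypothesis is rejected outright
once its gene passes screening (e.g. both transcripts of a two-transcript
DTU gene).

### Adjusted p-values

The procedure is defined by thresholds, so reported adjusted p-values are a
convention chosen to be threshold-equivalent: the within-gene adjusted
p-value is the step-down running maximum of min(1, p₍k₎·t(k)) (t = 0
contributing 0), and the stage-wise adjusted p-value rescales it by G/R and
clips at 1, so that "stage-wise adjusted p ≤ α_I" reproduces the two-stage
decision exactly (tested as a round-trip identity). Genes failing screening
report 1. Missing p-values are dropped from a gene's family with a warning —
a filtered transcript should not inflate the correction burden. When R = 0
the confirmation stage is skipped with a logged notice.

### Gene-level aggregation (DTU/DTE screening)

A gene's screening p-value may come from an omnibus F-test, or from its
minimum transcript p-value θ_g via the Šidák form 1 − (1 − θ_g)^{n_g}.
Gene-level q-values evaluate q*(θ) = Σ_g[1 − (1 − θ)^{n_g}]/R(θ) at the
observed θ_g only (between observed minima R(θ) is constant and the
numerator only grows), take the minimum of q*(θ) over θ ≥ θ_g, and enforce
monotonicity by a running minimum from the largest threshold downward.
Screening then rejects genes with q ≤ α_I and uses R = #{q ≤ α_I} directly.
With one transcript per gene this is exactly BH.

### Benchmarks

The conventional analysis applies BH within each contrast separately and
flags a gene on any rejection — it controls the hypothesis-level FDR, not
the gene-level rate. The Jiang–Doerge two-stage procedure spends 4/5 of the
level on BH screening and 1/5 on one pooled BH pass over the confirmation
p-values of passing genes (the screening p-values are not pooled; the split
is configurable). Its stage-1 rejections are always a subset of the
stage-wise procedure's screening rejections at equal total level.

## Simulators

### 2×2 DGE simulator (`dge_sim`)

Counts are negative binomial, K ~ NB(mean = L_s·μ_g·f, dispersion φ_g) with
variance μ + φμ². Defaults follow the study configuration: 13,000 genes;
2,000 with a constant fold change across timepoints, 1,000 + 1,000 with a
single-timepoint effect, 1,000 with distinct fold changes at the two
timepoints (interaction-both); 5 (or 3) replicates per treatment×time cell;
all fold changes 3 or 1/3, direction balanced exactly within every category
with ties toward up. Interaction-both genes draw (3, 1/3) or (1/3, 3) at the
two timepoints, which both fixes magnitudes at 3 and makes the interaction
real. A gene's (μ_g, φ_g) is shared across timepoints, linking its
characteristics over time.

The mean–dispersion sampler is parametric: μ ~ LogNormal(4, 1.5) (median
~55 counts) and φ = (0.1 + 3/μ)·LogNormal(0, 0.4), giving the usual
decreasing mean–dispersion trend (rank correlation ≈ −0.5) and a biological
CV near 0.3 for well-expressed genes, in the range estimated from large
human reference datasets. An empirical (μ, φ) table can be supplied for
fidelity to a particular dataset. Library size factors are
LogNormal(0, 0.25); the real-data value is study-specific and this spread is
typical of within-experiment depth variation.

`simulate_hypothesis_pvalues` skips count modelling entirely: null
hypotheses draw U(0,1) p-values, alternatives draw Beta(0.1, 1)
(stochastically much smaller; roughly the power profile of a strong effect),
independently across genes and hypotheses. This is the regime in which the
OFDR guarantee is exact, and it is what the calibration checks and the
acceptance computation use.

### Transcript simulator (`tx_sim`)

Transcripts per gene are 1 + NB(shape 1.5, mean 2) (mean ≈ 3 isoforms);
gene totals are LogNormal(4, 1.5); baseline usage is Dirichlet(1) with
proportions under 0.01 zeroed and renormalised (unexpressed isoforms);
per-sample usage is Dirichlet(concentration × baseline) over expressed
isoforms, concentration 100 by default — moderate biological usage
variability (per-isoform usage SD of a 50/50 pair ≈ 0.05). Transcript NB
dispersion follows (0.05 + 2/(m+1))·LogNormal(0, 0.3) on the transcript
mean m.

DTU genes are drawn from genes with expected count > 5 and ≥ 2 expressed
isoforms; per gene, k = max(2, Binomial(n_tx, 1/3)) transcripts (capped at
the number expressed, and chosen among expressed isoforms so the usage
change is real) have their condition-2 baseline proportions set to a random
non-identity permutation of the condition-1 values — a swap when k = 2.
This conserves the gene's expected total output. DTE genes (disjoint from
DTU) scale every transcript by a fold change from Exp(rate 1) truncated to
[1.5, 4], applied as the magnitude or its reciprocal with direction balanced
across genes; the truncation interval and rate are configuration, not a
fidelity claim, since no canonical values exist.

### Test engine (`engine`)

Low-count filtering keeps features with CPM above a threshold (default 2) in
at least `min_samples` samples (default 2). Size factors are
median-of-ratios against a geometric-mean reference over features nonzero in
all samples, falling back to library-size factors with a warning. Tests are
ordinary least squares on log2(CPM + 0.5) of normalised counts (pseudo-count
0.5, log2 scale fixed), with per-contrast t-tests and an omnibus F-test over
a named contrast set; for the 2×2 design the omnibus set {t1, interaction}
spans all three contrasts. The engine exists so the pipeline runs
end-to-end; it performs no variance moderation or NB modelling, and its
p-values are only approximately calibrated for NB counts at small sample
sizes (slightly liberal in the tails). Any fitting tool can replace it —
all procedures consume plain (gene, hypothesis, p-value) tables.

## Evaluation

`gene_level_fdp` counts a discovered gene as false when it is fully null or
carries any falsely rejected individual hypothesis; the OFDR is estimated as
the mean FDP over replicates with its Monte-Carlo standard error.
FDP–TPR curves rank units by adjusted p-value; working points use the
rejection set at a nominal cut-off and are flagged achieved when empirical
FDP ≤ nominal. When no true alternatives exist, TPR is reported as 0 with an
explicit flag rather than NaN so replicate aggregation stays total.
False-positive genes decompose into fully-null genes versus partly-true
genes (the counts sum to the FDP numerator).

## Problem sizes and what the tests show

Calibration checks use 30 replicates of the full 13,000-gene configuration
with idealised valid p-values (a few seconds of compute); the comparative
power and decomposition checks use ten 2,000-gene count simulations at five
replicates per cell analysed by the built-in engine. Passing these shows
that the procedure controls the OFDR when its p-value inputs are valid and
that its qualitative advantages (interaction power at matched FDP, fewer
fully-null genes among false positives) survive an imperfect but realistic
fitting engine. It does not show calibration under real-data features the
simulators omit: correlated genes, quantification uncertainty in transcript
abundances, library-composition biases, or the moderated variance estimators
of production fitting tools.

## Numerical choices

Within-gene ties in p-values receive identical adjusted values through the
running maximum (sorting is stable with hypothesis-id tie-break, and a
later tied position's smaller t cannot raise the maximum). Šidák values use
`-expm1(n·log1p(-p))` to avoid cancellation at small p. BH and q-value
monotonicity are enforced by running extrema rather than threshold search.
φ = 0 draws are Poisson (the NB limit). Degenerate truncation bounds
(a = b) make every DTE fold change exactly a.
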