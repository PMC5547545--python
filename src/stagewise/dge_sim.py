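"""Negative-binomial count simulator for a 2x2 treatment-by-time DGE design.

The simulated study mirrors a cross-sectional time-series experiment: two
conditions (control vs. treated) profiled at two timepoints, with independent
biological replicates in every treatment x time cell.  Per-gene baseline
means and dispersions are drawn jointly from a parametric mean-dispersion
model (log-normal means; dispersion decreasing in the mean with multiplicative
noise), standing in for pairs estimated from a large reference dataset; an
empirical (mu, phi) table can be supplied instead.  A gene's baseline (mu_g,
phi_g) is shared across timepoints, which is what links its characteristics
over time.

Truth structure (defaults follow the study configuration of 13,000 genes):

* ``constant``  — same treatment fold change at both timepoints (interaction null),
* ``t1_only`` / ``t2_only`` — treatment effect at one timepoint only
  (the other timepoint null, interaction non-null),
* ``both``      — distinct fold changes at the two timepoints (all three
  hypotheses non-null),
* ``null``      — no effect whatsoever.

All fold changes have magnitude 3 (up or down, i.e. 3 or 1/3), with
direction balanced exactly within every category (ties toward up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GENE_COL, HYPOTHESIS_COL, PVALUE_COL, ValidationError

#: hypothesis ids for the three contrasts of the 2x2 design
DGE_HYPOTHESES = ("t1", "t2", "interaction")

CATEGORIES = ("null", "constant", "t1_only", "t2_only", "both")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValidationError("a seed (or Generator) is required for simulation")
    return np.random.default_rng(seed)


@dataclass
class MeanDispersionModel:
    """Joint sampler for per-gene baseline mean mu and NB dispersion phi.

    ``mu ~ LogNormal(mu_meanlog, mu_sdlog)`` (counts scale) and
    ``phi = (a0 + a1/mu) * LogNormal(0, disp_sdlog)``, so phi decreases with
    mu on average — the usual RNA-seq mean-variance trend (NB variance is
    ``mu + phi * mu**2``).  Defaults give means centred near 55 counts and
    a biological CV of roughly sqrt(a0) ~ 0.3 for highly expressed genes.
    """

    mu_meanlog: float = 4.0
    mu_sdlog: float = 1.5
    disp_a0: float = 0.1
    disp_a1: float = 3.0
    disp_sdlog: float = 0.4
    #: optional empirical table with columns mu, phi; rows are resampled jointly
    empirical: pd.DataFrame | None = None

    def validate(self) -> None:
        if self.mu_sdlog < 0 or self.disp_sdlog < 0:
            raise ValidationError("scale parameters must be non-negative")
        if self.disp_a0 < 0 or self.disp_a1 < 0:
            raise ValidationError("dispersion trend coefficients must be non-negative")
        if self.empirical is not None:
            if not {"mu", "phi"} <= set(self.empirical.columns):
                raise ValidationError("empirical table needs columns 'mu' and 'phi'")
            if (self.empirical["mu"] <= 0).any() or (self.empirical["phi"] < 0).any():
                raise ValidationError("empirical table requires mu > 0 and phi >= 0")


def sample_mean_dispersion(
    n: int, model: MeanDispersionModel | None = None, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` joint (mu_g, phi_g) pairs respecting the mean-variance trend."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    model = model or MeanDispersionModel()
    model.validate()
    rng = _rng(seed)
    if model.empirical is not None:
        rows = rng.integers(0, len(model.empirical), size=n)
        sub = model.empirical.iloc[rows]
        return sub["mu"].to_numpy(dtype=float), sub["phi"].to_numpy(dtype=float)
    mu = rng.lognormal(model.mu_meanlog, model.mu_sdlog, size=n)
    trend = model.disp_a0 + model.disp_a1 / mu
    phi = trend * rng.lognormal(0.0, model.disp_sdlog, size=n)
    return mu, phi


@dataclass
class DGEConfig:
    """Configuration of the 2x2 DGE simulation (defaults: study scale)."""

    n_genes: int = 13_000
    n_constant: int = 2_000
    n_t1_only: int = 1_000
    n_t2_only: int = 1_000
    n_both: int = 1_000
    replicates: int = 5
    fold_change: float = 3.0
    lib_sdlog: float = 0.25  # log-normal spread of per-sample library factors
    seed: int | None = None

    def validate(self) -> None:
        sizes = (self.n_constant, self.n_t1_only, self.n_t2_only, self.n_both)
        if any(s < 0 for s in sizes) or sum(sizes) > self.n_genes:
            raise ValidationError("category sizes must be non-negative and sum <= n_genes")
        if self.replicates < 2:
            raise ValidationError("need at least 2 replicates per treatment x time cell")
        if self.fold_change <= 1:
            raise ValidationError("fold_change must exceed 1")

    @property
    def n_null(self) -> int:
        return self.n_genes - (self.n_constant + self.n_t1_only + self.n_t2_only + self.n_both)


def _balanced_signs(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly half up / half down (ties toward up), in random gene order."""
    n_up = (n + 1) // 2
    signs = np.concatenate([np.ones(n_up), -np.ones(n - n_up)])
    rng.shuffle(signs)
    return signs


def assign_dge_truth(config: DGEConfig, seed=None) -> pd.DataFrame:
    """Assign categories and realised fold changes; returns the truth table.

    Columns: gene, category, fc_t1, fc_t2 (treated/control mean ratio at each
    timepoint) and the null flags null_t1, null_t2, null_interaction,
    null_screening.
    """
    config.validate()
    rng = _rng(seed if seed is not None else config.seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])
    perm = rng.permutation(config.n_genes)
    cat = np.full(config.n_genes, "null", dtype=object)
    bounds = np.cumsum(
        [config.n_constant, config.n_t1_only, config.n_t2_only, config.n_both]
    )
    cat[perm[: bounds[0]]] = "constant"
    cat[perm[bounds[0]: bounds[1]]] = "t1_only"
    cat[perm[bounds[1]: bounds[2]]] = "t2_only"
    cat[perm[bounds[2]: bounds[3]]] = "both"

    fc = config.fold_change
    fc_t1 = np.ones(config.n_genes)
    fc_t2 = np.ones(config.n_genes)
    for name in ("constant", "t1_only", "t2_only", "both"):
        idx = np.flatnonzero(cat == name)
        if idx.size == 0:
            continue
        signs = _balanced_signs(idx.size, rng)
        primary = np.where(signs > 0, fc, 1.0 / fc)
        if name == "constant":
            fc_t1[idx] = primary
            fc_t2[idx] = primary
        elif name == "t1_only":
            fc_t1[idx] = primary
        elif name == "t2_only":
            fc_t2[idx] = primary
        else:  # both: distinct fold changes at the two timepoints
            fc_t1[idx] = primary
            fc_t2[idx] = np.where(signs > 0, 1.0 / fc, fc)

    truth = pd.DataFrame(
        {
            GENE_COL: genes,
            "category": cat,
            "fc_t1": fc_t1,
            "fc_t2": fc_t2,
        }
    )
    truth["null_t1"] = truth["fc_t1"] == 1.0
    truth["null_t2"] = truth["fc_t2"] == 1.0
    truth["null_interaction"] = truth["fc_t1"] == truth["fc_t2"]
    truth["null_screening"] = (
        truth["null_t1"] & truth["null_t2"] & truth["null_interaction"]
    )
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, phi) with variance mean + phi*mean^2; phi == 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def simulate_dge_counts(
    config: DGEConfig,
    model: MeanDispersionModel | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full 2x2 dataset.

    Returns
    -------
    counts : DataFrame, genes x samples (integer counts, gene ids as index)
    design : DataFrame with columns sample, condition (control/treated),
        time (t1/t2), replicate, lib_factor
    truth : truth table from :func:`assign_dge_truth`
    """
    config.validate()
    rng = _rng(seed if seed is not None else config.seed)
    truth = assign_dge_truth(config, rng)
    mu, phi = sample_mean_dispersion(config.n_genes, model, rng)

    cells = [
        (cond, time) for time in ("t1", "t2") for cond in ("control", "treated")
    ]
    samples, cond_l, time_l, rep_l = [], [], [], []
    for cond, time in cells:
        for r in range(1, config.replicates + 1):
            samples.append(f"{cond}_{time}_r{r}")
            cond_l.append(cond)
            time_l.append(time)
            rep_l.append(r)
    lib = rng.lognormal(0.0, config.lib_sdlog, size=len(samples))
    if (lib <= 0).any():
        raise ValidationError("library factors must be positive")
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": cond_l,
            "time": time_l,
            "replicate": rep_l,
            "lib_factor": lib,
        }
    )

    fc = {"t1": truth["fc_t1"].to_numpy(), "t2": truth["fc_t2"].to_numpy()}
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, (cond, time, L) in enumerate(zip(cond_l, time_l, lib)):
        mult = fc[time] if cond == "treated" else 1.0
        counts[:, j] = _nb_draw(rng, L * mu * mult, phi)
    counts_df = pd.DataFrame(counts, index=pd.Index(truth[GENE_COL], name=GENE_COL), columns=samples)
    return counts_df, design, truth


def truth_to_long(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-hypothesis null flags in long format (gene, hypothesis, is_null)."""
    rows = []
    for hyp, col in zip(DGE_HYPOTHESES, ("null_t1", "null_t2", "null_interaction")):
        rows.append(
            pd.DataFrame(
                {GENE_COL: truth[GENE_COL], HYPOTHESIS_COL: hyp, "is_null": truth[col]}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_hypothesis_pvalues(
    truth: pd.DataFrame,
    seed=None,
    alt_beta: tuple[float, float] = (0.1, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw idealised per-hypothesis and screening p-values for a truth table.

    Null hypotheses receive U(0,1) p-values; non-null hypotheses (and the
    screening test of any non-null gene) receive draws from a
    stochastically smaller Beta(a, b) law (default Beta(0.1, 1)).  This
    bypasses count modelling entirely and is the configuration under which
    the two-stage procedure's OFDR guarantee is exact, so it is used for
    calibration checks.

    Returns ``(screening_table, hypothesis_table)`` in the formats consumed
    by :func:`stagewise.core.screen` and :func:`stagewise.core.confirm`.
    """
    rng = _rng(seed)
    a, b = alt_beta
    long = truth_to_long(truth)
    n = len(long)
    is_null = long["is_null"].to_numpy()
    p = np.where(is_null, rng.uniform(size=n), rng.beta(a, b, size=n))
    hyp_table = long[[GENE_COL, HYPOTHESIS_COL]].assign(**{PVALUE_COL: p})

    null_screen = truth["null_screening"].to_numpy()
    ps = np.where(
        null_screen,
        rng.uniform(size=len(truth)),
        rng.beta(a, b, size=len(truth)),
    )
    screening = pd.DataFrame({GENE_COL: truth[GENE_COL], PVALUE_COL: ps})
    return screening, hyp_table
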