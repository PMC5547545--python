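"""Minimal per-feature testing engine for simulated counts.

This is deliberately simple plumbing so the two-stage pipeline runs
end-to-end on simulated data: low-count filtering, median-of-ratios size
factors, and ordinary least-squares fits on log2-CPM with per-contrast
t-tests plus an omnibus F-test for the screening stage.  Any fitting tool
can replace it — the testing procedures consume plain p-value tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import GENE_COL, HYPOTHESIS_COL, PVALUE_COL, ValidationError

logger = logging.getLogger(__name__)


def filter_low_counts(
    counts: pd.DataFrame, cpm_threshold: float = 2.0, min_samples: int = 2
) -> pd.DataFrame:
    """Keep features with CPM above ``cpm_threshold`` in >= ``min_samples`` samples.

    ``counts`` is a numeric features-x-samples frame (non-count columns such
    as gene maps are ignored for the CPM computation but preserved).
    """
    num = counts.select_dtypes(include=[np.number])
    if num.empty:
        raise ValidationError("no numeric sample columns in counts")
    mat = num.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValidationError("counts must be non-negative")
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    cpm = mat / lib * 1e6
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError("low-count filter removed every feature")
    return counts.loc[keep]


def normalize(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Features with a zero in any sample are excluded from the reference; if
    none remain, library-size factors (scaled to geometric mean 1) are used
    with a warning.
    """
    num = counts.select_dtypes(include=[np.number])
    mat = num.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValidationError("counts must be non-negative")
    positive = (mat > 0).all(axis=1)
    if positive.any():
        ref = np.exp(np.log(mat[positive]).mean(axis=1))
        factors = np.median(mat[positive] / ref[:, None], axis=0)
    else:
        logger.warning(
            "no feature is nonzero in all samples; falling back to library-size factors"
        )
        lib = mat.sum(axis=0)
        factors = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(factors, index=num.columns, name="size_factor")


@dataclass
class DesignSpec:
    """Design matrix, named contrast vectors and the omnibus contrast set."""

    matrix: pd.DataFrame  # samples x coefficients
    contrasts: dict[str, np.ndarray]
    omnibus: list[str] = field(default_factory=list)

    def validate(self) -> None:
        X = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            aliased = _aliased_columns(X, list(self.matrix.columns))
            raise ValidationError(f"design matrix is rank deficient; aliased columns: {aliased}")
        for name, c in self.contrasts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (X.shape[1],):
                raise ValidationError(f"contrast {name!r} has wrong length")
            if not c.any():
                raise ValidationError(f"contrast {name!r} is all zeros")
        unknown = set(self.omnibus) - set(self.contrasts)
        if unknown:
            raise ValidationError(f"omnibus refers to unknown contrasts: {sorted(unknown)}")


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], []
    for j, name in enumerate(names):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            aliased.append(name)
        else:
            kept.append(j)
    return aliased


def dge_2x2_design(design: pd.DataFrame) -> DesignSpec:
    """Design for a 2x2 treatment-by-time layout with the standard contrasts.

    Treatment coding with coefficients (intercept, trt, time, trt:time);
    contrasts: treatment effect at timepoint 1 (``t1``), at timepoint 2
    (``t2``) and the treatment-by-time interaction.  The omnibus set
    {t1, interaction} spans all three (t2 = t1 + interaction).
    """
    for col in ("sample", "condition", "time"):
        if col not in design.columns:
            raise ValidationError(f"design table lacks column {col!r}")
    trt = (design["condition"] == "treated").astype(float).to_numpy()
    tm = (design["time"] == "t2").astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "trt": trt,
            "time": tm,
            "trt_time": trt * tm,
        },
        index=design["sample"],
    )
    contrasts = {
        "t1": np.array([0.0, 1.0, 0.0, 0.0]),
        "t2": np.array([0.0, 1.0, 0.0, 1.0]),
        "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
    }
    return DesignSpec(X, contrasts, omnibus=["t1", "interaction"])


def feature_tests(
    counts: pd.DataFrame,
    design: DesignSpec,
    size_factors: pd.Series | None = None,
    feature_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS on log2-CPM per feature: contrast t-tests and an omnibus F-test.

    Parameters
    ----------
    counts
        Features x samples integer counts; ``feature_col`` (default: the
        index) names the feature id column used as the gene id in the
        output tables.
    design
        Validated :class:`DesignSpec`; samples must match the count columns.

    Returns
    -------
    (hypotheses, screening): a long table (gene, hypothesis, pvalue) with
    one row per named contrast per feature, and a per-feature table
    (gene, pvalue) holding the omnibus F-test p-values.
    """
    design.validate()
    X = design.matrix.to_numpy(dtype=float)
    n, k = X.shape
    if n - k < 2:
        raise ValidationError("need at least 2 residual degrees of freedom")

    sample_cols = list(design.matrix.index)
    missing = set(sample_cols) - set(counts.columns)
    if missing:
        raise ValidationError(f"count matrix lacks samples: {sorted(missing)[:3]}")
    mat = counts[sample_cols].to_numpy(dtype=float)
    if feature_col is not None:
        features = counts[feature_col].to_numpy()
    else:
        features = counts.index.to_numpy()

    if size_factors is None:
        size_factors = normalize(counts[sample_cols])
    sf = size_factors.reindex(sample_cols).to_numpy(dtype=float)
    norm = mat / sf
    cpm = norm / norm.sum(axis=0) * 1e6
    Y = np.log2(cpm + 0.5)

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # k x n
    B = Y @ H.T  # features x k
    resid = Y - B @ X.T
    dof = n - k
    s2 = (resid**2).sum(axis=1) / dof
    s2 = np.maximum(s2, 1e-300)

    rows = []
    for name, c in design.contrasts.items():
        c = np.asarray(c, dtype=float)
        est = B @ c
        se = np.sqrt(s2 * (c @ XtX_inv @ c))
        tstat = est / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        rows.append(
            pd.DataFrame({GENE_COL: features, HYPOTHESIS_COL: name, PVALUE_COL: p})
        )
    hypotheses = pd.concat(rows, ignore_index=True)
    hypotheses[PVALUE_COL] = hypotheses[PVALUE_COL].clip(lower=np.nextafter(0, 1))

    L = np.stack([np.asarray(design.contrasts[name], dtype=float) for name in design.omnibus])
    M = L @ XtX_inv @ L.T
    M_inv = np.linalg.inv(M)
    BL = B @ L.T  # features x q
    q = L.shape[0]
    quad = np.einsum("gi,ij,gj->g", BL, M_inv, BL)
    F = quad / (q * s2)
    p_omni = stats.f.sf(F, q, dof)
    screening = pd.DataFrame(
        {GENE_COL: features, PVALUE_COL: np.clip(p_omni, np.nextafter(0, 1), 1.0)}
    )
    return hypotheses, screening
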