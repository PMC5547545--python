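import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_gene_case():
    """Hand-traceable two-stage instance: 3 genes, Holm confirmation.

    Screening p = (0.001, 0.01, 0.9) at alpha_I = 0.05: BH-adjusted
    (0.003, 0.015, 0.9), so genes A and B pass, R = 2,
    alpha_II = 2 * 0.05 / 3 = 1/30.
    """
    screening = pd.DataFrame(
        {"gene": ["A", "B", "C"], "pvalue": [0.001, 0.01, 0.9]}
    )
    hypotheses = pd.DataFrame(
        {
            "gene": ["A", "A", "B", "B", "C", "C"],
            "hypothesis": ["h1", "h2", "h1", "h2", "h1", "h2"],
            "pvalue": [0.01, 0.04, 0.5, 0.6, 0.001, 0.002],
        }
    )
    return screening, hypotheses


def holm_adjust_reference(p):
    """Textbook Holm step-down adjustment (independent of the package path)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, p[order] * (n - np.arange(n)))
    adj = np.maximum.accumulate(adj)
    out = np.empty(n)
    out[order] = adj
    return out
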