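"""Comparison of fitted exponents across corpora.

Once each (species, sub-ontology, evidence-class) corpus has a fitted
frequency exponent beta, three questions follow: do the sub-ontologies
differ systematically (per-aspect mean beta), does evidence quality
shift the exponent (paired t-test of high-confidence vs electronic-only
fits), and does the exponent merely track corpus size (rank correlation
of beta with corpus size)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gozipf.depth_analysis import DegenerateInputError


@dataclass(frozen=True)
class ExponentRecord:
    """One fitted exponent: a (source, aspect, evidence class) cell."""

    source_label: str
    aspect: str
    evidence_class: str
    beta: float
    p_value: float | None = None
    n_total: int = 0
    n_distinct: int = 0


def group_mean_beta(records: list[ExponentRecord], aspect: str) -> float:
    """Arithmetic mean of beta over all records of one sub-ontology."""
    betas = [r.beta for r in records if r.aspect == aspect]
    if not betas:
        raise ValueError(f"no records for aspect {aspect!r}")
    return float(np.mean(betas))


def paired_t_test(
    pairs: list[tuple[float, float]], sides: str = "two"
) -> tuple[float, int, float]:
    """Paired t-test on (first, second) measurement pairs.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = first - second,
    with df = n - 1. ``sides='one'`` gives the one-sided p for
    first > second.

    Returns (t, df, p).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    first = np.array([a for a, _ in pairs], dtype=float)
    second = np.array([b for _, b in pairs], dtype=float)
    if np.allclose((first - second).std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    alternative = "two-sided" if sides == "two" else "greater"
    res = stats.ttest_rel(first, second, alternative=alternative)
    return float(res.statistic), len(pairs) - 1, float(res.pvalue)


def size_exponent_association(
    records: list[ExponentRecord],
) -> tuple[float, float, pd.DataFrame]:
    """Rank correlation of beta with corpus size.

    Returns Spearman correlations of beta with the number of distinct
    terms and with the total annotation count, plus the scatter data
    behind them (one row per record). A constant beta has, by
    convention, zero correlation with anything.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    scatter = pd.DataFrame(
        {
            "source": [r.source_label for r in records],
            "aspect": [r.aspect for r in records],
            "evidence_class": [r.evidence_class for r in records],
            "n_distinct": [r.n_distinct for r in records],
            "n_total": [r.n_total for r in records],
            "beta": [r.beta for r in records],
        }
    )

    def spearman(x, y) -> float:
        if np.allclose(np.std(x), 0.0) or np.allclose(np.std(y), 0.0):
            return 0.0
        return float(stats.spearmanr(x, y).statistic)

    corr_distinct = spearman(scatter["n_distinct"], scatter["beta"])
    corr_total = spearman(scatter["n_total"], scatter["beta"])
    return corr_distinct, corr_total, scatter
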