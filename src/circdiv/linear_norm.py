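"""TMM normalization of linear gene counts and circ-linear correlation.

The trimmed mean of M-values (TMM) scaling factor for sample k against a
reference r is

    f_k = 2 ** ( sum_g w_g M_g / sum_g w_g )

over genes nonzero in both samples, where M_g = log2((y_gk/N_k)/(y_gr/N_r)) is
the log-ratio, A_g = 0.5*log2((y_gk/N_k)(y_gr/N_r)) the log-abundance, genes in
the extreme 30% tails of M and 5% tails of A are discarded (rank-based double
trim), and w_g is the inverse asymptotic variance of M_g under binomial
sampling: w_g = 1 / ((N_k - y_gk)/(N_k y_gk) + (N_r - y_gr)/(N_r y_gr)).
The reference sample is the one whose upper-quartile of counts/library-size is
closest to the cohort mean upper-quartile. Factors are rescaled to geometric
mean 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormFactors",
    "CircLinearCorrelation",
    "tmm_factors",
    "normalized_expression",
    "circ_linear_correlation",
    "summarize_correlations",
    "classify_r",
]

logger = logging.getLogger(__name__)


@dataclass
class NormFactors:
    factors: "pd.Series"  # sample -> f_k, geometric mean 1
    reference: str


@dataclass
class CircLinearCorrelation:
    circ_id: str
    gene_id: str
    r: float
    n: int
    r_class: str  # negative / poor / positive / undefined


def _upper_quartiles(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0).astype(float)
    uq = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample} has no nonzero gene")
        uq[sample] = np.quantile(nz / lib[sample], 0.75)
    return pd.Series(uq)


def _tmm_pair(yk: np.ndarray, yr: np.ndarray, trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample vs the reference (unscaled)."""
    nk, nr = yk.sum(), yr.sum()
    both = (yk > 0) & (yr > 0)
    if not both.any():
        return np.nan
    yk, yr = yk[both].astype(float), yr[both].astype(float)
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
    if np.allclose(m, 0.0, atol=1e-10):
        # degenerate pair (scaled columns): weighted mean of M is exactly 0
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Compute TMM scaling factors for a genes x samples count matrix."""
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    uq = _upper_quartiles(counts)
    reference = (uq - uq.mean()).abs().idxmin()
    yr = counts[reference].to_numpy()
    raw = {}
    for sample in counts.columns:
        if sample == reference:
            raw[sample] = 1.0
            continue
        f = _tmm_pair(counts[sample].to_numpy(), yr, trim_m, trim_a)
        if np.isnan(f):
            warnings.warn(f"sample {sample} shares no nonzero gene with reference {reference}; factor set to 1")
            f = 1.0
        raw[sample] = f
    series = pd.Series(raw, dtype=float)
    series /= np.exp(np.mean(np.log(series)))  # geometric mean 1
    return NormFactors(factors=series, reference=reference)


def normalized_expression(counts: pd.DataFrame, factors: NormFactors) -> pd.DataFrame:
    """Counts per million on the TMM-effective library size, y/(N*f) * 1e6."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    eff = lib * factors.factors.reindex(counts.columns)
    return counts / eff * 1e6


def classify_r(r: float, boundary: float = 0.3) -> str:
    if not np.isfinite(r):
        return "undefined"
    if r < 0:
        return "negative"
    if r < boundary:
        return "poor"
    return "positive"


def circ_linear_correlation(
    junction_counts: pd.DataFrame,
    expr: pd.DataFrame,
    host_genes: "pd.Series | dict",
    min_samples_present: int = 20,
    boundary: float = 0.3,
    present_only: bool = False,
    log1p: bool = False,
) -> list[CircLinearCorrelation]:
    """Pearson correlation of each circRNA's junction reads with its host gene.

    ``junction_counts`` is circRNAs x samples (raw junction-fragment counts,
    0 where not detected); ``expr`` normalized genes x samples; ``host_genes``
    maps circRNA id -> gene id. circRNAs detected in fewer than
    ``min_samples_present`` samples are skipped, as are those with no host
    gene in ``expr``. Zero-variance vectors give an "undefined" record.
    """
    host = pd.Series(host_genes)
    results: list[CircLinearCorrelation] = []
    samples = [s for s in junction_counts.columns if s in expr.columns]
    for circ_id in junction_counts.index:
        gene_id = host.get(circ_id)
        if gene_id is None or gene_id not in expr.index:
            continue
        x = junction_counts.loc[circ_id, samples].to_numpy(dtype=float)
        n_present = int((x > 0).sum())
        if n_present < min_samples_present:
            continue
        y = expr.loc[gene_id, samples].to_numpy(dtype=float)
        if present_only:
            mask = x > 0
            x, y = x[mask], y[mask]
        if log1p:
            x, y = np.log1p(x), np.log1p(y)
        n = x.size
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            results.append(CircLinearCorrelation(circ_id, gene_id, float("nan"), n, "undefined"))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        results.append(CircLinearCorrelation(circ_id, gene_id, r, n, classify_r(r, boundary)))
    return results


def summarize_correlations(
    correlations: list[CircLinearCorrelation],
    boundary: float = 0.3,
    bin_width: float = 0.1,
) -> dict:
    """Counts per correlation class plus fixed-width histogram bins on [-1, 1]."""
    if not correlations:
        raise ValueError("no correlations to summarize")
    rs = np.array([c.r for c in correlations if np.isfinite(c.r)])
    n_negative = int((rs < 0).sum())
    n_poor = int(((rs >= 0) & (rs < boundary)).sum())
    n_positive = int((rs >= boundary).sum())
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    hist, _ = np.histogram(rs, bins=edges)
    return {
        "n_negative": n_negative,
        "n_poor": n_poor,
        "n_positive": n_positive,
        "n_undefined": sum(1 for c in correlations if not np.isfinite(c.r)),
        "hist_edges": edges,
        "hist_counts": hist,
    }
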