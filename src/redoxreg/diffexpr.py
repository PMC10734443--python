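"""Two-condition differential expression on a count matrix.

A deliberately simple negative-binomial Wald pipeline: median-of-ratios
size factors, per-gene method-of-moments dispersion (no trend or
shrinkage fitting), a Wald test on the log2 ratio of normalized condition
means, and Benjamini-Hochberg adjustment. Parity with full-featured DE
packages is not claimed; the point is a transparent, testable stage that
feeds the transcriptional-cluster caller.

Fold changes follow the signed convention used throughout the package:
fc = 2**lfc for lfc >= 0 and -2**(-lfc) for lfc < 0, so "fc = -23" means
23-fold lower in the mutant and |fc| >= 1 always. The mutant condition is
the numerator.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, fc_from_lfc

DISPERSION_FLOOR = 1e-8
DEFAULT_PSEUDOCOUNT = 0.5


def estimate_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Each sample's factor is the median over genes (restricted to genes
    with a positive geometric mean across samples) of count / geometric
    mean. Raises if no gene is usable (e.g. an all-zero matrix).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.isfinite(logc).all(axis=1)
    if not usable.any():
        raise ValueError("cannot normalize: no gene has nonzero counts in every sample")
    log_geomean = logc[usable].mean(axis=1)
    factors = np.exp(np.median(logc[usable] - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def estimate_dispersion(
    matrix: CountMatrix, size_factors: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion.

    On normalized counts q = K/s the model variance is mu/s + d*mu^2, so
    d = (pooled within-condition variance - mu * mean(1/s)) / mu^2.
    Residual variance is pooled across both conditions after removing
    each condition's mean; negative estimates floor at ``floor``.
    """
    matrix.require_replicates(2)
    sf = size_factors.loc[matrix.counts.columns].to_numpy()
    q = matrix.counts.to_numpy(dtype=float) / sf

    ss = np.zeros(q.shape[0])
    df = 0
    for label in matrix.condition_labels:
        idx = [matrix.counts.columns.get_loc(s) for s in matrix.samples_of(label)]
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    resid_var = ss / df
    mu = q.mean(axis=1)
    shot = mu * np.mean(1.0 / sf)  # Poisson component of the variance
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (resid_var - shot) / mu**2
    d = np.where(np.isfinite(d), d, 0.0)
    return pd.Series(np.maximum(d, floor), index=matrix.counts.index, name="dispersion")


def wald_test(
    matrix: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    *,
    reference: str = "wt",
    treatment: str = "mut",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB Wald test of treatment (mutant) vs reference (wild type).

    Per gene: lfc = log2((mean_mut + pc) / (mean_wt + pc)) on normalized
    counts; its standard error comes from the delta method under the NB
    variance mu + d*mu^2. The Wald statistic is referred to a Student-t
    distribution with n1 + n2 - 2 degrees of freedom — a small-sample
    correction for the plug-in variance, without which the test is badly
    anticonservative at the 3-replicate scale this pipeline targets.

    Genes with zero counts in every sample are flagged untested
    (p = 1 convention) and later excluded from the BH family.

    Returns a DataFrame indexed by gene id with columns base_mean,
    log2fc, fc, se_lfc, stat, pvalue, padj, tested. ``padj`` is filled by
    :func:`run_de`.
    """
    matrix.require_replicates(2)
    if {reference, treatment} != set(matrix.condition_labels):
        raise ValueError(
            f"conditions {matrix.condition_labels} do not match "
            f"reference={reference!r}, treatment={treatment!r}"
        )
    sf = size_factors.loc[matrix.counts.columns].to_numpy()
    q = matrix.counts.to_numpy(dtype=float) / sf
    d = dispersions.loc[matrix.counts.index].to_numpy()

    cols = {
        label: [matrix.counts.columns.get_loc(s) for s in matrix.samples_of(label)]
        for label in (reference, treatment)
    }
    n_ref, n_trt = len(cols[reference]), len(cols[treatment])
    m_ref = q[:, cols[reference]].mean(axis=1)
    m_trt = q[:, cols[treatment]].mean(axis=1)

    lfc = np.log2((m_trt + pseudocount) / (m_ref + pseudocount))

    def mean_var(m: np.ndarray, idx: list[int], n: int) -> np.ndarray:
        # Var(mean of K_s/s_s) under Var(K) = s*mu + d*(s*mu)^2
        s = sf[idx]
        return (m[:, None] / s + d[:, None] * m[:, None] ** 2).sum(axis=1) / n**2

    v_ref = mean_var(m_ref, cols[reference], n_ref)
    v_trt = mean_var(m_trt, cols[treatment], n_trt)
    se = np.sqrt(v_trt / (m_trt + pseudocount) ** 2 + v_ref / (m_ref + pseudocount) ** 2) / np.log(2)

    tested = matrix.counts.to_numpy().sum(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    stat = np.where(np.isfinite(stat), stat, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df=n_ref + n_trt - 2)
    pvalue = np.where(tested, pvalue, 1.0)

    return pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": np.where(tested, lfc, 0.0),
            "fc": [fc_from_lfc(x) for x in np.where(tested, lfc, 0.0)],
            "se_lfc": se,
            "stat": np.where(tested, stat, 0.0),
            "pvalue": pvalue,
            "padj": np.nan,
            "tested": tested,
        },
        index=matrix.counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, where p_(1..m) are
    the sorted raw p values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_de(
    matrix: CountMatrix,
    *,
    reference: str = "wt",
    treatment: str = "mut",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Full DE stage: normalization, dispersion, Wald test, BH adjustment.

    Untested (all-zero) genes are excluded from the BH family m; their
    padj is NaN.
    """
    sf = estimate_size_factors(matrix)
    disp = estimate_dispersion(matrix, sf, floor=dispersion_floor)
    de = wald_test(
        matrix, sf, disp, reference=reference, treatment=treatment, pseudocount=pseudocount
    )
    tested = de["tested"].to_numpy()
    padj = np.full(len(de), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(de.loc[tested, "pvalue"].to_numpy())
    de["padj"] = padj
    return de
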