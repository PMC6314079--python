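"""Vectorised nonparametric statistics shared across modules.

These exist because the pipeline applies the same scalar test to hundreds of
thousands of probes; the scipy equivalents are verified against these in the
test suite on small instances.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "rowwise_spearman",
    "spearman_rho_p",
    "paired_signed_rank",
    "rowwise_fligner_two_group",
    "hwe_exact_test",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values); NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1)


def rowwise_spearman(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for each row pair of two (m, n) arrays.

    Midrank tie handling; p from the t approximation with n-2 df, the same
    large-sample reference scipy.stats.spearmanr uses. Rows where either
    side is constant get NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("arrays must share shape")
    n = a.shape[1]
    ra = _rank_rows(a)
    rb = _rank_rows(b)
    ra -= ra.mean(axis=1, keepdims=True)
    rb -= rb.mean(axis=1, keepdims=True)
    va = (ra**2).sum(axis=1)
    vb = (rb**2).sum(axis=1)
    denom = np.sqrt(va * vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=1) / denom
    rho = np.where(denom == 0, np.nan, np.clip(rho, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(
        np.isnan(rho),
        np.nan,
        np.where(np.abs(rho) == 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2)),
    )
    return rho, p


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p = rowwise_spearman(x[None, :], y[None, :])
    return float(rho[0]), float(p[0])


def paired_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise paired Wilcoxon signed-rank test (two-sided).

    Zero differences are discarded (the 'wilcox' convention) and the normal
    approximation with tie correction is used, matching
    ``scipy.stats.wilcoxon(..., zero_method='wilcox', method='approx',
    correction=False)`` row by row. Rows with no nonzero differences return
    statistic NaN and p = 1 (degenerate: the two sides are identical).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    m, n = d.shape
    stat = np.full(m, np.nan)
    p = np.ones(m)

    absd = np.abs(d)
    nonzero = absd > 0
    n_eff = nonzero.sum(axis=1)

    # rank |d| among nonzero entries per row: push zeros beyond the largest
    big = np.where(nonzero, absd, np.inf)
    ranks = stats.rankdata(big, axis=1)
    ranks = np.where(nonzero, ranks, 0.0)

    w_plus = np.where(d > 0, ranks, 0.0).sum(axis=1)

    ne = n_eff.astype(float)
    mn = ne * (ne + 1) / 4.0
    var = ne * (ne + 1) * (2 * ne + 1) / 24.0
    var -= _rowwise_tie_term(np.where(nonzero, absd, np.nan)) / 48.0

    ok = (n_eff > 0) & (var > 0)
    z = np.zeros(m)
    z[ok] = (w_plus[ok] - mn[ok]) / np.sqrt(var[ok])
    stat[n_eff > 0] = w_plus[n_eff > 0]
    p[ok] = 2 * stats.norm.sf(np.abs(z[ok]))
    p[(n_eff > 0) & (var <= 0)] = 1.0
    return stat, np.clip(p, 0.0, 1.0)


def _rowwise_tie_term(x: np.ndarray) -> np.ndarray:
    """Per row, sum of (t^3 - t) over groups of tied finite values.

    NaN entries are excluded. Implemented by sorting each row and counting
    runs of equal adjacent values, so it stays vectorised across rows.
    """
    m, n = x.shape
    s = np.sort(x, axis=1)  # NaNs go last
    new_group = np.ones((m, n), dtype=bool)
    new_group[:, 1:] = s[:, 1:] != s[:, :-1]
    new_group[np.isnan(s)] = True  # each NaN its own group of size 1
    gid = np.cumsum(new_group.reshape(-1))  # global group ids across rows
    counts = np.bincount(gid)
    t = counts[gid].reshape(m, n).astype(float)
    # each member of a size-t group contributes (t^3 - t)/t = t^2 - 1
    contrib = np.where(np.isnan(s), 0.0, t**2 - 1.0)
    return contrib.sum(axis=1)


def rowwise_fligner_two_group(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Fligner-Killeen homogeneity-of-variances test for two groups.

    Per row: centre each group at its median, pool the absolute deviations,
    midrank them, transform ranks through the standard-normal quantile
    function a_i = Phi^-1(0.5 + r_i / (2(N+1))), and compare group means of
    the scores with a chi-square(1) statistic — the same construction as
    scipy.stats.fligner, applied across rows at once. Rows where the pooled
    scores have zero variance (both groups constant) get statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, na = a.shape
    nb = b.shape[1]
    dev_a = np.abs(a - np.median(a, axis=1, keepdims=True))
    dev_b = np.abs(b - np.median(b, axis=1, keepdims=True))
    pooled = np.concatenate([dev_a, dev_b], axis=1)
    n_tot = na + nb
    ranks = stats.rankdata(pooled, axis=1)
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n_tot + 1)))
    grand = scores.mean(axis=1)
    v = scores.var(axis=1, ddof=1)
    mean_a = scores[:, :na].mean(axis=1)
    mean_b = scores[:, na:].mean(axis=1)
    num = na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(v > 0, num / v, 0.0)
    p = np.where(v > 0, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    The conditional distribution of the heterozygote count given allele
    counts is enumerated and the p-value is the summed probability of all
    outcomes no more probable than the observed one (the standard SNP-HWE
    exact test). Monomorphic SNPs return p = 1.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_ab = h | allele counts) up to a constant
    logp = (
        hets * np.log(2.0)
        + special.gammaln(n + 1)
        - special.gammaln((n_a - hets) / 2 + 1)
        - special.gammaln(hets + 1)
        - special.gammaln((n_b - hets) / 2 + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_ab][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))
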