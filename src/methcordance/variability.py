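"""Inter-individual DNAm variability and between-tissue variance comparison.

Variability at a CpG is summarised by the *reference range*: the spread
between the 10th and 90th percentile of beta values across individuals.
Compared with the absolute range it is robust to outlier samples and to
non-normal beta distributions. Global tissue differences use a paired
Wilcoxon signed-rank test over probes; probewise differences use the
Fligner-Killeen homogeneity-of-variances test with Benjamini-Hochberg FDR.
A without-replacement subsampling study equalises sample size between
cohorts and reports per-probe averages over trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, rowwise_fligner_two_group, rowwise_spearman
from .data_io import BetaMatrix, CohortBundle

__all__ = [
    "reference_range",
    "reference_range_rows",
    "global_variability_test",
    "probewise_variance_test",
    "subsample_study",
    "GlobalVariabilityResult",
    "SubsampleResult",
]


def reference_range(values: np.ndarray) -> float:
    """90th minus 10th percentile of the non-missing values.

    Percentiles use linear interpolation between order statistics (the
    "type 7" convention shared by numpy and R defaults).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("reference_range needs at least 2 non-missing values")
    lo, hi = np.percentile(v, (10.0, 90.0))
    return float(hi - lo)


def reference_range_rows(values: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row-wise reference range of a probes x samples matrix (NaN-aware)."""
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        lo = np.nanpercentile(arr, 10.0, axis=1)
        hi = np.nanpercentile(arr, 90.0, axis=1)
    else:
        lo, hi = np.percentile(arr, (10.0, 90.0), axis=1)
    return hi - lo


@dataclass
class GlobalVariabilityResult:
    statistic: float
    p_value: float
    median_difference: float  # median of (a - b) over probes
    degenerate: bool


def global_variability_test(
    rr_tissue_a: np.ndarray, rr_tissue_b: np.ndarray
) -> GlobalVariabilityResult:
    """Paired two-sided Wilcoxon signed-rank test on per-probe reference ranges."""
    a = np.asarray(rr_tissue_a, dtype=float)
    b = np.asarray(rr_tissue_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    med = float(np.median(d))
    if np.all(d == 0):
        return GlobalVariabilityResult(np.nan, 1.0, 0.0, degenerate=True)
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return GlobalVariabilityResult(float(stat), float(p), med, degenerate=False)


def probewise_variance_test(
    beta_a: BetaMatrix, beta_b: BetaMatrix, fdr: float = 0.05
) -> pd.DataFrame:
    """Fligner-Killeen test of dispersion per CpG between two tissues.

    Returns a per-probe table with reference ranges in each tissue, the
    test statistic and p, BH-adjusted q, and a direction label
    (``more_variable_in``: the tissue with the larger reference range where
    q <= fdr, else "ns"; "tie" for equal ranges). Probes constant in both
    tissues get p = 1 and are flagged degenerate.
    """
    if not beta_a.probe_ids.equals(beta_b.probe_ids):
        raise ValueError("probe sets must match")
    A = beta_a.values.to_numpy(dtype=float)
    B = beta_b.values.to_numpy(dtype=float)
    n = A.shape[0]
    degenerate = (np.nanmax(A, axis=1) == np.nanmin(A, axis=1)) & (
        np.nanmax(B, axis=1) == np.nanmin(B, axis=1)
    )
    has_na = np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1)
    stat = np.zeros(n)
    p = np.ones(n)
    dense = ~has_na & ~degenerate
    if dense.any():
        stat[dense], p[dense] = rowwise_fligner_two_group(A[dense], B[dense])
    for i in np.flatnonzero(has_na & ~degenerate):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if a.size < 2 or b.size < 2:
            degenerate[i] = True
            continue
        stat[i], p[i] = stats.fligner(a, b)
    stat[degenerate] = np.nan
    rr_a = reference_range_rows(A)
    rr_b = reference_range_rows(B)
    q = bh_adjust(p)
    label = np.where(rr_a > rr_b, beta_a.tissue or "a", beta_b.tissue or "b")
    label = np.where(rr_a == rr_b, "tie", label)
    label = np.where((q <= fdr) & ~degenerate, label, "ns")
    return pd.DataFrame(
        {
            "rr_a": rr_a,
            "rr_b": rr_b,
            "fligner_stat": stat,
            "fligner_p": p,
            "fligner_q": q,
            "more_variable_in": label,
            "degenerate": degenerate,
        },
        index=beta_a.probe_ids,
    )


@dataclass
class SubsampleResult:
    """Per-probe arithmetic means over subsampling trials.

    ``table`` columns: mean reference range per tissue, mean cross-tissue
    Spearman rho and mean p over trials (the p-average mirrors how the
    subsampled dataset is summarised upstream of consensus calls; a
    geometric-mean alternative is available via ``p_average='geometric'``).
    """

    table: pd.DataFrame
    n_trials: int
    n_sub: int


def subsample_study(
    bundle: CohortBundle,
    n_sub: int,
    n_trials: int = 100,
    seed: int = 0,
    p_average: str = "arithmetic",
) -> SubsampleResult:
    """Monte-Carlo subsampling of matched individuals.

    Draws ``n_trials`` without-replacement subsets of ``n_sub`` individuals,
    recomputes per-probe reference ranges (both tissues) and cross-tissue
    Spearman rho/p per trial, and averages across trials. Deterministic
    given ``seed``.
    """
    if n_sub < 4:
        raise ValueError("n_sub must be at least 4")
    if n_sub > bundle.n_samples:
        raise ValueError("n_sub exceeds the cohort size")
    if p_average not in ("arithmetic", "geometric"):
        raise ValueError("p_average must be 'arithmetic' or 'geometric'")
    rng = np.random.default_rng(seed)
    A = bundle.beta_a.values.to_numpy(dtype=float)
    B = bundle.beta_b.values.to_numpy(dtype=float)
    n = bundle.n_samples
    acc = {k: np.zeros(A.shape[0]) for k in ("rr_a", "rr_b", "rho", "p")}
    for _ in range(n_trials):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub_a, sub_b = A[:, idx], B[:, idx]
        acc["rr_a"] += reference_range_rows(sub_a)
        acc["rr_b"] += reference_range_rows(sub_b)
        rho, p = rowwise_spearman(sub_a, sub_b)
        acc["rho"] += rho
        acc["p"] += np.log(np.maximum(p, 1e-300)) if p_average == "geometric" else p
    table = pd.DataFrame(
        {k: v / n_trials for k, v in acc.items()}, index=bundle.probe_ids
    )
    if p_average == "geometric":
        table["p"] = np.exp(table["p"])
    table.columns = ["mean_rr_a", "mean_rr_b", "mean_rho", "mean_p"]
    return SubsampleResult(table=table, n_trials=n_trials, n_sub=n_sub)
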