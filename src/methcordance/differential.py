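"""Differential methylation between matched tissues and cross-dataset consensus.

Per CpG, a paired two-sided Wilcoxon signed-rank test across matched
samples, with the effect size delta beta = mean(tissue_a) - mean(tissue_b).
Significance requires BH FDR <= 0.05 and |delta| >= 0.05 (inclusive at the
boundary). The consensus set keeps probes significant with the same delta
sign in every supplied dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, paired_signed_rank
from .data_io import BetaMatrix

__all__ = ["differential_scan", "consensus_differential", "table_from_subsample"]


def differential_scan(
    beta_a: BetaMatrix,
    beta_b: BetaMatrix,
    fdr: float = 0.05,
    min_delta: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG paired signed-rank test between two tissues of one dataset.

    Returns a table with mean beta per tissue, delta_beta (a - b), p, BH q,
    the significant flag (q <= fdr and |delta| >= min_delta), direction
    ('hyper_a' / 'hyper_b' / ''), and a degenerate flag for probes whose
    paired differences are all zero (p = 1 by convention).
    """
    if not beta_a.probe_ids.equals(beta_b.probe_ids):
        raise ValueError("probe sets must match")
    if not beta_a.sample_ids.equals(beta_b.sample_ids):
        raise ValueError("samples must be matched and ordered identically")
    A = beta_a.values.to_numpy(dtype=float)
    B = beta_b.values.to_numpy(dtype=float)
    stat, p = paired_signed_rank(A, B)
    degenerate = np.all(A == B, axis=1)
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)
    delta = mean_a - mean_b
    q = bh_adjust(p)
    significant = (q <= fdr) & (np.abs(delta) >= min_delta) & ~degenerate
    direction = np.where(significant, np.where(delta > 0, "hyper_a", "hyper_b"), "")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "wilcoxon_stat": stat,
            "wilcoxon_p": p,
            "q": q,
            "significant": significant,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=beta_a.probe_ids,
    )


def table_from_subsample(
    mean_p: pd.Series,
    mean_a: pd.Series,
    mean_b: pd.Series,
    fdr: float = 0.05,
    min_delta: float = 0.05,
) -> pd.DataFrame:
    """Differential table for a subsampled dataset summarised by trial-averaged
    p-values (the subsampling module's output), mirroring how an averaged
    dataset enters the consensus alongside fully observed cohorts."""
    delta = mean_a - mean_b
    q = pd.Series(bh_adjust(mean_p.to_numpy()), index=mean_p.index)
    significant = (q <= fdr) & (delta.abs() >= min_delta)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "wilcoxon_stat": np.nan,
            "wilcoxon_p": mean_p,
            "q": q,
            "significant": significant,
            "direction": np.where(significant, np.where(delta > 0, "hyper_a", "hyper_b"), ""),
            "degenerate": False,
        },
        index=mean_p.index,
    )


def consensus_differential(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Probes significant with the same delta sign in every dataset.

    All tables must cover the same probe set. Returns the consensus probes
    with their shared direction and per-dataset deltas.
    """
    if len(tables) < 2:
        raise ValueError("need at least two datasets for a consensus")
    index = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(index):
            raise ValueError("differential tables must share the probe set")
    sig = np.logical_and.reduce([t["significant"].to_numpy(dtype=bool) for t in tables])
    signs = np.stack([np.sign(t["delta_beta"].to_numpy(dtype=float)) for t in tables])
    same_sign = np.all(signs == signs[0], axis=0) & (signs[0] != 0)
    keep = sig & same_sign
    out = pd.DataFrame(
        {
            "direction": np.where(signs[0] > 0, "hyper_a", "hyper_b"),
            **{f"delta_{i}": t["delta_beta"] for i, t in enumerate(tables)},
        },
        index=index,
    )
    return out.loc[keep]
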