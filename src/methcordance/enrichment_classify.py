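"""Permutation enrichment tests and the final CpG categorization.

Overlap between probe sets is judged against a null of equal-sized uniform
random draws from a background set; feature enrichment compares a set's
composition over manifest annotation levels with the same null. Empirical
p-values use the add-one convention (1 + #{null as extreme}) / (n_perm + 1),
so they are never zero and the smallest attainable value at 10,000
permutations is just below 1e-4. The categorization assigns each background
probe one of eight labels from its informative / differential /
mQTL-associated flags, and overlap with user-supplied EWAS hit lists is
tabulated per category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .data_io import CpGManifest

__all__ = [
    "overlap_permutation_test",
    "feature_enrichment",
    "categorize",
    "tabulate_ewas_overlap",
    "PermutationResult",
    "CATEGORY_LABELS",
]

CATEGORY_LABELS = (
    "All",
    "Differential",
    "Informative",
    "Inform+Diff",
    "mQTL",
    "mQTL+Diff",
    "mQTL+Inform",
    "None",
)


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    fold_change: float
    p_value: float
    n_permutations: int
    direction: str  # "enriched" | "depleted"

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold_change": self.fold_change,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "direction": self.direction,
        }


def _as_index(s) -> pd.Index:
    return s if isinstance(s, pd.Index) else pd.Index(list(s))


def overlap_permutation_test(
    set_a,
    set_b,
    background,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Is the overlap of two probe sets larger (or smaller) than chance?

    Null: draw |set_a| probes uniformly without replacement from the
    background, count the overlap with set_b; repeat ``n_perm`` times.
    Two one-sided add-one p-values are computed and the smaller reported,
    labelled by direction. Deterministic given ``seed``.
    """
    bg = _as_index(background)
    a = _as_index(set_a)
    b = _as_index(set_b)
    if len(a) == 0 or len(b) == 0 or len(bg) == 0:
        raise ValueError("sets and background must be non-empty")
    if not a.isin(bg).all() or not b.isin(bg).all():
        raise ValueError("set_a and set_b must be subsets of the background")
    observed = len(a.intersection(b))
    rng = np.random.default_rng(seed)
    in_b = np.asarray(pd.Index(bg).isin(b), dtype=np.int64)
    n_bg, k = len(bg), len(a)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = in_b[rng.choice(n_bg, size=k, replace=False)].sum()
    return _summarise(observed, null, n_perm)


def _summarise(observed: float, null: np.ndarray, n_perm: int) -> PermutationResult:
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    p_hi = (1 + int((null >= observed).sum())) / (n_perm + 1)
    p_lo = (1 + int((null <= observed).sum())) / (n_perm + 1)
    if p_hi <= p_lo:
        p, direction = p_hi, "enriched"
    else:
        p, direction = p_lo, "depleted"
    fold = float(observed / null_mean) if null_mean > 0 else np.inf
    return PermutationResult(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold_change=fold,
        p_value=float(p),
        n_permutations=n_perm,
        direction=direction,
    )


def feature_enrichment(
    cpg_set,
    manifest: CpGManifest,
    feature_column: str,
    background,
    n_perm: int = 10_000,
    fdr: float = 0.05,
    seed: int = 0,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Per-feature-level enrichment of a probe set over a background.

    For each level of ``feature_column`` (e.g. gene_region or cgi_relation):
    observed count of set probes with that level, null distribution from
    |set|-sized uniform random background draws, fold change observed /
    null mean, two-direction empirical p, and BH q across levels.
    ``stratify_by`` optionally constrains null draws to preserve the set's
    composition over another annotation column.
    """
    bg = _as_index(background)
    cs = _as_index(cpg_set)
    if feature_column not in manifest.table.columns:
        raise ValueError(f"unknown feature column {feature_column!r}")
    if not cs.isin(bg).all():
        raise ValueError("cpg_set must be a subset of the background")
    feat = manifest.table.loc[bg, feature_column]
    levels = [lv for lv in pd.unique(feat)]
    codes = pd.Categorical(feat, categories=levels).codes
    set_mask = bg.isin(cs)
    observed = np.bincount(codes[set_mask], minlength=len(levels))

    rng = np.random.default_rng(seed)
    k, n_bg = len(cs), len(bg)
    if stratify_by is not None:
        strata = pd.Categorical(manifest.table.loc[bg, stratify_by]).codes
        strata_idx = [np.flatnonzero(strata == s) for s in range(strata.max() + 1)]
        set_strata = np.bincount(strata[set_mask], minlength=len(strata_idx))
    null = np.empty((n_perm, len(levels)), dtype=np.int64)
    for i in range(n_perm):
        if stratify_by is None:
            draw = rng.choice(n_bg, size=k, replace=False)
        else:
            draw = np.concatenate(
                [rng.choice(idx, size=m, replace=False) for idx, m in zip(strata_idx, set_strata) if m]
            )
        null[i] = np.bincount(codes[draw], minlength=len(levels))

    rows = []
    for j, lv in enumerate(levels):
        res = _summarise(observed[j], null[:, j], n_perm)
        rows.append(
            {
                "feature": lv,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "null_se": res.null_sd / np.sqrt(n_perm),
                "fold_change": res.fold_change,
                "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out


def categorize(informative_set, differential_set, mqtl_cpg_set, background) -> pd.DataFrame:
    """Eight-way CpG categorization from three boolean memberships.

    Labels: All (all three), mQTL+Inform, mQTL+Diff, mQTL (only),
    Inform+Diff, Informative (only), Differential (only), None.
    """
    bg = _as_index(background)
    for name, s in (
        ("informative_set", informative_set),
        ("differential_set", differential_set),
        ("mqtl_cpg_set", mqtl_cpg_set),
    ):
        if not _as_index(s).isin(bg).all():
            raise ValueError(f"{name} must be a subset of the background")
    inf = bg.isin(_as_index(informative_set))
    dif = bg.isin(_as_index(differential_set))
    mq = bg.isin(_as_index(mqtl_cpg_set))
    label = np.full(len(bg), "None", dtype=object)
    label[dif] = "Differential"
    label[inf] = "Informative"
    label[inf & dif] = "Inform+Diff"
    label[mq] = "mQTL"
    label[mq & dif] = "mQTL+Diff"
    label[mq & inf] = "mQTL+Inform"
    label[mq & inf & dif] = "All"
    return pd.DataFrame(
        {"informative": inf, "differential": dif, "mqtl_cpg": mq, "category": label},
        index=bg,
    )


def category_summary(categories: pd.DataFrame) -> pd.Series:
    """Counts per category label, in the canonical label order."""
    counts = categories["category"].value_counts()
    return counts.reindex(CATEGORY_LABELS, fill_value=0)


def tabulate_ewas_overlap(hit_list, categories: pd.DataFrame) -> pd.DataFrame:
    """Distribute an external hit list over the CpG categories.

    ``hit_list`` is any iterable of probe ids (e.g. significant CpGs from a
    published EWAS); ids absent from the background are counted under
    ``unmatched``. Returns per-category count and proportion of the matched
    hits.
    """
    hits = _as_index(hit_list)
    if len(hits) == 0:
        raise ValueError("hit list is empty")
    hits = hits.unique()
    matched = hits[hits.isin(categories.index)]
    unmatched = len(hits) - len(matched)
    counts = (
        categories.loc[matched, "category"].value_counts().reindex(CATEGORY_LABELS, fill_value=0)
    )
    total = max(len(matched), 1)
    out = pd.DataFrame({"count": counts, "proportion": counts / total})
    out.loc["unmatched"] = (unmatched, np.nan)
    return out
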