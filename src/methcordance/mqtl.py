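"""cis-mQTL discovery and validation.

A methylation quantitative trait locus (mQTL) is a SNP whose genotype
associates with DNAm at a CpG. Only *cis* effects are considered: SNP-CpG
pairs strictly less than 5 kb apart, a window that enriches for pairs
likely to be functionally linked. The scan is rank-based (Spearman rho of
beta on additive dosage, so invariant to how genotypes are numerically
coded), with the effect size reported as the OLS slope of beta on dosage —
the DNAm change per additional alternate allele, in beta units. Hits
require BH FDR <= 0.05 and |effect| >= 2.5% per allele. Discovery hits are
re-tested in an independent cohort (validation FDR computed over the
validation test set only); validated hits are classified as tissue-specific
or shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, hwe_exact_test, rowwise_spearman
from .data_io import BetaMatrix, CpGManifest, GenotypeMatrix, SNPManifest
from .variability import reference_range_rows

__all__ = [
    "snp_qc",
    "enumerate_cis_pairs",
    "scan",
    "validate",
    "classify_sharing",
    "SnpQCReport",
]

MQTL_COLUMNS = [
    "snp_id",
    "cpg_id",
    "distance",
    "tissue",
    "cohort",
    "n",
    "spearman_rho",
    "p",
    "q",
    "effect_per_allele",
    "hit",
    "stage",
]


_COLUMN_DTYPES = {
    "snp_id": object, "cpg_id": object, "distance": np.int64, "tissue": object,
    "cohort": object, "n": np.int64, "spearman_rho": float, "p": float,
    "q": float, "effect_per_allele": float, "hit": bool, "stage": object,
}


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=d) for c, d in _COLUMN_DTYPES.items()})


@dataclass
class SnpQCReport:
    """Per-SNP QC metrics and pass/fail with the first failing reason."""

    table: pd.DataFrame  # columns: missing_frac, maf, hwe_p, passed, reason

    @property
    def passed_ids(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


def snp_qc(
    geno: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    hwe_p: float = 1e-3,
) -> tuple[GenotypeMatrix, SnpQCReport]:
    """Filter SNPs by missingness, minor allele frequency, and HWE.

    Rules, in order: missing calls in more than ``max_missing`` of samples;
    MAF below ``min_maf``; Hardy-Weinberg exact-test p below ``hwe_p``.
    """
    D = geno.dosage.to_numpy(dtype=float)
    n_samp = D.shape[1]
    miss = np.isnan(D).sum(axis=1) / n_samp
    n_bb = np.nansum(D == 2, axis=1)
    n_ab = np.nansum(D == 1, axis=1)
    n_called = (~np.isnan(D)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = (2 * n_bb + n_ab) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(freq_b, 1 - freq_b)
    hwe = np.array(
        [
            hwe_exact_test(int(nc - nab - nbb), int(nab), int(nbb))
            for nc, nab, nbb in zip(n_called, n_ab, n_bb)
        ]
    )
    reason = np.full(len(D), "", dtype=object)
    reason[np.where((reason == "") & (miss > max_missing))[0]] = "missingness"
    reason[np.where((reason == "") & (maf < min_maf))[0]] = "maf"
    reason[np.where((reason == "") & (hwe < hwe_p))[0]] = "hwe"
    passed = reason == ""
    report = SnpQCReport(
        pd.DataFrame(
            {
                "missing_frac": miss,
                "maf": maf,
                "hwe_p": hwe,
                "passed": passed,
                "reason": reason,
            },
            index=geno.snp_ids,
        )
    )
    kept = geno.select_snps(list(geno.snp_ids[passed]))
    return kept, report


def enumerate_cis_pairs(
    cpg_manifest: CpGManifest,
    snp_manifest: SNPManifest,
    window: int = 5000,
) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with |pos_snp - pos_cpg| < window.

    Strict inequality: a pair exactly ``window`` bp apart is not cis.
    Returns columns snp_id, cpg_id, distance.
    """
    out = []
    cpg = cpg_manifest.table
    snp = snp_manifest.table
    for chrom, snps_c in snp.groupby("chromosome", sort=False):
        cpgs_c = cpg[cpg["chromosome"] == chrom]
        if cpgs_c.empty:
            continue
        cpos = cpgs_c["position"].to_numpy()
        order = np.argsort(cpos)
        cpos_sorted = cpos[order]
        cids = cpgs_c.index.to_numpy()[order]
        for sid, spos in zip(snps_c.index, snps_c["position"].to_numpy()):
            lo = np.searchsorted(cpos_sorted, spos - window + 1, side="left")
            hi = np.searchsorted(cpos_sorted, spos + window - 1, side="right")
            for j in range(lo, hi):
                out.append((sid, cids[j], int(abs(spos - cpos_sorted[j]))))
    return pd.DataFrame(out, columns=["snp_id", "cpg_id", "distance"])


def _ols_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise OLS slope of Y on X for paired (m, n) arrays (NaN-free)."""
    xm = X - X.mean(axis=1, keepdims=True)
    ym = Y - Y.mean(axis=1, keepdims=True)
    denom = (xm**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (xm * ym).sum(axis=1) / denom, np.nan)


def scan(
    beta: BetaMatrix,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    min_rr: float = 0.05,
    fdr: float = 0.05,
    min_effect: float = 0.025,
    min_samples: int = 10,
    tissue: str = "",
    cohort: str = "",
    stage: str = "discovery",
    effect_estimator: str = "ols",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test candidate cis pairs in one tissue of one cohort.

    CpGs with reference range < ``min_rr`` are excluded before testing.
    Per remaining pair, Spearman rho and p between beta and dosage over
    samples with a genotype call, and the per-allele effect (OLS slope of
    beta on dosage by default; ``effect_estimator='homozygote_half'``
    reports half the BB-minus-AA group-mean difference instead). BH FDR is
    computed over all tested pairs in this tissue; hits satisfy
    q <= ``fdr`` and |effect| >= ``min_effect``.

    Returns (records, untested) — ``untested`` lists pairs skipped with a
    reason (low_rr, monomorphic, too_few_samples, missing_id).
    """
    if effect_estimator not in ("ols", "homozygote_half"):
        raise ValueError("effect_estimator must be 'ols' or 'homozygote_half'")
    samples = beta.sample_ids.intersection(geno.sample_ids)
    if len(samples) < min_samples:
        raise ValueError("too few samples shared between beta and genotype matrices")
    B = beta.values.loc[:, samples]
    G = geno.dosage.loc[:, samples]
    rr = pd.Series(reference_range_rows(B), index=B.index)

    tested_rows: list[tuple] = []
    untested: list[tuple] = []
    xs, ys = [], []
    n_eff = []
    for snp_id, cpg_id, dist in pairs[["snp_id", "cpg_id", "distance"]].itertuples(index=False):
        if cpg_id not in B.index or snp_id not in G.index:
            untested.append((snp_id, cpg_id, "missing_id"))
            continue
        if rr.loc[cpg_id] < min_rr:
            untested.append((snp_id, cpg_id, "low_rr"))
            continue
        x = G.loc[snp_id].to_numpy(dtype=float)
        y = B.loc[cpg_id].to_numpy(dtype=float)
        keep = ~np.isnan(x) & ~np.isnan(y)
        if keep.sum() < min_samples:
            untested.append((snp_id, cpg_id, "too_few_samples"))
            continue
        if np.ptp(x[keep]) == 0:
            untested.append((snp_id, cpg_id, "monomorphic"))
            continue
        tested_rows.append((snp_id, cpg_id, dist))
        n = int(keep.sum())
        n_eff.append(n)
        xs.append(x[keep])
        ys.append(y[keep])

    if not tested_rows:
        return _empty_records(), pd.DataFrame(untested, columns=["snp_id", "cpg_id", "reason"])

    # group by effective n so each block is rectangular for the vectorised tests
    n_eff_arr = np.array(n_eff)
    rho = np.empty(len(xs))
    pval = np.empty(len(xs))
    slope = np.empty(len(xs))
    for n in np.unique(n_eff_arr):
        idx = np.flatnonzero(n_eff_arr == n)
        X = np.vstack([xs[i] for i in idx])
        Y = np.vstack([ys[i] for i in idx])
        r, p = rowwise_spearman(Y, X)
        rho[idx], pval[idx] = r, p
        if effect_estimator == "ols":
            slope[idx] = _ols_slopes(X, Y)
        else:
            for k, i in enumerate(idx):
                x, y = X[k], Y[k]
                m0 = y[x == 0].mean() if (x == 0).any() else np.nan
                m2 = y[x == 2].mean() if (x == 2).any() else np.nan
                slope[i] = (m2 - m0) / 2.0 if np.isfinite(m0) and np.isfinite(m2) else _ols_slopes(x[None], y[None])[0]

    q = bh_adjust(pval)
    records = pd.DataFrame(tested_rows, columns=["snp_id", "cpg_id", "distance"])
    records["tissue"] = tissue or beta.tissue
    records["cohort"] = cohort or beta.cohort
    records["n"] = n_eff_arr
    records["spearman_rho"] = rho
    records["p"] = pval
    records["q"] = q
    records["effect_per_allele"] = slope
    records["hit"] = (q <= fdr) & (np.abs(slope) >= min_effect)
    records["stage"] = stage
    return records[MQTL_COLUMNS], pd.DataFrame(untested, columns=["snp_id", "cpg_id", "reason"])


def validate(
    discovery_hits: pd.DataFrame,
    beta: BetaMatrix,
    geno: GenotypeMatrix,
    min_het: int = 2,
    min_rr: float = 0.05,
    fdr: float = 0.05,
    min_effect: float = 0.025,
    tissue: str = "",
    cohort: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-test discovery hits in an independent validation cohort.

    Pairs whose SNP is absent from the validation genotypes, monomorphic, or
    carries fewer than ``min_het`` heterozygotes are untestable and excluded
    before FDR, which is computed over validation tests only.

    Returns (validated records with stage='validated', testability report).
    """
    hits = discovery_hits[discovery_hits["hit"]] if "hit" in discovery_hits else discovery_hits
    testable = []
    report_rows = []
    G = geno.dosage
    for snp_id, cpg_id, dist in hits[["snp_id", "cpg_id", "distance"]].itertuples(index=False):
        if snp_id not in G.index or cpg_id not in beta.probe_ids:
            report_rows.append((snp_id, cpg_id, False, "absent"))
            continue
        x = G.loc[snp_id].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0 or np.ptp(x) == 0:
            report_rows.append((snp_id, cpg_id, False, "monomorphic"))
            continue
        if int((x == 1).sum()) < min_het:
            report_rows.append((snp_id, cpg_id, False, "too_few_heterozygotes"))
            continue
        testable.append((snp_id, cpg_id, dist))
        report_rows.append((snp_id, cpg_id, True, ""))
    report = pd.DataFrame(report_rows, columns=["snp_id", "cpg_id", "testable", "reason"])
    if not testable:
        return _empty_records(), report
    pairs = pd.DataFrame(testable, columns=["snp_id", "cpg_id", "distance"])
    records, untested = scan(
        beta,
        geno,
        pairs,
        min_rr=min_rr,
        fdr=fdr,
        min_effect=min_effect,
        tissue=tissue,
        cohort=cohort,
        stage="validated",
    )
    if len(untested):
        untested = untested.assign(testable=False)
        report = pd.concat(
            [report[~report.set_index(["snp_id", "cpg_id"]).index.isin(
                untested.set_index(["snp_id", "cpg_id"]).index)],
             untested[["snp_id", "cpg_id", "testable", "reason"]]],
            ignore_index=True,
        )
    return records, report


def classify_sharing(
    validated_by_tissue: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Label each validated pair shared or tissue-specific.

    A pair is *shared* when it is a validated hit in both tissues; a pair
    validated in exactly one tissue is specific to it (including pairs that
    were untested or non-significant in the other tissue).
    """
    if len(validated_by_tissue) != 2:
        raise ValueError("expected exactly two tissues")
    (t1, rec1), (t2, rec2) = validated_by_tissue.items()
    hits1 = set(map(tuple, rec1.loc[rec1["hit"], ["snp_id", "cpg_id"]].to_numpy()))
    hits2 = set(map(tuple, rec2.loc[rec2["hit"], ["snp_id", "cpg_id"]].to_numpy()))
    rows = []
    for pair in sorted(hits1 | hits2):
        if pair in hits1 and pair in hits2:
            label = "shared"
        elif pair in hits1:
            label = f"{t1}_specific"
        else:
            label = f"{t2}_specific"
        rows.append((*pair, label))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "sharing"])
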