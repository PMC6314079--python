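import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from methcordance.data_io import BetaMatrix, CpGManifest, GenotypeMatrix, SNPManifest
from methcordance.mqtl import (
    classify_sharing,
    enumerate_cis_pairs,
    scan,
    snp_qc,
    validate,
)
from methcordance._stats import hwe_exact_test
from conftest import make_beta


def geno_from(rows, samples=None):
    arr = np.asarray(rows, dtype=float)
    return GenotypeMatrix(
        pd.DataFrame(
            arr,
            index=[f"rs{i:04d}" for i in range(arr.shape[0])],
            columns=samples or [f"s{j:03d}" for j in range(arr.shape[1])],
        )
    )


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent oracle: enumerate every genotype configuration with the
    observed allele counts and sum probabilities <= P(observed)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def log_prob(h):
        aa = (n_a - h) // 2
        bb = n - aa - h
        return (
            h * np.log(2)
            + gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(2 * n - n_a + 1))
        )

    hs = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0 and n - (n_a - h) // 2 - h >= 0]
    probs = {h: np.exp(log_prob(h)) for h in hs}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestSnpQC:
    def test_monomorphic_fails_maf(self):
        geno = geno_from([np.zeros(40)])
        _, report = snp_qc(geno)
        assert not report.table["passed"].iloc[0]
        assert report.table["reason"].iloc[0] == "maf"

    def test_perfect_hwe_passes(self):
        dosage = np.array([0] * 25 + [1] * 50 + [2] * 25)
        _, report = snp_qc(geno_from([dosage]))
        assert report.table["passed"].iloc[0]
        assert report.table["hwe_p"].iloc[0] == pytest.approx(1.0, abs=0.2)

    def test_all_het_fails_hwe(self):
        dosage = np.ones(40)
        _, report = snp_qc(geno_from([dosage]))
        assert report.table["reason"].iloc[0] == "hwe"
        assert report.table["hwe_p"].iloc[0] < 1e-3

    def test_missingness_rule(self):
        dosage = np.array([0, 1, 2, 1] * 10, dtype=float)
        dosage[:3] = np.nan  # 7.5% missing
        _, report = snp_qc(geno_from([dosage]))
        assert report.table["reason"].iloc[0] == "missingness"

    @pytest.mark.parametrize(
        "counts",
        [(10, 20, 10), (0, 40, 0), (25, 50, 25), (30, 5, 5), (12, 2, 26), (5, 0, 5)],
    )
    def test_hwe_exact_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_simulated_violators_filtered(self, small_sim):
        _, bundles, truth = small_sim
        _, report = snp_qc(bundles[0].genotypes)
        violators = truth.snps.index[truth.snps["hwe_violator"]]
        assert len(violators) > 0
        assert (report.table.loc[violators, "reason"] == "hwe").all()


class TestCisPairs:
    def _manifests(self, cpgs, snps):
        cm = CpGManifest(
            pd.DataFrame(
                {
                    "chromosome": [c for c, _ in cpgs],
                    "position": [p for _, p in cpgs],
                    "gene_region": "intergenic",
                    "cgi_relation": "open_sea",
                    "flag_sex": False,
                    "flag_polymorphic": False,
                    "flag_cross_hybridizing": False,
                },
                index=[f"cg{i}" for i in range(len(cpgs))],
            )
        )
        sm = SNPManifest(
            pd.DataFrame(
                {
                    "chromosome": [c for c, _ in snps],
                    "position": [p for _, p in snps],
                    "allele_a": "A",
                    "allele_b": "B",
                },
                index=[f"rs{i}" for i in range(len(snps))],
            )
        )
        return cm, sm

    def test_window_boundary_strict(self):
        cm, sm = self._manifests(
            cpgs=[("chr1", 5999), ("chr1", 6000)], snps=[("chr1", 1000)]
        )
        pairs = enumerate_cis_pairs(cm, sm, window=5000)
        assert pairs[["snp_id", "cpg_id"]].to_numpy().tolist() == [["rs0", "cg0"]]
        assert pairs["distance"].iloc[0] == 4999

    def test_cross_chromosome_never_paired(self):
        cm, sm = self._manifests(cpgs=[("chr2", 1000)], snps=[("chr1", 1000)])
        assert len(enumerate_cis_pairs(cm, sm)) == 0

    def test_matches_brute_force(self, rng):
        cpgs = [(f"chr{rng.integers(1, 3)}", int(rng.integers(1, 100_000))) for _ in range(500)]
        snps = [(f"chr{rng.integers(1, 3)}", int(rng.integers(1, 100_000))) for _ in range(200)]
        cm, sm = self._manifests(cpgs, snps)
        pairs = enumerate_cis_pairs(cm, sm, window=5000)
        got = set(map(tuple, pairs[["snp_id", "cpg_id", "distance"]].to_numpy()))
        expected = set()
        for (sid, srow), (cid, crow) in itertools.product(
            sm.table.iterrows(), cm.table.iterrows()
        ):
            if srow["chromosome"] == crow["chromosome"] and abs(srow["position"] - crow["position"]) < 5000:
                expected.add((sid, cid, abs(srow["position"] - crow["position"])))
        assert got == expected


def _scan_inputs(rng, n_pairs=20, n=60, effect=0.0, maf=0.3, noise=0.05):
    dosage = rng.binomial(2, maf, size=(n_pairs, n)).astype(float)
    beta = np.clip(0.3 + effect * dosage + rng.normal(0, noise, (n_pairs, n)), 0, 1)
    bm = make_beta(beta)
    gm = GenotypeMatrix(
        pd.DataFrame(dosage, index=[f"rs{i:04d}" for i in range(n_pairs)],
                     columns=bm.sample_ids)
    )
    pairs = pd.DataFrame(
        {"snp_id": gm.snp_ids, "cpg_id": bm.probe_ids, "distance": 100}
    )
    return bm, gm, pairs


class TestScan:
    def test_exact_slope_on_balanced_groups(self):
        dosage = np.array([0.0] * 10 + [1.0] * 10 + [2.0] * 10)
        beta = np.where(dosage == 0, 0.20, np.where(dosage == 1, 0.25, 0.30))
        bm = make_beta(beta[None, :])
        gm = geno_from([dosage], samples=list(bm.sample_ids))
        pairs = pd.DataFrame({"snp_id": ["rs0000"], "cpg_id": ["cg0000"], "distance": [10]})
        rec, untested = scan(bm, gm, pairs, min_rr=0.05)
        assert len(untested) == 0
        assert rec["effect_per_allele"].iloc[0] == pytest.approx(0.05, abs=1e-12)
        assert bool(rec["hit"].iloc[0])

    def test_dosage_recode_invariance(self, rng):
        """Spearman rho is identical whether genotypes are coded 0/1/2 or 1/2/3."""
        bm, gm, pairs = _scan_inputs(rng, effect=0.05)
        from methcordance._stats import rowwise_spearman

        rec1, _ = scan(bm, gm, pairs)
        shifted = gm.dosage.to_numpy() + 1.0  # 1/2/3 coding
        rho2, _ = rowwise_spearman(bm.values.to_numpy(), shifted)
        assert np.allclose(rec1["spearman_rho"].to_numpy(), rho2)

    def test_matches_per_pair_scipy_recomputation(self, rng):
        bm, gm, pairs = _scan_inputs(rng, n_pairs=50, effect=0.03)
        rec, _ = scan(bm, gm, pairs, min_rr=0.0)
        for _, row in rec.iterrows():
            x = gm.dosage.loc[row["snp_id"]].to_numpy()
            y = bm.values.loc[row["cpg_id"]].to_numpy()
            ref = stats.spearmanr(x, y)
            slope = stats.linregress(x, y).slope
            assert row["spearman_rho"] == pytest.approx(ref.statistic, abs=1e-12)
            assert row["p"] == pytest.approx(ref.pvalue, rel=1e-9)
            assert row["effect_per_allele"] == pytest.approx(slope, abs=1e-12)

    def test_low_rr_probes_excluded(self, rng):
        bm, gm, pairs = _scan_inputs(rng, noise=0.001, effect=0.0)
        rec, untested = scan(bm, gm, pairs, min_rr=0.05)
        assert len(rec) == 0
        assert (untested["reason"] == "low_rr").all()

    def test_monomorphic_recorded(self, rng):
        bm, gm, pairs = _scan_inputs(rng, effect=0.05)
        gm.dosage.iloc[0, :] = 1.0
        rec, untested = scan(bm, gm, pairs)
        assert ("rs0000", "cg0000", "monomorphic") in set(map(tuple, untested.to_numpy()))

    def test_tightening_thresholds_never_adds_hits(self, rng):
        bm, gm, pairs = _scan_inputs(rng, n_pairs=80, effect=0.04, noise=0.04)
        base, _ = scan(bm, gm, pairs, fdr=0.05, min_effect=0.025, min_rr=0.05)
        base_hits = set(map(tuple, base.loc[base["hit"], ["snp_id", "cpg_id"]].to_numpy()))
        for kwargs in ({"fdr": 0.01}, {"min_effect": 0.05}, {"min_rr": 0.1}):
            rec, _ = scan(bm, gm, pairs, **{"fdr": 0.05, "min_effect": 0.025, "min_rr": 0.05, **kwargs})
            hits = set(map(tuple, rec.loc[rec["hit"], ["snp_id", "cpg_id"]].to_numpy()))
            assert hits <= base_hits

    def test_homozygote_half_estimator(self):
        dosage = np.array([0.0] * 8 + [1.0] * 4 + [2.0] * 8)
        beta = np.where(dosage == 0, 0.2, np.where(dosage == 1, 0.32, 0.4))
        bm = make_beta(beta[None, :])
        gm = geno_from([dosage], samples=list(bm.sample_ids))
        pairs = pd.DataFrame({"snp_id": ["rs0000"], "cpg_id": ["cg0000"], "distance": [10]})
        rec, _ = scan(bm, gm, pairs, effect_estimator="homozygote_half")
        assert rec["effect_per_allele"].iloc[0] == pytest.approx(0.1, abs=1e-12)


class TestValidate:
    def _discovery(self):
        return pd.DataFrame(
            {
                "snp_id": ["rs0000", "rs0001"],
                "cpg_id": ["cg0000", "cg0001"],
                "distance": [10, 10],
                "hit": [True, True],
            }
        )

    def test_monomorphic_snp_untestable(self, rng):
        bm = make_beta(rng.uniform(0.2, 0.8, (2, 16)))
        gm = geno_from(
            [np.zeros(16), rng.binomial(2, 0.4, 16)], samples=list(bm.sample_ids)
        )
        rec, report = validate(self._discovery(), bm, gm)
        r0 = report[report["snp_id"] == "rs0000"].iloc[0]
        assert not r0["testable"] and r0["reason"] == "monomorphic"
        assert set(rec["snp_id"]) <= {"rs0001"}

    def test_single_heterozygote_untestable(self, rng):
        bm = make_beta(rng.uniform(0.2, 0.8, (2, 16)))
        g0 = np.zeros(16); g0[0] = 1.0  # one heterozygote only
        gm = geno_from([g0, rng.binomial(2, 0.4, 16)], samples=list(bm.sample_ids))
        _, report = validate(self._discovery(), bm, gm)
        r0 = report[report["snp_id"] == "rs0000"].iloc[0]
        assert not r0["testable"] and r0["reason"] == "too_few_heterozygotes"

    def test_absent_snp_untestable(self, rng):
        bm = make_beta(rng.uniform(0.2, 0.8, (2, 16)))
        gm = geno_from([rng.binomial(2, 0.4, 16)], samples=list(bm.sample_ids))
        gm = GenotypeMatrix(gm.dosage.rename(index={"rs0000": "rs0001"}))
        disc = self._discovery().iloc[:1]  # rs0000 only
        rec, report = validate(disc, bm, gm)
        assert len(rec) == 0
        assert report["reason"].iloc[0] == "absent"


class TestSharing:
    def _rec(self, pairs_hit):
        return pd.DataFrame(
            {
                "snp_id": [p[0] for p in pairs_hit],
                "cpg_id": [p[1] for p in pairs_hit],
                "hit": True,
            }
        )

    def test_shared_and_specific(self):
        out = classify_sharing(
            {"BEC": self._rec([("rs1", "cg1"), ("rs2", "cg2")]),
             "PBMC": self._rec([("rs1", "cg1"), ("rs3", "cg3")])}
        )
        labels = dict(zip(zip(out["snp_id"], out["cpg_id"]), out["sharing"]))
        assert labels[("rs1", "cg1")] == "shared"
        assert labels[("rs2", "cg2")] == "BEC_specific"
        assert labels[("rs3", "cg3")] == "PBMC_specific"

    def test_shared_fraction_recovered(self):
        """Planted shared/tissue-specific mQTL mix: recovered shared fraction
        tracks the planted proportion."""
        from methcordance import SimConfig, simulate_cohorts

        cfg = SimConfig(
            n_cpgs=1500, n_snps=400, cohort_sizes=[79, 60], seed=33,
            frac_mqtl_bec=0.08, frac_mqtl_pbmc=0.08, frac_mqtl_shared=0.04,
            effect_per_allele_range=(0.08, 0.15),
            sd_indiv_bec=0.15, sd_indiv_pbmc=0.12, sd_noise=0.05, sd_cell_effect=0.02,
        )
        bundles, truth = simulate_cohorts(cfg)
        disc, val = bundles
        pairs = enumerate_cis_pairs(disc.cpg_manifest, disc.snp_manifest)
        validated = {}
        for attr, tissue in (("beta_a", "BEC"), ("beta_b", "PBMC")):
            rec, _ = scan(getattr(disc, attr), disc.genotypes, pairs, tissue=tissue)
            vrec, _ = validate(rec[rec["hit"]], getattr(val, attr), val.genotypes, tissue=tissue)
            validated[tissue] = vrec
        sharing = classify_sharing(validated)
        assert len(sharing) > 100
        shared_frac = (sharing["sharing"] == "shared").mean()
        planted = 0.04 / 0.20  # shared fraction among planted mQTL
        assert shared_frac == pytest.approx(planted, abs=0.05)
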