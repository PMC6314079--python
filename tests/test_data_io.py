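import numpy as np
import pandas as pd
import pytest

from methcordance.data_io import (
    BetaMatrix,
    CohortBundle,
    CpGManifest,
    GenotypeMatrix,
    ParseError,
    intersect_probes,
    manifest_to_bed,
    qc_filter_probes,
    read_beta,
    read_genotypes,
    read_manifest,
    read_vcf_genotypes,
    write_beta,
    write_genotypes,
    write_manifest,
)
from methcordance.simulate import simulate_cohorts

from conftest import make_beta


def toy_manifest(n, flags_sex=()):
    return CpGManifest(
        pd.DataFrame(
            {
                "chromosome": ["chr1"] * n,
                "position": np.arange(1, n + 1) * 100,
                "gene_region": ["promoter"] * n,
                "cgi_relation": ["island"] * n,
                "flag_sex": [i in flags_sex for i in range(n)],
                "flag_polymorphic": [False] * n,
                "flag_cross_hybridizing": [False] * n,
            },
            index=[f"cg{i:04d}" for i in range(n)],
        )
    )


class TestReadWrite:
    def test_toy_beta_shape(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("probe\ts1\ts2\ncgA\t0.1\t0.2\ncgB\t0.3\t0.4\ncgC\t0.5\tNA\n")
        beta = read_beta(path)
        assert beta.shape == (3, 2)
        assert np.isnan(beta.values.loc["cgC", "s2"])

    def test_beta_round_trip(self, tmp_path, rng):
        beta = make_beta(rng.random((50, 7)))
        write_beta(beta, tmp_path / "b.tsv")
        back = read_beta(tmp_path / "b.tsv")
        assert np.abs(back.values.to_numpy() - beta.values.to_numpy()).max() < 1e-10
        assert list(back.probe_ids) == list(beta.probe_ids)

    def test_genotype_round_trip_and_missing(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("snp\ts1\ts2\ts3\nrs1\t0\t1\t2\nrs2\tNA\t2\t0\n")
        geno = read_genotypes(path)
        assert geno.missing_mask.sum() == 1
        assert geno.dosage.loc["rs1"].tolist() == [0.0, 1.0, 2.0]
        write_genotypes(geno, tmp_path / "g2.tsv")
        again = read_genotypes(tmp_path / "g2.tsv")
        pd.testing.assert_frame_equal(again.dosage, geno.dosage)

    def test_genotype_letter_calls(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("snp\ts1\ts2\ts3\nrs1\tAA\tAB\tBB\n")
        geno = read_genotypes(path)
        assert geno.dosage.loc["rs1"].tolist() == [0.0, 1.0, 2.0]

    def test_unknown_dosage_symbol(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("snp\ts1\nrs1\tXY\n")
        with pytest.raises(ParseError, match="row 2"):
            read_genotypes(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("probe\ts1\ncgA\t0.1\ncgA\t0.2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_beta(path)

    def test_out_of_range_beta_rejected(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("probe\ts1\ncgA\t1.5\n")
        with pytest.raises(ParseError):
            read_beta(path)

    def test_manifest_round_trip_and_bed(self, tmp_path):
        m = toy_manifest(4, flags_sex=(1,))
        write_manifest(m, tmp_path / "m.tsv")
        back = read_manifest(tmp_path / "m.tsv", "cpg")
        assert back.table["flag_sex"].tolist() == m.table["flag_sex"].tolist()
        manifest_to_bed(back, tmp_path / "m.bed")
        bed = pd.read_csv(tmp_path / "m.bed", sep="\t", header=None)
        # 1-based inclusive -> 0-based half-open
        assert (bed[1] == m.table["position"].to_numpy() - 1).all()
        assert (bed[2] == m.table["position"].to_numpy()).all()

    def test_vcf_ingest_matches_dosage(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
            "chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|1\t./.\n"
        )
        geno, manifest = read_vcf_genotypes(vcf)
        assert geno.dosage.loc["rs1"].tolist() == [0.0, 1.0]
        assert geno.dosage.loc["rs2", "s1"] == 2.0
        assert np.isnan(geno.dosage.loc["rs2", "s2"])
        assert manifest.table.loc["rs2", "position"] == 200


class TestQC:
    def _bundle(self, n=10, n_samples=50):
        rng = np.random.default_rng(0)
        vals_a = rng.uniform(0.2, 0.8, (n, n_samples))
        vals_b = rng.uniform(0.2, 0.8, (n, n_samples))
        beta_a = make_beta(vals_a, tissue="BEC")
        beta_b = make_beta(vals_b, tissue="PBMC")
        det = pd.DataFrame(
            np.zeros((n, n_samples)), index=beta_a.probe_ids, columns=beta_a.sample_ids
        )
        return CohortBundle(
            name="toy", beta_a=beta_a, beta_b=beta_b,
            cpg_manifest=toy_manifest(n), detection_p=det,
        )

    def test_hand_counted_toy(self):
        """1 sex-flagged + 1 detection-p fail + 1 missingness fail out of 10 -> 7 survive."""
        b = self._bundle()
        b.cpg_manifest.table.loc["cg0000", "flag_sex"] = True
        b.detection_p.iloc[1, :3] = 0.02  # 3/50 = 6% of samples above 0.01
        b.beta_a.values.iloc[2, :2] = np.nan  # 4% missing
        out, report = qc_filter_probes(b)
        assert report.as_dict() == {
            "n_input": 10,
            "removed_flagged": 1,
            "removed_detection_p": 1,
            "removed_missingness": 1,
            "n_output": 7,
        }
        assert len(out.probe_ids) == 7
        assert "cg0000" not in out.probe_ids

    def test_clean_bundle_identity(self):
        b = self._bundle()
        out, report = qc_filter_probes(b)
        assert list(out.probe_ids) == list(b.probe_ids)
        assert report.n_output == report.n_input

    def test_failure_in_either_tissue_removes_from_both(self):
        b = self._bundle()
        b.beta_b.values.iloc[4, :5] = np.nan  # fails only in tissue b
        out, _ = qc_filter_probes(b)
        assert "cg0004" not in out.beta_a.probe_ids
        assert "cg0004" not in out.beta_b.probe_ids

    def test_idempotent(self):
        b = self._bundle()
        b.cpg_manifest.table.loc["cg0003", "flag_polymorphic"] = True
        once, _ = qc_filter_probes(b)
        twice, rep2 = qc_filter_probes(once)
        assert list(twice.probe_ids) == list(once.probe_ids)
        assert rep2.n_input == rep2.n_output

    def test_probe_order_preserved(self):
        b = self._bundle()
        b.cpg_manifest.table.loc["cg0005", "flag_sex"] = True
        out, _ = qc_filter_probes(b)
        kept = [p for p in b.probe_ids if p != "cg0005"]
        assert list(out.probe_ids) == kept


class TestIntersect:
    def _bundle_with(self, probes):
        n = len(probes)
        vals = np.full((n, 6), 0.5)
        beta = BetaMatrix(
            pd.DataFrame(vals, index=probes, columns=[f"s{j}" for j in range(6)])
        )
        return CohortBundle(name="x", beta_a=beta, beta_b=beta)

    def test_basic_intersection(self):
        b1 = self._bundle_with(["a", "b", "c"])
        b2 = self._bundle_with(["b", "c", "d"])
        out = intersect_probes([b1, b2])
        assert list(out[0].probe_ids) == ["b", "c"]
        assert list(out[1].probe_ids) == ["b", "c"]

    def test_identical_sets_identity(self):
        b1 = self._bundle_with(["a", "b", "c"])
        b2 = self._bundle_with(["a", "b", "c"])
        out = intersect_probes([b1, b2])
        assert list(out[0].probe_ids) == ["a", "b", "c"]

    def test_matches_set_oracle(self, rng):
        universe = [f"p{i}" for i in range(60)]
        sets = [sorted(rng.choice(universe, size=40, replace=False)) for _ in range(3)]
        bundles = [self._bundle_with(s) for s in sets]
        out = intersect_probes(bundles)
        expected = set(sets[0]) & set(sets[1]) & set(sets[2])
        assert set(out[0].probe_ids) == expected
        assert set(out[2].probe_ids) == expected

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            intersect_probes([self._bundle_with(["a"]), self._bundle_with(["b"])])


def test_dosage_matrix_rejects_bad_values():
    with pytest.raises(ParseError):
        GenotypeMatrix(pd.DataFrame({"s1": [3.0]}, index=["rs1"]))
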