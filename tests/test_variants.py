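"""Variant scoring: pairs, overlap, the empirical null, outlier calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peakvar.seqdata import GenomicInterval, Peak
from peakvar.variants import (
    NullModel,
    VariantRecord,
    build_null,
    build_variant_pair,
    gaussian_mass_within,
    laplace_scale_equivalent,
    load_variants,
    normality_diagnostics,
    normalize_and_call,
    overlap_filter,
    sample_background_variants,
    score_variant,
    score_variants,
    two_sided_gaussian_p,
    validate_against_genome,
)


class TestVariantRecord:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            VariantRecord("chr1", 100, "A", "A")

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 100, "AT", "A")

    def test_position_conversion(self):
        assert VariantRecord("chr1", 100, "A", "G").pos0 == 99


class TestBuildVariantPair:
    def test_window_and_index_1000(self, tiny_genome):
        ref = tiny_genome["chrX"][999]
        alt = "A" if ref != "A" else "C"
        pair = build_variant_pair(VariantRecord("chrX", 1000, ref, alt),
                                  tiny_genome, 1000)
        assert pair.variant_index == 499
        diff = np.argwhere(pair.ref_onehot != pair.alt_onehot)
        assert set(diff[:, 0]) == {499}

    def test_window_index_500(self, tiny_genome):
        ref = tiny_genome["chrX"][999]
        alt = "G" if ref != "G" else "T"
        pair = build_variant_pair(VariantRecord("chrX", 1000, ref, alt),
                                  tiny_genome, 500)
        assert pair.variant_index == 249
        assert pair.ref_onehot.shape == (500, 4)

    def test_ref_mismatch_names_position(self, tiny_genome):
        ref = tiny_genome["chrX"][999]
        wrong = "C" if ref != "C" else "G"
        alt = "T" if wrong != "T" and ref != "T" else "A"
        with pytest.raises(ValueError, match="chrX:1000"):
            build_variant_pair(VariantRecord("chrX", 1000, wrong, alt),
                               tiny_genome, 500)


class TestScoreVariant:
    def test_constant_model_gives_zero_delta(self, tiny_genome):
        from peakvar.models import ModelSpec, build_model

        spec = ModelSpec("regression", 80, ((4, 8, 1),), (73, 73), 0.0, 0,
                         "none")
        net = build_model(spec, seed=0)
        net.layers[-1].W[...] = 0.0

        class R:
            def __init__(self):
                self.spec = spec
                self.network = net

            def predict(self, X, batch_size=256):
                return net.forward(np.asarray(X, dtype=float)).ravel()

        results = R()
        ref = tiny_genome["chrX"][200]
        alt = "A" if ref != "A" else "C"
        pair = build_variant_pair(VariantRecord("chrX", 201, ref, alt),
                                  tiny_genome, 80)
        assert score_variant(results, pair) == 0.0

    def test_antisymmetry_under_allele_swap(self, tiny_regression,
                                            small_synth):
        variants = small_synth.disease_variants[:20]
        genome = small_synth.genome
        deltas = score_variants(tiny_regression, variants, genome, 80)
        swapped = [VariantRecord(v.chrom, v.pos, v.alt, v.ref, v.id)
                   for v in variants]
        # swapped ref/alt: windows swap roles exactly, so deltas negate —
        # up to the genome check, so substitute manually via pairs
        from peakvar.variants import SequencePair, score_pairs

        pairs = [build_variant_pair(v, genome, 80) for v in variants]
        rev = [SequencePair(p.alt_onehot, p.ref_onehot, p.variant_index)
               for p in pairs]
        np.testing.assert_allclose(score_pairs(tiny_regression, rev),
                                   -deltas, atol=1e-10)

    def test_classifier_deltas_on_logit_scale(self, tiny_classifier,
                                              small_synth):
        deltas = score_variants(tiny_classifier,
                                small_synth.disease_variants[:10],
                                small_synth.genome, 80)
        assert np.isfinite(deltas).all()

    def test_disrupting_variant_positive_delta(self, tiny_regression,
                                               small_synth):
        """Destroying a planted activating motif lowers predicted activity."""
        truth = small_synth.truth.variant_truth
        dis = [v for v in small_synth.disease_variants
               if truth[v.id]["kind"] == "disrupting"
               and truth[v.id]["true_effect"] > 0][:30]
        deltas = score_variants(tiny_regression, dis, small_synth.genome, 80)
        assert np.mean(deltas) > 0


class TestOverlapFilter:
    def test_boundary_semantics(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        v_in = VariantRecord("chr1", 150, "A", "G")
        v_out = VariantRecord("chr1", 201, "A", "G")
        v_edge = VariantRecord("chr1", 200, "A", "G")  # 0-based 199: inside
        flags = overlap_filter([v_in, v_out, v_edge], peaks)
        assert flags.tolist() == [True, False, True]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        peaks = []
        for _ in range(150):
            s = int(rng.integers(0, 10_000))
            peaks.append(GenomicInterval(f"chr{int(rng.integers(1, 4))}", s,
                                         s + int(rng.integers(1, 300))))
        variants = [
            VariantRecord(f"chr{int(rng.integers(1, 4))}",
                          int(rng.integers(1, 10_500)), "A", "G", f"v{i}")
            for i in range(500)
        ]
        expected = [
            any(p.chrom == v.chrom and p.start <= v.pos0 < p.end
                for p in peaks)
            for v in variants
        ]
        assert overlap_filter(variants, peaks).tolist() == expected


class TestNullModel:
    def test_sample_sd_definition(self):
        scores = np.concatenate([np.tile([-1.0, 0.0, 1.0], 34)])  # n=102
        null = NullModel.from_scores(scores)
        assert null.sd == pytest.approx(np.std(scores, ddof=1))
        assert null.n == 102

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        a = NullModel.from_scores(scores)
        b = NullModel.from_scores(scores * 3.5)
        assert b.sd == pytest.approx(3.5 * a.sd)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            NullModel.from_scores(np.arange(50, dtype=float))

    def test_half_sample_stability(self, tiny_regression, small_synth):
        """Null sd is stable across disjoint background half-samples."""
        bg = small_synth.background_variants
        deltas = score_variants(tiny_regression, bg, small_synth.genome, 80)
        half = len(deltas) // 2
        sd1 = np.std(deltas[:half], ddof=1)
        sd2 = np.std(deltas[half:], ddof=1)
        assert abs(sd1 - sd2) / sd1 < 0.25

    def test_build_null_requires_ocr_overlap(self, tiny_regression,
                                             small_synth):
        far = [VariantRecord("chr1", 5, "A", "G", f"x{i}") for i in range(3)]
        with pytest.raises(ValueError, match="background"):
            build_null(tiny_regression, far, small_synth.peaks,
                       small_synth.genome, 80)


class TestNormalizeAndCall:
    def _call(self, zs, in_ocr=None, sd=1.0):
        n = len(zs)
        variants = [VariantRecord("chr1", 1000 + i, "A", "G", f"v{i}")
                    for i in range(n)]
        scores = np.asarray(zs, dtype=float) * sd
        null = NullModel(np.zeros(100), sd, 100)
        flags = np.ones(n, dtype=bool) if in_ocr is None else in_ocr
        return normalize_and_call(variants, scores, flags, null)

    def test_printed_z_to_p_pairs(self):
        """Two-sided Gaussian p at |z|=3.31 and |z|=2.49 match to 2 s.f."""
        table = self._call([3.31, 2.49])
        assert float(f"{table.p[0]:.1e}") == pytest.approx(9.3e-4)
        assert float(f"{table.p[1]:.1e}") == pytest.approx(1.3e-2)

    def test_zero_z_never_outlier(self):
        table = self._call([0.0])
        assert table.p[0] == pytest.approx(1.0)
        assert not table.outlier[0]

    def test_self_normalization_unit_sd(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(scale=2.3, size=500)
        null = NullModel.from_scores(scores)
        variants = [VariantRecord("c", i + 1, "A", "G") for i in range(500)]
        table = normalize_and_call(variants, scores, np.ones(500, bool), null)
        assert np.std(table.z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_bh_properties(self):
        rng = np.random.default_rng(1)
        zs = rng.normal(size=60) * 2
        table = self._call(zs).sort_values("p").reset_index(drop=True)
        q = table.q.to_numpy()
        p = table.p.to_numpy()
        m = len(p)
        assert (np.diff(q) >= -1e-12).all()  # nondecreasing in p
        assert (q <= 1.0 + 1e-12).all()
        # step-up definition: q_i = min over j>=i of p_j * m/(j+1)
        expected = np.minimum.accumulate(
            (p * m / (np.arange(m) + 1))[::-1])[::-1]
        np.testing.assert_allclose(q, np.minimum(expected, 1.0), atol=1e-12)

    def test_single_test_q_equals_p(self):
        table = self._call([1.7])
        assert table.q[0] == pytest.approx(table.p[0])

    def test_non_ocr_variants_never_flagged(self):
        table = self._call([5.0, 5.0], in_ocr=np.array([True, False]))
        assert table.outlier.tolist() == [True, False]
        assert np.isnan(table.q[1])

    def test_bh_family_is_in_ocr_only(self):
        t_all = self._call([3.0, 2.5, 0.1, 0.2])
        flags = np.array([True, True, False, False])
        t_sub = self._call([3.0, 2.5, 0.1, 0.2], in_ocr=flags)
        # with the family restricted to 2 in-OCR tests, q-values change
        assert t_sub.q[0] == pytest.approx(t_sub.p[0] * 2 / 1, abs=1e-12) or \
            t_sub.q[0] <= t_sub.p[1]
        assert np.isnan(t_sub.q[2])
        assert t_all.q.notna().all()


class TestDistributionFacts:
    def test_gaussian_mass_within_two_sd(self):
        assert gaussian_mass_within(2.0) == pytest.approx(0.9545, abs=5e-5)

    def test_laplace_scale_equivalent(self):
        assert laplace_scale_equivalent(2.0) == pytest.approx(2.82, abs=0.01)

    def test_two_sided_p_matches_scipy(self):
        for z in (0.5, 1.0, 2.0, 3.31):
            assert two_sided_gaussian_p(z) == \
                pytest.approx(2 * (1 - sps.norm.cdf(z)))


class TestNormalityDiagnostics:
    def test_gaussian_null_high_W(self):
        rng = np.random.default_rng(0)
        null = NullModel.from_scores(rng.normal(size=5000))
        diag = normality_diagnostics(null, seed=0)
        assert diag["shapiro_W"] > 0.99

    def test_laplace_kurtosis_and_lower_W(self):
        rng = np.random.default_rng(0)
        lap = NullModel.from_scores(rng.laplace(size=5000))
        gauss = NullModel.from_scores(rng.normal(size=5000))
        d_lap = normality_diagnostics(lap, seed=1)
        d_gauss = normality_diagnostics(gauss, seed=1)
        assert d_lap["data_excess_kurtosis"] == pytest.approx(3.0, abs=1.0)
        assert d_gauss["data_excess_kurtosis"] == pytest.approx(0.0, abs=0.5)
        assert d_lap["shapiro_W"] < d_gauss["shapiro_W"]

    def test_subsampling_recorded(self):
        rng = np.random.default_rng(2)
        null = NullModel.from_scores(rng.normal(size=9000))
        diag = normality_diagnostics(null, seed=3, max_n=5000)
        assert diag["n_used"] == 5000
        assert diag["seed"] == 3

    def test_constant_scores_rejected(self):
        null = NullModel(np.ones(100), 1.0, 100)
        with pytest.raises(ValueError, match="constant"):
            normality_diagnostics(null)


class TestLoading:
    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a", "b"], "chrom": ["chr1", "chr2"], "pos": [10, 20],
            "ref": ["A", "C"], "alt": ["G", "T"],
        })
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        variants = load_variants(path)
        assert [v.id for v in variants] == ["a", "b"]
        assert variants[1].pos0 == 19

    def test_vcf_loading(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t42\trs1\tA\tG\t.\t.\t.\n"
        )
        (v,) = load_variants(vcf)
        assert (v.chrom, v.pos, v.ref, v.alt, v.id) == \
            ("chr1", 42, "A", "G", "rs1")

    def test_validation_against_genome(self, small_synth):
        validate_against_genome(small_synth.disease_variants,
                                small_synth.genome)
        bad = VariantRecord("chr1", 1000, "A", "G", "bad")
        if small_synth.genome["chr1"][999] == "A":
            bad = VariantRecord("chr1", 1000, "C", "G", "bad")
        with pytest.raises(ValueError, match="bad"):
            validate_against_genome([bad], small_synth.genome)


def test_sample_background_variants_valid(small_synth):
    bg = sample_background_variants(small_synth.peaks, small_synth.genome,
                                    50, seed=0)
    assert len(bg) == 50
    validate_against_genome(bg, small_synth.genome)
    flags = overlap_filter(bg, small_synth.peaks)
    assert flags.all()
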