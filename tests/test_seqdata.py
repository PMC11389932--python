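"""Sequence dataset construction: parsing, windows, encodings, splits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peakvar.seqdata import (
    BULK_SPLIT,
    GenomicInterval,
    Peak,
    SequenceExample,
    SplitSpec,
    chromosome_split,
    examples_from_peaks,
    extend_window,
    fetch_sequence,
    gc_fraction,
    generate_gc_matched_negatives,
    one_hot,
    parse_narrowpeak,
    reverse_complement,
    subtract_overlapping,
    summit_window,
    write_narrowpeak,
)

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


# ---------------------------------------------------------------------------
# narrowPeak parsing
# ---------------------------------------------------------------------------

class TestParseNarrowpeak:
    def test_missing_summit_uses_floor_midpoint(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t0\t.\t7.5\t-1\t-1\t-1\n")
        (peak,) = parse_narrowpeak(path)
        assert peak.interval == GenomicInterval("chr1", 100, 600)
        assert peak.summit == 350
        assert peak.signal == 7.5

    def test_summit_is_start_plus_offset(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t0\t.\t7.5\t-1\t-1\t50\n")
        (peak,) = parse_narrowpeak(path)
        assert peak.summit == 150

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text(
            "chr1\t100\t600\tp1\t0\t.\t7.5\t-1\t-1\t50\n"
            "chr1\tnotanint\t600\tp2\t0\t.\t1\t-1\t-1\t-1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_narrowpeak(path)

    def test_offset_beyond_peak_length_rejected(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t1\t-1\t-1\t150\n")
        with pytest.raises(ValueError, match="offset"):
            parse_narrowpeak(path)

    def test_synthetic_roundtrip_field_by_field(self, tmp_path, small_synth):
        path = tmp_path / "peaks.narrowPeak"
        write_narrowpeak(small_synth.peaks, path)
        reread = parse_narrowpeak(path)
        assert len(reread) == len(small_synth.peaks)
        for a, b in zip(small_synth.peaks, reread):
            assert a.interval == b.interval
            assert a.summit == b.summit
            assert a.signal == pytest.approx(b.signal, rel=1e-5)
            assert a.interval.start <= a.summit < a.interval.end


# ---------------------------------------------------------------------------
# window arithmetic
# ---------------------------------------------------------------------------

class TestWindows:
    @pytest.mark.parametrize(
        "center,left,right,expected",
        [
            (10_000, 499, 500, (9_501, 10_501)),
            (10_000, 249, 250, (9_751, 10_251)),
            (5, 0, 0, (5, 6)),
        ],
    )
    def test_extend_window(self, center, left, right, expected):
        iv = extend_window("chr1", center, left, right)
        assert (iv.start, iv.end) == expected
        assert len(iv) == left + right + 1

    @given(st.integers(0, 10**6), st.integers(0, 2000), st.integers(0, 2000))
    def test_length_and_center_index(self, center, left, right):
        if center - left < 0:
            with pytest.raises(ValueError):
                extend_window("c", center, left, right)
        else:
            iv = extend_window("c", center, left, right)
            assert len(iv) == left + right + 1
            assert center - iv.start == left

    def test_summit_expansion_even_length(self):
        peak = Peak(GenomicInterval("chr1", 9000, 11000), 10_000, 1.0)
        iv = summit_window(peak, 1000)
        # summit at index L/2 - 1 = 499, mirroring the 499/500 variant flanks
        assert 10_000 - iv.start == 499
        assert len(iv) == 1000


# ---------------------------------------------------------------------------
# sequences and one-hot encoding
# ---------------------------------------------------------------------------

class TestSequences:
    def test_fetch(self):
        genome = {"chrX": "ACGTN"}
        assert fetch_sequence(genome, GenomicInterval("chrX", 1, 4)) == "CGT"

    def test_fetch_reverse_complement(self):
        genome = {"chrX": "ACGTN"}
        assert fetch_sequence(genome, GenomicInterval("chrX", 1, 4),
                              reverse_complement_seq=True) == "ACG"

    def test_fetch_errors(self):
        genome = {"chrX": "ACGTN"}
        with pytest.raises(KeyError):
            fetch_sequence(genome, GenomicInterval("chrZ", 0, 1))
        with pytest.raises(ValueError):
            fetch_sequence(genome, GenomicInterval("chrX", 2, 9))

    def test_full_chromosome_roundtrip(self, tiny_genome):
        L = len(tiny_genome["chrY"])
        assert fetch_sequence(tiny_genome, GenomicInterval("chrY", 0, L)) == \
            tiny_genome["chrY"]

    def test_one_hot_basics(self):
        mat = one_hot("ACGT")
        assert mat.shape == (4, 4)
        np.testing.assert_array_equal(mat, np.eye(4))
        np.testing.assert_array_equal(one_hot("N"), np.zeros((1, 4)))

    def test_one_hot_invalid_base_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            one_hot("ACXGT")

    @given(dna)
    def test_one_hot_rc_commutes_with_flip_and_swap(self, seq):
        direct = one_hot(reverse_complement(seq))
        swapped = one_hot(seq)[::-1, ::-1]  # reverse length, swap A<->T C<->G
        np.testing.assert_array_equal(direct, swapped)

    @given(dna)
    def test_row_sums_zero_or_one(self, seq):
        sums = one_hot(seq).sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0}


# ---------------------------------------------------------------------------
# interval subtraction vs brute force
# ---------------------------------------------------------------------------

class TestSubtractOverlapping:
    def test_one_bp_overlap_removed_abutting_kept(self):
        cand = [GenomicInterval("c", 100, 200)]
        assert subtract_overlapping(cand, [[GenomicInterval("c", 199, 300)]]) == []
        assert subtract_overlapping(cand, [[GenomicInterval("c", 200, 300)]]) == cand

    def test_matches_bruteforce_oracle(self, rng):
        r = np.random.default_rng(5)
        def rand_ivs(n):
            out = []
            for _ in range(n):
                start = int(r.integers(0, 5000))
                out.append(GenomicInterval(f"chr{int(r.integers(1, 4))}",
                                           start, start + int(r.integers(1, 200))))
            return out

        candidates, exclusions = rand_ivs(400), rand_ivs(300)
        expected = [
            c for c in candidates
            if not any(c.overlaps(e) for e in exclusions)
        ]
        assert subtract_overlapping(candidates, [exclusions]) == expected


# ---------------------------------------------------------------------------
# chromosome splits
# ---------------------------------------------------------------------------

def _examples_on(chroms):
    return [
        SequenceExample(GenomicInterval(c, 0, 10), one_hot("ACGTACGTAC"), 0.0)
        for c in chroms
    ]


class TestChromosomeSplit:
    def test_bulk_split_assignment(self):
        examples = _examples_on(["chr1", "chr4", "chr8", "chr9", "chr2"])
        chromosome_split(examples, BULK_SPLIT)
        assert [e.split for e in examples] == \
            ["train", "val", "test", "test", "train"]

    def test_mpra_split_honored(self):
        from peakvar.seqdata import MPRA_SPLIT

        examples = _examples_on(["chr3", "chr7", "chr1", "chr20", "chr5"])
        chromosome_split(examples, MPRA_SPLIT)
        assert [e.split for e in examples] == \
            ["val", "val", "test", "test", "train"]

    def test_empty_spec_all_train(self):
        examples = _examples_on(["chr1", "chr2"])
        chromosome_split(examples, SplitSpec())
        assert all(e.split == "train" for e in examples)

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(val_chroms={"chr1"}, test_chroms={"chr1", "chr2"})

    @given(st.lists(st.sampled_from([f"chr{i}" for i in range(1, 10)]),
                    min_size=1, max_size=40))
    def test_partition_property(self, chroms):
        examples = _examples_on(chroms)
        chromosome_split(examples, BULK_SPLIT)
        groups = {s: [e for e in examples if e.split == s]
                  for s in ("train", "val", "test")}
        assert sum(len(g) for g in groups.values()) == len(examples)
        for e in groups["val"]:
            assert e.chrom in BULK_SPLIT.val_chroms
        for e in groups["test"]:
            assert e.chrom in BULK_SPLIT.test_chroms


# ---------------------------------------------------------------------------
# GC-matched negatives
# ---------------------------------------------------------------------------

class TestGCMatching:
    def test_matched_within_tolerance(self, small_synth):
        peaks = small_synth.peaks[:100]
        positives = [summit_window(p, 150) for p in peaks]
        negatives, summary = generate_gc_matched_negatives(
            positives, small_synth.genome, xfold=2.0, gc_tol=0.02, seed=0,
            exclude=[[p.interval for p in small_synth.peaks]],
        )
        assert summary["emitted"] == pytest.approx(2 * len(positives), abs=1)
        assert summary["matched_within_tol"] / summary["emitted"] >= 0.95
        assert all(len(iv) == 150 for iv in negatives)

    def test_gc_distributions_close(self, small_synth):
        positives = [summit_window(p, 150) for p in small_synth.peaks]
        negatives, _ = generate_gc_matched_negatives(
            positives, small_synth.genome, xfold=2.0, gc_tol=0.02, seed=1)
        from scipy.stats import ks_2samp

        pos_gc = [gc_fraction(fetch_sequence(small_synth.genome, iv))
                  for iv in positives]
        neg_gc = [gc_fraction(fetch_sequence(small_synth.genome, iv))
                  for iv in negatives]
        assert ks_2samp(pos_gc, neg_gc).statistic <= 0.05 + 0.1

    def test_seed_reproducible(self, small_synth):
        positives = [summit_window(p, 150) for p in small_synth.peaks[:20]]
        a, _ = generate_gc_matched_negatives(positives, small_synth.genome,
                                             seed=3)
        b, _ = generate_gc_matched_negatives(positives, small_synth.genome,
                                             seed=3)
        assert a == b

    def test_exhaustion_warns(self):
        # GC-rich positive block in an otherwise AT-only genome: background
        # sampling can never match its G+C content
        genome = {"chr1": "AT" * 350 + "GC" * 50 + "AT" * 350}
        positives = [GenomicInterval("chr1", 700, 800)]
        with pytest.warns(UserWarning, match="GC matching exhausted"):
            negatives, summary = generate_gc_matched_negatives(
                positives, genome, xfold=2.0, gc_tol=0.02, seed=0,
                max_attempts_per_negative=20,
            )
        assert summary["matched_within_tol"] < summary["requested"]


def test_example_serialization_roundtrip(tiny_genome, tmp_path):
    from peakvar.seqdata import load_examples, save_examples

    peaks = [Peak(GenomicInterval("chrX", 1000, 1400), 1200, 3.5, "p0"),
             Peak(GenomicInterval("chrX", 2000, 2400), 2200, 1.25, "p1")]
    examples = examples_from_peaks(tiny_genome, peaks, 300,
                                   SplitSpec(val_chroms={"chrX"}))
    prefix = str(tmp_path / "examples")
    save_examples(examples, prefix)
    reread = load_examples(prefix)
    assert len(reread) == len(examples)
    for a, b in zip(examples, reread):
        assert a.interval == b.interval
        assert a.label == b.label
        assert a.split == b.split
        np.testing.assert_array_equal(a.onehot, b.onehot)


def test_examples_from_peaks_drops_out_of_bounds(tiny_genome):
    peaks = [
        Peak(GenomicInterval("chrY", 0, 100), 10, 1.0),  # too close to start
        Peak(GenomicInterval("chrY", 1000, 1400), 1200, 2.0),
    ]
    examples = examples_from_peaks(tiny_genome, peaks, 500)
    assert len(examples) == 1
    assert examples[0].label == 2.0
    assert examples[0].onehot.shape == (500, 4)
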