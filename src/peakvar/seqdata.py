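"""Genomic sequence dataset construction.

Reads genomes, peak calls and variant tables, builds fixed-length one-hot
encoded training windows centred on peak summits, samples GC-matched negative
background intervals, and assigns chromosome-holdout train/val/test splits.

Coordinates are 0-based half-open throughout (BED arithmetic); 1-based VCF
positions are converted on ingest.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
#: column order of the one-hot encoding
BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self):
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """Peak call: interval, absolute summit position and accessibility signal.

    ``signal`` is the regression label — the pipeline signalValue for bulk
    peaks, or the natural-log MACS2 score for scATAC pseudobulk peaks.
    """

    interval: GenomicInterval
    summit: int
    signal: float
    name: str = "."

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(f"summit {self.summit} outside {self.interval}")
        if self.signal < 0:
            raise ValueError(f"negative signal {self.signal}")


@dataclass
class SequenceExample:
    """Fixed-length one-hot window with a label and a split assignment."""

    interval: GenomicInterval
    onehot: np.ndarray  # (L, 4)
    label: float
    split: str = "train"

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome-holdout split: named val/test chromosomes, remainder train."""

    val_chroms: frozenset = frozenset()
    test_chroms: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "val_chroms", frozenset(self.val_chroms))
        object.__setattr__(self, "test_chroms", frozenset(self.test_chroms))
        shared = self.val_chroms & self.test_chroms
        if shared:
            raise ValueError(f"chromosomes in both val and test: {sorted(shared)}")

    def assign(self, chrom: str) -> str:
        if chrom in self.val_chroms:
            return "val"
        if chrom in self.test_chroms:
            return "test"
        return "train"


# canonical holdouts: bulk accessibility models (val chr4, test chr8+9) and
# the reporter-assay models (val chr3+7, twelve test chromosomes)
BULK_SPLIT = SplitSpec(val_chroms={"chr4"}, test_chroms={"chr8", "chr9"})
MPRA_SPLIT = SplitSpec(
    val_chroms={"chr3", "chr7"},
    test_chroms={f"chr{c}" for c in (1, 2, 4, 6, 8, 10, 13, 14, 15, 16, 18, 20)},
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_narrowpeak(path) -> list:
    """Parse an ENCODE narrowPeak (BED6+4) file into a list of :class:`Peak`.

    Column 7 is signalValue; column 10 the summit offset from ``start``
    (-1 means no summit was called, in which case the floor midpoint is used).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 10:
                raise ValueError(
                    f"{path}: line {lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if offset >= end - start:
                raise ValueError(
                    f"{path}: line {lineno}: summit offset {offset} >= peak "
                    f"length {end - start}"
                )
            if offset == -1:
                summit = start + (end - start) // 2
            else:
                summit = start + offset
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), summit, signal, name)
            )
    return peaks


def write_narrowpeak(peaks, path) -> None:
    """Write peaks in narrowPeak format (summit as offset in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t"
                f"{p.signal:.6g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# window arithmetic and sequence handling
# ---------------------------------------------------------------------------

def extend_window(chrom: str, center: int, left: int, right: int) -> GenomicInterval:
    """Interval of length ``left + right + 1`` around a focal position.

    The focal position sits at index ``left`` of the resulting window; the
    1000 bp variant windows use left=499/right=500 and the 500 bp windows
    left=249/right=250.
    """
    if left < 0 or right < 0:
        raise ValueError("flank sizes must be non-negative")
    if center - left < 0:
        raise ValueError(
            f"window [{center - left}, {center + right + 1}) runs off the "
            f"chromosome start"
        )
    return GenomicInterval(chrom, center - left, center + right + 1)


def summit_window(peak: Peak, length: int) -> GenomicInterval:
    """Symmetric summit expansion to ``length`` bp.

    For even lengths the summit lands at index ``length // 2 - 1``
    (left flank length//2 - 1, right flank length//2), mirroring the
    variant-window convention of 499 left / 500 right for 1000 bp.
    """
    left = (length - 1) // 2 if length % 2 else length // 2 - 1
    right = length - 1 - left
    return extend_window(peak.interval.chrom, peak.summit, left, right)


def chrom_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def fetch_sequence(genome, interval: GenomicInterval, reverse_complement_seq: bool = False) -> str:
    """Fetch the uppercase sequence of ``interval`` from a genome.

    ``genome`` may be a ``pyfaidx.Fasta`` handle or any mapping of chromosome
    name to string-like sequence.
    """
    try:
        record = genome[interval.chrom]
    except KeyError:
        raise KeyError(f"chromosome {interval.chrom!r} absent from genome") from None
    if interval.end > len(record):
        raise ValueError(
            f"{interval} out of bounds for {interval.chrom} "
            f"(length {len(record)})"
        )
    seq = str(record[interval.start : interval.end]).upper()
    if reverse_complement_seq:
        seq = reverse_complement(seq)
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def one_hot(seq: str) -> np.ndarray:
    """L x 4 one-hot encoding, columns A,C,G,T; N rows are all zero."""
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(f"invalid base {base!r} at position {i}")
        if idx >= 0:
            out[i, idx] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (all-zero rows decode to N)."""
    bases = []
    for row in np.asarray(mat):
        idx = int(np.argmax(row))
        bases.append(BASES[idx] if row[idx] > 0 else "N")
    return "".join(bases)


def gc_fraction(seq: str) -> float:
    """G+C fraction over non-N bases (0 if the sequence is all N)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


# ---------------------------------------------------------------------------
# negatives and interval set operations
# ---------------------------------------------------------------------------

def _build_trees(interval_lists):
    trees = {}
    for intervals in interval_lists:
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def subtract_overlapping(candidates, exclusion_sets) -> list:
    """Drop every candidate that overlaps (>= 1 bp) any exclusion interval.

    Mirrors ``bedtools subtract -A``: overlapping candidates are removed
    entirely; input order is preserved.
    """
    trees = _build_trees(exclusion_sets)
    kept = []
    for iv in candidates:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            continue
        kept.append(iv)
    return kept


def generate_gc_matched_negatives(
    positives,
    genome,
    xfold: float = 2.0,
    gc_tol: float = 0.02,
    seed: int = 0,
    exclude=None,
    max_attempts_per_negative: int = 200,
):
    """Sample background intervals GC-matched to a set of positive windows.

    For each positive window, ``xfold`` negatives of the same length are drawn
    uniformly from the genome (avoiding ``exclude`` intervals and mostly-N
    sequence) such that their G+C fraction differs from that positive's by at
    most ``gc_tol``. When a GC bin cannot be satisfied within the attempt
    budget a warning is raised and the unmatched slots are filled best-effort.

    Returns ``(negatives, summary)`` where summary reports match quality.
    """
    positives = list(positives)
    if not positives:
        raise ValueError("positives must be non-empty")
    rng = np.random.default_rng(seed)
    pos_intervals = [
        p.interval if isinstance(p, (SequenceExample, Peak)) else p for p in positives
    ]
    pos_gc = np.array(
        [gc_fraction(fetch_sequence(genome, iv)) for iv in pos_intervals]
    )
    length = len(pos_intervals[0])
    if any(len(iv) != length for iv in pos_intervals):
        raise ValueError("positives must share one window length")

    n_target = int(round(xfold * len(pos_intervals)))
    # one matching slot per emitted negative, cycling over positives
    slots = [pos_gc[i % len(pos_gc)] for i in range(n_target)]

    chroms = list(genome.keys()) if hasattr(genome, "keys") else [r.name for r in genome]
    lengths = np.array([chrom_length(genome, c) for c in chroms], dtype=float)
    usable = lengths >= length
    if not usable.any():
        raise ValueError("genome has no chromosome long enough to sample from")
    chroms = [c for c, u in zip(chroms, usable) if u]
    lengths = lengths[usable]
    probs = lengths / lengths.sum()

    exclusion_trees = _build_trees([pos_intervals] + list(exclude or []))

    negatives: list[GenomicInterval] = []
    matched = 0
    gaps = []
    budget = max_attempts_per_negative * n_target
    unfilled = list(range(n_target))
    best_effort = {}  # slot -> (gap, interval)
    attempts = 0
    while unfilled and attempts < budget:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        start = int(rng.integers(0, int(lengths[ci]) - length + 1))
        iv = GenomicInterval(chrom, start, start + length)
        tree = exclusion_trees.get(chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            continue
        seq = fetch_sequence(genome, iv)
        if seq.count("N") > 0.1 * length:
            continue
        gc = gc_fraction(seq)
        # nearest outstanding slot by GC
        diffs = [abs(gc - slots[s]) for s in unfilled]
        k = int(np.argmin(diffs))
        slot = unfilled[k]
        if diffs[k] <= gc_tol:
            negatives.append(iv)
            gaps.append(diffs[k])
            matched += 1
            unfilled.pop(k)
        else:
            prev = best_effort.get(slot)
            if prev is None or diffs[k] < prev[0]:
                best_effort[slot] = (diffs[k], iv)
    if unfilled:
        warnings.warn(
            f"GC matching exhausted after {attempts} attempts: "
            f"{len(unfilled)} of {n_target} negatives unmatched within "
            f"tol={gc_tol}; filling best-effort",
            stacklevel=2,
        )
        for slot in list(unfilled):
            if slot in best_effort:
                gap, iv = best_effort[slot]
                negatives.append(iv)
                gaps.append(gap)
                unfilled.remove(slot)
    summary = {
        "requested": n_target,
        "emitted": len(negatives),
        "matched_within_tol": matched,
        "max_gc_gap": float(max(gaps)) if gaps else float("nan"),
        "gc_tol": gc_tol,
    }
    return negatives, summary


def chromosome_split(examples, spec: SplitSpec):
    """Assign train/val/test strictly by chromosome; returns the same list."""
    for ex in examples:
        ex.split = spec.assign(ex.chrom)
    return examples


# ---------------------------------------------------------------------------
# example construction and serialization
# ---------------------------------------------------------------------------

def examples_from_peaks(
    genome,
    peaks,
    length: int,
    split_spec: SplitSpec | None = None,
    label: str = "signal",
    shifts=(0,),
    add_rc: bool = False,
):
    """Summit-centred labelled windows for every peak that fits the genome.

    Windows running off a chromosome end are dropped (not padded) and counted
    in a log message. ``label`` is "signal" for regression or a constant for
    classifier positives. ``shifts`` (window offsets around the summit) and
    ``add_rc`` (add the reverse-complement of each window) provide the usual
    training-time augmentation; leave at defaults for val/test windows.
    """
    examples = []
    dropped = 0
    for peak in peaks:
        y = peak.signal if label == "signal" else float(label)
        left = (length - 1) // 2 if length % 2 else length // 2 - 1
        for shift in shifts:
            try:
                iv = extend_window(peak.interval.chrom, peak.summit + shift,
                                   left, length - 1 - left)
                seq = fetch_sequence(genome, iv)
            except (ValueError, KeyError):
                dropped += 1
                continue
            examples.append(SequenceExample(iv, one_hot(seq), y))
            if add_rc:
                examples.append(
                    SequenceExample(iv, one_hot(reverse_complement(seq)), y)
                )
    if dropped:
        logger.info(
            "dropped %d/%d windows running off chromosome ends",
            dropped,
            len(peaks),
        )
    if split_spec is not None:
        chromosome_split(examples, split_spec)
    return examples


def examples_from_intervals(genome, intervals, label: float, split_spec=None):
    """Fixed-label windows (e.g. negatives with signal 0 / class 0)."""
    examples = [
        SequenceExample(iv, one_hot(fetch_sequence(genome, iv)), float(label))
        for iv in intervals
    ]
    if split_spec is not None:
        chromosome_split(examples, split_spec)
    return examples


@dataclass
class SequenceDataset:
    """Dense batch view over a list of :class:`SequenceExample`."""

    X: np.ndarray  # (N, L, 4) float32
    y: np.ndarray  # (N,)
    chroms: list
    intervals: list

    @classmethod
    def from_examples(cls, examples):
        if not examples:
            raise ValueError("no examples")
        X = np.stack([ex.onehot for ex in examples]).astype(np.float32)
        y = np.array([ex.label for ex in examples], dtype=np.float32)
        return cls(X, y, [ex.chrom for ex in examples], [ex.interval for ex in examples])

    def __len__(self):
        return len(self.y)


def split_datasets(examples):
    """Partition examples by split into a dict of SequenceDataset."""
    out = {}
    for name in ("train", "val", "test"):
        subset = [ex for ex in examples if ex.split == name]
        if subset:
            out[name] = SequenceDataset.from_examples(subset)
    return out


def save_examples(examples, prefix):
    """Serialize examples as a compressed tensor file + a TSV manifest."""
    import pandas as pd

    X = np.stack([ex.onehot for ex in examples]).astype(np.uint8)
    np.savez_compressed(f"{prefix}.npz", onehot=X)
    manifest = pd.DataFrame(
        {
            "chrom": [ex.chrom for ex in examples],
            "start": [ex.interval.start for ex in examples],
            "end": [ex.interval.end for ex in examples],
            "label": [ex.label for ex in examples],
            "split": [ex.split for ex in examples],
        }
    )
    manifest.to_csv(f"{prefix}.manifest.tsv", sep="\t", index=False)


def load_examples(prefix):
    import pandas as pd

    X = np.load(f"{prefix}.npz")["onehot"].astype(np.float32)
    manifest = pd.read_csv(f"{prefix}.manifest.tsv", sep="\t")
    return [
        SequenceExample(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            X[i],
            float(row.label),
            row.split,
        )
        for i, row in enumerate(manifest.itertuples())
    ]
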