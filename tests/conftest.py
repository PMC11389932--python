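"""Shared fixtures: tiny in-memory genomes, synthetic datasets, trained models.

Heavy artifacts (the default synthetic dataset and the CNN trained on it) are
session-scoped so the end-to-end checks and the unit tests share one training
run.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_genome():
    """Deterministic 2-chromosome toy genome as a plain mapping."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {
        "chrX": "".join(rng.choice(bases, size=5000)),
        "chrY": "".join(rng.choice(bases, size=3000)),
    }


@pytest.fixture(scope="session")
def small_synth():
    """Reduced synthetic dataset for fast structural/round-trip tests."""
    from peakvar.synth import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_chroms=4, chrom_len=40_000, n_peaks=60, peak_width=300,
        n_disease_variants=40, n_background_variants=300, n_mpra_oligos=80,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def default_synth():
    """The default study conditions used by the end-to-end benchmark."""
    from peakvar.synth import SyntheticSpec, generate

    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def trained_regression(default_synth):
    """Regression CNN trained once on the default synthetic peaks."""
    from peakvar.pipeline import benchmark_regression

    results, datasets, metrics = benchmark_regression(default_synth, seed=0)
    return {"results": results, "datasets": datasets, "metrics": metrics}


def _motif_dataset(n, length, rng, motif="TTGCGCAA"):
    """Separable toy task: label = number of planted motif copies (0-2)."""
    from peakvar.seqdata import GenomicInterval, SequenceDataset, one_hot

    bases = np.array(list("ACGT"))
    X, y, intervals, chroms = [], [], [], []
    for i in range(n):
        seq = list(rng.choice(bases, size=length))
        copies = int(rng.integers(0, 3))
        for c in range(copies):
            start = int(rng.integers(0, length - len(motif)))
            seq[start : start + len(motif)] = list(motif)
        X.append(one_hot("".join(seq)))
        y.append(float(copies))
        intervals.append(GenomicInterval("chrT", i * length, (i + 1) * length))
        chroms.append("chrT")
    return SequenceDataset(np.stack(X), np.array(y, dtype=np.float32),
                           chroms, intervals)


@pytest.fixture(scope="session")
def motif_task(rng):
    """Train/val/test splits of the planted-motif toy regression task."""
    r = np.random.default_rng(7)
    return {
        "train": _motif_dataset(300, 80, r),
        "val": _motif_dataset(80, 80, r),
        "test": _motif_dataset(80, 80, r),
    }


@pytest.fixture(scope="session")
def tiny_regression(motif_task):
    """Small CNN regression trained on the toy motif-count task."""
    from peakvar.models import ModelSpec, SequenceRegression, TrainSpec

    spec = ModelSpec("regression", 80, ((16, 8, 1),), (73, 73), 0.0, 0, "none")
    tspec = TrainSpec(loss="mse", learning_rate=0.01, batch_size=32,
                      epochs=40, momentum=0.9, seed=3)
    return SequenceRegression(motif_task["train"], motif_task["val"], spec,
                              tspec).fit()


@pytest.fixture(scope="session")
def tiny_classifier(motif_task):
    """Small CNN classifier: motif-present vs motif-absent."""
    from peakvar.models import ModelSpec, SequenceClassifier, TrainSpec
    from peakvar.seqdata import SequenceDataset

    def binarize(ds):
        return SequenceDataset(ds.X, (ds.y > 0).astype(np.float32), ds.chroms,
                               ds.intervals)

    spec = ModelSpec("classifier", 80, ((16, 8, 1),), (73, 73), 0.0, 0, "none")
    tspec = TrainSpec(loss="cross_entropy", learning_rate=0.05, batch_size=32,
                      epochs=40, momentum=0.9, seed=3)
    return SequenceClassifier(binarize(motif_task["train"]),
                              binarize(motif_task["val"]), spec, tspec).fit()
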