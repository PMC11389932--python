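"""Reproducible runs: config parsing, stage orchestration, benchmarks.

The config-driven entry points (``run_train``, ``run_score``, ``run_mpra``)
read real files (FASTA, narrowPeak, variant/oligo TSV) and write checkpoints,
score tables and manifests. The ``benchmark_*`` functions run the same
machinery end-to-end on the bundled synthetic generator — train a regression,
recover planted variant effects through the empirical-null outlier caller,
evaluate reporter-assay direction-of-effect, and compare transfer learning
against its two baselines — and are what the test-suite and the acceptance
script execute.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import mpra as mpra_mod
from . import seqdata, synth, variants as var_mod
from .models import (
    CNNResults,
    SequenceClassifier,
    SequenceRegression,
    TrainSpec,
    evaluate_regression,
    get_preset,
    pretrain_finetune,
)
from .seqdata import SequenceDataset, SplitSpec

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML)."""

    outdir: str
    genome: str | None = None
    peaks: str | None = None
    variants: str | None = None
    background: str | None = None
    mpra: str | None = None
    checkpoint: str | None = None
    preset: str = "synthetic_regression"
    val_chroms: tuple = ("chr3",)
    test_chroms: tuple = ("chr4",)
    window_len: int | None = None
    z_threshold: float = 2.0
    epochs: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, need=()) -> None:
        """Check referenced files exist before any compute starts."""
        for key in need:
            path = getattr(self, key)
            if path is None:
                raise FileNotFoundError(f"config is missing required path {key!r}")
            if key == "checkpoint":
                path = f"{path}.json"  # checkpoints are a prefix + sidecar
            if not os.path.exists(path):
                raise FileNotFoundError(f"{key} path does not exist: {path}")

    def split_spec(self) -> SplitSpec:
        return SplitSpec(val_chroms=set(self.val_chroms),
                         test_chroms=set(self.test_chroms))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: RunConfig, outdir, extra=None) -> str:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "input_hashes": {
            key: _sha256(getattr(config, key))
            for key in ("genome", "peaks", "variants", "background", "mpra")
            if getattr(config, key) and os.path.exists(getattr(config, key))
        },
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# config-driven stages
# ---------------------------------------------------------------------------

def _open_genome(path):
    import pyfaidx

    return pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)


def run_train(config: RunConfig) -> dict:
    """Train a model from files; write checkpoint, history and metrics."""
    config.validate(need=("genome", "peaks"))
    spec, tspec = get_preset(config.preset)
    if config.epochs:
        tspec = TrainSpec(**{**asdict(tspec), "epochs": config.epochs,
                             "seed": config.seed})
    else:
        tspec = TrainSpec(**{**asdict(tspec), "seed": config.seed})
    os.makedirs(config.outdir, exist_ok=True)
    genome = _open_genome(config.genome)
    peaks = seqdata.parse_narrowpeak(config.peaks)
    examples = seqdata.examples_from_peaks(genome, peaks, spec.input_length,
                                           config.split_spec())
    datasets = seqdata.split_datasets(examples)
    if "val" not in datasets:
        raise ValueError("no validation examples; check val_chroms")
    cls = SequenceClassifier if spec.kind == "classifier" else SequenceRegression
    results = cls(datasets["train"], datasets["val"], spec=spec,
                  train_spec=tspec).fit()
    results.save(os.path.join(config.outdir, "model"))
    metrics = {"val": results.evaluate(datasets["val"])}
    if "test" in datasets:
        metrics["test"] = results.evaluate(datasets["test"])
    metrics["selected_epoch"] = int(results.selected_epoch)
    with open(os.path.join(config.outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
    write_manifest(config, config.outdir)
    return metrics


def run_score(config: RunConfig) -> pd.DataFrame:
    """Score disease variants against an empirical background null."""
    config.validate(need=("genome", "peaks", "variants", "background",
                          "checkpoint"))
    os.makedirs(config.outdir, exist_ok=True)
    results = CNNResults.load(config.checkpoint)
    genome = _open_genome(config.genome)
    peaks = seqdata.parse_narrowpeak(config.peaks)
    disease = var_mod.load_variants(config.variants)
    window = config.window_len or results.spec.input_length
    if window != results.spec.input_length:
        raise ValueError(
            f"window_len {window} incompatible with checkpoint input length "
            f"{results.spec.input_length}"
        )
    header = ["id", "chrom", "pos", "ref", "alt", "in_ocr", "delta", "z",
              "p", "q", "outlier"]
    out_path = os.path.join(config.outdir, "variant_scores.tsv")
    if not disease:
        pd.DataFrame(columns=header).to_csv(out_path, sep="\t", index=False)
        write_manifest(config, config.outdir)
        return pd.DataFrame(columns=header)
    background = var_mod.load_variants(config.background)
    null = var_mod.build_null(results, background, peaks, genome, window)
    deltas = var_mod.score_variants(results, disease, genome, window)
    in_ocr = var_mod.overlap_filter(disease, peaks)
    table = var_mod.normalize_and_call(disease, deltas, in_ocr, null,
                                       config.z_threshold)
    table.to_csv(out_path, sep="\t", index=False)
    diag = var_mod.normality_diagnostics(null, seed=config.seed)
    with open(os.path.join(config.outdir, "null_summary.json"), "w") as fh:
        json.dump({"n": null.n, "sd": null.sd,
                   "shapiro_W": diag["shapiro_W"],
                   "shapiro_p": diag["shapiro_p"]}, fh, indent=1)
    write_manifest(config, config.outdir)
    return table


def run_mpra(config: RunConfig) -> dict:
    """Predict allelic skew for an oligo table and evaluate it."""
    config.validate(need=("genome", "mpra", "checkpoint"))
    os.makedirs(config.outdir, exist_ok=True)
    results = CNNResults.load(config.checkpoint)
    genome = _open_genome(config.genome)
    oligos = mpra_mod.read_mpra_table(config.mpra)
    report = evaluate_mpra(results, oligos, genome)
    report["predictions"].to_csv(
        os.path.join(config.outdir, "mpra_predictions.tsv"), sep="\t",
        index=False)
    report["direction_accuracy"].to_csv(
        os.path.join(config.outdir, "direction_accuracy.tsv"), sep="\t",
        index=False)
    with open(os.path.join(config.outdir, "ttests.json"), "w") as fh:
        json.dump(report["ttests"], fh, indent=1)
    write_manifest(config, config.outdir)
    return report


# ---------------------------------------------------------------------------
# synthetic benchmarks (shared by tests, CLI and the acceptance script)
# ---------------------------------------------------------------------------

#: training-time augmentation for the synthetic benchmark: windows shifted
#: around the summit plus reverse complements (evaluation windows are plain)
BENCHMARK_SHIFTS = (-150, -100, -50, 0, 50, 100, 150)


def benchmark_regression(data: synth.SyntheticData, seed: int = 0,
                         preset: str = "synthetic_regression"):
    """Train the regression on synthetic peaks; return (results, datasets,
    metrics) with chromosome-holdout val/test.

    Training windows are augmented with summit shifts and reverse
    complements; validation/test metrics use one plain summit-centred window
    per peak.
    """
    spec, tspec = get_preset(preset)
    tspec = TrainSpec(**{**asdict(tspec), "seed": seed})
    split = SplitSpec(val_chroms={"chr3"}, test_chroms={"chr4"})
    augmented = seqdata.examples_from_peaks(
        data.genome, data.peaks, spec.input_length, split,
        shifts=BENCHMARK_SHIFTS, add_rc=True)
    train = seqdata.SequenceDataset.from_examples(
        [e for e in augmented if e.split == "train"])
    plain = seqdata.examples_from_peaks(data.genome, data.peaks,
                                        spec.input_length, split)
    datasets = seqdata.split_datasets(plain)
    datasets["train"] = train
    cls = SequenceClassifier if spec.kind == "classifier" else SequenceRegression
    results = cls(datasets["train"], datasets["val"], spec=spec,
                  train_spec=tspec).fit()
    metrics = {name: results.evaluate(ds) for name, ds in datasets.items()}
    return results, datasets, metrics


def benchmark_classifier(data: synth.SyntheticData, seed: int = 0,
                         preset: str = "synthetic_classifier"):
    """Train the open-vs-closed classifier on synthetic peaks and GC-matched
    negatives; returns (results, datasets, metrics)."""
    spec, tspec = get_preset(preset)
    tspec = TrainSpec(**{**asdict(tspec), "seed": seed})
    split = SplitSpec(val_chroms={"chr3"}, test_chroms={"chr4"})
    pos = seqdata.examples_from_peaks(data.genome, data.peaks,
                                      spec.input_length, split, label="1")
    negs, _ = seqdata.generate_gc_matched_negatives(
        [ex.interval for ex in pos], data.genome, xfold=2.0, gc_tol=0.02,
        seed=seed, exclude=[[p.interval for p in data.peaks]])
    neg = seqdata.examples_from_intervals(data.genome, negs, 0.0, split)
    datasets = seqdata.split_datasets(pos + neg)
    results = SequenceClassifier(datasets["train"], datasets["val"],
                                 spec=spec, train_spec=tspec).fit()
    metrics = {name: results.evaluate(ds) for name, ds in datasets.items()}
    return results, datasets, metrics


def benchmark_variant_recovery(data: synth.SyntheticData, results,
                               z_threshold: float = 2.0) -> dict:
    """Score planted variants, build the null, and measure recovery.

    Reports the outlier rate among planted motif-disrupting vs planted
    neutral variants (in-OCR only) and the sign agreement of flagged
    disrupting variants with the planted effect direction.
    """
    genome, peaks = data.genome, data.peaks
    null = var_mod.build_null(results, data.background_variants, peaks, genome)
    deltas = var_mod.score_variants(results, data.disease_variants, genome)
    in_ocr = var_mod.overlap_filter(data.disease_variants, peaks)
    table = var_mod.normalize_and_call(data.disease_variants, deltas, in_ocr,
                                       null, z_threshold)
    kinds = np.array([
        data.truth.variant_truth[v.id]["kind"] for v in data.disease_variants
    ])
    signs = np.array([
        data.truth.variant_truth[v.id]["sign"] for v in data.disease_variants
    ])
    ocr = table.in_ocr.to_numpy()
    flagged = table.outlier.to_numpy()
    dis = (kinds == "disrupting") & ocr
    neu = (kinds == "neutral") & ocr
    rate_dis = float(flagged[dis].mean()) if dis.any() else float("nan")
    rate_neu = float(flagged[neu].mean()) if neu.any() else float("nan")
    flagged_dis = flagged & dis
    if flagged_dis.any():
        agree = float(
            np.mean(np.sign(table.z.to_numpy()[flagged_dis])
                    == signs[flagged_dis])
        )
    else:
        agree = float("nan")
    return {
        "table": table,
        "null": null,
        "outlier_rate_disrupting": rate_dis,
        "outlier_rate_neutral": rate_neu,
        "rate_ratio": rate_dis / max(rate_neu, 1.0 / max(neu.sum(), 1)),
        "sign_agreement": agree,
        "n_disrupting_in_ocr": int(dis.sum()),
        "n_neutral_in_ocr": int(neu.sum()),
    }


def evaluate_mpra(results, oligos, genome,
                  q_cutoffs=(0.2, 0.1, 0.05, 0.01, 0.001),
                  skew_thr: float = 0.2, q_thr: float = 0.01) -> dict:
    """Predicted skew, emVar categories, direction accuracy, group t-tests."""
    predicted = mpra_mod.predict_allelic_skews(results, oligos, genome)
    calls = mpra_mod.categorize_emvars(oligos, skew_thr=skew_thr, q_thr=q_thr)
    classes = [c.emvar_class for c in calls]
    measured = np.array([o.skew for o in oligos], dtype=float)
    q = np.array([o.skew_q for o in oligos], dtype=float)
    acc = mpra_mod.direction_accuracy(predicted, measured, q, q_cutoffs,
                                      skew_thr)
    keep = [i for i, c in enumerate(classes) if c != "unclassified"]
    ttests = mpra_mod.skew_group_ttests(predicted[keep],
                                        [classes[i] for i in keep])
    predictions = pd.DataFrame({
        "id": [o.id for o in oligos],
        "measured_skew": measured,
        "skew_q": q,
        "predicted_skew": predicted,
        "emvar_class": classes,
    })
    return {
        "predictions": predictions,
        "direction_accuracy": acc,
        "ttests": ttests,
    }


def _transfer_datasets(data: synth.SyntheticData, seed: int,
                       input_length: int = 150):
    """150 bp accessibility (peaks + GC-matched negatives at signal 0) and
    MPRA activity datasets with shared chromosome splits."""
    split = SplitSpec(val_chroms={"chr3"}, test_chroms={"chr4"})
    pos = seqdata.examples_from_peaks(data.genome, data.peaks, input_length,
                                      split)
    negs, _ = seqdata.generate_gc_matched_negatives(
        [ex.interval for ex in pos], data.genome, xfold=2.0, gc_tol=0.02,
        seed=seed, exclude=[[p.interval for p in data.peaks]],
    )
    neg_examples = seqdata.examples_from_intervals(data.genome, negs, 0.0,
                                                   split)
    access = seqdata.split_datasets(pos + neg_examples)
    mpra_examples = mpra_mod.mpra_examples(data.oligos, data.genome,
                                           input_length, split)
    mpra_sets = seqdata.split_datasets(mpra_examples)
    return access, mpra_sets


def benchmark_transfer(data: synth.SyntheticData, seeds=(0, 1, 2),
                       quarter: float = 0.25) -> dict:
    """Transfer-learning three-way comparison on held-out synthetic MPRA.

    For each seed: (a) pre-train on accessibility and fine-tune on a quarter
    of the MPRA training set; (b) train on the same quarter only; (c) use the
    accessibility model without fine-tuning. Reports the Spearman correlation
    of each with measured activity on the held-out MPRA test chromosomes,
    plus per-model medians across seeds.
    """
    spec, tspec = get_preset("synthetic_transfer")
    rows = []
    for seed in seeds:
        access, mpra_sets = _transfer_datasets(data, seed)
        train, val, test = mpra_sets["train"], mpra_sets["val"], mpra_sets["test"]
        rng = np.random.default_rng(seed)
        n_q = max(8, int(round(quarter * len(train))))
        idx = rng.choice(len(train), size=n_q, replace=False)
        quarter_set = SequenceDataset(
            train.X[idx], train.y[idx],
            [train.chroms[i] for i in idx], [train.intervals[i] for i in idx],
        )
        this_tspec = TrainSpec(**{**asdict(tspec), "seed": seed})
        finetuned, pretrained = pretrain_finetune(
            access["train"], access["val"], quarter_set, val,
            spec=spec, pretrain_train_spec=this_tspec,
            finetune_lr=0.01, finetune_epochs=this_tspec.epochs, seed=seed,
        )
        mpra_only = SequenceRegression(quarter_set, val, spec=spec,
                                       train_spec=this_tspec).fit()

        def rho(results):
            return evaluate_regression(results.predict(test.X),
                                       test.y)["spearman_rho"]

        rows.append({
            "seed": seed,
            "finetuned": rho(finetuned),
            "mpra_only_quarter": rho(mpra_only),
            "accessibility_only": rho(pretrained),
        })
    df = pd.DataFrame(rows)
    return {
        "per_seed": df,
        "median": {
            k: float(df[k].median())
            for k in ("finetuned", "mpra_only_quarter", "accessibility_only")
        },
        "n_quarter": int(n_q),
        "n_test": int(len(test)),
    }


def run_benchmark(spec: synth.SyntheticSpec | None = None, seed: int = 0,
                  outdir=None, transfer_seeds=(0, 1, 2)) -> dict:
    """Full synthetic benchmark report (JSON-serialisable dict).

    Any stage failure is caught and recorded under ``failures`` so a partial
    report is still produced.
    """
    spec = spec or synth.SyntheticSpec()
    report: dict = {"seed": seed, "synthetic_spec": {"seed": spec.seed,
                    "n_peaks": spec.n_peaks, "n_chroms": spec.n_chroms,
                    "chrom_len": spec.chrom_len}, "failures": {}}
    data = synth.generate(spec)
    results = None
    try:
        results, datasets, metrics = benchmark_regression(data, seed=seed)
        report["regression"] = metrics
    except Exception as exc:  # partial report on stage failure
        report["failures"]["regression"] = repr(exc)
    if results is not None:
        try:
            rec = benchmark_variant_recovery(data, results)
            report["variant_recovery"] = {
                k: rec[k] for k in (
                    "outlier_rate_disrupting", "outlier_rate_neutral",
                    "rate_ratio", "sign_agreement", "n_disrupting_in_ocr",
                    "n_neutral_in_ocr")
            }
            report["null"] = {
                "n": rec["null"].n, "sd": rec["null"].sd,
                **{k: v for k, v in var_mod.normality_diagnostics(
                    rec["null"], seed=seed).items()
                   if k in ("shapiro_W", "shapiro_p", "data_excess_kurtosis")},
            }
        except Exception as exc:
            report["failures"]["variant_recovery"] = repr(exc)
        try:
            m = evaluate_mpra(results, data.oligos, data.genome)
            report["mpra"] = {
                "direction_accuracy": m["direction_accuracy"].to_dict("records"),
                "ttests": m["ttests"],
            }
        except Exception as exc:
            report["failures"]["mpra"] = repr(exc)
    try:
        t = benchmark_transfer(data, seeds=transfer_seeds)
        report["transfer"] = {"median": t["median"],
                              "per_seed": t["per_seed"].to_dict("records")}
    except Exception as exc:
        report["failures"]["transfer"] = repr(exc)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "benchmark.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "benchmark.md"), "w") as fh:
            fh.write(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# Synthetic benchmark report", ""]
    if "regression" in report:
        test = report["regression"].get("test", {})
        lines += ["## Regression (held-out chromosome)",
                  f"- Pearson r: {test.get('pearson_r', float('nan')):.3f}",
                  f"- Spearman rho: {test.get('spearman_rho', float('nan')):.3f}",
                  ""]
    if "variant_recovery" in report:
        v = report["variant_recovery"]
        lines += ["## Variant-effect recovery",
                  f"- outlier rate (disrupting): {v['outlier_rate_disrupting']:.3f}",
                  f"- outlier rate (neutral): {v['outlier_rate_neutral']:.3f}",
                  f"- sign agreement: {v['sign_agreement']:.3f}", ""]
    if "transfer" in report:
        med = report["transfer"]["median"]
        lines += ["## Transfer learning (median Spearman, held-out MPRA)",
                  *(f"- {k}: {v:.3f}" for k, v in med.items()), ""]
    if report.get("failures"):
        lines += ["## Failures", *(f"- {k}: {v}" for k, v in
                                   report["failures"].items())]
    return "\n".join(lines) + "\n"
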