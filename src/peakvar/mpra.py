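"""Massively parallel reporter assay (MPRA) reconstruction and evaluation.

MPRA oligo records carry a focal variant, a 150 bp assayed span, a
reverse-complement flag, optional co-variant substitutions, the measured
activity (log2 RNA / plasmid DNA), and the measured allelic skew with its FDR
q-value. This module rebuilds model-length sequences around each oligo
(centre the oligo, fill flanks from the reference genome, substitute alleles,
reverse-complement the whole window when the assayed oligo was), predicts
allelic skew through a trained model, categorises expression-modulating
variants (emVars), and evaluates direction-of-effect accuracy and group-level
shifts.

Measured skew follows the repo-wide orientation: reference minus alternate,
positive when the reference allele is more active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import logit
from .seqdata import (
    GenomicInterval,
    SequenceExample,
    chromosome_split,
    fetch_sequence,
    one_hot,
    reverse_complement,
)
from .variants import VariantRecord

EMVAR_CLASSES = ("skew_positive", "skew_negative", "neutral", "unclassified")


@dataclass
class MPRAOligo:
    """One reporter-assay record for a focal variant."""

    variant: VariantRecord
    oligo_len: int = 150
    is_rc: bool = False
    covariants: tuple = ()
    activity: float = 0.0
    active: bool = False
    skew: float | None = None
    skew_q: float | None = None

    @property
    def id(self):
        return self.variant.id


@dataclass(frozen=True)
class EmVarCall:
    variant: VariantRecord
    emvar_class: str

    def __post_init__(self):
        if self.emvar_class not in EMVAR_CLASSES:
            raise ValueError(f"unknown emVar class {self.emvar_class!r}")


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _oligo_span(oligo: MPRAOligo) -> GenomicInterval:
    # focal variant at index oligo_len//2 - 1 of the span (even lengths),
    # matching the summit/variant window convention
    left = oligo.oligo_len // 2 - 1 if oligo.oligo_len % 2 == 0 else oligo.oligo_len // 2
    start = oligo.variant.pos0 - left
    if start < 0:
        raise ValueError(f"{oligo.id}: oligo span runs off the chromosome start")
    return GenomicInterval(oligo.variant.chrom, start, start + oligo.oligo_len)


def reconstruct_oligo_window(oligo: MPRAOligo, genome, allele: str = "ref",
                             target_len: int = 1000) -> str:
    """Model-length sequence around the oligo span carrying ``allele``.

    The oligo's span is centred in a ``target_len`` window (odd padding puts
    the extra base on the right); the focal allele is substituted at the
    variant position; every co-variant's alternate allele is substituted in
    both members of a ref/alt pair; finally the whole window is
    reverse-complemented when the assayed oligo was.
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    span = _oligo_span(oligo)
    pad = target_len - oligo.oligo_len
    if pad < 0:
        raise ValueError(
            f"target_len {target_len} shorter than the oligo ({oligo.oligo_len})"
        )
    left_pad = pad // 2
    window = GenomicInterval(span.chrom, span.start - left_pad,
                             span.end + (pad - left_pad))
    if window.start < 0:
        raise ValueError(f"{oligo.id}: window runs off the chromosome start")
    seq = list(fetch_sequence(genome, window))

    def substitute(variant: VariantRecord, base: str):
        idx = variant.pos0 - window.start
        if not 0 <= idx < target_len:
            raise ValueError(
                f"{oligo.id}: variant {variant.id} at {variant.chrom}:"
                f"{variant.pos} lies outside the reconstruction window"
            )
        if seq[idx] != variant.ref and seq[idx] == variant.alt:
            # already substituted (co-variant listed twice); leave as-is
            return
        if seq[idx] != variant.ref:
            raise ValueError(
                f"{oligo.id}: reference allele {variant.ref} of {variant.id} "
                f"does not match genome base {seq[idx]}"
            )
        seq[idx] = base

    for cov in oligo.covariants:
        substitute(cov, cov.alt)
    substitute(oligo.variant,
               oligo.variant.ref if allele == "ref" else oligo.variant.alt)
    out = "".join(seq)
    return reverse_complement(out) if oligo.is_rc else out


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_allelic_skew(results, oligo: MPRAOligo, genome,
                         target_len: int | None = None) -> float:
    return float(predict_allelic_skews(results, [oligo], genome, target_len)[0])


def predict_allelic_skews(results, oligos, genome,
                          target_len: int | None = None) -> np.ndarray:
    """Ref-minus-alt predicted skew for each oligo (classifier: logit scale)."""
    target_len = target_len or results.spec.input_length
    if not len(oligos):
        return np.zeros(0)
    refs = np.stack([
        one_hot(reconstruct_oligo_window(o, genome, "ref", target_len))
        for o in oligos
    ])
    alts = np.stack([
        one_hot(reconstruct_oligo_window(o, genome, "alt", target_len))
        for o in oligos
    ])
    out = results.predict(np.concatenate([refs, alts]))
    if results.spec.kind == "classifier":
        out = logit(out, eps=1e-7)
    n = len(oligos)
    return out[:n] - out[n:]


def mpra_examples(oligos, genome, target_len: int, split_spec=None):
    """Activity-labelled sequence examples (ref-allele windows) for training."""
    examples = []
    for o in oligos:
        seq = reconstruct_oligo_window(o, genome, "ref", target_len)
        span = _oligo_span(o)
        pad_left = (target_len - o.oligo_len) // 2
        iv = GenomicInterval(span.chrom, span.start - pad_left,
                             span.start - pad_left + target_len)
        examples.append(SequenceExample(iv, one_hot(seq), float(o.activity)))
    if split_spec is not None:
        chromosome_split(examples, split_spec)
    return examples


# ---------------------------------------------------------------------------
# emVar categorisation and evaluation
# ---------------------------------------------------------------------------

def categorize_emvars(oligos, skew_thr: float = 0.2, q_thr: float = 0.01) -> list:
    """Partition oligos with measured skew into emVar classes.

    skew_positive: skew >= skew_thr and q < q_thr;
    skew_negative: skew <= -skew_thr and q < q_thr;
    neutral: |skew| < skew_thr and q > q_thr; anything else is unclassified
    (confident q with small skew, or large skew with poor q).
    """
    calls = []
    for o in oligos:
        if o.skew is None or o.skew_q is None:
            continue
        if o.skew >= skew_thr and o.skew_q < q_thr:
            cls = "skew_positive"
        elif o.skew <= -skew_thr and o.skew_q < q_thr:
            cls = "skew_negative"
        elif abs(o.skew) < skew_thr and o.skew_q > q_thr:
            cls = "neutral"
        else:
            cls = "unclassified"
        calls.append(EmVarCall(o.variant, cls))
    return calls


def direction_accuracy(predicted, measured_skew, q, q_cutoffs,
                       skew_thr: float = 0.2) -> pd.DataFrame:
    """Direction-of-effect accuracy at increasingly stringent emVar cutoffs.

    At each q cutoff, emVars are records with |skew| >= skew_thr and
    q < cutoff; accuracy is the fraction whose predicted skew sign matches
    the measured sign, and majority_baseline the larger measured-sign class
    fraction (the naive always-majority classifier). Cutoffs with zero emVars
    yield NaN rows.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured_skew, dtype=float)
    q = np.asarray(q, dtype=float)
    rows = []
    for cutoff in q_cutoffs:
        mask = (np.abs(measured) >= skew_thr) & (q < cutoff)
        n = int(mask.sum())
        if n == 0:
            rows.append({"q_cutoff": cutoff, "n_emvars": 0,
                         "accuracy": np.nan, "majority_baseline": np.nan})
            continue
        signs_true = np.sign(measured[mask])
        signs_pred = np.sign(predicted[mask])
        acc = float(np.mean(signs_pred == signs_true))
        pos_frac = float(np.mean(signs_true > 0))
        rows.append({
            "q_cutoff": cutoff,
            "n_emvars": n,
            "accuracy": acc,
            "majority_baseline": max(pos_frac, 1.0 - pos_frac),
        })
    return pd.DataFrame(rows)


def skew_group_ttests(predicted, emvar_classes) -> dict:
    """One-sample t-tests of predicted skew shifts per emVar class.

    skew_positive: mean > 0 (one-sided); skew_negative: mean < 0 (one-sided);
    neutral: mean != 0 (two-sided). Groups of fewer than 3 members give NaN
    with a warning. ``unclassified`` records are excluded.
    """
    predicted = np.asarray(predicted, dtype=float)
    classes = np.asarray(
        [c.emvar_class if isinstance(c, EmVarCall) else c for c in emvar_classes]
    )
    if predicted.size != classes.size:
        raise ValueError("predicted and classes must align")

    def one(group, alternative):
        vals = predicted[classes == group]
        if vals.size < 3:
            warnings.warn(
                f"{group}: only {vals.size} members, t-test skipped",
                stacklevel=2,
            )
            return float("nan")
        return float(sps.ttest_1samp(vals, 0.0, alternative=alternative).pvalue)

    return {
        "p_pos": one("skew_positive", "greater"),
        "p_neg": one("skew_negative", "less"),
        "p_neutral": one("neutral", "two-sided"),
    }


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _covariants_to_str(covariants) -> str:
    return ",".join(f"{c.chrom}:{c.pos}:{c.ref}:{c.alt}" for c in covariants)


def _covariants_from_str(s) -> tuple:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return ()
    out = []
    for i, item in enumerate(str(s).split(",")):
        chrom, pos, ref, alt = item.split(":")
        out.append(VariantRecord(chrom, int(pos), ref, alt, f"cov{i}"))
    return tuple(out)


def write_mpra_table(oligos, path) -> None:
    df = pd.DataFrame(
        {
            "id": [o.id for o in oligos],
            "chrom": [o.variant.chrom for o in oligos],
            "pos": [o.variant.pos for o in oligos],
            "ref": [o.variant.ref for o in oligos],
            "alt": [o.variant.alt for o in oligos],
            "oligo_len": [o.oligo_len for o in oligos],
            "is_rc": [int(o.is_rc) for o in oligos],
            "covariants": [_covariants_to_str(o.covariants) for o in oligos],
            "activity": [o.activity for o in oligos],
            "active": [int(o.active) for o in oligos],
            "skew": [np.nan if o.skew is None else o.skew for o in oligos],
            "skew_q": [np.nan if o.skew_q is None else o.skew_q for o in oligos],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_mpra_table(path) -> list[MPRAOligo]:
    df = pd.read_csv(path, sep="\t")
    oligos = []
    for _, row in df.iterrows():
        variant = VariantRecord(str(row["chrom"]), int(row["pos"]),
                                str(row["ref"]), str(row["alt"]),
                                str(row["id"]))
        oligos.append(
            MPRAOligo(
                variant=variant,
                oligo_len=int(row.get("oligo_len", 150)),
                is_rc=bool(int(row["is_rc"])),
                covariants=_covariants_from_str(row.get("covariants", "")),
                activity=float(row["activity"]),
                active=bool(int(row["active"])),
                skew=None if pd.isna(row["skew"]) else float(row["skew"]),
                skew_q=None if pd.isna(row["skew_q"]) else float(row["skew_q"]),
            )
        )
    return oligos
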