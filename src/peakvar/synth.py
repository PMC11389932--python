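"""Seeded synthetic genomes, peaks, variants and MPRA tables.

Every other module is testable without downloads: this module fabricates a
small genome of i.i.d. background sequence, plants transcription-factor
motif instances whose position-weight-matrix (PWM) log-odds drive a
quantitative "accessibility" signal, derives variants with known effect
direction (motif-disrupting vs neutral), and emits a reporter-assay table
with measured activity/skew and replicate-based q-values.

The generative model is deliberately the simplest one under which a CNN
regression is well specified: peak signal is a linear function of the best
planted motif log-odds per factor plus Gaussian noise, truncated at zero.
Reporter activity uses its own per-motif weights — the architectural
(CTCF-like) factor contributes to chromatin accessibility but not to the
episomal reporter — which is what makes fine-tuning on reporter data
genuinely informative in the transfer-learning benchmark.

All randomness flows from ``SyntheticSpec.seed``; artifacts are
byte-identical across runs with the same spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mpra import MPRAOligo, write_mpra_table
from .seqdata import GenomicInterval, Peak, write_narrowpeak
from .variants import VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _pwm(consensus: str, p_consensus: float) -> np.ndarray:
    """4 x w probability matrix concentrated on a consensus (columns sum to 1)."""
    w = len(consensus)
    rest = (1.0 - p_consensus) / 3.0
    pwm = np.full((4, w), rest)
    for j, base in enumerate(consensus):
        pwm["ACGT".index(base), j] = p_consensus
    return pwm


# CEBP-like activator and CTCF-like architectural factor
DEFAULT_MOTIFS = (
    {"name": "cebp", "pwm": _pwm("TTGCGCAA", 0.85), "weight": 0.45,
     "mpra_weight": 0.45},
    {"name": "ctcf", "pwm": _pwm("CCGCGTAGGGGC", 0.80), "weight": 0.20,
     "mpra_weight": 0.0},
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults are sized so the full pipeline (train, score, MPRA, transfer)
    runs on one CPU in minutes: a 1 Mb genome in 4 chromosomes (chromosome-
    holdout splits need whole chromosomes for train/val/test), 400 peaks,
    two motifs, 200 disease-like variants, 2000 background variants and a
    600-oligo reporter table.
    """

    n_chroms: int = 4
    chrom_len: int = 250_000
    gc_background: float = 0.41
    motifs: tuple = DEFAULT_MOTIFS
    n_peaks: int = 400
    peak_width: int = 500
    signal_base: float = 1.0
    signal_noise_sd: float = 0.25
    n_disease_variants: int = 200
    frac_disrupting: float = 0.5
    n_background_variants: int = 2000
    n_mpra_oligos: int = 600
    oligo_len: int = 150
    mpra_noise_sd: float = 0.25
    mpra_replicates: int = 5
    mpra_active_quantile: float = 0.6
    mpra_rc_fraction: float = 0.2
    mpra_covariant_fraction: float = 0.1
    seed: int = 7

    def __post_init__(self):
        for m in self.motifs:
            cols = np.asarray(m["pwm"]).sum(axis=0)
            if not np.allclose(cols, 1.0):
                raise ValueError(f"PWM columns of {m['name']} must sum to 1")
        if self.chrom_len < 10_000:
            raise ValueError("chrom_len must comfortably hold model windows")
        if not 0 <= self.frac_disrupting <= 1:
            raise ValueError("frac_disrupting must be in [0, 1]")

    @property
    def background_probs(self) -> np.ndarray:
        gc = self.gc_background
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """What was planted: motif placements and per-variant/oligo true effects."""

    placements: list = field(default_factory=list)  # dicts per motif instance
    peak_signal_true: dict = field(default_factory=dict)  # peak name -> signal
    variant_truth: dict = field(default_factory=dict)  # id -> dict
    oligo_truth: dict = field(default_factory=dict)  # id -> dict

    def to_json(self, path):
        def clean(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            json.dump(
                clean({
                    "placements": self.placements,
                    "peak_signal_true": self.peak_signal_true,
                    "variant_truth": self.variant_truth,
                    "oligo_truth": self.oligo_truth,
                }),
                fh,
            )


class SyntheticGenome:
    """Mutable in-memory genome exposing the mapping protocol fetch needs."""

    def __init__(self, sequences: dict):
        self._arrays = sequences  # chrom -> numpy S1 array
        self._cache: dict[str, str] = {}

    def keys(self):
        return self._arrays.keys()

    def __contains__(self, chrom):
        return chrom in self._arrays

    def __getitem__(self, chrom) -> str:
        if chrom not in self._cache:
            self._cache[chrom] = self._arrays[chrom].tobytes().decode()
        return self._cache[chrom]

    def write(self, chrom: str, start: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        self._arrays[chrom][start : start + len(arr)] = arr
        self._cache.pop(chrom, None)

    def write_fasta(self, path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.keys():
                fh.write(f">{chrom}\n")
                seq = self[chrom]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        try:
            import pyfaidx

            pyfaidx.Faidx(str(path))
        except Exception:  # index is a convenience; plain FASTA still valid
            pass


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def make_genome(spec: SyntheticSpec, rng=None) -> SyntheticGenome:
    """i.i.d. background genome at the requested G+C composition."""
    rng = rng or np.random.default_rng(spec.seed)
    seqs = {
        chrom: rng.choice(_BASES, p=spec.background_probs, size=spec.chrom_len)
        for chrom in spec.chrom_names()
    }
    return SyntheticGenome(seqs)


def _sample_motif(pwm, rng) -> tuple[str, float, np.ndarray]:
    """Draw an instance from the PWM; return (sequence, log-odds, base idx)."""
    w = pwm.shape[1]
    idx = np.array([rng.choice(4, p=pwm[:, j]) for j in range(w)])
    seq = "".join("ACGT"[i] for i in idx)
    return seq, 0.0, idx


def _log_odds(pwm, idx, background_probs) -> float:
    probs = pwm[idx, np.arange(len(idx))]
    return float(np.sum(np.log2(probs / background_probs[idx])))


def plant_peaks(genome: SyntheticGenome, spec: SyntheticSpec, rng=None,
                truth: GroundTruth | None = None):
    """Plant 1-3 motif instances per peak and assign a signal.

    signal = base + sum over motifs of weight * (best planted log-odds of
    that motif in the peak) + Normal(0, noise), truncated at 0. The summit is
    the centre of the strongest (weight x log-odds) instance.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    truth = truth if truth is not None else GroundTruth()
    chroms = spec.chrom_names()
    per_chrom = int(np.ceil(spec.n_peaks / len(chroms)))
    margin = 600  # keep full model windows inside the chromosome
    width = spec.peak_width
    slot = (spec.chrom_len - 2 * margin) // per_chrom
    if slot < width + 50:
        raise ValueError("too many peaks for the genome size")

    peaks = []
    k = 0
    bg = spec.background_probs
    for chrom in chroms:
        for j in range(per_chrom):
            if k >= spec.n_peaks:
                break
            start = margin + j * slot + int(rng.integers(0, slot - width))
            iv = GenomicInterval(chrom, start, start + width)
            n_inst = int(rng.integers(1, 4))
            placed = []
            for _ in range(n_inst):
                mi = int(rng.integers(0, len(spec.motifs)))
                motif = spec.motifs[mi]
                w = motif["pwm"].shape[1]
                lo_pos = iv.start + width // 2
                offset = int(rng.integers(-width // 3, width // 3 - w))
                mstart = lo_pos + offset
                if any(not (mstart + w <= p["start"] or mstart >= p["end"])
                       for p in placed):
                    continue  # skip overlapping placements
                seq, _, idx = _sample_motif(motif["pwm"], rng)
                lo = _log_odds(motif["pwm"], idx, bg)
                genome.write(chrom, mstart, seq)
                placed.append({
                    "motif": mi, "name": motif["name"], "chrom": chrom,
                    "start": mstart, "end": mstart + w, "log_odds": lo,
                    "weight": motif["weight"],
                    "mpra_weight": motif["mpra_weight"],
                    "base_idx": idx.tolist(), "peak": f"peak{k}",
                })
            if not placed:  # guarantee at least one instance
                motif = spec.motifs[0]
                w = motif["pwm"].shape[1]
                mstart = iv.start + width // 2
                seq, _, idx = _sample_motif(motif["pwm"], rng)
                genome.write(chrom, mstart, seq)
                placed.append({
                    "motif": 0, "name": motif["name"], "chrom": chrom,
                    "start": mstart, "end": mstart + w,
                    "log_odds": _log_odds(motif["pwm"], idx, bg),
                    "weight": motif["weight"],
                    "mpra_weight": motif["mpra_weight"],
                    "base_idx": idx.tolist(), "peak": f"peak{k}",
                })
            best_per_motif = {}
            for p in placed:
                best_per_motif[p["motif"]] = max(
                    best_per_motif.get(p["motif"], 0.0), p["log_odds"]
                )
            true_signal = spec.signal_base + sum(
                spec.motifs[mi]["weight"] * lo for mi, lo in best_per_motif.items()
            )
            signal = max(0.0, true_signal + rng.normal(0, spec.signal_noise_sd))
            strongest = max(placed, key=lambda p: p["weight"] * p["log_odds"])
            summit = (strongest["start"] + strongest["end"]) // 2
            name = f"peak{k}"
            peaks.append(Peak(iv, summit, signal, name))
            truth.placements.extend(placed)
            truth.peak_signal_true[name] = true_signal
            k += 1
    return peaks, truth


def _effect_of_substitution(motif, col: int, ref_idx: int, alt_idx: int,
                            weight_key: str) -> float:
    pwm = motif["pwm"]
    p_ref = max(pwm[ref_idx, col], 1e-3)
    p_alt = max(pwm[alt_idx, col], 1e-3)
    return float(motif[weight_key] * np.log2(p_ref / p_alt))


def plant_variants(peaks, truth: GroundTruth, genome: SyntheticGenome,
                   spec: SyntheticSpec, rng=None):
    """Disease-like variants with known effects, plus a neutral background.

    Disrupting variants sit at the most informative PWM column of a planted
    instance whose planted base is strong (probability >= 0.5), with the
    least-likely base as alternate — guaranteeing a log-odds change of more
    than 1 bit. Neutral disease-like variants and the background set sit in
    peak sequence outside every motif footprint, so their true effect is 0.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    placements_by_peak: dict[str, list] = {}
    for p in truth.placements:
        placements_by_peak.setdefault(p["peak"], []).append(p)
    peak_by_name = {pk.name: pk for pk in peaks}

    n_disrupt = int(round(spec.frac_disrupting * spec.n_disease_variants))
    disease = []

    # motif-affecting variants at the most informative PWM column of a
    # planted instance: loss-of-function when the planted base is strong
    # (alternate = least likely base, positive effect = ref more active),
    # gain-of-function when the planted base is weak (alternate = consensus,
    # negative effect). Both directions change the log-odds by > 1 bit.
    losses, gains = [], []
    for p in truth.placements:
        motif = spec.motifs[p["motif"]]
        col = int(np.argmax(motif["pwm"].max(axis=0)))
        ref_idx = p["base_idx"][col]
        if motif["pwm"][ref_idx, col] >= 0.5:
            alt_idx = int(np.argmin(motif["pwm"][:, col]))
            losses.append((p, col, ref_idx, alt_idx))
        else:
            alt_idx = int(np.argmax(motif["pwm"][:, col]))
            if alt_idx != ref_idx:
                gains.append((p, col, ref_idx, alt_idx))
    if not losses and not gains:
        raise ValueError("no motif positions available for disrupting variants")
    candidates = [losses[i] for i in rng.permutation(len(losses))] + []
    gain_pool = [gains[i] for i in rng.permutation(len(gains))]
    # interleave so that roughly a quarter of motif-affecting variants are
    # gain-of-function (when available), giving both effect signs
    mixed = []
    gi = 0
    for i, cand in enumerate(candidates):
        if gi < len(gain_pool) and i % 3 == 0:
            mixed.append(gain_pool[gi])
            gi += 1
        mixed.append(cand)
    mixed.extend(gain_pool[gi:])
    used_positions = set()
    for p, col, ref_idx, alt_idx in mixed:
        if len(disease) >= n_disrupt:
            break
        pos0 = p["start"] + col
        if (p["chrom"], pos0) in used_positions:
            continue
        used_positions.add((p["chrom"], pos0))
        motif = spec.motifs[p["motif"]]
        vid = f"dis{len(disease)}"
        v = VariantRecord(p["chrom"], pos0 + 1, "ACGT"[ref_idx],
                          "ACGT"[alt_idx], vid)
        effect = _effect_of_substitution(motif, col, ref_idx, alt_idx, "weight")
        mpra_effect = _effect_of_substitution(motif, col, ref_idx, alt_idx,
                                              "mpra_weight")
        disease.append(v)
        truth.variant_truth[vid] = {
            "kind": "disrupting", "true_effect": effect,
            "true_mpra_effect": mpra_effect,
            "sign": float(np.sign(effect)), "peak": p["peak"],
        }

    footprints = {
        (p["chrom"], pos)
        for p in truth.placements
        for pos in range(p["start"] - 2, p["end"] + 2)
    }

    def sample_nonmotif(prefix, count, start_index=0):
        out = []
        widths = np.array([len(pk.interval) for pk in peaks], dtype=float)
        probs = widths / widths.sum()
        while len(out) < count:
            pk = peaks[int(rng.choice(len(peaks), p=probs))]
            pos0 = int(rng.integers(pk.interval.start, pk.interval.end))
            if (pk.interval.chrom, pos0) in footprints:
                continue
            if (pk.interval.chrom, pos0) in used_positions:
                continue
            used_positions.add((pk.interval.chrom, pos0))
            ref = genome[pk.interval.chrom][pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            vid = f"{prefix}{start_index + len(out)}"
            out.append(VariantRecord(pk.interval.chrom, pos0 + 1, ref, alt, vid))
            truth.variant_truth[vid] = {
                "kind": "neutral" if prefix == "neu" else "background",
                "true_effect": 0.0, "true_mpra_effect": 0.0, "sign": 0.0,
                "peak": pk.name,
            }
        return out

    disease.extend(sample_nonmotif("neu", spec.n_disease_variants - len(disease)))
    background = sample_nonmotif("bg", spec.n_background_variants)
    return disease, background, truth


def make_mpra(peaks, disease_variants, background_variants, truth: GroundTruth,
              genome: SyntheticGenome, spec: SyntheticSpec, rng=None):
    """Reporter-assay oligo table with measured activity, skew and q-values.

    Activity of the (ref-allele) oligo is the reporter-weighted motif content
    of its 150 bp span plus noise; measured skew is the true reporter-scale
    allelic effect plus noise; q-values come from a two-sample t-test on
    simulated replicate measurements of each allele, BH-corrected across
    oligos. ~20%% of records are reverse-complemented and ~10%% carry one
    non-motif co-variant.
    """
    rng = rng or np.random.default_rng(spec.seed + 3)
    chosen = list(disease_variants)
    n_extra = max(0, spec.n_mpra_oligos - len(chosen))
    if n_extra and background_variants:
        idx = rng.choice(len(background_variants),
                         size=min(n_extra, len(background_variants)),
                         replace=False)
        chosen.extend(background_variants[i] for i in sorted(idx))

    placements = truth.placements
    half = spec.oligo_len // 2

    def reporter_content(chrom, lo, hi):
        total = 0.0
        for p in placements:
            if p["chrom"] == chrom and p["start"] >= lo and p["end"] <= hi:
                total += p["mpra_weight"] * p["log_odds"]
        return total

    oligos = []
    raw_p = []
    for v in chosen:
        lo, hi = v.pos0 - (half - 1), v.pos0 + half + 1
        if lo < 0 or hi > spec.chrom_len:
            continue
        vt = truth.variant_truth[v.id]
        # the episomal reporter sees only the oligo span itself
        true_activity = reporter_content(v.chrom, lo, hi)
        true_skew = vt["true_mpra_effect"]
        activity = true_activity + rng.normal(0, spec.mpra_noise_sd)
        # replicate measurements of each allele -> two-sample t-test
        ref_reps = true_activity + rng.normal(0, spec.mpra_noise_sd,
                                              spec.mpra_replicates)
        alt_reps = (true_activity - true_skew
                    + rng.normal(0, spec.mpra_noise_sd, spec.mpra_replicates))
        skew = float(np.mean(ref_reps) - np.mean(alt_reps))
        t = sps.ttest_ind(ref_reps, alt_reps)
        raw_p.append(t.pvalue)
        is_rc = bool(rng.random() < spec.mpra_rc_fraction)
        covariants = ()
        if rng.random() < spec.mpra_covariant_fraction:
            cov = _nonmotif_covariant(v, genome, truth, spec, rng)
            if cov is not None:
                covariants = (cov,)
        oligos.append(
            MPRAOligo(variant=v, oligo_len=spec.oligo_len, is_rc=is_rc,
                      covariants=covariants, activity=float(activity),
                      active=False, skew=skew, skew_q=None)
        )
        truth.oligo_truth[v.id] = {
            "true_activity": true_activity, "true_skew": true_skew,
        }

    from statsmodels.stats.multitest import multipletests

    if oligos:
        qs = multipletests(np.asarray(raw_p), method="fdr_bh")[1]
        activities = np.array([o.activity for o in oligos])
        cut = float(np.quantile(activities, spec.mpra_active_quantile))
        for o, q in zip(oligos, qs):
            o.skew_q = float(q)
            o.active = bool(o.activity >= cut)
    return oligos, truth


def _nonmotif_covariant(v, genome, truth, spec, rng):
    footprints = {
        (p["chrom"], pos)
        for p in truth.placements
        for pos in range(p["start"] - 2, p["end"] + 2)
    }
    half = spec.oligo_len // 2
    for _ in range(20):
        offset = int(rng.integers(-(half - 5), half - 5))
        if abs(offset) < 3:
            continue
        pos0 = v.pos0 + offset
        if pos0 < 0 or pos0 >= spec.chrom_len:
            continue
        if (v.chrom, pos0) in footprints:
            continue
        ref = genome[v.chrom][pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantRecord(v.chrom, pos0 + 1, ref, alt, f"cov_{v.id}")
    return None


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticData:
    spec: SyntheticSpec
    genome: SyntheticGenome
    peaks: list
    disease_variants: list
    background_variants: list
    oligos: list
    truth: GroundTruth


def generate(spec: SyntheticSpec | None = None, outdir=None) -> SyntheticData:
    """Run all stages; optionally write genome.fa(.fai), peaks.narrowPeak,
    variants.tsv, background.tsv, mpra.tsv and truth.json to ``outdir``."""
    spec = spec or SyntheticSpec()
    genome = make_genome(spec)
    peaks, truth = plant_peaks(genome, spec)
    disease, background, truth = plant_variants(peaks, truth, genome, spec)
    oligos, truth = make_mpra(peaks, disease, background, truth, genome, spec)
    data = SyntheticData(spec, genome, peaks, disease, background, oligos, truth)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        genome.write_fasta(os.path.join(outdir, "genome.fa"))
        write_narrowpeak(peaks, os.path.join(outdir, "peaks.narrowPeak"))
        _write_variant_tsv(disease, os.path.join(outdir, "variants.tsv"))
        _write_variant_tsv(background, os.path.join(outdir, "background.tsv"))
        write_mpra_table(oligos, os.path.join(outdir, "mpra.tsv"))
        truth.to_json(os.path.join(outdir, "truth.json"))
    return data


def _write_variant_tsv(variants, path):
    pd.DataFrame(
        {
            "id": [v.id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)
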