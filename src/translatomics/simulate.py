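"""Synthetic study generator with planted ground truth.

Emulates every input the analysis pipeline consumes, for a pulsed-SILAC
study of mutant versus wild-type astrocytes:

* a replicate ratio table with log-normal (log2-scale Gaussian) noise,
  label-swapped replicates and random missingness, where a configurable
  fraction of proteins is regulated with a strong upward bias
  (``up_bias``, default 0.9 — roughly nine of ten regulated proteins up);
* transcript sets with one to several mRNA variants per protein, whose
  5'-UTRs are longer and carry more context-valid upstream start codons in
  the regulated group;
* signal-peptide / transmembrane annotation flags, either drawn per-group
  Bernoulli or as an exact study-scale fixture reproducing the printed
  group-by-trait marginals of the secretory-pathway summary;
* a metabolite peak table with one planted mutant-only metabolite and
  medium metabolites shifted up (secreted) or down (consumed) against an
  unconditioned reference.

Each generator draws from its own named substream of the master seed, so
adding one generator never perturbs another's output, and a fixed seed
reproduces every table byte-for-byte.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexp import QuantTable
from .metabolome import PeakTable
from .targeting import AnnotationRecord
from .utr import DEFAULT_RULE, TranscriptRecord, UORFRule

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "TABLE3_COUNTS",
    "draw_truth_labels",
    "gen_proteome",
    "gen_transcripts",
    "gen_annotations",
    "gen_metabolome",
    "gen_study",
    "table3_fixture",
]

GROUPS = ("regulated", "non_regulated")

# study-scale fixture: group -> (n, n_sp, n_tm, n_both)
TABLE3_COUNTS = {
    "all": (1240, 237, 177, 97),
    "regulated": (80, 27, 24, 13),
    "upregulated": (72, 27, 24, 13),
    "downregulated": (8, 0, 0, 0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults encode the scale and effect structure of the emulated study:
    1240 quantifiable proteins of which ~80 regulated, ~90% of those up,
    twofold regulation (1 log2 unit) against 0.25 log2 units of replicate
    noise in 4 replicates, two of which are label-swapped. Regulated-group
    5'-UTRs are drawn longer (log-normal, median ~365 vs ~148 nt) with a
    higher expected number of planted upstream starts (3.5 vs 1.5).
    """

    seed: int = 0
    n_proteins: int = 1240
    frac_regulated: float = 80 / 1240
    up_bias: float = 0.9
    effect_log2: float = 1.0
    noise_sd: float = 0.25
    n_replicates: int = 4
    missing_rate: float = 0.1
    variants_per_protein_max: int = 4
    variant_geom_p: float = 0.5
    utr_length_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "regulated": (5.9, 0.9),
            "non_regulated": (5.0, 0.9),
        }
    )
    gc_fraction: float = 0.6
    uorf_rate: Mapping[str, float] = field(
        default_factory=lambda: {"regulated": 3.5, "non_regulated": 1.5}
    )
    # group -> (p_signal_peptide, p_transmembrane, p_both); marginals include both
    sp_tm_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "regulated": (0.34, 0.30, 0.16),
            "non_regulated": (0.18, 0.13, 0.07),
        }
    )
    # metabolome scales
    n_metabolites: int = 12
    metab_replicates: int = 2
    metab_timepoints: tuple[float, ...] = (24.0, 72.0)
    metab_intensity_scale: float = 1e6
    metab_sigma: float = 0.25
    consumed_factor: float = 0.4
    secreted_factor: float = 2.5

    def __post_init__(self) -> None:
        fractions = {
            "frac_regulated": self.frac_regulated,
            "up_bias": self.up_bias,
            "missing_rate": self.missing_rate,
            "gc_fraction": self.gc_fraction,
            "variant_geom_p": self.variant_geom_p,
        }
        for name, value in fractions.items():
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0,1], got {value}")
        for name in ("effect_log2", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.variants_per_protein_max < 1:
            raise ValueError("variants_per_protein_max must be >= 1")
        for g, (p_sp, p_tm, p_both) in self.sp_tm_probs.items():
            if p_both > min(p_sp, p_tm):
                raise ValueError(f"sp_tm_probs[{g!r}]: p_both exceeds a marginal")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (independent per generator)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticStudy:
    quant_table: QuantTable
    truth_labels: pd.Series  # protein_id -> up | down | null
    transcripts: list[TranscriptRecord]
    planted_uorfs: dict[str, list[int]]  # transcript_id -> 1-based UTR positions
    annotations: list[AnnotationRecord]
    groups: dict[str, set[str]]  # protein_id -> group labels
    peaks: PeakTable
    metabolite_truth: dict[str, list[str]]


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def draw_truth_labels(config: SimConfig) -> pd.Series:
    """Planted regulation labels (up/down/null), one Bernoulli stream.

    Exposed separately so the label stream can be re-drawn independently of
    the ratio noise for verification.
    """
    rng = config.rng("proteome-labels")
    ids = _protein_ids(config.n_proteins)
    regulated = rng.random(config.n_proteins) < config.frac_regulated
    up = rng.random(config.n_proteins) < config.up_bias
    labels = np.where(regulated, np.where(up, "up", "down"), "null")
    return pd.Series(labels, index=ids, name="truth")


def gen_proteome(config: SimConfig) -> tuple[QuantTable, pd.Series]:
    """Replicate log2-ratio table with planted regulation and label swaps.

    Null proteins draw around 0, regulated around +/- ``effect_log2``; each
    cell goes missing independently at ``missing_rate``. The second half of
    the replicates is label-swapped: stored as log2(wt/mutant), to be
    re-oriented downstream.
    """
    truth = draw_truth_labels(config)
    n, reps = config.n_proteins, config.n_replicates
    effect = np.where(
        truth == "up", config.effect_log2, np.where(truth == "down", -config.effect_log2, 0.0)
    )
    rng = config.rng("proteome-noise")
    ratios = effect[:, None] + rng.normal(0.0, config.noise_sd, size=(n, reps))
    missing = config.rng("proteome-missing").random((n, reps)) < config.missing_rate
    ratios[missing] = np.nan

    columns = [f"rep{j + 1}" for j in range(reps)]
    orientation = {
        c: ("swapped" if j >= reps - reps // 2 else "standard")
        for j, c in enumerate(columns)
    }
    data = pd.DataFrame(ratios, index=truth.index, columns=columns)
    for c in columns:
        if orientation[c] == "swapped":
            data[c] = -data[c]  # stored in raw label orientation
    return QuantTable(data, orientation), truth


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _plant_uorf(seq: np.ndarray, pos: int, rng: np.random.Generator, rule: UORFRule) -> None:
    """Overwrite a context-valid start at 1-based ``pos`` (window pos-3..pos+3)."""
    i = pos - 1
    seq[i - 3] = rng.choice(sorted(rule.minus3_allowed))
    codon = rng.choice(sorted(rule.start_codons))
    seq[i : i + 3] = list(codon)
    seq[i + 3] = rule.plus4_required


def gen_transcripts(
    config: SimConfig,
    truth: pd.Series,
    rule: UORFRule = DEFAULT_RULE,
) -> tuple[list[TranscriptRecord], dict[str, list[int]]]:
    """Transcript variants with group-dependent UTR length and planted uORFs.

    Each protein gets 1..``variants_per_protein_max`` variants (truncated
    geometric). UTR lengths are log-normal per group; sequences are i.i.d.
    at the configured GC, then Poisson-many context-valid upstream starts
    are overwritten at non-overlapping positions at least 3 nt from the 5'
    end, so every planted start is recoverable by the scanner. The main
    ORF (AUG + 30 nt + stop) follows; ``cds_start`` = UTR length + 1.
    """
    rng = config.rng("transcripts")
    records: list[TranscriptRecord] = []
    planted: dict[str, list[int]] = {}
    for pid, label in truth.items():
        group = "regulated" if label in ("up", "down") else "non_regulated"
        loc, scale = config.utr_length_params[group]
        k = min(int(rng.geometric(config.variant_geom_p)), config.variants_per_protein_max)
        for v in range(k):
            utr_len = int(round(float(rng.lognormal(loc, scale))))
            utr_len = max(1, utr_len)
            if utr_len < 1:
                raise ValueError("requested UTR length < 1")
            utr = _random_rna(rng, utr_len, config.gc_fraction)
            positions: list[int] = []
            n_plant = int(rng.poisson(config.uorf_rate[group]))
            if n_plant > 0 and utr_len >= 7:
                # candidate 1-based starts whose 7-nt context window fits the UTR
                candidates = rng.permutation(np.arange(4, utr_len - 2))
                for p in candidates:
                    if len(positions) == n_plant:
                        break
                    if all(abs(int(p) - q) >= 7 for q in positions):
                        positions.append(int(p))
                for p in sorted(positions):
                    _plant_uorf(utr, p, rng, rule)
            cds = ["A", "U", "G"] + list(_random_rna(rng, 30, config.gc_fraction)) + ["U", "A", "A"]
            tid = f"{pid}.{v + 1}"
            records.append(
                TranscriptRecord(tid, pid, "".join(utr) + "".join(cds), utr_len + 1)
            )
            planted[tid] = sorted(positions)
    return records, planted


def _flag_records(
    ids: list[str], n_both: int, n_sp_only: int, n_tm_only: int
) -> list[AnnotationRecord]:
    recs = []
    for i, pid in enumerate(ids):
        sp = i < n_both + n_sp_only
        tm = i < n_both or n_both + n_sp_only <= i < n_both + n_sp_only + n_tm_only
        recs.append(AnnotationRecord(pid, sp, tm))
    return recs


def table3_fixture(
    truth: pd.Series | None = None,
) -> tuple[list[AnnotationRecord], dict[str, set[str]]]:
    """Study-scale annotation fixture reproducing the printed group marginals.

    1240 proteins: 237 with a signal peptide, 177 with a transmembrane
    domain, 97 with both (union 317); a regulated subset of 80 (72 up with
    27/24/13, 8 down with no flags). If ``truth`` is given it must contain
    exactly 1240 proteins with 72 up and 8 down; otherwise synthetic ids
    are used.
    """
    if truth is not None:
        counts = truth.value_counts()
        if len(truth) != 1240 or counts.get("up", 0) != 72 or counts.get("down", 0) != 8:
            raise ValueError(
                "table3 fixture requires 1240 proteins with exactly 72 up and 8 down"
            )
        up_ids = list(truth.index[truth == "up"])
        down_ids = list(truth.index[truth == "down"])
        rest_ids = list(truth.index[truth == "null"])
    else:
        ids = _protein_ids(1240)
        up_ids, down_ids, rest_ids = ids[:72], ids[72:80], ids[80:]

    # up: 13 both + 14 SP-only + 11 TM-only = 27 SP, 24 TM, union 38
    records = _flag_records(up_ids, 13, 14, 11)
    records += [AnnotationRecord(pid, False, False) for pid in down_ids]
    # remaining 1160: totals 237/177/97 minus the regulated 27/24/13
    records += _flag_records(rest_ids, 84, 126, 69)

    groups: dict[str, set[str]] = {}
    for pid in up_ids:
        groups[pid] = {"all", "regulated", "upregulated"}
    for pid in down_ids:
        groups[pid] = {"all", "regulated", "downregulated"}
    for pid in rest_ids:
        groups[pid] = {"all", "non-regulated"}
    return records, groups


def gen_annotations(
    config: SimConfig,
    truth: pd.Series,
    mode: str = "stochastic",
) -> tuple[list[AnnotationRecord], dict[str, set[str]]]:
    """Signal-peptide / transmembrane flags per protein.

    ``mode="stochastic"`` draws flags per group from the configured
    (p_sp, p_tm, p_both) with the stated overlap; ``mode="table3"``
    delegates to :func:`table3_fixture` and requires a compatible truth
    vector (1240 proteins, 72 up, 8 down).
    """
    if mode == "table3":
        return table3_fixture(truth)
    if mode != "stochastic":
        raise ValueError(f"unknown annotation mode {mode!r}")
    rng = config.rng("annotations")
    records = []
    groups: dict[str, set[str]] = {}
    for pid, label in truth.items():
        group = "regulated" if label in ("up", "down") else "non_regulated"
        p_sp, p_tm, p_both = config.sp_tm_probs[group]
        u = rng.random()
        if u < p_both:
            sp = tm = True
        elif u < p_sp:
            sp, tm = True, False
        elif u < p_sp + (p_tm - p_both):
            sp, tm = False, True
        else:
            sp = tm = False
        records.append(AnnotationRecord(pid, sp, tm))
        if label == "up":
            groups[pid] = {"all", "regulated", "upregulated"}
        elif label == "down":
            groups[pid] = {"all", "regulated", "downregulated"}
        else:
            groups[pid] = {"all", "non-regulated"}
    return records, groups


def gen_metabolome(config: SimConfig) -> tuple[PeakTable, dict[str, list[str]]]:
    """Metabolite peak table with planted presence and uptake structure.

    Generic metabolites are log-normal everywhere. One planted metabolite
    ("ppp_intermediate") is present in mutant cells at every timepoint and
    absent (zero) in wt cells. Two medium metabolites are planted below
    ("uptake_*": consumed) and two above ("secreted_*": released) the
    unconditioned-medium reference in both genotypes.
    """
    rng = config.rng("metabolome")
    generic = [f"M{i + 1:03d}" for i in range(config.n_metabolites)]
    planted_cell = ["ppp_intermediate"]
    consumed = ["uptake_a", "uptake_b"]
    secreted = ["secreted_a", "secreted_b"]
    metabolites = generic + planted_cell + consumed + secreted

    samples, meta_rows = [], []
    for g in ("wt", "mutant"):
        for comp in ("cell", "medium"):
            for tp in config.metab_timepoints:
                for r in range(config.metab_replicates):
                    sid = f"{g}_{comp}_t{int(tp)}_r{r + 1}"
                    samples.append(sid)
                    meta_rows.append((sid, g, comp, tp))
    for r in range(config.metab_replicates):
        sid = f"unconditioned_r{r + 1}"
        samples.append(sid)
        meta_rows.append((sid, "none", "unconditioned", 0.0))

    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "genotype", "compartment", "timepoint"]
    ).set_index("sample_id")

    base = config.metab_intensity_scale * rng.lognormal(0.0, 1.0, size=len(metabolites))
    data = pd.DataFrame(0.0, index=metabolites, columns=samples)
    for j, sid in enumerate(samples):
        g = meta.loc[sid, "genotype"]
        comp = meta.loc[sid, "compartment"]
        noise = rng.lognormal(0.0, config.metab_sigma, size=len(metabolites))
        level = base * noise
        for i, m in enumerate(metabolites):
            x = level[i]
            if m in planted_cell:
                if comp == "cell" and g == "mutant":
                    pass  # present at base level
                else:
                    x = 0.0
            elif m in consumed and comp == "medium":
                x *= config.consumed_factor
            elif m in secreted and comp == "medium":
                x *= config.secreted_factor
            data.iloc[i, j] = x

    truth = {"mutant_only": planted_cell, "consumed": consumed, "secreted": secreted}
    return PeakTable(data, meta), truth


def gen_study(config: SimConfig, annotation_mode: str = "stochastic") -> SyntheticStudy:
    """Generate every pipeline input with planted, recoverable ground truth."""
    quant, truth = gen_proteome(config)
    transcripts, planted = gen_transcripts(config, truth)
    annotations, groups = gen_annotations(config, truth, mode=annotation_mode)
    peaks, metab_truth = gen_metabolome(config)
    return SyntheticStudy(
        quant, truth, transcripts, planted, annotations, groups, peaks, metab_truth
    )
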