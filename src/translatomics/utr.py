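"""5'-UTR extraction and translational-feature computation.

A transcript record carries the full mRNA sequence and the 1-based position
of the first base of the main start codon (``cds_start``); everything
upstream is the 5'-UTR. Features computed per UTR:

* length (nt) — UTRs shorter than a configurable minimum (default 13 nt)
  are excluded from analysis, since start codons that close to the cap
  initiate poorly;
* GC percentage;
* upstream-ORF starts: near-cognate start codons (AUG/CUG/GUG/UUG/ACG by
  default) in a favourable initiation context — purine at the -3 position
  and G at +4, positions numbered with the first codon base as +1;
* folding free energy, delegated to a pluggable folding backend.

All coordinates at the interface are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "TranscriptRecord",
    "UORFRule",
    "UTRFeatures",
    "normalize_rna",
    "extract_utr",
    "gc_percent",
    "scan_uorfs",
    "compute_features",
]

_RNA_ALPHABET = frozenset("ACGUN")
_PURINES = frozenset("AG")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert to the RNA alphabet (T -> U); validate characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TranscriptRecord:
    """One mRNA variant mapped to the protein it encodes.

    ``cds_start`` is the 1-based position of the first base of the main
    start codon on ``sequence``.
    """

    transcript_id: str
    protein_id: str
    sequence: str
    cds_start: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 1 <= self.cds_start <= n - 2:
            raise ValueError(
                f"{self.transcript_id}: cds_start {self.cds_start} outside "
                f"1..{n - 2} for sequence of length {n}"
            )


@dataclass(frozen=True)
class UORFRule:
    """Operational definition of an upstream ORF start.

    A hit is a codon from ``start_codons`` lying entirely in the 5'-UTR with
    a base from ``minus3_allowed`` three positions 5' of it and
    ``plus4_required`` immediately 3' of it (the +4 base may fall at or past
    the main start). No in-frame stop is required: the start plus its
    context *is* the operational uORF. Candidates whose -3 position would
    precede the transcript start are not counted, since the context cannot
    be evaluated.
    """

    start_codons: frozenset[str] = frozenset({"AUG", "CUG", "GUG", "UUG", "ACG"})
    minus3_allowed: frozenset[str] = _PURINES
    plus4_required: str = "G"
    min_utr_length: int = 13

    def __post_init__(self) -> None:
        if not self.start_codons or not self.minus3_allowed:
            raise ValueError("start_codons and minus3_allowed must be non-empty")
        if any(len(c) != 3 for c in self.start_codons):
            raise ValueError("start codons must be trinucleotides")


DEFAULT_RULE = UORFRule()


@dataclass
class UTRFeatures:
    transcript_id: str
    protein_id: str
    length: int
    gc_percent: float | None = None
    delta_g: float | None = None
    uorf_count: int | None = None
    uorf_positions: list[int] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""


def extract_utr(record: TranscriptRecord) -> str:
    """5'-UTR of a transcript: bases 1..cds_start-1, normalized to RNA."""
    seq = normalize_rna(record.sequence)
    return seq[: record.cds_start - 1]


def gc_percent(seq: str) -> float:
    """100 * (G+C) / length; N counts in the denominator only."""
    s = normalize_rna(seq)
    if not s:
        raise ValueError("gc_percent of empty sequence is undefined")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def scan_uorfs(record: TranscriptRecord, rule: UORFRule = DEFAULT_RULE) -> list[int]:
    """1-based start positions of context-valid uORFs in the 5'-UTR.

    Every position is scanned (all three frames); overlapping hits all
    count. The codon must lie entirely upstream of ``cds_start``; the +4
    context base is read from the full transcript and may fall at or beyond
    the main start. ``N`` matches no codon or context requirement.
    """
    seq = normalize_rna(record.sequence)
    cds0 = record.cds_start - 1  # 0-based index of main start
    hits: list[int] = []
    # 1-based candidate position p needs p >= 4 (for -3) and p+2 <= cds_start-1
    for p in range(4, cds0 - 1):  # p is 1-based; codon must end before cds_start
        i = p - 1
        if seq[i - 3] not in rule.minus3_allowed:
            continue
        if seq[i : i + 3] not in rule.start_codons:
            continue
        if i + 3 >= len(seq) or seq[i + 3] != rule.plus4_required:
            continue
        hits.append(p)
    return hits


def compute_features(
    record: TranscriptRecord,
    rule: UORFRule = DEFAULT_RULE,
    fold_model: Callable[[str], "object"] | None = None,
) -> UTRFeatures:
    """Full feature vector for one transcript's 5'-UTR.

    UTRs shorter than ``rule.min_utr_length`` are excluded (reason
    ``"min_length"``) and carry no feature values. ``fold_model`` is any
    callable returning an object with a ``delta_g`` attribute (e.g.
    ``functools.partial``-wrapped :func:`translatomics.fold.mfe_fold`);
    when None, ``delta_g`` is left unset.
    """
    utr = extract_utr(record)
    n = len(utr)
    if n < rule.min_utr_length:
        return UTRFeatures(
            record.transcript_id,
            record.protein_id,
            length=n,
            excluded=True,
            reason="min_length",
        )
    positions = scan_uorfs(record, rule)
    dg = None
    if fold_model is not None:
        dg = float(fold_model(utr).delta_g)
    return UTRFeatures(
        record.transcript_id,
        record.protein_id,
        length=n,
        gc_percent=gc_percent(utr),
        delta_g=dg,
        uorf_count=len(positions),
        uorf_positions=positions,
    )
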