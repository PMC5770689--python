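"""Readers and writers for the pipeline's interchange formats.

Everything tabular is TSV with a header row; lines starting with ``#`` are
comments and carry a provenance header (package version, stage, seed,
parameters) sufficient to re-run the stage. Transcripts travel as FASTA
(uppercase RNA) plus a TSV annotation mapping transcript to protein and
1-based CDS start. Ground truth and integrated reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._version import __version__
from .diffexp import QuantTable
from .metabolome import PeakTable
from .targeting import AnnotationRecord
from .utr import TranscriptRecord, normalize_rna

__all__ = [
    "read_fasta",
    "write_fasta",
    "provenance_header",
    "read_tsv",
    "write_tsv",
    "read_quant_table",
    "write_quant_table",
    "read_transcripts",
    "write_transcripts",
    "read_annotations",
    "write_annotations",
    "read_groups",
    "write_groups",
    "read_peak_table",
    "write_peak_table",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs.

    Multi-line sequences are joined; the description after the first
    whitespace is discarded from the id. Empty files, duplicate ids and
    non-nucleotide characters raise named errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, normalize_rna(str(rec.seq))))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(normalize_rna(seq)), id=rid, description="")
        for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def provenance_header(stage: str, seed: int | None = None, **params) -> str:
    lines = [f"# translatomics v{__version__}", f"# stage: {stage}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in sorted(params.items()):
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_tsv(
    path: str | Path,
    frame: pd.DataFrame,
    stage: str,
    seed: int | None = None,
    index: bool = False,
    **params,
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed, **params))
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_quant_table(
    path: str | Path, table: QuantTable, seed: int | None = None
) -> None:
    orientation = ",".join(f"{c}={table.orientation[c]}" for c in table.data.columns)
    with open(path, "w") as fh:
        fh.write(provenance_header("quant", seed, orientation=orientation))
        table.data.to_csv(fh, sep="\t", index_label="protein_id")


def read_quant_table(path: str | Path) -> QuantTable:
    orientation: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# orientation:"):
                for item in line.split(":", 1)[1].strip().split(","):
                    col, o = item.split("=")
                    orientation[col.strip()] = o.strip()
    data = read_tsv(path, index_col="protein_id")
    if not orientation:
        orientation = {c: "standard" for c in data.columns}
    return QuantTable(data, orientation)


def write_transcripts(
    fasta_path: str | Path,
    ann_path: str | Path,
    records: Iterable[TranscriptRecord],
    seed: int | None = None,
) -> None:
    records = list(records)
    write_fasta(fasta_path, [(r.transcript_id, r.sequence) for r in records])
    frame = pd.DataFrame(
        [(r.transcript_id, r.protein_id, r.cds_start) for r in records],
        columns=["transcript_id", "protein_id", "cds_start"],
    )
    write_tsv(ann_path, frame, "transcripts", seed)


def read_transcripts(fasta_path: str | Path, ann_path: str | Path) -> list[TranscriptRecord]:
    seqs = dict(read_fasta(fasta_path))
    ann = read_tsv(ann_path)
    out = []
    for row in ann.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise ValueError(f"transcript {row.transcript_id!r} missing from FASTA")
        out.append(
            TranscriptRecord(
                row.transcript_id, row.protein_id, seqs[row.transcript_id], int(row.cds_start)
            )
        )
    return out


def write_annotations(
    path: str | Path, records: Iterable[AnnotationRecord], seed: int | None = None
) -> None:
    frame = pd.DataFrame(
        [(r.protein_id, int(r.has_signal_peptide), int(r.has_transmembrane)) for r in records],
        columns=["protein_id", "has_signal_peptide", "has_transmembrane"],
    )
    write_tsv(path, frame, "annotations", seed)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    frame = read_tsv(path)
    return [
        AnnotationRecord(str(r.protein_id), bool(r.has_signal_peptide), bool(r.has_transmembrane))
        for r in frame.itertuples(index=False)
    ]


def write_groups(
    path: str | Path, groups: Mapping[str, Iterable[str]], seed: int | None = None
) -> None:
    rows = [(pid, g) for pid, gs in groups.items() for g in sorted(gs)]
    write_tsv(path, pd.DataFrame(rows, columns=["protein_id", "group"]), "groups", seed)


def read_groups(path: str | Path) -> dict[str, set[str]]:
    frame = read_tsv(path)
    out: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.protein_id), set()).add(str(row.group))
    return out


def write_peak_table(
    peaks_path: str | Path,
    meta_path: str | Path,
    table: PeakTable,
    seed: int | None = None,
) -> None:
    long = table.data.stack().rename_axis(["metabolite", "sample_id"]).reset_index(name="intensity")
    write_tsv(peaks_path, long, "peaks", seed)
    write_tsv(meta_path, table.meta.reset_index(), "peak-metadata", seed)


def read_peak_table(peaks_path: str | Path, meta_path: str | Path) -> PeakTable:
    long = read_tsv(peaks_path)
    dup = long.duplicated(subset=["metabolite", "sample_id"])
    if dup.any():
        pair = long.loc[dup.idxmax(), ["metabolite", "sample_id"]].tolist()
        raise ValueError(f"duplicate (metabolite, sample) entry: {pair}")
    meta = read_tsv(meta_path).set_index("sample_id")
    data = long.pivot(index="metabolite", columns="sample_id", values="intensity")
    data = data[list(meta.index)]
    return PeakTable(data.fillna(0.0), meta)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
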