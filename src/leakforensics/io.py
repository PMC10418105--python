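"""Readers and writers for the pipeline's plain-text formats.

Genomes travel as FASTA with the taxon path (and, when present, the
provenance segments) encoded in the header after ``|`` delimiters; reads as
FASTQ with the true origin in the description; count matrices as TSV
(samples as rows) with a sample-metadata TSV keyed by sample id; normalized
matrices as TSV plus a JSON provenance sidecar; run configuration as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    CountMatrix,
    GenomeRecord,
    NormalizedMatrix,
    ReadRecord,
    ReadSet,
    Segment,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_normalized_tsv",
    "write_normalized_tsv",
    "RunConfig",
]


def _genome_header(g: GenomeRecord) -> str:
    segs = ",".join(
        f"{s.start}-{s.end}:{s.source_id}:{s.source_label}" for s in g.segments
    )
    return f"{g.id}|{';'.join(g.taxon_path)}|segments={segs}"


def write_fasta(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=_genome_header(g), description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Parse genomes; headers are ``id|taxon;path[|segments=...]``."""
    genomes: list[GenomeRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        header = rec.description or rec.id
        parts = header.split("|")
        if len(parts) < 2 or not parts[1]:
            raise ValueError(
                f"{path}: record {i + 1} ({rec.id!r}): header must be "
                "'id|taxon;path[|segments=...]'"
            )
        gid = parts[0]
        taxon_path = tuple(parts[1].split(";"))
        seq = str(rec.seq).upper()
        segments: list[Segment] = []
        if len(parts) > 2 and parts[2].startswith("segments="):
            for chunk in parts[2][len("segments=") :].split(","):
                span, source_id, label = chunk.split(":", 2)
                start, end = span.split("-")
                segments.append(Segment(int(start), int(end), source_id, label))
        genomes.append(
            GenomeRecord(id=gid, taxon_path=taxon_path, sequence=seq, segments=segments)
        )
    return genomes


def write_fastq(reads: ReadSet | Sequence[ReadRecord], path: str | Path) -> None:
    """Reads as FASTQ; the comment carries origin and true source."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.id} origin={r.true_origin_genome}:{r.true_origin_pos} "
                f"source={r.true_source}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n"
            )


def read_fastq(path: str | Path) -> ReadSet:
    reads: list[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        origin_genome, origin_pos = "unknown", -1
        if "origin" in fields:
            origin_genome, pos = fields["origin"].rsplit(":", 1)
            origin_pos = int(pos)
        reads.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                true_origin_genome=origin_genome,
                true_origin_pos=origin_pos,
                true_source=fields.get("source", "unknown"),
            )
        )
    return ReadSet(reads)


def write_counts_tsv(
    matrix: CountMatrix, path: str | Path, meta_path: str | Path
) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="sample_id")
    matrix.metadata.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_counts_tsv(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Counts TSV (samples x genera) plus metadata TSV keyed by sample_id.

    Cells must be non-negative integers; a sample without metadata is an
    error. Validation errors name the offending cell.
    """
    counts = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            bad = counts.index[
                pd.to_numeric(counts[col], errors="coerce").isna()
            ].tolist()
            raise ValueError(
                f"{path}: non-numeric count at sample {bad[0]!r}, genus {col!r}"
            )
    missing = counts.index.difference(meta.index).tolist()
    if missing:
        raise ValueError(f"{meta_path}: samples missing metadata: {missing[:5]}")
    return CountMatrix(counts, meta.loc[counts.index])


def write_normalized_tsv(
    matrix: NormalizedMatrix, path: str | Path, provenance_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
    if provenance_path is not None:
        Path(provenance_path).write_text(
            json.dumps(matrix.provenance, indent=2, sort_keys=True) + "\n"
        )


def read_normalized_tsv(
    path: str | Path, provenance_path: str | Path | None = None
) -> NormalizedMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    provenance = {"transform": "unknown"}
    if provenance_path is not None and Path(provenance_path).exists():
        provenance = json.loads(Path(provenance_path).read_text())
    return NormalizedMatrix(values=values, provenance=provenance)


@dataclass
class RunConfig:
    """Resolved parameters of one reproducible run; JSON round-trippable."""

    seed: int = 0
    k: int = 31
    read_length: int = 150
    error_rate: float = 0.001
    nb_mean: float = 50.0
    nb_dispersion: float = 0.5
    leak_mode: str = "class_offsets"
    offset_sd: float = 1.0
    noise_sd: float = 0.05
    prevalence_cutoff: int = 50
    inflation_thresholds: tuple[int, ...] = (10, 100)
    classifier: dict = field(
        default_factory=lambda: {
            "n_folds": 10,
            "n_estimators": 150,
            "max_depth": 3,
            "learning_rate": 0.1,
        }
    )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["inflation_thresholds"] = list(d["inflation_thresholds"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "inflation_thresholds" in d:
            d["inflation_thresholds"] = tuple(d["inflation_thresholds"])
        return cls(**d)
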