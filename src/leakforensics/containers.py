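"""Core in-memory containers shared across the pipeline.

Sequences carry a provenance track: every genome is tiled by segments that
record where each stretch of sequence truly came from, so that reads sampled
from a mislabeled ("contaminated") draft genome can later be audited against
their true origin. Count matrices pair a samples x genera integer table with
per-sample metadata (class label, sample type, library size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "GenomeRecord",
    "ReadRecord",
    "ReadSet",
    "CountMatrix",
    "NormalizedMatrix",
    "source_label",
]

HOST_DOMAIN = "Eukaryota"

#: metadata columns every CountMatrix carries
METADATA_COLUMNS = ("class_label", "sample_type", "library_size")


def source_label(taxon_path: Sequence[str]) -> str:
    """Audit label for a source genome: ``host`` or ``microbe:<genus>``.

    A genome whose domain is eukaryotic plays the role of the host; anything
    else is a microbe identified by its genus (the second-to-last taxon).
    """
    if len(taxon_path) > 1 and taxon_path[1] == HOST_DOMAIN:
        return "host"
    genus = taxon_path[-2] if len(taxon_path) >= 2 else taxon_path[-1]
    return f"microbe:{genus}"


@dataclass(frozen=True)
class Segment:
    """Half-open interval [start, end) of a genome with its true source."""

    start: int
    end: int
    source_id: str
    source_label: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A labeled genome whose sequence provenance is tracked per segment.

    ``taxon_path`` is the claimed taxonomy (root -> leaf); for a contaminated
    draft it stays microbial even though a segment's true source is the host —
    the mislabeling is the object of study, not an error.
    """

    id: str
    taxon_path: tuple[str, ...]
    sequence: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.taxon_path = tuple(self.taxon_path)
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if not self.segments:
            self.segments = [
                Segment(0, len(self.sequence), self.id, source_label(self.taxon_path))
            ]
        self._check_segments()

    def _check_segments(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end <= seg.start:
                raise ValueError(
                    f"genome {self.id!r}: segments must tile [0, {len(self.sequence)})"
                )
            pos = seg.end
        if pos != len(self.sequence):
            raise ValueError(
                f"genome {self.id!r}: segments cover [0, {pos}), "
                f"sequence has length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_at(self, pos: int) -> Segment:
        """The segment covering base ``pos``."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside genome {self.id!r}")
        for seg in self.segments:
            if seg.start <= pos < seg.end:
                return seg
        raise AssertionError("segments do not tile the genome")  # pragma: no cover


@dataclass(frozen=True)
class ReadRecord:
    """A simulated read with its hidden true origin for auditing."""

    id: str
    sequence: str
    true_origin_genome: str
    true_origin_pos: int
    true_source: str


@dataclass
class ReadSet:
    """An ordered collection of reads."""

    reads: list[ReadRecord]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> ReadRecord:
        return self.reads[i]

    def source_counts(self) -> dict[str, int]:
        """Reads per true_source label (the audit trail)."""
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.true_source] = out.get(r.true_source, 0) + 1
        return out


class CountMatrix:
    """Samples x genera non-negative integer counts plus sample metadata.

    ``counts`` is indexed by sample id with one column per genus;
    ``metadata`` is indexed identically with columns ``class_label``,
    ``sample_type`` and ``library_size``. The library size is the sample's
    total sequencing depth and must be at least the row sum of counts (the
    remainder being host/unclassified reads).
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        metadata = metadata.copy()
        if not counts.index.equals(metadata.index):
            missing = counts.index.symmetric_difference(metadata.index).tolist()
            raise ValueError(f"counts/metadata sample ids differ: {missing[:10]}")
        for col in METADATA_COLUMNS:
            if col not in metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {counts.index[bad[0]]!r}, "
                    f"genus {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[bad[0]]!r}, "
                f"genus {counts.columns[bad[1]]!r}"
            )
        lib = metadata["library_size"].to_numpy()
        if (lib <= 0).any():
            raise ValueError("library_size must be positive for every sample")
        if (arr.sum(axis=1) > lib).any():
            raise ValueError("library_size smaller than row sum of counts")
        self.counts = counts
        self.metadata = metadata

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def genus_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def zero_features(self) -> list[str]:
        """Genera with no reads in any sample."""
        col = self.counts.sum(axis=0)
        return col.index[col == 0].tolist()

    def subset(self, sample_ids=None, genus_ids=None) -> "CountMatrix":
        counts = self.counts
        meta = self.metadata
        if sample_ids is not None:
            counts = counts.loc[sample_ids]
            meta = meta.loc[sample_ids]
        if genus_ids is not None:
            counts = counts[genus_ids]
        return CountMatrix(counts, meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return f"CountMatrix({n} samples x {p} genera)"


@dataclass
class NormalizedMatrix:
    """Real-valued matrix aligned with a CountMatrix, plus provenance.

    ``provenance`` records the transform chain (name, parameters, leak mode)
    and, when produced by :func:`leakforensics.normalize.voom_logcpm`, the
    list of features that were all-zero in the raw counts.
    """

    values: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
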