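"""Synthetic inputs: genomes, contaminated drafts, reads, count matrices.

Everything the pipeline consumes can be generated here, with full provenance,
so no external sequencing data is ever needed. The three case-study fixtures
(:func:`hepandensovirus_fixture`, :func:`thiorhodospira_fixture`,
:func:`mulikevirus_fixture`) rebuild normalized-value pathologies from their
published summary statistics: per-class constant "tag" values on features
whose raw counts are (almost) all zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .containers import (
    CountMatrix,
    GenomeRecord,
    NormalizedMatrix,
    ReadRecord,
    ReadSet,
    Segment,
    source_label,
)

__all__ = [
    "simulate_genome",
    "contaminate_draft",
    "simulate_reads",
    "simulate_count_matrix",
    "FixtureSpec",
    "SampleGroup",
    "ValueBlock",
    "FeatureFixture",
    "build_fixture",
    "hepandensovirus_fixture",
    "thiorhodospira_fixture",
    "mulikevirus_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    id: str = "genome",
    taxon_path: Sequence[str] = ("root", "Bacteria", "GenusX", "genome"),
) -> GenomeRecord:
    """I.i.d. random genome with the requested GC fraction.

    Bases are drawn independently with P(G)+P(C) = ``gc`` (split evenly
    within each pair). Lengths below 31 are rejected: no 31-mer fits.
    """
    if length < 31:
        raise ValueError(f"genome length must be >= 31 (k-mer size), got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = _BASES[codes].tobytes().decode("ascii")
    return GenomeRecord(id=id, taxon_path=tuple(taxon_path), sequence=seq)


def contaminate_draft(
    microbe: GenomeRecord,
    host: GenomeRecord,
    contig_length: int,
    seed: int = 0,
) -> GenomeRecord:
    """Append a host-derived contig to a microbial draft, keeping its label.

    Models the database flaw under study: a contiguous stretch of host
    sequence (uniform random start) is appended to the microbe's assembly,
    recorded in the segment track as host-sourced, while the genome's
    claimed taxon_path stays microbial. ``contig_length`` 0 is the identity.
    """
    if contig_length > len(host):
        raise ValueError(
            f"contig_length {contig_length} exceeds host length {len(host)}"
        )
    if contig_length < 0:
        raise ValueError("contig_length must be >= 0")
    if contig_length == 0:
        return GenomeRecord(
            id=microbe.id,
            taxon_path=microbe.taxon_path,
            sequence=microbe.sequence,
            segments=list(microbe.segments),
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(host) - contig_length + 1))
    contig = host.sequence[start : start + contig_length]
    offset = len(microbe.sequence)
    segments = list(microbe.segments) + [
        Segment(offset, offset + contig_length, host.id, source_label(host.taxon_path))
    ]
    return GenomeRecord(
        id=microbe.id,
        taxon_path=microbe.taxon_path,
        sequence=microbe.sequence + contig,
        segments=segments,
    )


def simulate_reads(
    genomes: Sequence[tuple[GenomeRecord, int]],
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Fixed-length single-end reads with i.i.d. substitution errors.

    Start positions are uniform over valid (non-wrapping) placements; each
    read's ``true_source`` is the label of the genome segment covering its
    start position, giving an exact audit trail for false-positive counts.
    """
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    for genome, n_reads in genomes:
        if read_length > len(genome):
            raise ValueError(
                f"read_length {read_length} exceeds genome {genome.id!r} "
                f"length {len(genome)}"
            )
        if n_reads == 0:
            continue
        codes = _CODE[np.frombuffer(genome.sequence.encode("ascii"), np.uint8)]
        starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
        window = starts[:, None] + np.arange(read_length)[None, :]
        mat = codes[window]
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            # shift by 1..3 guarantees a substitution, never a silent "error"
            shift = rng.integers(1, 4, size=mat.shape)
            mat = np.where(err, (mat + shift) % 4, mat)
        chars = _BASES[mat]
        for i in range(n_reads):
            pos = int(starts[i])
            seg = genome.segment_at(pos)
            reads.append(
                ReadRecord(
                    id=f"{genome.id}_r{i}",
                    sequence=chars[i].tobytes().decode("ascii"),
                    true_origin_genome=genome.id,
                    true_origin_pos=pos,
                    true_source=seg.source_label,
                )
            )
    return ReadSet(reads)


def simulate_count_matrix(
    classes: Sequence[str],
    n_per_class: int,
    n_common_features: int = 20,
    n_rare_features: int = 5,
    n_zero_features: int = 5,
    nb_mean: float = 50.0,
    nb_dispersion: float = 0.5,
    rare_prevalence: int = 3,
    host_reads: int = 1_000_000,
    seed: int = 0,
) -> CountMatrix:
    """Class-structured raw count matrix with common, rare and zero genera.

    Common features are negative binomial with variance mu + phi*mu^2
    (identical across classes — no true class signal); each rare feature is
    nonzero in exactly ``rare_prevalence`` random samples; zero features are
    identically zero. Library size is the row sum plus a host-read
    allowance, mimicking host-dominated tissue sequencing.
    """
    for name, v in [
        ("n_per_class", n_per_class),
        ("nb_mean", nb_mean),
        ("nb_dispersion", nb_dispersion),
        ("rare_prevalence", rare_prevalence),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    n_samples = n_per_class * len(classes)
    if rare_prevalence >= n_samples and n_rare_features > 0:
        raise ValueError("rare_prevalence must be < total number of samples")
    rng = np.random.default_rng(seed)
    # NB(mean mu, var mu + phi mu^2): numpy's (n, p) with n=1/phi, p=n/(n+mu)
    n_param = 1.0 / nb_dispersion
    p_param = n_param / (n_param + nb_mean)
    common = rng.negative_binomial(n_param, p_param, size=(n_samples, n_common_features))
    rare = np.zeros((n_samples, n_rare_features), dtype=np.int64)
    for j in range(n_rare_features):
        rows = rng.choice(n_samples, size=rare_prevalence, replace=False)
        rare[rows, j] = rng.integers(1, 20, size=rare_prevalence)
    zero = np.zeros((n_samples, n_zero_features), dtype=np.int64)
    counts = np.hstack([common, rare, zero]).astype(np.int64)

    sample_ids = [f"s{i:05d}" for i in range(n_samples)]
    genus_ids = (
        [f"g_common_{j}" for j in range(n_common_features)]
        + [f"g_rare_{j}" for j in range(n_rare_features)]
        + [f"g_zero_{j}" for j in range(n_zero_features)]
    )
    labels = np.repeat(list(classes), n_per_class)
    meta = pd.DataFrame(
        {
            "class_label": labels,
            "sample_type": "tumor",
            "library_size": counts.sum(axis=1) + host_reads,
        },
        index=sample_ids,
    )
    return CountMatrix(pd.DataFrame(counts, index=sample_ids, columns=genus_ids), meta)


# ---------------------------------------------------------------------------
# Fixture machinery: rebuild normalized-value case studies from printed facts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleGroup:
    """A block of samples sharing class label and sample type."""

    class_label: str
    sample_type: str
    n: int


@dataclass(frozen=True)
class ValueBlock:
    """Normalized-value generator for a subset of one feature's samples.

    ``n`` = None means "all remaining samples" in the matching group(s).
    ``kind`` is one of constant / uniform / normal with ``params``:
    (value,), (low, high) or (mean, sd).
    """

    kind: str
    params: tuple[float, ...]
    class_label: str | None = None
    sample_type: str | None = None
    n: int | None = None


@dataclass(frozen=True)
class FeatureFixture:
    name: str
    blocks: tuple[ValueBlock, ...]
    raw_nonzero: tuple[tuple[int, int], ...] = ()  # (sample index, count)


@dataclass(frozen=True)
class FixtureSpec:
    groups: tuple[SampleGroup, ...]
    features: tuple[FeatureFixture, ...]
    seed: int = 0
    library_size: int = 1_000_000


def build_fixture(
    spec: FixtureSpec,
) -> tuple[CountMatrix, NormalizedMatrix, pd.Series]:
    """Materialize a (raw, normalized, labels) triple from a FixtureSpec.

    Raw counts obey the per-feature nonzero exceptions (everything else is
    zero); normalized values realize each block in order. Requesting more
    tagged samples than a group holds is an error.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids: list[str] = []
    classes: list[str] = []
    types: list[str] = []
    for g in spec.groups:
        for i in range(g.n):
            sample_ids.append(f"{g.class_label}_{g.sample_type}_{i:05d}")
            classes.append(g.class_label)
            types.append(g.sample_type)
    n = len(sample_ids)
    class_arr = np.array(classes)
    type_arr = np.array(types)

    raw = np.zeros((n, len(spec.features)), dtype=np.int64)
    values = np.zeros((n, len(spec.features)))
    for j, feat in enumerate(spec.features):
        assigned = np.zeros(n, dtype=bool)
        for block in feat.blocks:
            mask = ~assigned
            if block.class_label is not None:
                mask &= class_arr == block.class_label
            if block.sample_type is not None:
                mask &= type_arr == block.sample_type
            idx = np.flatnonzero(mask)
            if block.n is not None:
                if block.n > len(idx):
                    raise ValueError(
                        f"feature {feat.name!r}: block requests {block.n} samples, "
                        f"only {len(idx)} remain in the group"
                    )
                idx = idx[: block.n]
            if block.kind == "constant":
                values[idx, j] = block.params[0]
            elif block.kind == "uniform":
                lo, hi = block.params
                values[idx, j] = rng.uniform(lo, hi, size=len(idx))
            elif block.kind == "normal":
                mu, sd = block.params
                values[idx, j] = rng.normal(mu, sd, size=len(idx))
            else:
                raise ValueError(f"unknown block kind {block.kind!r}")
            assigned[idx] = True
        if not assigned.all():
            raise ValueError(
                f"feature {feat.name!r}: {int((~assigned).sum())} samples "
                "not covered by any block"
            )
        for sample_idx, count in feat.raw_nonzero:
            raw[sample_idx, j] = count

    meta = pd.DataFrame(
        {
            "class_label": classes,
            "sample_type": types,
            "library_size": raw.sum(axis=1) + spec.library_size,
        },
        index=sample_ids,
    )
    feature_names = [f.name for f in spec.features]
    raw_cm = CountMatrix(
        pd.DataFrame(raw, index=sample_ids, columns=feature_names), meta
    )
    norm = NormalizedMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_names),
        provenance={
            "transform": "fixture",
            "seed": spec.seed,
            "all_zero_features": raw_cm.zero_features(),
        },
    )
    labels = pd.Series(classes, index=sample_ids, name="class_label")
    return raw_cm, norm, labels


#: the tagged normalized value assigned to most ACC samples
HEPANDENSOVIRUS_TAG = 3.078874655

#: duplicated normal-tissue values and their multiplicities
MULIKEVIRUS_CLUSTERS = ((3.07584214, 38), (3.07585718, 18), (3.076237397, 5))


def hepandensovirus_fixture(seed: int = 0):
    """Single-virus tagging fixture: 17,625 samples, 79 ACC positives.

    71 of 79 ACC samples sit exactly at the tag value; the other 8 fall
    below it; 69 non-ACC samples sit at or above it. The inclusive rule
    "value >= tag => ACC" then labels 71/79 (90%) of positives correctly
    with 77/17,625 (0.4%) total errors, while the raw column holds a single
    sample with 2 reads and zeros everywhere else.
    """
    tag = HEPANDENSOVIRUS_TAG
    n_other = 17_625 - 79
    spec = FixtureSpec(
        groups=(
            SampleGroup("ACC", "tumor", 79),
            SampleGroup("OTHER", "tumor", n_other),
        ),
        features=(
            FeatureFixture(
                name="Hepandensovirus",
                blocks=(
                    ValueBlock("constant", (tag,), class_label="ACC", n=71),
                    ValueBlock("uniform", (tag - 1.0, tag - 0.1), class_label="ACC"),
                    ValueBlock("uniform", (tag + 0.05, tag + 2.0), class_label="OTHER", n=69),
                    ValueBlock("uniform", (tag - 4.0, tag - 0.05), class_label="OTHER"),
                ),
                raw_nonzero=((79, 2),),  # one non-ACC sample with 2 reads
            ),
        ),
        seed=seed,
    )
    return build_fixture(spec)


def thiorhodospira_fixture(seed: int = 0):
    """Tumor-vs-normal fixture: 51 tumor + 41 normal kidney samples.

    Raw counts: 85 zeros and 7 ones (4 tumor, 3 normal). Normalized values
    for tumors occupy an (almost) disjoint, higher range than normals, so a
    single-feature threshold separates the groups despite raw near-zeros.
    """
    spec = FixtureSpec(
        groups=(
            SampleGroup("KICH", "tumor", 51),
            SampleGroup("KICH", "normal", 41),
        ),
        features=(
            FeatureFixture(
                name="Thiorhodospira",
                blocks=(
                    ValueBlock("uniform", (-2.05, -1.0), sample_type="tumor"),
                    ValueBlock("uniform", (-4.0, -1.95), sample_type="normal"),
                ),
                # 4 tumor samples and 3 normal samples with one read each
                raw_nonzero=((0, 1), (1, 1), (2, 1), (3, 1), (51, 1), (52, 1), (53, 1)),
            ),
        ),
        seed=seed,
    )
    return build_fixture(spec)


def mulikevirus_fixture(seed: int = 0):
    """Duplicate-tag fixture: 906 head-and-neck samples, all raw zero.

    The 70 normal-tissue samples are pinned to low values with duplicated
    clusters of sizes 38, 18 and 5 (the remaining 9 normals get distinct low
    values); all 693 tumor and 143 blood samples get larger values. A
    classifier needs only "low value => normal" for near-perfect accuracy.
    """
    (v38, n38), (v18, n18), (v5, n5) = MULIKEVIRUS_CLUSTERS
    spec = FixtureSpec(
        groups=(
            SampleGroup("HNSC", "normal", 70),
            SampleGroup("HNSC", "tumor", 693),
            SampleGroup("HNSC", "blood", 143),
        ),
        features=(
            FeatureFixture(
                name="Mulikevirus",
                blocks=(
                    ValueBlock("constant", (v38,), sample_type="normal", n=n38),
                    ValueBlock("constant", (v18,), sample_type="normal", n=n18),
                    ValueBlock("constant", (v5,), sample_type="normal", n=n5),
                    ValueBlock("uniform", (3.077, 3.090), sample_type="normal"),
                    ValueBlock("uniform", (3.2, 5.0), sample_type="tumor"),
                    ValueBlock("uniform", (3.2, 5.0), sample_type="blood"),
                ),
            ),
        ),
        seed=seed,
    )
    return build_fixture(spec)
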