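"""Exact k-mer LCA read classifier (Kraken-style) and database builder.

Every canonical 31-mer in the reference genomes is stored under the LCA of
all genomes that contain it. A read is classified by collecting k-mer hits
per taxon, scoring every root-to-leaf path by the sum of hits on its nodes,
and assigning the leaf of the maximal path (ties resolved by the LCA of the
tied leaves). The point of the surrounding package: whether the HOST genome
is in the database decides whether host-derived reads become microbial false
positives (host absent) or collapse to host/root (host present).

K-mers are 2-bit packed into uint64 (k <= 31), canonicalized as the
numeric = lexicographic minimum of a window and its reverse complement, and
looked up by binary search in a sorted array, which keeps million-read
experiments tractable in plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .containers import GenomeRecord, ReadRecord, ReadSet
from .taxonomy import TaxonomyTree, build_taxonomy, lca, lca_many

__all__ = [
    "KmerDatabase",
    "ClassificationResult",
    "HostInclusionReport",
    "encode_sequence",
    "canonical_kmers",
    "build_database",
    "classify_read",
    "classify_readset",
    "host_prefilter",
    "host_inclusion_experiment",
]

# base -> 2-bit code; anything non-ACGT maps to 4 and invalidates its windows
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All valid canonical k-mers of ``seq`` as packed uint64, in order.

    Windows containing non-ACGT characters are skipped. The canonical form
    is min(window, reverse complement), identical for a sequence and its
    reverse complement read in the opposite direction.
    """
    codes = encode_sequence(seq)
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    invalid = (codes > 3).astype(np.int32)
    bad_prefix = np.concatenate([[0], np.cumsum(invalid)])
    window_bad = bad_prefix[k:] - bad_prefix[:-k]  # invalid bases per window
    c = (codes & 3).astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + m]
        rev |= (three - c[j : j + m]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[window_bad == 0]


@dataclass
class KmerDatabase:
    """Sorted canonical k-mers with the LCA taxon of their source genomes."""

    k: int
    kmers: np.ndarray  # sorted uint64
    taxon_index: np.ndarray  # int32, parallel to kmers
    taxon_names: list[str]
    source_genomes: list[tuple[str, tuple[str, ...]]]

    def __len__(self) -> int:
        return len(self.kmers)

    def lookup(self, kmers: np.ndarray) -> np.ndarray:
        """Taxon index per query k-mer, -1 for misses."""
        out = np.full(len(kmers), -1, dtype=np.int32)
        if len(self.kmers) == 0 or len(kmers) == 0:
            return out
        pos = np.searchsorted(self.kmers, kmers)
        np.minimum(pos, len(self.kmers) - 1, out=pos)
        found = self.kmers[pos] == kmers
        out[found] = self.taxon_index[pos[found]]
        return out


def build_database(
    genomes: Sequence[GenomeRecord],
    tree: TaxonomyTree | None = None,
    k: int = 31,
) -> KmerDatabase:
    """Map every canonical k-mer in ``genomes`` to the LCA of its sources.

    Genomes shorter than k contribute nothing. ``k`` must be odd (so no
    k-mer is its own reverse complement) and at most 31 (2-bit packing).
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("cannot build a database from an empty genome list")
    if k % 2 == 0 or k < 11:
        raise ValueError(f"k must be odd and >= 11, got {k}")
    if k > 31:
        raise ValueError("k > 31 not supported by 64-bit packing")
    if tree is None:
        tree = build_taxonomy(genomes)

    names: list[str] = []
    name_idx: dict[str, int] = {}

    def idx_of(name: str) -> int:
        if name not in name_idx:
            name_idx[name] = len(names)
            names.append(name)
        return name_idx[name]

    parts: list[np.ndarray] = []
    taxa_parts: list[np.ndarray] = []
    for g in genomes:
        leaf = g.taxon_path[-1]
        if leaf not in tree:
            raise ValueError(f"genome taxon {leaf!r} missing from taxonomy")
        kk = np.unique(canonical_kmers(g.sequence, k))
        parts.append(kk)
        taxa_parts.append(np.full(len(kk), idx_of(leaf), dtype=np.int32))

    allk = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    allt = np.concatenate(taxa_parts) if taxa_parts else np.empty(0, np.int32)
    order = np.argsort(allk, kind="stable")
    allk, allt = allk[order], allt[order]

    if len(allk):
        starts = np.concatenate([[0], np.flatnonzero(np.diff(allk)) + 1, [len(allk)]])
        uk = allk[starts[:-1]]
        ut = allt[starts[:-1]].copy()
        pair_lca: dict[tuple[int, int], int] = {}
        for gi in np.flatnonzero(np.diff(starts) > 1):
            group = allt[starts[gi] : starts[gi + 1]]
            acc = int(group[0])
            for t in group[1:]:
                key = (acc, int(t)) if acc <= t else (int(t), acc)
                if key not in pair_lca:
                    pair_lca[key] = idx_of(lca(tree, names[key[0]], names[key[1]]))
                acc = pair_lca[key]
            ut[gi] = acc
    else:
        uk = allk
        ut = allt

    return KmerDatabase(
        k=k,
        kmers=uk,
        taxon_index=ut,
        taxon_names=names,
        source_genomes=[(g.id, g.taxon_path) for g in genomes],
    )


@dataclass
class ClassificationResult:
    """Per-read assignments plus genus-level aggregation.

    ``assignments[i]`` is a taxon name or None (unclassified). Genus counts
    include every read assigned at or below that genus; reads assigned above
    genus rank (domain/root) count toward no genus.
    """

    assignments: list[str | None]
    genus_counts: dict[str, int]
    n_unclassified: int
    hit_profiles: list[dict[str, int]] | None = None

    @property
    def n_reads(self) -> int:
        return len(self.assignments)

    @property
    def n_classified(self) -> int:
        return self.n_reads - self.n_unclassified


@dataclass
class _PathScorer:
    """Precomputed root-to-leaf paths of a tree, restricted per database."""

    tree: TaxonomyTree
    names: list[str]
    leaf_paths: list[tuple[str, set[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        name_idx = {n: i for i, n in enumerate(self.names)}
        for leaf in self.tree.leaves():
            path = {
                name_idx[t] for t in self.tree.ancestors(leaf) if t in name_idx
            }
            self.leaf_paths.append((leaf, path))

    def assign(self, counts: dict[int, int]) -> str:
        best = -1
        tied: list[str] = []
        for leaf, path in self.leaf_paths:
            score = sum(c for t, c in counts.items() if t in path)
            if score > best:
                best, tied = score, [leaf]
            elif score == best:
                tied.append(leaf)
        if len(tied) == 1:
            return tied[0]
        return lca_many(self.tree, tied)


def classify_read(
    read: ReadRecord | str,
    db: KmerDatabase,
    tree: TaxonomyTree,
    _scorer: _PathScorer | None = None,
) -> str | None:
    """Assign a single read; None when no database k-mer matches."""
    seq = read if isinstance(read, str) else read.sequence
    hits = db.lookup(canonical_kmers(seq, db.k))
    hits = hits[hits >= 0]
    if len(hits) == 0:
        return None
    if hits.min() == hits.max():  # single taxon hit: the common fast path
        return db.taxon_names[int(hits[0])]
    scorer = _scorer or _PathScorer(tree, db.taxon_names)
    counts = np.bincount(hits)
    return scorer.assign({int(t): int(c) for t, c in enumerate(counts) if c})


def read_hit_profile(
    read: ReadRecord | str, db: KmerDatabase, tree: TaxonomyTree
) -> dict[str, int]:
    """Taxon -> k-mer hit count for one read (diagnostic view)."""
    seq = read if isinstance(read, str) else read.sequence
    hits = db.lookup(canonical_kmers(seq, db.k))
    hits = hits[hits >= 0]
    counts = np.bincount(hits) if len(hits) else np.empty(0, int)
    return {db.taxon_names[t]: int(c) for t, c in enumerate(counts) if c}


def classify_readset(
    reads: ReadSet | Iterable[ReadRecord],
    db: KmerDatabase,
    tree: TaxonomyTree,
    store_profiles: bool = False,
) -> ClassificationResult:
    """Classify all reads and aggregate counts at genus rank."""
    scorer = _PathScorer(tree, db.taxon_names)
    assignments: list[str | None] = []
    profiles: list[dict[str, int]] | None = [] if store_profiles else None
    genus_counts: dict[str, int] = {}
    n_unclassified = 0
    genus_cache: dict[str, str | None] = {}
    for read in reads:
        taxon = classify_read(read, db, tree, _scorer=scorer)
        assignments.append(taxon)
        if store_profiles:
            profiles.append(read_hit_profile(read, db, tree))
        if taxon is None:
            n_unclassified += 1
            continue
        if taxon not in genus_cache:
            genus_cache[taxon] = tree.at_rank(taxon, "genus")
        genus = genus_cache[taxon]
        if genus is not None:
            genus_counts[genus] = genus_counts.get(genus, 0) + 1
    return ClassificationResult(assignments, genus_counts, n_unclassified, profiles)


def save_database(db: KmerDatabase, path) -> None:
    """Serialize a database as sorted, diffable JSON."""
    import json

    payload = {
        "k": db.k,
        "taxon_names": db.taxon_names,
        "source_genomes": [[gid, list(path_)] for gid, path_ in db.source_genomes],
        "entries": [
            [int(km), int(tx)] for km, tx in zip(db.kmers, db.taxon_index)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, separators=(",", ":"))
        fh.write("\n")


def load_database(path) -> KmerDatabase:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    entries = payload["entries"]
    kmers = np.array([e[0] for e in entries], dtype=np.uint64)
    taxa = np.array([e[1] for e in entries], dtype=np.int32)
    return KmerDatabase(
        k=payload["k"],
        kmers=kmers,
        taxon_index=taxa,
        taxon_names=list(payload["taxon_names"]),
        source_genomes=[
            (gid, tuple(path_)) for gid, path_ in payload["source_genomes"]
        ],
    )


def host_prefilter(
    readset: ReadSet,
    host_genome: GenomeRecord,
    k: int = 31,
    threshold: float = 0.5,
) -> tuple[ReadSet, int]:
    """Drop reads whose fraction of host-matching k-mers is >= ``threshold``.

    Abstract stand-in for re-aligning reads against the host reference: a
    read is considered host if at least half of its k-mers occur in the host
    genome. Returns the surviving reads and the number removed.
    """
    host_db = build_database([host_genome], k=k)
    kept: list[ReadRecord] = []
    dropped = 0
    for read in readset:
        kk = canonical_kmers(read.sequence, k)
        if len(kk) == 0:
            kept.append(read)
            continue
        frac = float((host_db.lookup(kk) >= 0).mean())
        if frac >= threshold:
            dropped += 1
        else:
            kept.append(read)
    return ReadSet(kept), dropped


@dataclass
class HostInclusionReport:
    """Outcome of classifying one read set against two databases.

    DB1 holds the microbial genomes only; DB2 additionally holds the host.
    ``fold_decline`` is the contaminated genus's read count under DB1 over
    its count under DB2 (floored at 1); ``host_fraction_db1`` is the share
    of DB1 assignments to the contaminated genus whose true origin is host.
    """

    contaminated_genus: str
    genus_counts_db1: dict[str, int]
    genus_counts_db2: dict[str, int]
    fold_decline: float
    host_fraction_db1: float
    n_reads: int
    n_host_reads: int

    def to_dict(self) -> dict:
        return {
            "contaminated_genus": self.contaminated_genus,
            "genus_counts_microbes_only": dict(sorted(self.genus_counts_db1.items())),
            "genus_counts_with_host": dict(sorted(self.genus_counts_db2.items())),
            "fold_decline": self.fold_decline,
            "host_fraction_microbes_only": self.host_fraction_db1,
            "n_reads": self.n_reads,
            "n_host_reads": self.n_host_reads,
        }


def host_inclusion_experiment(
    readset: ReadSet,
    microbial_genomes: Sequence[GenomeRecord],
    host_genome: GenomeRecord,
    tree: TaxonomyTree | None = None,
    k: int = 31,
) -> HostInclusionReport:
    """Classify reads with and without the host genome in the database.

    Exactly the mechanism under study: a draft genome carrying a mislabeled
    host-derived segment soaks up host reads when the host genome is absent;
    adding the host genome moves those shared k-mers to the root (host and
    microbe live under different domains) and the false counts collapse.

    One genome in ``microbial_genomes`` must carry a host-sourced segment.
    """
    contaminated = [
        g
        for g in microbial_genomes
        if any(s.source_label == "host" for s in g.segments)
    ]
    if len(contaminated) != 1:
        raise ValueError(
            f"expected exactly one host-contaminated genome, found {len(contaminated)}"
        )
    draft = contaminated[0]
    if tree is None:
        tree = build_taxonomy(list(microbial_genomes) + [host_genome])
    genus = tree.at_rank(draft.taxon_path[-1], "genus")

    db1 = build_database(microbial_genomes, tree, k=k)
    db2 = build_database(list(microbial_genomes) + [host_genome], tree, k=k)
    res1 = classify_readset(readset, db1, tree)
    res2 = classify_readset(readset, db2, tree)

    count1 = res1.genus_counts.get(genus, 0)
    count2 = res2.genus_counts.get(genus, 0)
    fold = count1 / max(count2, 1)

    genus_cache: dict[str, str | None] = {}
    n_genus = n_genus_host = 0
    for read, taxon in zip(readset, res1.assignments):
        if taxon is None:
            continue
        if taxon not in genus_cache:
            genus_cache[taxon] = tree.at_rank(taxon, "genus")
        if genus_cache[taxon] == genus:
            n_genus += 1
            n_genus_host += read.true_source == "host"
    host_fraction = n_genus_host / n_genus if n_genus else 0.0

    n_host_reads = sum(1 for r in readset if r.true_source == "host")
    return HostInclusionReport(
        contaminated_genus=genus,
        genus_counts_db1=res1.genus_counts,
        genus_counts_db2=res2.genus_counts,
        fold_decline=fold,
        host_fraction_db1=host_fraction,
        n_reads=len(readset),
        n_host_reads=n_host_reads,
    )
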