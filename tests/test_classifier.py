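"""K-mer database and LCA classification against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leakforensics.classifier import (
    _PathScorer,
    build_database,
    canonical_kmers,
    classify_read,
    classify_readset,
    host_inclusion_experiment,
    host_prefilter,
    load_database,
    save_database,
)
from leakforensics.simulate import contaminate_draft, simulate_genome, simulate_reads
from leakforensics.taxonomy import build_taxonomy, lca_many

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _brute_force_db(genomes, tree, k):
    """Dict-based canonical k-mer -> LCA map over string k-mers."""
    by_kmer: dict[str, set[str]] = {}
    for g in genomes:
        for i in range(len(g.sequence) - k + 1):
            mer = g.sequence[i : i + k]
            if any(c not in "ACGT" for c in mer):
                continue
            canon = min(mer, _revcomp(mer))
            by_kmer.setdefault(canon, set()).add(g.taxon_path[-1])
    return {mer: lca_many(tree, sorted(taxa)) for mer, taxa in by_kmer.items()}


def _encode(mer: str) -> int:
    value = 0
    for c in mer:
        value = value * 4 + "ACGT".index(c)
    return value


class TestDatabase:
    def test_single_kmer_genome(self):
        g = simulate_genome(31, seed=1, id="g", taxon_path=("root", "Bacteria", "G", "g"))
        db = build_database([g], k=31)
        assert len(db) == 1
        assert db.taxon_names[db.taxon_index[0]] == "g"

    def test_shared_kmer_maps_to_lca(self):
        base = simulate_genome(60, seed=2, id="a", taxon_path=("root", "Bacteria", "G1", "a"))
        shared = base.sequence[:40]
        from leakforensics.containers import GenomeRecord

        a = GenomeRecord("a", ("root", "Bacteria", "G1", "a"), shared + "A" * 0)
        b = GenomeRecord("b", ("root", "Bacteria", "G2", "b"), shared)
        tree = build_taxonomy([a, b])
        db = build_database([a, b], tree, k=31)
        mers = canonical_kmers(shared, 31)
        taxa = {db.taxon_names[t] for t in db.lookup(mers)}
        assert taxa == {"Bacteria"}

    @pytest.mark.parametrize("k", [11, 15, 31])
    def test_matches_brute_force_on_small_genomes(self, k):
        genomes = [
            simulate_genome(
                2000, gc=0.5, seed=30 + i, id=f"g{i}",
                taxon_path=("root", "Bacteria", f"G{i % 2}", f"g{i}"),
            )
            for i in range(4)
        ]
        tree = build_taxonomy(genomes)
        db = build_database(genomes, tree, k=k)
        oracle = _brute_force_db(genomes, tree, k)
        assert len(db) == len(oracle)
        got = {
            int(mer): db.taxon_names[t] for mer, t in zip(db.kmers, db.taxon_index)
        }
        expected = {
            min(_encode(m), _encode(_revcomp(m))): taxon for m, taxon in oracle.items()
        }
        assert got == expected

    def test_short_genomes_contribute_nothing(self):
        from leakforensics.containers import GenomeRecord

        tiny = GenomeRecord("t", ("root", "Bacteria", "G", "t"), "ACGT" * 5)  # 20 bp
        g = simulate_genome(100, seed=3, id="g", taxon_path=("root", "Bacteria", "G", "g"))
        db = build_database([g, tiny], k=31)
        assert {db.taxon_names[t] for t in np.unique(db.taxon_index)} == {"g"}

    def test_empty_genome_list_rejected(self):
        with pytest.raises(ValueError):
            build_database([], k=31)

    def test_even_k_rejected(self):
        g = simulate_genome(100, seed=1)
        with pytest.raises(ValueError):
            build_database([g], k=30)

    def test_json_round_trip(self, tmp_path, tiny_genomes):
        g1, g2, _ = tiny_genomes
        db = build_database([g1, g2], k=31)
        save_database(db, tmp_path / "db.json")
        back = load_database(tmp_path / "db.json")
        assert back.k == db.k
        assert np.array_equal(back.kmers, db.kmers)
        assert np.array_equal(back.taxon_index, db.taxon_index)
        assert back.taxon_names == db.taxon_names


class TestCanonicalKmers:
    @given(st.integers(min_value=0, max_value=5000))
    def test_strand_symmetry(self, seed):
        """A sequence and its reverse complement share canonical k-mers."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        fwd = canonical_kmers(seq, 31)
        rev = canonical_kmers(_revcomp(seq), 31)
        assert sorted(fwd.tolist()) == sorted(rev.tolist())

    def test_ambiguous_bases_skipped(self):
        seq = "A" * 31 + "N" + "C" * 31
        mers = canonical_kmers(seq, 31)
        assert len(mers) == 2  # only the two clean windows


class TestClassification:
    def test_unique_region_read_assigned_to_genome(self, tiny_genomes):
        g1, g2, _ = tiny_genomes
        tree = build_taxonomy([g1, g2])
        db = build_database([g1, g2], tree)
        read = g1.sequence[100:200]
        assert classify_read(read, db, tree) == "g1"

    def test_no_hits_unclassified(self, tiny_genomes):
        g1, g2, _ = tiny_genomes
        tree = build_taxonomy([g1, g2])
        db = build_database([g1, g2], tree)
        assert classify_read("A" * 100, db, tree) is None
        assert classify_read("ACGT", db, tree) is None  # shorter than k

    def test_tie_resolved_by_lca_of_tied_leaves(self):
        """Hit profile {G: 3, a: 2, b: 2} ties paths a and b at 5 -> genus G."""
        from leakforensics.containers import GenomeRecord
        from leakforensics.taxonomy import TaxonomyTree

        tree = TaxonomyTree()
        tree.add_path(("root", "Bacteria", "G", "a"))
        tree.add_path(("root", "Bacteria", "G", "b"))
        scorer = _PathScorer(tree, ["G", "a", "b"])
        assert scorer.assign({0: 3, 1: 2, 2: 2}) == "G"
        # exhaustive check: path scores a=5, b=5; breaking the tie moves it
        assert scorer.assign({0: 3, 1: 3, 2: 2}) == "a"

    def test_readset_conservation_and_genus_counts(self, tiny_genomes):
        g1, g2, _ = tiny_genomes
        tree = build_taxonomy([g1, g2])
        db = build_database([g1, g2], tree)
        reads = simulate_reads([(g1, 40)], read_length=100, error_rate=0.0, seed=8)
        result = classify_readset(reads, db, tree)
        assert result.n_classified + result.n_unclassified == len(reads)
        assert result.genus_counts == {"G1": 40}

    def test_empty_readset(self, tiny_genomes):
        g1, g2, _ = tiny_genomes
        from leakforensics.containers import ReadSet

        tree = build_taxonomy([g1, g2])
        db = build_database([g1, g2], tree)
        result = classify_readset(ReadSet([]), db, tree)
        assert result.genus_counts == {} and result.n_unclassified == 0

    def test_host_reads_vs_clean_microbe_db_near_zero(self, tiny_genomes):
        """Without shared sequence, host reads do not hit microbial genera."""
        g1, g2, host = tiny_genomes
        tree = build_taxonomy([g1, g2, host])
        db = build_database([g1, g2], tree)
        reads = simulate_reads([(host, 300)], read_length=100, error_rate=0.0, seed=4)
        result = classify_readset(reads, db, tree)
        assert sum(result.genus_counts.values()) == 0


class TestHostInclusion:
    def test_report_structure_and_collapse(self, contaminated_scenario):
        draft, g2, host, reads = contaminated_scenario
        report = host_inclusion_experiment(reads, [draft, g2], host)
        assert report.contaminated_genus == "G1"
        c1 = report.genus_counts_db1.get("G1", 0)
        c2 = report.genus_counts_db2.get("G1", 0)
        assert report.fold_decline == c1 / max(c2, 1)
        assert c1 > c2
        assert report.host_fraction_db1 > 0.5

    def test_no_host_reads_fold_near_one(self, tiny_genomes):
        g1, g2, host = tiny_genomes
        draft = contaminate_draft(g1, host, 1000, seed=21)
        reads = simulate_reads([(g1, 50)], read_length=100, error_rate=0.0, seed=3)
        report = host_inclusion_experiment(reads, [draft, g2], host)
        assert report.fold_decline == pytest.approx(1.0, abs=0.1)

    def test_missing_contaminated_genome_rejected(self, tiny_genomes):
        g1, g2, host = tiny_genomes
        reads = simulate_reads([(g1, 5)], read_length=100, seed=1)
        with pytest.raises(ValueError, match="contaminated"):
            host_inclusion_experiment(reads, [g1, g2], host)

    def test_adding_host_never_increases_microbial_host_reads(
        self, contaminated_scenario
    ):
        """Monotonicity of safety, per microbial taxon over host-origin reads."""
        from leakforensics.containers import ReadSet

        draft, g2, host, reads = contaminated_scenario
        host_reads = ReadSet([r for r in reads if r.true_source == "host"])
        tree = build_taxonomy([draft, g2, host])
        db1 = build_database([draft, g2], tree)
        db2 = build_database([draft, g2, host], tree)
        res1 = classify_readset(host_reads, db1, tree)
        res2 = classify_readset(host_reads, db2, tree)

        def microbial_counts(res):
            out = {}
            for taxon in res.assignments:
                if taxon is not None and "Eukaryota" not in tree.ancestors(taxon):
                    if tree.depth(taxon) >= 1:  # below root
                        out[taxon] = out.get(taxon, 0) + 1
            return out

        c1, c2 = microbial_counts(res1), microbial_counts(res2)
        for taxon, n2 in c2.items():
            assert n2 <= c1.get(taxon, 0) + 0, (
                f"host genome addition increased {taxon}: {c1.get(taxon, 0)} -> {n2}"
            )

    def test_host_prefilter_drops_host_reads(self, contaminated_scenario):
        draft, g2, host, reads = contaminated_scenario
        kept, dropped = host_prefilter(reads, host)
        n_host = sum(r.true_source == "host" for r in reads)
        assert dropped >= 0.99 * n_host
        assert all(r.true_source != "host" for r in kept)
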