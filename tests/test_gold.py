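import numpy as np
import pytest

from mgsim.community import CommunityProfile, CommunityRow
from mgsim.fixtures import random_sequence
from mgsim.genomes import GenomeRecord
from mgsim.gold import (
    anonymize,
    binning_gold_standard,
    perfect_assembly,
    perfect_assembly_coverage_oracle,
    perfect_coassembly,
    profiling_gold_standard,
)
from mgsim.reads import Mate, ReadPair, ReadSimParams, prepare_genome, simulate_reads


def _pair(gid, contig, s1, e1, s2, e2, pid="p0"):
    return ReadPair(
        pair_id=pid,
        genome_id=gid,
        mate1=Mate("A" * (e1 - s1), "I" * (e1 - s1), contig, s1, e1, False),
        mate2=Mate("A" * (e2 - s2), "I" * (e2 - s2), contig, s2, e2, True),
    )


def _genome(length=1000, seed=0, gid="g0"):
    rng = np.random.default_rng(seed)
    rec = GenomeRecord(gid, "t0", {f"{gid}_c0": random_sequence(length, rng)})
    return prepare_genome(rec, rng)


class TestPerfectAssembly:
    def test_single_read_single_contig(self):
        prep = _genome(1000)
        ref = prep.contigs[0][1]
        pairs = [_pair("g0", "g0_c0", 10, 160, 300, 450)]
        contigs = perfect_assembly(pairs, {"g0": prep})
        assert len(contigs) == 2
        assert contigs[0].sequence == ref[10:160]
        assert contigs[1].sequence == ref[300:450]

    def test_disjoint_regions_give_two_contigs(self):
        prep = _genome(1000)
        pairs = [_pair("g0", "g0_c0", 0, 100, 200, 300)]
        contigs = perfect_assembly(pairs, {"g0": prep})
        assert [(c.start, c.end) for c in contigs] == [(0, 100), (200, 300)]

    def test_touching_intervals_merge(self):
        prep = _genome(1000)
        pairs = [_pair("g0", "g0_c0", 0, 100, 100, 200)]
        contigs = perfect_assembly(pairs, {"g0": prep})
        assert [(c.start, c.end) for c in contigs] == [(0, 200)]

    def test_dangling_genome_errors(self):
        with pytest.raises(KeyError):
            perfect_assembly([_pair("gX", "c", 0, 10, 20, 30)], {"g0": _genome()})

    def test_matches_coverage_array_oracle_on_random_reads(self, rng):
        """200 random reads: intervals equal runs of per-base coverage >= 1."""
        prep = _genome(2000)
        pairs = simulate_reads(prep, 200, ReadSimParams(read_length=50), rng)
        merge = perfect_assembly(pairs, {"g0": prep})
        oracle = perfect_assembly_coverage_oracle(pairs, {"g0": prep})
        assert [(c.contig, c.start, c.end, c.sequence) for c in merge] == [
            (c.contig, c.start, c.end, c.sequence) for c in oracle
        ]

    def test_contigs_are_reference_substrings(self, rng):
        prep = _genome(3000)
        ref = dict(prep.contigs)
        pairs = simulate_reads(prep, 100, ReadSimParams(), rng)
        for c in perfect_assembly(pairs, {"g0": prep}):
            assert c.sequence == ref[c.contig][c.start : c.end]
            assert ref[c.contig].find(c.sequence) != -1

    def test_total_gold_length_bounded_by_genome(self, rng):
        prep = _genome(2000)
        pairs = simulate_reads(prep, 400, ReadSimParams(read_length=50), rng)
        total = sum(c.end - c.start for c in perfect_assembly(pairs, {"g0": prep}))
        assert total <= prep.total_length


class TestCoassembly:
    def test_overlapping_samples_pool(self):
        prep = _genome(1000)
        samples = {
            "S0": [_pair("g0", "g0_c0", 0, 100, 150, 250)],
            "S1": [_pair("g0", "g0_c0", 50, 150, 400, 500)],
        }
        contigs = perfect_coassembly(samples, {"g0": prep})
        assert [(c.start, c.end) for c in contigs] == [(0, 250), (400, 500)]
        assert all(c.scope == "pooled" for c in contigs)

    def test_single_sample_equals_assembly(self, rng):
        prep = _genome(2000)
        pairs = simulate_reads(prep, 60, ReadSimParams(), rng)
        a = perfect_assembly(pairs, {"g0": prep}, scope="S0")
        b = perfect_coassembly({"S0": pairs}, {"g0": prep})
        assert [(c.start, c.end, c.sequence) for c in a] == [
            (c.start, c.end, c.sequence) for c in b
        ]

    def test_per_sample_contained_in_pooled(self, rng):
        prep = _genome(5000)
        samples = {
            f"S{i}": simulate_reads(prep, 40, ReadSimParams(), rng) for i in range(3)
        }
        pooled = perfect_coassembly(samples, {"g0": prep})
        for sname, pairs in samples.items():
            for c in perfect_assembly(pairs, {"g0": prep}, scope=sname):
                assert any(
                    p.contig == c.contig and p.start <= c.start and c.end <= p.end
                    for p in pooled
                )


class TestBinning:
    def test_rows_per_sequence(self):
        seqs = [(f"r{i}", "g1") for i in range(10)]
        rows = binning_gold_standard(seqs, {"g1": "t1"})
        assert len(rows) == 10
        assert all(r.genome_id == "g1" and r.taxid == "t1" for r in rows)

    def test_missing_provenance_errors(self):
        with pytest.raises(KeyError):
            binning_gold_standard([("r0", "gX")], {"g1": "t1"})

    def test_taxid_must_resolve_in_db(self, toy_db):
        with pytest.raises(KeyError):
            binning_gold_standard([("r0", "g1")], {"g1": "bogus"}, toy_db)
        rows = binning_gold_standard([("r0", "g1")], {"g1": "S1"}, toy_db)
        assert rows[0].taxid == "S1"


class TestProfilingGoldStandard:
    def test_single_genome_100pct_at_defined_ranks(self, toy_db):
        prof = CommunityProfile([CommunityRow("g1", "S1", 1.0)], normalized=True)
        table = profiling_gold_standard(prof, toy_db)
        assert table["strain"] == [("g1", 100.0)]
        assert table["species"] == [("S1", 100.0)]
        assert table["genus"] == [("G1", 100.0)]
        assert table["family"] == [("F1", 100.0)]
        assert table["order"] == [("unassigned", 100.0)]

    def test_two_species_same_genus(self, toy_db):
        toy_db.nodes["S2"] = type(toy_db.nodes["S1"])("S2", "G1", "species", "Escherichia two")
        prof = CommunityProfile(
            [CommunityRow("g1", "S1", 0.5), CommunityRow("g2", "S2", 0.5)],
            normalized=True,
        )
        table = profiling_gold_standard(prof, toy_db)
        assert table["genus"] == [("G1", 100.0)]
        assert sorted(table["species"]) == [("S1", 50.0), ("S2", 50.0)]

    def test_rank_sums_are_100(self, fixture_db, rng):
        species = sorted(t for t, n in fixture_db.nodes.items() if n.rank == "species")
        ab = rng.dirichlet(np.ones(len(species)))
        prof = CommunityProfile(
            [CommunityRow(f"g{i}", t, float(a)) for i, (t, a) in enumerate(zip(species, ab))],
            normalized=True,
        )
        table = profiling_gold_standard(prof, fixture_db)
        for rank, rows in table.items():
            assert sum(p for _, p in rows) == pytest.approx(100.0, abs=1e-6)

    def test_uniform_community_equal_strain_shares(self, toy_db):
        k = 4
        prof = CommunityProfile(
            [CommunityRow(f"g{i}", "S1", 1 / k) for i in range(k)], normalized=True
        )
        table = profiling_gold_standard(prof, toy_db)
        assert all(p == pytest.approx(100 / k) for _, p in table["strain"])

    def test_requires_normalized(self, toy_db):
        prof = CommunityProfile([CommunityRow("g1", "S1", 2.0)])
        with pytest.raises(ValueError):
            profiling_gold_standard(prof, toy_db)


class TestAnonymize:
    def test_round_trip_multiset(self, rng):
        records = [(f"id{i}", f"payload{i}") for i in range(1000)]
        anon, amap = anonymize(records, rng)
        assert sorted(p for _, p in anon) == sorted(p for _, p in records)
        inv = amap.inverse
        restored = sorted((inv[a], p) for a, p in anon)
        assert restored == sorted(records)

    def test_same_seed_same_permutation(self):
        records = [(f"id{i}", i) for i in range(50)]
        a1, m1 = anonymize(records, np.random.default_rng(4))
        a2, m2 = anonymize(records, np.random.default_rng(4))
        assert a1 == a2 and m1.forward == m2.forward

    def test_ids_unique_and_sequential(self, rng):
        anon, _ = anonymize([(f"x{i}", None) for i in range(20)], rng, prefix="S")
        assert [a for a, _ in anon] == [f"S{i}" for i in range(20)]

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError):
            anonymize([("a", 1), ("a", 2)], rng)
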