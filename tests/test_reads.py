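import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from mgsim.fixtures import random_sequence
from mgsim.genomes import GenomeRecord
from mgsim.reads import (
    ReadSimParams,
    allocate_reads,
    mean_coverage,
    prepare_genome,
    revcomp,
    simulate_reads,
    simulate_sample,
    subsample_reads,
    write_fastq,
    write_sam,
)


def _prepared(length=5000, seed=0, gid="g0"):
    rng = np.random.default_rng(seed)
    rec = GenomeRecord(gid, "t0", {f"{gid}_c0": random_sequence(length, rng)})
    return prepare_genome(rec, rng)


class TestPrepareGenome:
    def test_run_of_two_splits(self, rng):
        rec = GenomeRecord("g", "t", {"c": "ACGTNNACGT"})
        prep = prepare_genome(rec, rng)
        assert [s for _, s in prep.contigs] == ["ACGT", "ACGT"]
        assert [n for n, _ in prep.contigs] == ["c.0", "c.1"]

    def test_single_ambiguity_resolved(self, rng):
        rec = GenomeRecord("g", "t", {"c": "ACGTNACGT"})
        prep = prepare_genome(rec, rng)
        assert len(prep.contigs) == 1
        seq = prep.contigs[0][1]
        assert len(seq) == 9 and set(seq) <= set("ACGT")
        assert prep.n_ambiguities_resolved == 1

    def test_all_ambiguous_yields_no_contigs(self, rng):
        prep = prepare_genome(GenomeRecord("g", "t", {"c": "NNNN"}), rng)
        assert prep.contigs == []
        with pytest.raises(ValueError, match="g"):
            simulate_reads(prep, 2, ReadSimParams(read_length=2), rng)


class TestAllocateReads:
    def test_equal_split(self):
        alloc = allocate_reads({"a": 0.5, "b": 0.5}, {"a": 100, "b": 100}, 10_000, 100)
        assert alloc.counts == {"a": 50, "b": 50}

    def test_abundance_ratio(self):
        alloc = allocate_reads({"a": 2.0, "b": 1.0}, {"a": 100, "b": 100}, 9_000, 100)
        assert alloc.counts == {"a": 60, "b": 30}

    def test_size_ratio(self):
        alloc = allocate_reads({"a": 1.0, "b": 1.0}, {"a": 200, "b": 100}, 9_000, 100)
        assert alloc.counts == {"a": 60, "b": 30}

    def test_empty_profile(self):
        with pytest.raises(ValueError):
            allocate_reads({}, {}, 1000, 100)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        weights=st.lists(st.floats(0.01, 100), min_size=1, max_size=12),
        total_kb=st.integers(1, 500),
    )
    def test_conservation_property(self, weights, total_kb):
        """Sum of n_t equals n exactly, every count even, for random profiles."""
        ab = {f"g{i}": w for i, w in enumerate(weights)}
        sizes = {g: 1000 for g in ab}
        alloc = allocate_reads(ab, sizes, total_kb * 1000, 150)
        assert sum(alloc.counts.values()) == alloc.total
        assert all(c % 2 == 0 for c in alloc.counts.values())
        assert alloc.total == (total_kb * 1000 // 150) // 2 * 2


class TestSimulateReads:
    def test_pair_count(self, rng):
        pairs = simulate_reads(_prepared(), 10, ReadSimParams(), rng)
        assert len(pairs) == 5
        assert all(len(p.mate1.seq) == 150 and len(p.mate2.seq) == 150 for p in pairs)

    def test_error_free_reads_match_reference(self, rng):
        """With error rate 0, every mate reconstructs from its truth coordinates."""
        prep = _prepared()
        ref = dict(prep.contigs)
        pairs = simulate_reads(prep, 400, ReadSimParams(error_rate=0.0), rng)
        for p in pairs:
            for mate in (p.mate1, p.mate2):
                sub = ref[mate.contig][mate.start : mate.end]
                assert mate.seq == (revcomp(sub) if mate.reverse else sub)

    def test_mate_orientation_fr(self, rng):
        pairs = simulate_reads(_prepared(), 100, ReadSimParams(), rng)
        for p in pairs:
            assert p.mate1.reverse != p.mate2.reverse
            assert p.mate1.contig == p.mate2.contig

    def test_intervals_within_contig(self, rng):
        prep = _prepared(length=800)
        pairs = simulate_reads(prep, 200, ReadSimParams(), rng)
        lens = {n: len(s) for n, s in prep.contigs}
        for p in pairs:
            for mate in (p.mate1, p.mate2):
                assert 0 <= mate.start < mate.end <= lens[mate.contig]

    def test_error_rate_recovered(self, rng):
        """2% uniform errors: empirical mismatch within 3 binomial SEs (~3e5 bases)."""
        prep = _prepared(length=20_000)
        ref = dict(prep.contigs)
        pairs = simulate_reads(prep, 2000, ReadSimParams(error_rate=0.02), rng)
        mism = bases = 0
        for p in pairs:
            for mate in (p.mate1, p.mate2):
                sub = ref[mate.contig][mate.start : mate.end]
                obs = revcomp(mate.seq) if mate.reverse else mate.seq
                mism += sum(x != y for x, y in zip(obs, sub))
                bases += len(sub)
                assert len(mate.error_positions) == sum(x != y for x, y in zip(obs, sub))
        se = np.sqrt(0.02 * 0.98 / bases)
        assert abs(mism / bases - 0.02) <= 3 * se

    def test_odd_count_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_reads(_prepared(), 3, ReadSimParams(), rng)


class TestSubsample:
    def test_identity(self, rng):
        pairs = simulate_reads(_prepared(), 20, ReadSimParams(), rng)
        assert subsample_reads(pairs, 1.0, rng) == pairs

    def test_binomial_keep_count(self, rng):
        pairs = simulate_reads(_prepared(length=100_000), 20_000, ReadSimParams(), rng)
        kept = subsample_reads(pairs, 0.5, rng)
        se = np.sqrt(10_000 * 0.25)
        assert abs(len(kept) - 5000) <= 3 * se

    def test_pairs_kept_atomically(self, rng):
        pairs = simulate_reads(_prepared(), 100, ReadSimParams(), rng)
        kept = subsample_reads(pairs, 0.5, rng)
        assert all(k in pairs for k in kept)

    def test_bad_fraction(self, rng):
        with pytest.raises(ValueError):
            subsample_reads([], 0.0, rng)


class TestSimulateSample:
    def test_single_genome_coverage(self, rng):
        """10x coverage config yields total bases = 10 * genome size, within one read."""
        prep = _prepared(length=30_000)
        pairs, alloc = simulate_sample(
            {"g0": 1.0}, {"g0": prep}, 300_000, ReadSimParams(), rng
        )
        total = sum(len(p.mate1.seq) + len(p.mate2.seq) for p in pairs)
        assert abs(total - 300_000) < 300
        assert mean_coverage(pairs, 30_000) == pytest.approx(10.0, rel=0.01)

    def test_equal_split_and_unique_ids(self, rng):
        preps = {g: _prepared(5000, seed=i, gid=g) for i, g in enumerate(["a", "b"])}
        all_ids = set()
        for s in range(3):
            pairs, alloc = simulate_sample(
                {"a": 0.5, "b": 0.5}, preps, 60_000, ReadSimParams(), rng,
                sample_name=f"S{s}",
            )
            assert alloc.counts["a"] == alloc.counts["b"] == 200
            ids = {p.pair_id for p in pairs}
            assert len(ids) == len(pairs)
            assert not ids & all_ids
            all_ids |= ids

    def test_base_share_proportionality(self, rng):
        """Per-genome base share tracks ab*size within 2% at 1e5 reads."""
        preps = {g: _prepared(4000, seed=i, gid=g) for i, g in enumerate(["a", "b", "c"])}
        ab = {"a": 0.6, "b": 0.3, "c": 0.1}
        pairs, alloc = simulate_sample(ab, preps, 15_000_000, ReadSimParams(), rng)
        w = {g: ab[g] * 4000 for g in ab}
        wsum = sum(w.values())
        for g in ab:
            share = alloc.counts[g] / alloc.total
            assert share == pytest.approx(w[g] / wsum, rel=0.02)


class TestWriters:
    def test_fastq_and_sam_round_trip(self, tmp_path, rng):
        prep = _prepared(3000)
        pairs = simulate_reads(prep, 40, ReadSimParams(), rng, id_prefix="S0_r")
        write_fastq(pairs, tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz")
        write_sam(pairs, {"g0": prep}, tmp_path / "truth.sam")
        ref = dict(prep.contigs)
        n = 0
        with pysam.AlignmentFile(str(tmp_path / "truth.sam"), "r") as fh:
            for aln in fh:
                n += 1
                assert aln.is_paired and aln.is_proper_pair
                assert aln.mapping_quality == 255
                assert aln.cigarstring == "150M"
                sub = ref[aln.reference_name][aln.reference_start : aln.reference_end]
                assert aln.query_sequence == sub  # SAM stores reference-strand sequence
        assert n == 40  # 20 pairs, one record per mate

    def test_fastq_deterministic_gzip(self, tmp_path, rng):
        prep = _prepared(3000)
        pairs = simulate_reads(prep, 20, ReadSimParams(), rng)
        write_fastq(pairs, tmp_path / "a1.fastq.gz", tmp_path / "a2.fastq.gz")
        write_fastq(pairs, tmp_path / "b1.fastq.gz", tmp_path / "b2.fastq.gz")
        # same content, same bytes apart from the embedded file name
        import gzip

        assert gzip.open(tmp_path / "a1.fastq.gz").read() == gzip.open(
            tmp_path / "b1.fastq.gz"
        ).read()
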