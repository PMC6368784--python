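import logging

import numpy as np
import pytest

from mgsim.community import (
    TAXON_EXCLUDED,
    CommunityProfile,
    CommunityRow,
    InputProfile,
    build_lineage_index,
    design_from_profile,
    split_abundance,
    truncated_geometric_pmf,
    truncated_geometric_sample,
)
from mgsim.genomes import GenomeCollection, GenomeRecord
from mgsim.taxonomy import ranks_up_to

from conftest import make_collection


def _single_genome_collection(taxid="S1", quality="complete"):
    coll = GenomeCollection()
    coll.add(GenomeRecord("g1", taxid, {"c": "ACGT" * 200}, quality=quality))
    return coll


class TestLineageIndex:
    def test_single_complete_genome_indexed_at_three_ranks(self, toy_db):
        idx = build_lineage_index(_single_genome_collection(), toy_db, "family")
        assert set(idx.index) == {"S1", "G1", "F1"}
        assert all(idx.get(t) == {"g1"} for t in ("S1", "G1", "F1"))

    def test_scaffold_excluded_by_default_gives_empty_index(self, toy_db):
        coll = _single_genome_collection(quality="scaffold")
        with pytest.raises(ValueError, match="empty index"):
            build_lineage_index(coll, toy_db, "family")
        # opting in to scaffolds indexes it
        idx = build_lineage_index(coll, toy_db, "family", {"complete", "scaffold"})
        assert idx.get("S1") == {"g1"}

    def test_matches_per_genome_lineage_expansion_oracle(self, fixture_db):
        coll = make_collection(fixture_db, genome_length=200, seed=3)
        idx = build_lineage_index(coll, fixture_db, "family")
        expected: dict[str, set[str]] = {}
        for rec in coll:
            lin = fixture_db.lineage(rec.taxid)
            for r in ranks_up_to("family"):
                if lin[r] is not None:
                    expected.setdefault(lin[r], set()).add(rec.genome_id)
        assert idx.index == expected


class TestTruncatedGeometric:
    def test_m2_is_degenerate_at_one(self, rng):
        assert all(truncated_geometric_sample(2, rng) == 1 for _ in range(50))

    def test_m1_returns_one(self, rng):
        assert truncated_geometric_sample(1, rng) == 1

    def test_m10_renormalized_p0(self):
        # brute-force: raw pmf 0.2 * 0.8^k over k=0..9, renormalized
        raw = [0.2 * 0.8**k for k in range(10)]
        expected_p0 = raw[0] / sum(raw)
        assert expected_p0 == pytest.approx(0.2240, abs=1e-4)
        assert truncated_geometric_pmf(10)[0] == pytest.approx(expected_p0, rel=1e-12)

    def test_empirical_frequencies_match_pmf(self, rng):
        """1e4 draws at m=10: per-bin freq within 3 binomial SEs of the pmf."""
        m, n = 10, 10_000
        pmf = truncated_geometric_pmf(m)
        draws = np.array([truncated_geometric_sample(m, rng) for _ in range(n)])
        assert draws.min() >= 1 and draws.max() <= m
        for k in range(m):
            freq = np.mean(draws == k + 1)
            se = np.sqrt(pmf[k] * (1 - pmf[k]) / n)
            assert abs(freq - pmf[k]) <= 3 * se + 1e-12

    def test_invalid_m(self, rng):
        with pytest.raises(ValueError):
            truncated_geometric_sample(0, rng)


class TestSplitAbundance:
    def test_single_genome_gets_everything(self, rng):
        assert split_abundance(0.6, ["g1"], 1, 2, rng) == [("g1", 0.6)]

    def test_sigma_zero_equal_shares(self, rng):
        rows = split_abundance(1.0, ["a", "b", "c", "d"], 1, 0.0, rng)
        assert all(ab == pytest.approx(0.25) for _, ab in rows)

    @pytest.mark.parametrize("trial", range(20))
    def test_conservation(self, trial):
        rng = np.random.default_rng(trial)
        ab_t = float(rng.uniform(0.01, 10))
        k = int(rng.integers(1, 20))
        sigma = float(rng.uniform(0, 3))
        rows = split_abundance(ab_t, [f"g{i}" for i in range(k)], 1, sigma, rng)
        assert sum(ab for _, ab in rows) == pytest.approx(ab_t, rel=1e-12)
        assert all(ab > 0 for _, ab in rows)

    def test_empty_selection(self, rng):
        with pytest.raises(ValueError):
            split_abundance(1.0, [], 1, 2, rng)


class TestDesignFromProfile:
    def test_single_match_trivial(self, toy_db, rng):
        coll = _single_genome_collection()
        idx = build_lineage_index(coll, toy_db, "family")
        out = design_from_profile(InputProfile([("S1", 0.6)]), idx, toy_db, coll, rng, m=1)
        assert [(r.genome_id, r.abundance) for r in out.rows] == [("g1", 0.6)]
        assert out.rows[0].matched_rank == "species"

    def test_unmatched_taxon_warns_then_empty_community_errors(self, toy_db, rng, caplog):
        coll = _single_genome_collection()
        idx = build_lineage_index(coll, toy_db, "family")
        # F2 does not exist in the db -> lineage lookup fails cleanly via another species-less taxon
        profile = InputProfile([("B", 0.4)])  # superkingdom: above r_max, no genome at searched ranks
        with caplog.at_level(logging.WARNING):
            with pytest.raises(ValueError, match="empty community"):
                design_from_profile(profile, idx, toy_db, coll, rng)
        assert sum(TAXON_EXCLUDED in r.message for r in caplog.records) == 1

    def test_no_genome_selected_twice(self, toy_db, rng, caplog):
        """Two taxa resolving to the same sole genome: second is excluded."""
        coll = _single_genome_collection()
        idx = build_lineage_index(coll, toy_db, "family")
        profile = InputProfile([("S1", 0.6), ("G1", 0.4)])
        with caplog.at_level(logging.WARNING):
            out = design_from_profile(profile, idx, toy_db, coll, rng)
        assert out.genome_ids() == ["g1"]
        assert sum(TAXON_EXCLUDED in r.message for r in caplog.records) == 1

    def test_reuse_allows_both(self, toy_db, rng):
        coll = _single_genome_collection()
        idx = build_lineage_index(coll, toy_db, "family")
        profile = InputProfile([("S1", 0.6), ("G1", 0.4)])
        out = design_from_profile(profile, idx, toy_db, coll, rng, allow_reuse=True)
        assert out.genome_ids() == ["g1", "g1"]
        merged = out.merged()
        assert merged.total() == pytest.approx(1.0)

    def test_abundance_conservation_and_matched_rank_oracle(self, fixture_db):
        """Random profiles: mass conserved; matched rank is the lowest non-empty."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coll = make_collection(fixture_db, genome_length=200, seed=seed)
            idx = build_lineage_index(coll, fixture_db, "family")
            frozen = {t: set(g) for t, g in idx.index.items()}
            taxa = sorted(idx.index)
            picks = [taxa[i] for i in rng.choice(len(taxa), size=3, replace=False)]
            profile = InputProfile([(t, float(rng.uniform(0.1, 5))) for t in picks])
            out = design_from_profile(profile, idx, fixture_db, coll, rng, m=3)
            matched_mass = sum(
                abund for t, abund in profile.rows
                if any(r.source_taxon == t for r in out.rows)
            )
            assert out.total() == pytest.approx(matched_mass, rel=1e-9)
            # genomes unique without reuse
            assert len(out.genome_ids()) == len(set(out.genome_ids()))
            # matched rank oracle: with reuse on, the index never shrinks, so
            # every taxon must match at the lowest searched rank with genomes
            idx2 = build_lineage_index(coll, fixture_db, "family")
            out2 = design_from_profile(
                profile, idx2, fixture_db, coll, np.random.default_rng(seed),
                m=3, allow_reuse=True,
            )
            for t, _ in profile.rows:
                rows = [r for r in out2.rows if r.source_taxon == t]
                if not rows:
                    continue
                lin = fixture_db.lineage(t)
                lowest = next(
                    r for r in ranks_up_to("family")
                    if lin[r] is not None and frozen.get(lin[r])
                )
                assert rows[0].matched_rank == lowest

    def test_determinism(self, fixture_db):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            coll = make_collection(fixture_db, genome_length=200, seed=1)
            idx = build_lineage_index(coll, fixture_db, "family")
            taxa = sorted(idx.index)
            profile = InputProfile([(t, 1.0) for t in taxa[:4]])
            out = design_from_profile(profile, idx, fixture_db, coll, rng, m=3)
            outs.append([(r.genome_id, r.abundance) for r in out.rows])
        assert outs[0] == outs[1]


class TestCommunityProfile:
    def test_normalize_sums_to_one(self):
        p = CommunityProfile(
            rows=[CommunityRow("a", "t1", 3.0), CommunityRow("b", "t2", 1.0)]
        )
        n = p.normalize()
        assert n.total() == pytest.approx(1.0, abs=1e-9)
        assert n.abundances()["a"] == pytest.approx(0.75)

    def test_tsv_round_trip(self, tmp_path):
        p = CommunityProfile(rows=[CommunityRow("a", "t1", 0.5)])
        p.to_tsv(tmp_path / "c.tsv")
        q = CommunityProfile.from_tsv(tmp_path / "c.tsv")
        assert q.rows[0].genome_id == "a" and q.rows[0].abundance == 0.5
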