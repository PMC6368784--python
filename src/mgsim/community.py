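"""Profile-based community design.

Turns an input taxonomic profile P_in — pairs (t, ab_t) of taxon ids and
nonnegative abundances — into a genome-resolved community profile P_out.
For each profile taxon the lineage is walked from species up to a highest
search rank r_max; at the first rank with genomes available, the number of
genomes (strains) to include is drawn from a truncated geometric
distribution with mean m/2, and the taxon's abundance is split across the
chosen genomes with lognormal weights:

    Y_i ~ Lognormal(mu, sigma),   ab_i = Y_i / sum_j Y_j * ab_t

so the per-taxon abundance mass is conserved exactly. By default a genome
is never selected twice; taxa whose lineage has no genomes at any searched
rank are excluded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mgsim.genomes import GenomeCollection
from mgsim.taxonomy import DEFAULT_R_MAX, TaxonomyDB, ranks_up_to

logger = logging.getLogger(__name__)

#: machine-greppable prefix for excluded-taxon warnings
TAXON_EXCLUDED = "TAXON-EXCLUDED"


@dataclass
class InputProfile:
    """The input taxonomic profile P_in: rows of (taxon id, abundance)."""

    rows: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for t, ab in self.rows:
            if ab < 0:
                raise ValueError(f"taxon {t}: negative abundance {ab}")
        if not any(ab > 0 for _, ab in self.rows):
            raise ValueError("input profile has no positive abundance")

    def total(self) -> float:
        return float(sum(ab for _, ab in self.rows))


@dataclass
class CommunityRow:
    genome_id: str
    taxid: str
    abundance: float
    source_taxon: str | None = None
    matched_rank: str | None = None


@dataclass
class CommunityProfile:
    """The designed community P_out: (genome, taxon, abundance) rows."""

    rows: list[CommunityRow] = field(default_factory=list)
    normalized: bool = False

    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.rows]

    def total(self) -> float:
        return float(sum(r.abundance for r in self.rows))

    def merged(self) -> "CommunityProfile":
        """Merge duplicate genome rows (genome reuse) by summing abundances."""
        seen: dict[str, CommunityRow] = {}
        for r in self.rows:
            if r.genome_id in seen:
                seen[r.genome_id].abundance += r.abundance
            else:
                seen[r.genome_id] = CommunityRow(
                    r.genome_id, r.taxid, r.abundance, r.source_taxon, r.matched_rank
                )
        return CommunityProfile(rows=list(seen.values()), normalized=self.normalized)

    def normalize(self) -> "CommunityProfile":
        """Rescale abundances to sum to 1 (duplicate genome rows merged first)."""
        merged = self.merged()
        total = merged.total()
        if total <= 0:
            raise ValueError("cannot normalize a community with zero total abundance")
        for r in merged.rows:
            r.abundance /= total
        merged.normalized = True
        return merged

    def abundances(self) -> dict[str, float]:
        return {r.genome_id: r.abundance for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.genome_id, r.taxid, r.abundance, r.source_taxon, r.matched_rank)
                for r in self.rows
            ],
            columns=["genome_id", "taxid", "abundance", "source_taxon", "matched_rank"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame()[["genome_id", "taxid", "abundance"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "CommunityProfile":
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "taxid": str})
        rows = [
            CommunityRow(r.genome_id, r.taxid, float(r.abundance))
            for r in df.itertuples(index=False)
        ]
        return cls(rows=rows, normalized=normalized)


@dataclass
class LineageIndex:
    """Map lineage taxon id -> set of genome ids (the collection F of sets G_t)."""

    index: dict[str, set[str]]

    def get(self, taxid: str) -> set[str]:
        return self.index.get(taxid, set())

    def remove_genome(self, genome_id: str) -> None:
        for members in self.index.values():
            members.discard(genome_id)


def build_lineage_index(
    collection: GenomeCollection,
    db: TaxonomyDB,
    r_max: str = DEFAULT_R_MAX,
    quality: set[str] | frozenset[str] = frozenset({"complete"}),
) -> LineageIndex:
    """Index genomes under every lineage taxon at ranks species..r_max.

    Only genomes whose assembly quality tag is in ``quality`` are indexed
    (by default only ``complete`` genomes; scaffolds and contigs are
    opt-in).
    """
    if len(collection) == 0:
        raise ValueError("genome collection is empty")
    index: dict[str, set[str]] = {}
    searched = ranks_up_to(r_max)
    for rec in collection:
        if rec.quality not in quality:
            continue
        lin = db.lineage(rec.taxid)
        for r in searched:
            t_r = lin[r]
            if t_r is not None:
                index.setdefault(t_r, set()).add(rec.genome_id)
    if not index:
        raise ValueError(
            f"empty index: no genome passes the quality filter {sorted(quality)}"
        )
    return LineageIndex(index=index)


def truncated_geometric_pmf(m: int) -> np.ndarray:
    """Renormalized pmf of the truncated geometric strain-count draw.

    With mean mu = m/2 the raw pmf is p(k) = (1 - 1/mu)^k / mu on
    k = 0..m-1; renormalizing over that support gives the distribution of
    k, and the returned strain count is X = k + 1 in 1..m.
    """
    if m < 1:
        raise ValueError(f"maximum strain count m must be >= 1, got {m}")
    if m == 1:
        return np.array([1.0])
    mu = m / 2.0
    k = np.arange(m)
    raw = (1.0 - 1.0 / mu) ** k / mu
    return raw / raw.sum()


def truncated_geometric_sample(m: int, rng: np.random.Generator) -> int:
    """Draw a strain count X in 1..m from the truncated geometric pmf."""
    pmf = truncated_geometric_pmf(m)
    return int(rng.choice(len(pmf), p=pmf)) + 1


def split_abundance(
    ab_t: float,
    selected: list[str],
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """Split a taxon abundance across selected genomes with lognormal weights.

    Conserves the total exactly: the weights are normalized to sum to 1
    before scaling by ``ab_t``. ``sigma = 0`` gives equal shares.
    """
    if not selected:
        raise ValueError("cannot split abundance over an empty genome set")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    y = rng.lognormal(mean=mu, sigma=sigma, size=len(selected))
    shares = y / y.sum()
    return [(gid, float(share * ab_t)) for gid, share in zip(selected, shares)]


def design_from_profile(
    p_in: InputProfile,
    index: LineageIndex,
    db: TaxonomyDB,
    collection: GenomeCollection,
    rng: np.random.Generator,
    r_max: str = DEFAULT_R_MAX,
    m: int = 10,
    mu: float = 1.0,
    sigma: float = 2.0,
    allow_reuse: bool = False,
) -> CommunityProfile:
    """Resolve an input profile to a genome community (Algorithm 1 analogue).

    For each (t, ab_t): walk ranks species -> r_max along t's lineage; at
    the first rank whose taxon has genomes in the index, draw the strain
    count X, sample min(X, available) genomes uniformly without
    replacement, and split ab_t across them. Unless ``allow_reuse``,
    chosen genomes are removed from the whole index. Taxa with no genomes
    at any searched rank are excluded with a warning; if every taxon is
    excluded an error is raised.
    """
    searched = ranks_up_to(r_max)
    out = CommunityProfile()
    for t, ab_t in p_in.rows:
        lin = db.lineage(t)
        match_rank = None
        candidates: list[str] = []
        for r in searched:
            t_r = lin[r]
            if t_r is None:
                continue
            members = sorted(index.get(t_r))
            if members:
                match_rank = r
                candidates = members
                break
        if match_rank is None:
            logger.warning(
                "%s taxon %s has no available genome at any rank up to %s",
                TAXON_EXCLUDED,
                t,
                r_max,
            )
            continue
        x = truncated_geometric_sample(m, rng)
        if len(candidates) <= x:
            selected = candidates
        else:
            selected = [
                candidates[i]
                for i in sorted(rng.choice(len(candidates), size=x, replace=False))
            ]
        for gid, ab_i in split_abundance(ab_t, selected, mu, sigma, rng):
            out.rows.append(
                CommunityRow(
                    genome_id=gid,
                    taxid=collection[gid].taxid,
                    abundance=ab_i,
                    source_taxon=t,
                    matched_rank=match_rank,
                )
            )
        if not allow_reuse:
            for gid in selected:
                index.remove_genome(gid)
    if not out.rows:
        raise ValueError("empty community: no input taxon could be resolved to a genome")
    return out
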