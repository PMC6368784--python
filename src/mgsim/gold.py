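"""Gold standards derived from ground-truth alignments.

The perfect assembly of a sample is the set of maximal reference regions
covered by at least one simulated read, extracted error-free from the
reference; the co-assembly applies the same rule to the pooled truth of
all samples. Because truth coordinates are exact, coverage is computed
directly by merging the mate intervals — provably equivalent to a
per-base pileup for error-free coordinates (each mate covers exactly its
interval; the insert interior between mates is not covered).

Binning gold standards assign every emitted sequence (read or gold
contig) its source genome and taxon; the profiling gold standard reports
per-rank relative abundances in percent, from strain (genome) level up to
superkingdom. Sequences can be anonymized and shuffled with a reversible,
seeded mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mgsim.community import CommunityProfile
from mgsim.ioutil import open_text
from mgsim.reads import PreparedGenome, ReadPair
from mgsim.taxonomy import RANKS, TaxonomyDB

BINNING_HEADER = ["@Version:1.0", "@@SEQUENCEID\tBINID\tTAXID"]


@dataclass
class GoldContig:
    """An error-free contig covering one maximal covered region."""

    scope: str  # sample id or "pooled"
    genome_id: str
    contig: str
    start: int  # 0-based half-open on the reference contig
    end: int
    sequence: str

    @property
    def contig_id(self) -> str:
        return f"{self.scope}_{self.contig}_{self.start}_{self.end}"


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as maximal disjoint runs.

    Touching intervals ([0,100) + [100,200)) merge: coverage >= 1 is
    contiguous across the boundary.
    """
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _truth_intervals(pairs: list[ReadPair]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    by_contig: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in pairs:
        for mate in (p.mate1, p.mate2):
            by_contig.setdefault((p.genome_id, mate.contig), []).append(
                (mate.start, mate.end)
            )
    return by_contig


def perfect_assembly(
    pairs: list[ReadPair],
    genomes: dict[str, PreparedGenome],
    scope: str = "S0",
) -> list[GoldContig]:
    """Error-free contigs for every maximal region with coverage >= 1."""
    out: list[GoldContig] = []
    for (gid, cname), intervals in sorted(_truth_intervals(pairs).items()):
        if gid not in genomes:
            raise KeyError(f"truth references unknown genome {gid!r}")
        ref = genomes[gid].contig_seq(cname)
        for s, e in _merge_intervals(intervals):
            if e > len(ref):
                raise ValueError(
                    f"truth interval [{s},{e}) exceeds contig {cname} length {len(ref)}"
                )
            out.append(
                GoldContig(
                    scope=scope, genome_id=gid, contig=cname, start=s, end=e,
                    sequence=ref[s:e],
                )
            )
    return out


def perfect_coassembly(
    samples: dict[str, list[ReadPair]],
    genomes: dict[str, PreparedGenome],
) -> list[GoldContig]:
    """Perfect assembly of all samples pooled together."""
    pooled = [p for pairs in samples.values() for p in pairs]
    return perfect_assembly(pooled, genomes, scope="pooled")


def perfect_assembly_coverage_oracle(
    pairs: list[ReadPair],
    genomes: dict[str, PreparedGenome],
    scope: str = "S0",
) -> list[GoldContig]:
    """Per-base coverage-array route to the same contigs (cross-check).

    Builds an explicit coverage counter per reference position and
    extracts maximal runs with coverage >= 1. Kept as a first-class
    alternative implementation so the interval-merge route can be
    verified against it.
    """
    out: list[GoldContig] = []
    for (gid, cname), intervals in sorted(_truth_intervals(pairs).items()):
        ref = genomes[gid].contig_seq(cname)
        cov = np.zeros(len(ref) + 1, dtype=np.int32)
        for s, e in intervals:
            cov[s] += 1
            cov[e] -= 1
        covered = np.cumsum(cov[:-1]) > 0
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(
                GoldContig(
                    scope=scope, genome_id=gid, contig=cname,
                    start=int(s), end=int(e), sequence=ref[int(s):int(e)],
                )
            )
    return out


# -- binning ---------------------------------------------------------------


@dataclass
class BinningAssignment:
    sequence_id: str
    genome_id: str
    taxid: str


def binning_gold_standard(
    sequences: list[tuple[str, str]],
    genome_taxids: dict[str, str],
    db: TaxonomyDB | None = None,
) -> list[BinningAssignment]:
    """One (sequence id, genome id, taxon id) row per emitted sequence.

    ``sequences`` are (sequence id, source genome id) pairs — reads or
    gold contigs. If a taxonomy is supplied, every taxid must resolve in
    it (so the taxon binning file is lineage-resolvable downstream).
    """
    out = []
    for seq_id, gid in sequences:
        if gid not in genome_taxids:
            raise KeyError(f"sequence {seq_id}: no provenance for genome {gid!r}")
        taxid = genome_taxids[gid]
        if db is not None and taxid not in db:
            raise KeyError(f"genome {gid}: taxid {taxid!r} not in taxonomy")
        out.append(BinningAssignment(seq_id, gid, taxid))
    return out


def write_binning_tsv(assignments: list[BinningAssignment], path, sample_id: str = "") -> None:
    with open_text(path) as fh:
        if sample_id:
            fh.write(f"@SampleID:{sample_id}\n")
        for line in BINNING_HEADER:
            fh.write(line + "\n")
        for a in assignments:
            fh.write(f"{a.sequence_id}\t{a.genome_id}\t{a.taxid}\n")


# -- profiling -------------------------------------------------------------


def profiling_gold_standard(
    profile: CommunityProfile,
    db: TaxonomyDB,
) -> dict[str, list[tuple[str, float]]]:
    """Per-rank relative abundances in percent, strain to superkingdom.

    The ``strain`` level reports each genome; at every rank of the rank
    list, a taxon's percentage is the summed relative abundance of its
    member genomes times 100. Mass from genomes with no defined taxon at
    a rank is reported under the pseudo-taxon ``unassigned``, so each
    rank's column sums to 100.
    """
    if not profile.normalized:
        raise ValueError("profiling gold standard requires a normalized profile")
    table: dict[str, list[tuple[str, float]]] = {
        "strain": [(r.genome_id, 100.0 * r.abundance) for r in profile.rows]
    }
    for rank in RANKS:
        acc: dict[str, float] = {}
        for r in profile.rows:
            t = db.lineage(r.taxid)[rank]
            key = t if t is not None else "unassigned"
            acc[key] = acc.get(key, 0.0) + 100.0 * r.abundance
        table[rank] = sorted(acc.items())
    return table


def write_profiling_tsv(table: dict[str, list[tuple[str, float]]], path, db: TaxonomyDB | None = None) -> None:
    """Rank-sectioned percentage TSV (rank, taxid, name, percent)."""
    with open_text(path) as fh:
        fh.write("@Ranks:strain|" + "|".join(RANKS) + "\n")
        fh.write("@@RANK\tTAXID\tNAME\tPERCENTAGE\n")
        for rank, rows in table.items():
            for taxid, pct in rows:
                name = ""
                if db is not None and taxid in db:
                    name = db.name(taxid)
                fh.write(f"{rank}\t{taxid}\t{name}\t{pct:.6f}\n")


# -- anonymization ---------------------------------------------------------


@dataclass
class AnonymizationMap:
    forward: dict[str, str]  # original -> anonymous
    seed_note: str = ""

    @property
    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.forward.items()}

    def write_tsv(self, path) -> None:
        with open_text(path) as fh:
            fh.write("anonymous_id\toriginal_id\n")
            for orig, anon in self.forward.items():
                fh.write(f"{anon}\t{orig}\n")


def anonymize(
    records: list[tuple[str, object]],
    rng: np.random.Generator,
    prefix: str = "SEQ",
) -> tuple[list[tuple[str, object]], AnonymizationMap]:
    """Shuffle records and rename them with serial anonymous ids.

    Returns the shuffled, renamed records plus the bijective id map; the
    inverse map restores the originals exactly.
    """
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate original ids; anonymization map would not be bijective")
    perm = rng.permutation(len(records))
    shuffled = [records[i] for i in perm]
    forward = {}
    out: list[tuple[str, object]] = []
    for serial, (rid, payload) in enumerate(shuffled):
        anon = f"{prefix}{serial}"
        forward[rid] = anon
        out.append((anon, payload))
    return out, AnonymizationMap(forward=forward)


def write_gold_fasta(contigs: list[GoldContig], path) -> None:
    with open_text(path) as fh:
        for c in contigs:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")
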