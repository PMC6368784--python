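"""Paired-end shotgun read simulation with ground truth.

The engine follows the wgsim uniform-error model: fragments of normally
distributed length are placed uniformly on contigs, a mate is cut from
each fragment end (mate 2 reverse-complemented; on the minus strand the
roles swap, preserving forward/reverse orientation), and each read base
is substituted independently with probability ``error_rate`` to a
uniformly chosen different base. Base qualities are constant. Every mate
carries its exact source coordinates and error positions, the substrate
for all gold standards.

Read counts per genome follow the abundance-weighted allocation

    n_t = n * ab_t * s_t / sum_i ab_i * s_i

with n = floor(total_bases / read_length) rounded down to even, and
largest-remainder rounding over pairs so the per-genome counts are even
and sum to n exactly.

Genomes are prepared before simulation: contigs are split at runs of two
or more ambiguous bases (the runs removed) so no read spans such a
border, and isolated single ambiguities are replaced by a random concrete
base.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pysam

from mgsim.genomes import GenomeRecord
from mgsim.ioutil import open_text

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_AMBIG_RUN = re.compile(r"[^ACGTacgt]{2,}")
_SINGLE_AMBIG = re.compile(r"[^ACGTacgt]")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSimParams:
    """Tunable read-simulation parameters.

    Insert (fragment) size defaults to 2*read_length + 120 with a 10%
    standard deviation; fragment lengths are clipped to at least
    2*read_length (non-overlapping mates) and at most the contig length.
    """

    read_length: int = 150
    insert_mean: int | None = None
    insert_sd: float | None = None
    error_rate: float = 0.0
    base_quality: int = 40

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.insert_mean is None:
            self.insert_mean = 2 * self.read_length + 120
        if self.insert_sd is None:
            self.insert_sd = 0.1 * self.insert_mean
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")

    @property
    def quality_char(self) -> str:
        return chr(33 + self.base_quality)


@dataclass
class PreparedGenome:
    """A genome after ambiguity splitting, ready for simulation."""

    genome_id: str
    contigs: list[tuple[str, str]]  # (contig name, ACGT-only sequence)
    n_ambiguities_resolved: int = 0

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def contig_seq(self, name: str) -> str:
        for cname, seq in self.contigs:
            if cname == name:
                return seq
        raise KeyError(f"genome {self.genome_id}: unknown contig {name!r}")


@dataclass
class ReadAllocation:
    """Per-genome read counts n_t summing exactly to the sample total n."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("allocation counts do not sum to the total")
        for gid, c in self.counts.items():
            if c < 0 or c % 2:
                raise ValueError(f"genome {gid}: read count {c} not an even nonnegative")


@dataclass
class Mate:
    """One read of a pair, with its truth alignment."""

    seq: str
    qual: str
    contig: str
    start: int  # 0-based, half-open [start, end) on the prepared contig
    end: int
    reverse: bool
    error_positions: tuple[int, ...] = ()


@dataclass
class ReadPair:
    pair_id: str
    genome_id: str
    mate1: Mate
    mate2: Mate


def prepare_genome(record: GenomeRecord, rng: np.random.Generator) -> PreparedGenome:
    """Split contigs at ambiguity runs and resolve isolated ambiguities.

    Maximal runs of >= 2 non-ACGT characters split the contig (the run
    itself is dropped); remaining single ambiguous bases are replaced by
    an rng-chosen concrete base, logged. Pieces shorter than a read are
    kept but will never host a fragment.
    """
    contigs: list[tuple[str, str]] = []
    resolved = 0
    for cname, seq in record.sequences.items():
        pieces = [p for p in _AMBIG_RUN.split(seq) if p]
        multi = len(pieces) > 1
        for i, piece in enumerate(pieces):
            ambigs = _SINGLE_AMBIG.findall(piece)
            if ambigs:
                chars = list(piece)
                for j, ch in enumerate(chars):
                    if ch.upper() not in _BASE_IDX:
                        chars[j] = _BASES[rng.integers(4)]
                        resolved += 1
                piece = "".join(chars)
            name = f"{cname}.{i}" if multi else cname
            contigs.append((name, piece.upper()))
    if resolved:
        logger.info(
            "genome %s: resolved %d isolated ambiguous bases", record.genome_id, resolved
        )
    return PreparedGenome(
        genome_id=record.genome_id, contigs=contigs, n_ambiguities_resolved=resolved
    )


def allocate_reads(
    abundances: dict[str, float],
    sizes: dict[str, int],
    total_bases: int,
    read_length: int = 150,
) -> ReadAllocation:
    """Allocate reads to genomes proportionally to abundance x genome size.

    ``n = floor(total_bases / read_length)`` rounded down to even; the
    per-genome counts use largest-remainder rounding over pairs so every
    count is even and the counts sum to n exactly.
    """
    if not abundances:
        raise ValueError("empty community profile")
    if total_bases < read_length:
        raise ValueError("total_bases must be at least one read length")
    gids = sorted(abundances)
    for gid in gids:
        if sizes.get(gid, 0) <= 0:
            raise ValueError(f"genome {gid}: missing or nonpositive size")
    n = (total_bases // read_length) // 2 * 2
    n_pairs = n // 2
    w = np.array([abundances[g] * sizes[g] for g in gids], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total abundance mass is zero")
    raw = n_pairs * w / w.sum()
    base = np.floor(raw).astype(int)
    short = n_pairs - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    counts = {g: int(2 * c) for g, c in zip(gids, base)}
    return ReadAllocation(counts=counts, total=n)


def _host_contigs(genome: PreparedGenome, read_length: int):
    usable = [(name, seq) for name, seq in genome.contigs if len(seq) >= 2 * read_length]
    if not usable:
        raise ValueError(
            f"genome {genome.genome_id}: no contig can host a fragment of "
            f"{2 * read_length} bp"
        )
    weights = np.array([len(s) - 2 * read_length + 1 for _, s in usable], dtype=float)
    return usable, weights / weights.sum()


def simulate_reads(
    genome: PreparedGenome,
    n_t: int,
    params: ReadSimParams,
    rng: np.random.Generator,
    id_prefix: str = "",
) -> list[ReadPair]:
    """Simulate ``n_t`` reads (``n_t``/2 pairs) from one prepared genome."""
    if n_t % 2:
        raise ValueError(f"read count must be even for pairing, got {n_t}")
    n_pairs = n_t // 2
    if n_pairs == 0:
        return []
    usable, probs = _host_contigs(genome, params.read_length)
    r = params.read_length
    lens = np.array([len(s) for _, s in usable])
    cidx = rng.choice(len(usable), size=n_pairs, p=probs)
    frag = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)).astype(int)
    frag = np.clip(frag, 2 * r, lens[cidx])
    start = (rng.random(n_pairs) * (lens[cidx] - frag + 1)).astype(int)
    minus = rng.random(n_pairs) < 0.5

    pairs: list[ReadPair] = []
    qual = params.quality_char * r
    for k in range(n_pairs):
        cname, cseq = usable[cidx[k]]
        s, f = int(start[k]), int(frag[k])
        left = cseq[s : s + r]
        right = revcomp(cseq[s + f - r : s + f])
        m_left = Mate(seq=left, qual=qual, contig=cname, start=s, end=s + r, reverse=False)
        m_right = Mate(
            seq=right, qual=qual, contig=cname, start=s + f - r, end=s + f, reverse=True
        )
        m1, m2 = (m_right, m_left) if minus[k] else (m_left, m_right)
        pairs.append(
            ReadPair(
                pair_id=f"{id_prefix}{k}",
                genome_id=genome.genome_id,
                mate1=m1,
                mate2=m2,
            )
        )
    if params.error_rate > 0:
        _apply_errors(pairs, params, rng)
    return pairs


def _apply_errors(pairs: list[ReadPair], params: ReadSimParams, rng: np.random.Generator) -> None:
    """Substitute read bases i.i.d. with prob error_rate, in place.

    Implemented as a binomial error count per mate plus a uniform choice
    of distinct positions, which is distributionally identical to
    independent per-base Bernoulli draws.
    """
    r = params.read_length
    counts = rng.binomial(r, params.error_rate, size=2 * len(pairs))
    i = 0
    for pair in pairs:
        for mate in (pair.mate1, pair.mate2):
            c = int(counts[i])
            i += 1
            if c == 0:
                continue
            pos = np.sort(rng.choice(r, size=c, replace=False))
            offs = rng.integers(1, 4, size=c)
            chars = list(mate.seq)
            for p, o in zip(pos, offs):
                chars[p] = _BASES[(_BASE_IDX[chars[p]] + o) % 4]
            mate.seq = "".join(chars)
            mate.error_positions = tuple(int(p) for p in pos)


def subsample_reads(
    pairs: list[ReadPair], fraction: float, rng: np.random.Generator
) -> list[ReadPair]:
    """Keep each pair atomically with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(pairs)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


def simulate_sample(
    abundances: dict[str, float],
    genomes: dict[str, PreparedGenome],
    total_bases: int,
    params: ReadSimParams,
    rng: np.random.Generator,
    sample_name: str = "S0",
) -> tuple[list[ReadPair], ReadAllocation]:
    """Simulate one sample: allocate reads across genomes, then simulate.

    Read pair ids are ``{sample_name}_r{serial}`` with a sample-wide
    serial, so ids are unique within and across samples of a run.
    """
    sizes = {gid: genomes[gid].total_length for gid in abundances}
    alloc = allocate_reads(abundances, sizes, total_bases, params.read_length)
    pairs: list[ReadPair] = []
    serial = 0
    for gid in sorted(alloc.counts):
        n_t = alloc.counts[gid]
        if n_t == 0:
            continue
        new = simulate_reads(genomes[gid], n_t, params, rng, id_prefix=f"{sample_name}_r")
        for p in new:
            p.pair_id = f"{sample_name}_r{serial}"
            serial += 1
        pairs.extend(new)
    return pairs, alloc


def mean_coverage(pairs: list[ReadPair], genome_length: int) -> float:
    """Mean per-base fold coverage: total simulated bases / genome length."""
    total = sum(len(p.mate1.seq) + len(p.mate2.seq) for p in pairs)
    return total / genome_length


# -- writers ---------------------------------------------------------------


def write_fastq(pairs: list[ReadPair], path_r1, path_r2) -> None:
    """Write mates to a FASTQ file pair (gzip if the paths end in .gz)."""
    with open_text(path_r1) as f1, open_text(path_r2) as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.mate1.seq}\n+\n{p.mate1.qual}\n")
            f2.write(f"@{p.pair_id}/2\n{p.mate2.seq}\n+\n{p.mate2.qual}\n")


def sam_header(genomes: dict[str, PreparedGenome]) -> dict:
    """SAM header dict with one @SQ line per prepared contig."""
    sq = []
    seen: set[str] = set()
    for gid in sorted(genomes):
        for cname, seq in genomes[gid].contigs:
            if cname in seen:
                raise ValueError(f"duplicate contig name {cname!r} across genomes")
            seen.add(cname)
            sq.append({"SN": cname, "LN": len(seq)})
    return {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq}


def write_sam(pairs: list[ReadPair], genomes: dict[str, PreparedGenome], path) -> None:
    """Write truth alignments as SAM (QNAME/FLAG/RNAME/POS/MAPQ=255/CIGAR).

    Proper-pair and reverse flags are set; positions are the exact truth
    coordinates, CIGAR is full-length match.
    """
    header = pysam.AlignmentHeader.from_dict(sam_header(genomes))
    tid = {sq["SN"]: i for i, sq in enumerate(header.to_dict()["SQ"])}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for idx, (mate, other) in enumerate(
                ((p.mate1, p.mate2), (p.mate2, p.mate1))
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = p.pair_id
                a.flag = (
                    0x1
                    | 0x2
                    | (0x10 if mate.reverse else 0)
                    | (0x20 if other.reverse else 0)
                    | (0x40 if idx == 0 else 0x80)
                )
                a.reference_id = tid[mate.contig]
                a.reference_start = mate.start
                a.mapping_quality = 255
                a.cigarstring = f"{len(mate.seq)}M"
                a.next_reference_id = tid[other.contig]
                a.next_reference_start = other.start
                tlen = max(mate.end, other.end) - min(mate.start, other.start)
                a.template_length = tlen if mate.start <= other.start else -tlen
                a.query_sequence = revcomp(mate.seq) if mate.reverse else mate.seq
                a.query_qualities = pysam.qualitystring_to_array(mate.qual)
                out.write(a)
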