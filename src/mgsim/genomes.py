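"""Genome records and collections.

A :class:`GenomeRecord` holds a genome's contig sequences plus the
metadata the community designers need: its taxon id, an optional OTU id
and novelty category (de novo design), and an assembly quality tag
(``complete`` / ``scaffold`` / ``contig``). A :class:`GenomeCollection`
is the pool both design modes sample from; it loads lazily from a
metadata TSV pointing at FASTA files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

QUALITY_TAGS = ("complete", "scaffold", "contig")

IUPAC = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")


@dataclass
class GenomeRecord:
    genome_id: str
    taxid: str
    sequences: dict[str, str]
    quality: str = "complete"
    otu: str | None = None
    novelty_category: str | None = None

    def __post_init__(self) -> None:
        if self.quality not in QUALITY_TAGS:
            raise ValueError(
                f"genome {self.genome_id}: quality {self.quality!r} not in {QUALITY_TAGS}"
            )
        for cname, seq in self.sequences.items():
            bad = set(seq) - IUPAC
            if bad:
                raise ValueError(
                    f"genome {self.genome_id} contig {cname}: non-IUPAC characters {sorted(bad)}"
                )

    @property
    def size(self) -> int:
        """Total genome length in bp (summed contig lengths)."""
        return sum(len(s) for s in self.sequences.values())

    @classmethod
    def from_fasta(cls, genome_id: str, path: str | Path, **kwargs) -> "GenomeRecord":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        if not sequences:
            raise ValueError(f"no sequences in FASTA {path}")
        return cls(genome_id=genome_id, sequences=sequences, **kwargs)


@dataclass
class GenomeCollection:
    """A mapping genome id -> :class:`GenomeRecord`."""

    records: dict[str, GenomeRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.records

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self.records[genome_id]

    def add(self, record: GenomeRecord) -> None:
        if record.genome_id in self.records:
            raise ValueError(f"duplicate genome id {record.genome_id!r}")
        self.records[record.genome_id] = record

    def ids(self) -> list[str]:
        return list(self.records)

    def sizes(self) -> dict[str, int]:
        return {gid: rec.size for gid, rec in self.records.items()}

    @classmethod
    def from_metadata(cls, metadata_path: str | Path) -> "GenomeCollection":
        """Load from a metadata TSV.

        Columns: ``genome_id``, ``fasta_path`` (relative paths resolved
        against the TSV's directory), ``taxid``, ``quality`` and optionally
        ``otu`` and ``novelty_category``.
        """
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        required = {"genome_id", "fasta_path", "taxid"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata {metadata_path}: missing columns {sorted(missing)}")
        base = Path(metadata_path).parent
        coll = cls()
        for row in meta.itertuples(index=False):
            fasta = Path(row.fasta_path)
            if not fasta.is_absolute():
                fasta = base / fasta
            coll.add(
                GenomeRecord.from_fasta(
                    row.genome_id,
                    fasta,
                    taxid=row.taxid,
                    quality=getattr(row, "quality", "complete") or "complete",
                    otu=getattr(row, "otu", None),
                    novelty_category=getattr(row, "novelty_category", None),
                )
            )
        return coll

    def write_fasta(self, genome_id: str, path: str | Path) -> None:
        rec = self[genome_id]
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for cname, seq in rec.sequences.items():
                fh.write(f">{cname}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def read_otu_mapping(path: str | Path) -> pd.DataFrame:
    """Read a de novo design mapping TSV.

    Columns: ``genome_id``, ``taxid``, ``novelty_category``, ``otu``.
    Every genome in the sampling collection must have exactly one row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "taxid", "novelty_category", "otu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping {path}: missing columns {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"mapping {path}: duplicate genome ids {dups}")
    return df
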