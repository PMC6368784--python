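"""Synthetic fixture generation: toy taxonomies, genomes and profiles.

Everything the pipeline consumes can be generated offline and
reproducibly from a seed: a toy taxonomy (families x genera x species
under one superkingdom), random ACGT genomes with one FASTA and metadata
row per species, an OTU mapping for de novo design, and a BIOM profile
referencing a subset of the species names (optionally including
unresolvable names, to exercise the exclusion warnings). The same seed
always yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mgsim.biomio import write_biom
from mgsim.taxonomy import TaxonomyDB

NOVELTY_CATEGORIES = ("known_strain", "new_species", "new_genus")


@dataclass
class FixturePaths:
    root: Path
    nodes: Path
    names: Path
    metadata: Path
    mapping: Path
    biom: Path
    config: Path | None = None


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def generate_taxonomy(
    outdir: str | Path,
    n_families: int = 3,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
) -> tuple[Path, Path]:
    """Write a toy nodes/names TSV pair and return their paths.

    Tree: root -> Bacteria (superkingdom) -> families -> genera ->
    species. Genus names are single tokens; species names are binomials
    whose first token is the genus name, so the genus-fallback resolution
    step is exercisable. Every species also gets one synonym.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = [("1", "1", "no rank"), ("2", "1", "superkingdom")]
    names = [("1", "root", "scientific name"), ("2", "Bacteria", "scientific name")]
    next_id = 3
    for f in range(n_families):
        fid = str(next_id)
        next_id += 1
        nodes.append((fid, "2", "family"))
        names.append((fid, f"Fam{f + 1}aceae", "scientific name"))
        for g in range(genera_per_family):
            gid = str(next_id)
            next_id += 1
            nodes.append((gid, fid, "genus"))
            genus_name = f"Genus{f + 1}x{g + 1}"
            names.append((gid, genus_name, "scientific name"))
            for s in range(species_per_genus):
                sid = str(next_id)
                next_id += 1
                nodes.append((sid, gid, "species"))
                names.append((sid, f"{genus_name} species{s + 1}", "scientific name"))
                names.append((sid, f"{genus_name} sp. strain{s + 1}", "synonym"))
    nodes_path = outdir / "nodes.tsv"
    names_path = outdir / "names.tsv"
    nodes_path.write_text("".join(f"{a}\t{b}\t{c}\n" for a, b, c in nodes))
    names_path.write_text("".join(f"{a}\t{b}\t{c}\n" for a, b, c in names))
    return nodes_path, names_path


def generate_genomes(
    outdir: str | Path,
    db: TaxonomyDB,
    seed: int,
    genome_length: int = 10_000,
    gc: float = 0.5,
    quality_cycle: tuple[str, ...] = ("complete",),
    ambiguity_rate: float = 0.0,
) -> tuple[Path, Path]:
    """One random genome per species in the taxonomy.

    Writes FASTA files plus a metadata TSV (genome_id, fasta_path, taxid,
    quality, otu, novelty_category) and an OTU mapping TSV. OTU ids group
    the species of a genus; novelty categories cycle deterministically.
    Optionally sprinkles ambiguous bases (N) at ``ambiguity_rate`` to
    exercise genome preparation.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    species = sorted(
        (tid for tid, node in db.nodes.items() if node.rank == "species"), key=int
    )
    meta_rows, map_rows = [], []
    for i, taxid in enumerate(species):
        gid = f"g{i}"
        seq = random_sequence(genome_length, rng, gc)
        if ambiguity_rate > 0:
            n_amb = int(round(ambiguity_rate * genome_length))
            pos = rng.choice(genome_length, size=n_amb, replace=False)
            chars = list(seq)
            for p in pos:
                chars[p] = "N"
            seq = "".join(chars)
        fasta = outdir / "genomes" / f"{gid}.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{gid}_c0\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
        quality = quality_cycle[i % len(quality_cycle)]
        otu = db.nodes[taxid].parent  # genus groups the OTU
        novelty = NOVELTY_CATEGORIES[i % len(NOVELTY_CATEGORIES)]
        meta_rows.append((gid, f"genomes/{gid}.fasta", taxid, quality, otu, novelty))
        map_rows.append((gid, taxid, novelty, otu))
    metadata = outdir / "metadata.tsv"
    with open(metadata, "w") as fh:
        fh.write("genome_id\tfasta_path\ttaxid\tquality\totu\tnovelty_category\n")
        for row in meta_rows:
            fh.write("\t".join(row) + "\n")
    mapping = outdir / "mapping.tsv"
    with open(mapping, "w") as fh:
        fh.write("genome_id\ttaxid\tnovelty_category\totu\n")
        for row in map_rows:
            fh.write("\t".join(row) + "\n")
    return metadata, mapping


def generate_biom_profile(
    path: str | Path,
    db: TaxonomyDB,
    seed: int,
    n_taxa: int | None = None,
    n_unresolvable: int = 0,
    matrix_type: str = "dense",
) -> Path:
    """A toy BIOM profile over species names from the taxonomy.

    Picks ``n_taxa`` species (default: all), assigns lognormal
    abundances, and appends ``n_unresolvable`` nonsense names with
    positive abundance to exercise exclusion warnings.
    """
    rng = np.random.default_rng(seed)
    species = sorted(
        (tid for tid, node in db.nodes.items() if node.rank == "species"), key=int
    )
    if n_taxa is not None:
        idx = sorted(rng.choice(len(species), size=min(n_taxa, len(species)), replace=False))
        species = [species[i] for i in idx]
    names = [db.name(tid) for tid in species]
    names += [f"Zzyzx nonexistens{i + 1}" for i in range(n_unresolvable)]
    abundances = rng.lognormal(1.0, 1.0, size=len(names))
    write_biom(
        path,
        observations=names,
        samples=["sample0"],
        matrix=[[float(a)] for a in abundances],
        matrix_type=matrix_type,
    )
    return Path(path)


def generate_full_fixture(
    outdir: str | Path,
    seed: int,
    n_families: int = 3,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
    genome_length: int = 10_000,
    n_unresolvable: int = 0,
    mode: str = "profile",
    total_bases: int = 400_000,
    n_samples: int = 1,
    sample_mode: str = "single",
    error_rate: float = 0.0,
) -> FixturePaths:
    """Generate a complete, runnable input tree plus a config file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes, names = generate_taxonomy(
        outdir, n_families, genera_per_family, species_per_genus
    )
    db = TaxonomyDB.from_tsv(nodes, names)
    metadata, mapping = generate_genomes(outdir, db, seed=seed, genome_length=genome_length)
    biom = generate_biom_profile(
        outdir / "profile.biom", db, seed=seed, n_unresolvable=n_unresolvable
    )
    n_species = n_families * genera_per_family * species_per_genus
    config = outdir / "config.ini"
    lines = [
        "[general]",
        f"seed = {seed}",
        "",
        "[community]",
        f"mode = {mode}",
        "taxonomy_nodes = nodes.tsv",
        "taxonomy_names = names.tsv",
        "metadata = metadata.tsv",
    ]
    if mode == "profile":
        lines += ["profile = profile.biom"]
    else:
        g_real = max(2, n_species // 2)
        lines += [
            "mapping = mapping.tsv",
            f"g_real = {g_real}",
            f"g_tot = {g_real + 2}",
        ]
    lines += [
        "max_strains = 3",
        "",
        "[samples]",
        f"mode = {sample_mode}",
        f"count = {n_samples}",
        "",
        "[reads]",
        f"total_bases = {total_bases}",
        f"error_rate = {error_rate}",
        "",
        "[output]",
        "dir = output",
    ]
    config.write_text("\n".join(lines) + "\n")
    return FixturePaths(
        root=outdir, nodes=nodes, names=names, metadata=metadata,
        mapping=mapping, biom=biom, config=config,
    )
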