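"""End-to-end pipeline: design -> abundances -> reads -> gold standards.

Output tree (gzip applied when ``compress`` is on)::

    <output>/
      community.tsv[.gz]        designed community P_out (genome, taxon, abundance)
      abundances.tsv[.gz]       genomes x samples abundance matrix
      provenance.tsv[.gz]       evolved-strain provenance (de novo mode)
      resolved_config.ini       audit copy of the fully resolved configuration
      pipeline.log
      sample_<i>/
        reads_R1.fastq[.gz], reads_R2.fastq[.gz]
        truth.sam[.gz]          ground-truth alignments (pre-anonymization ids)
        gold_assembly.fasta[.gz]
        reads_binning.tsv[.gz], contigs_binning.tsv[.gz]
        profile_gold.tsv[.gz]
        reads_anonymization.tsv[.gz], contigs_anonymization.tsv[.gz]
      coassembly/
        gold_coassembly.fasta[.gz], contigs_binning.tsv[.gz], ...

Every random stream derives from the master seed plus a stage token, so a
rerun with the same config and seed is byte-identical (log timestamps are
not written), and changing e.g. only the sample index leaves the
community design untouched.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from mgsim import abundance as ab
from mgsim.biomio import read_biom_profile
from mgsim.community import (
    CommunityProfile,
    CommunityRow,
    InputProfile,
    build_lineage_index,
    design_from_profile,
)
from mgsim.config import RunConfig, write_resolved
from mgsim.denovo import design_denovo
from mgsim.genomes import GenomeCollection, read_otu_mapping
from mgsim.gold import (
    anonymize,
    binning_gold_standard,
    perfect_assembly,
    perfect_coassembly,
    profiling_gold_standard,
    write_binning_tsv,
    write_gold_fasta,
    write_profiling_tsv,
)
from mgsim.ioutil import open_text
from mgsim.reads import (
    ReadSimParams,
    prepare_genome,
    simulate_sample,
    write_fastq,
    write_sam,
)
from mgsim.seeding import derive_rng
from mgsim.taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)


def _ext(cfg: RunConfig) -> str:
    return ".gz" if cfg.compress else ""


def _design_community(cfg: RunConfig, out: Path):
    """Returns (community profile, genome collection, taxonomy or None)."""
    db = None
    if cfg.taxonomy_nodes is not None:
        db = TaxonomyDB.from_tsv(cfg.resolve("taxonomy_nodes"), cfg.resolve("taxonomy_names"))
    collection = GenomeCollection.from_metadata(cfg.resolve("metadata"))
    rng = derive_rng(cfg.seed, "design")
    if cfg.mode == "profile":
        if db is None:
            raise ValueError("profile mode requires a taxonomy")
        rows = []
        for name, abundance in read_biom_profile(cfg.resolve("profile")):
            taxid = name if name in db else db.map_name_to_taxid(name)
            if taxid is None:
                continue  # warning already logged by the resolver
            rows.append((taxid, abundance))
        if not rows:
            raise ValueError("no BIOM observation could be resolved to a taxid")
        p_in = InputProfile(rows=rows)
        index = build_lineage_index(collection, db, cfg.r_max, set(cfg.quality))
        profile = design_from_profile(
            p_in, index, db, collection, rng,
            r_max=cfg.r_max, m=cfg.max_strains,
            mu=cfg.log_mu, sigma=cfg.log_sigma, allow_reuse=cfg.allow_reuse,
        ).merged()
        community = collection
    else:
        mapping = read_otu_mapping(cfg.resolve("mapping"))
        community, provenance = design_denovo(
            mapping, collection, cfg.g_real, cfg.g_tot, rng,
            m=cfg.max_strains, ani_range=(cfg.ani_min, cfg.ani_max),
        )
        with open_text(out / f"provenance.tsv{_ext(cfg)}") as fh:
            provenance.to_csv(fh, sep="\t", index=False)
        profile = CommunityProfile(
            rows=[
                CommunityRow(genome_id=rec.genome_id, taxid=rec.taxid, abundance=1.0)
                for rec in community
            ]
        )
    return profile, community, db


def _abundance_matrix(cfg: RunConfig, profile: CommunityProfile) -> ab.AbundanceMatrix:
    rng = derive_rng(cfg.seed, "abundance")
    sample_rngs = [derive_rng(cfg.seed, "abundance", i) for i in range(cfg.n_samples)]
    gids = profile.genome_ids()
    base = np.array([r.abundance for r in profile.rows])
    kw = dict(mu=cfg.log_mu, sigma=cfg.log_sigma)
    if cfg.sample_mode == "single":
        if cfg.mode == "profile":
            return ab.AbundanceMatrix(gids, base[:, None], "single", cfg.log_mu, cfg.log_sigma)
        return ab.single_sample(gids, rng, **kw)
    if cfg.sample_mode == "differential":
        return ab.differential(gids, cfg.n_samples, rng, sample_rngs=sample_rngs, **kw)
    profile_base = base if cfg.mode == "profile" else None
    if cfg.sample_mode == "replicates":
        return ab.replicates(
            gids, cfg.n_samples, rng, noise_sd=cfg.noise_sd,
            log_space=cfg.log_space, base=profile_base, sample_rngs=sample_rngs, **kw,
        )
    return ab.timeseries(
        gids, cfg.n_samples, rng, mode=cfg.timeseries_mode,
        noise_sd=cfg.noise_sd, log_space=cfg.log_space, base=profile_base,
        sample_rngs=sample_rngs, **kw,
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full simulation described by ``cfg``; returns the output dir."""
    cfg.validate()
    out = Path(cfg.output_dir)
    if not out.is_absolute():
        out = cfg.base_dir / out
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("mgsim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        ext = _ext(cfg)
        profile, community, db = _design_community(cfg, out)
        with open_text(out / f"community.tsv{ext}") as fh:
            profile.to_frame()[["genome_id", "taxid", "abundance"]].to_csv(
                fh, sep="\t", index=False
            )

        matrix = _abundance_matrix(cfg, profile)
        with open_text(out / f"abundances.tsv{ext}") as fh:
            matrix.to_frame().to_csv(fh, sep="\t")
        rel = ab.normalize(matrix)

        prep_rng = derive_rng(cfg.seed, "prepare")
        prepared = {
            gid: prepare_genome(community[gid], prep_rng)
            for gid in matrix.genome_ids
        }
        taxids = {gid: community[gid].taxid for gid in matrix.genome_ids}
        params = ReadSimParams(
            read_length=cfg.read_length, insert_mean=cfg.insert_mean,
            insert_sd=cfg.insert_sd, error_rate=cfg.error_rate,
            base_quality=cfg.base_quality,
        )

        all_samples = {}
        for i in range(matrix.n_samples):
            sdir = out / f"sample_{i}"
            sdir.mkdir(exist_ok=True)
            sname = f"S{i}"
            abunds = {g: a for g, a in rel.sample(i).items() if a > 0}
            pairs, alloc = simulate_sample(
                abunds, prepared, cfg.total_bases, params,
                derive_rng(cfg.seed, "reads", i), sample_name=sname,
            )
            all_samples[sname] = pairs
            logger.info("sample %s: %d reads over %d genomes", sname, alloc.total, len(abunds))

            write_sam(pairs, prepared, sdir / "truth.sam")
            if cfg.compress:
                from mgsim.ioutil import gzip_file

                gzip_file(sdir / "truth.sam")

            out_pairs = pairs
            if cfg.anonymize:
                anon_records, read_map = anonymize(
                    [(p.pair_id, p) for p in pairs],
                    derive_rng(cfg.seed, "anonymize-reads", i),
                    prefix=f"{sname}_R",
                )
                out_pairs = []
                for anon_id, p in anon_records:
                    p = type(p)(pair_id=anon_id, genome_id=p.genome_id, mate1=p.mate1, mate2=p.mate2)
                    out_pairs.append(p)
                read_map.write_tsv(sdir / f"reads_anonymization.tsv{ext}")
            write_fastq(out_pairs, sdir / f"reads_R1.fastq{ext}", sdir / f"reads_R2.fastq{ext}")
            read_assign = binning_gold_standard(
                [
                    (f"{p.pair_id}/{m}", p.genome_id)
                    for p in out_pairs
                    for m in (1, 2)
                ],
                taxids, db,
            )
            write_binning_tsv(read_assign, sdir / f"reads_binning.tsv{ext}", sample_id=sname)

            contigs = perfect_assembly(pairs, prepared, scope=sname)
            out_contigs = contigs
            if cfg.anonymize:
                anon_contigs, contig_map = anonymize(
                    [(c.contig_id, c) for c in contigs],
                    derive_rng(cfg.seed, "anonymize-contigs", i),
                    prefix=f"{sname}_C",
                )
                out_contigs = []
                id_of = {}
                for anon_id, c in anon_contigs:
                    id_of[id(c)] = anon_id
                    out_contigs.append(c)
                contig_map.write_tsv(sdir / f"contigs_anonymization.tsv{ext}")
                contig_ids = [id_of[id(c)] for c in out_contigs]
            else:
                contig_ids = [c.contig_id for c in out_contigs]
            with open_text(sdir / f"gold_assembly.fasta{ext}") as fh:
                for cid, c in zip(contig_ids, out_contigs):
                    fh.write(f">{cid}\n")
                    for j in range(0, len(c.sequence), 80):
                        fh.write(c.sequence[j : j + 80] + "\n")
            contig_assign = binning_gold_standard(
                list(zip(contig_ids, (c.genome_id for c in out_contigs))), taxids, db
            )
            write_binning_tsv(contig_assign, sdir / f"contigs_binning.tsv{ext}", sample_id=sname)

            sample_profile = CommunityProfile(
                rows=[
                    CommunityRow(genome_id=g, taxid=taxids[g], abundance=a)
                    for g, a in abunds.items()
                ],
                normalized=True,
            )
            if db is not None:
                table = profiling_gold_standard(sample_profile, db)
            else:
                table = {"strain": [(r.genome_id, 100.0 * r.abundance) for r in sample_profile.rows]}
            write_profiling_tsv(table, sdir / f"profile_gold.tsv{ext}", db)

        codir = out / "coassembly"
        codir.mkdir(exist_ok=True)
        co = perfect_coassembly(all_samples, prepared)
        if cfg.anonymize:
            anon_co, co_map = anonymize(
                [(c.contig_id, c) for c in co],
                derive_rng(cfg.seed, "anonymize-coassembly"),
                prefix="P_C",
            )
            co_map.write_tsv(codir / f"contigs_anonymization.tsv{ext}")
            co_ids = [cid for cid, _ in anon_co]
            co = [c for _, c in anon_co]
        else:
            co_ids = [c.contig_id for c in co]
        with open_text(codir / f"gold_coassembly.fasta{ext}") as fh:
            for cid, c in zip(co_ids, co):
                fh.write(f">{cid}\n")
                for j in range(0, len(c.sequence), 80):
                    fh.write(c.sequence[j : j + 80] + "\n")
        co_assign = binning_gold_standard(
            list(zip(co_ids, (c.genome_id for c in co))), taxids, db
        )
        write_binning_tsv(co_assign, codir / f"contigs_binning.tsv{ext}", sample_id="pooled")

        write_resolved(cfg, out / "resolved_config.ini")
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
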