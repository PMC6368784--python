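"""De novo community design.

Samples ``g_real`` genomes from a collection, balanced across novelty
categories (how taxonomically distant each genome is from public
references), then evolves simulated strain genomes OTU by OTU until the
community holds ``g_tot = g_real + g_sim`` genomes. The number of strains
added per source genome is geometric with mean 1/0.3 (success probability
0.3), capped at ``m - 1`` so no OTU exceeds ``m`` strains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mgsim.genomes import GenomeCollection, GenomeRecord
from mgsim.strain import evolve_strain

logger = logging.getLogger(__name__)

DEFAULT_STRAIN_P = 0.3
DEFAULT_ANI_RANGE = (0.95, 0.999)


@dataclass
class DenovoDesign:
    g_real: int
    g_tot: int
    m: int = 10

    def __post_init__(self) -> None:
        if self.g_real < 1:
            raise ValueError(f"g_real must be >= 1, got {self.g_real}")
        if self.g_tot < self.g_real:
            raise ValueError(f"g_tot ({self.g_tot}) must be >= g_real ({self.g_real})")

    @property
    def g_sim(self) -> int:
        return self.g_tot - self.g_real


def sample_real_genomes(
    mapping: pd.DataFrame, g_real: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``g_real`` genome ids balanced over novelty categories.

    Quotas start as an even split of ``g_real`` across categories (the
    remainder spread over rng-chosen categories). Categories with fewer
    genomes than their quota contribute everything; their deficit is
    redistributed over the categories that still have spare genomes,
    iterating until the total is filled. Within a category, genomes are
    drawn uniformly without replacement.
    """
    total_available = len(mapping)
    if g_real > total_available:
        raise ValueError(f"g_real={g_real} exceeds available genomes ({total_available})")
    by_cat: dict[str, list[str]] = {
        cat: sorted(sub["genome_id"]) for cat, sub in mapping.groupby("novelty_category")
    }
    cats = sorted(by_cat)
    alloc = {c: 0 for c in cats}
    need = g_real
    while need > 0:
        open_cats = [c for c in cats if alloc[c] < len(by_cat[c])]
        base, rem = divmod(need, len(open_cats))
        extra_cats = set(
            np.array(open_cats)[rng.choice(len(open_cats), size=rem, replace=False)]
        )
        granted = 0
        for c in open_cats:
            want = base + (1 if c in extra_cats else 0)
            take = min(want, len(by_cat[c]) - alloc[c])
            alloc[c] += take
            granted += take
        need -= granted
    chosen: list[str] = []
    for c in cats:
        members = by_cat[c]
        idx = sorted(rng.choice(len(members), size=alloc[c], replace=False))
        chosen.extend(members[i] for i in idx)
    return chosen


def strain_count_sample(
    m: int, rng: np.random.Generator, p: float = DEFAULT_STRAIN_P
) -> int:
    """Number of simulated strains to add for one source genome.

    Geometric on {1, 2, ...} with mean 1/p, capped at m - 1 so an OTU
    never exceeds m genomes in total.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2 to add simulated strains, got {m}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"geometric success probability must be in (0, 1), got {p}")
    return min(int(rng.geometric(p)), m - 1)


def design_denovo(
    mapping: pd.DataFrame,
    collection: GenomeCollection,
    g_real: int,
    g_tot: int,
    rng: np.random.Generator,
    m: int = 10,
    strain_p: float = DEFAULT_STRAIN_P,
    ani_range: tuple[float, float] = DEFAULT_ANI_RANGE,
) -> tuple[GenomeCollection, pd.DataFrame]:
    """Build a g_tot-genome community collection with simulated strains.

    Returns the community collection (real + evolved genomes) and a
    provenance table with one row per evolved genome: evolved id, source
    id, OTU id and the target ANI drawn (uniformly from ``ani_range``).
    """
    design = DenovoDesign(g_real=g_real, g_tot=g_tot, m=m)
    real_ids = sample_real_genomes(mapping, design.g_real, rng)
    meta = mapping.set_index("genome_id")
    out = GenomeCollection()
    for gid in real_ids:
        src = collection[gid]
        out.add(
            GenomeRecord(
                genome_id=gid,
                taxid=str(meta.at[gid, "taxid"]),
                sequences=dict(src.sequences),
                quality=src.quality,
                otu=str(meta.at[gid, "otu"]),
                novelty_category=str(meta.at[gid, "novelty_category"]),
            )
        )
    provenance: list[dict] = []
    remaining = design.g_sim
    if remaining > 0:
        if m < 2:
            raise ValueError("g_tot > g_real requires m >= 2")
        if remaining > len(real_ids) * (m - 1):
            raise ValueError(
                f"g_sim={remaining} strains cannot be hosted by {len(real_ids)} "
                f"genomes with at most {m - 1} strains each"
            )
        added_per_source = {gid: 0 for gid in real_ids}
        order = [real_ids[i] for i in rng.permutation(len(real_ids))]
        cursor = 0
        while remaining > 0:
            gid = order[cursor % len(order)]
            cursor += 1
            capacity = (m - 1) - added_per_source[gid]
            if capacity <= 0:
                continue
            count = min(strain_count_sample(m, rng, p=strain_p), capacity, remaining)
            src = out[gid]
            for _ in range(count):
                added_per_source[gid] += 1
                target_ani = float(rng.uniform(*ani_range))
                evolved_id = f"{gid}.sim{added_per_source[gid]}"
                # contig names must stay unique across the whole community
                sequences = {
                    f"{evolved_id}_c{j}": evolve_strain(
                        seq, target_ani, rng, source_id=gid
                    ).sequence
                    for j, (cname, seq) in enumerate(src.sequences.items())
                }
                out.add(
                    GenomeRecord(
                        genome_id=evolved_id,
                        taxid=src.taxid,
                        sequences=sequences,
                        quality=src.quality,
                        otu=src.otu,
                        novelty_category=src.novelty_category,
                    )
                )
                provenance.append(
                    {
                        "evolved_id": evolved_id,
                        "source_id": gid,
                        "otu": src.otu,
                        "target_ani": target_ani,
                    }
                )
                remaining -= 1
    prov = pd.DataFrame(
        provenance, columns=["evolved_id", "source_id", "otu", "target_ani"]
    )
    logger.info(
        "de novo design: %d real + %d simulated = %d genomes", len(real_ids), len(prov), len(out)
    )
    return out, prov
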