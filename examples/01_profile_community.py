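"""Design a community from a taxonomic profile.

Builds a toy taxonomy + genome collection + BIOM profile, resolves the
profile's free-text names to taxon ids, and runs the rank-walking design:
each profile taxon is matched to genomes at the lowest possible rank (up
to family), a truncated-geometric number of strains is drawn, and the
taxon's abundance is split across them with lognormal weights.
"""

import tempfile

import numpy as np

from mgsim import InputProfile, build_lineage_index, design_from_profile
from mgsim.biomio import read_biom_profile
from mgsim.fixtures import generate_full_fixture
from mgsim.genomes import GenomeCollection
from mgsim.taxonomy import TaxonomyDB

fx = generate_full_fixture(tempfile.mkdtemp(), seed=7, n_unresolvable=1)
db = TaxonomyDB.from_tsv(fx.nodes, fx.names)
collection = GenomeCollection.from_metadata(fx.metadata)

rows = []
for name, abundance in read_biom_profile(fx.biom):
    taxid = db.map_name_to_taxid(name)  # one planted name will not resolve
    if taxid is not None:
        rows.append((taxid, abundance))

index = build_lineage_index(collection, db, r_max="family")
profile = design_from_profile(
    InputProfile(rows), index, db, collection, np.random.default_rng(1), m=3
)

print(f"input taxa resolved: {len(rows)}  ->  community genomes: {len(profile.rows)}")
print(f"{'genome':<8}{'taxon':<8}{'matched rank':<14}abundance")
for r in sorted(profile.rows, key=lambda r: -r.abundance)[:6]:
    print(f"{r.genome_id:<8}{r.taxid:<8}{r.matched_rank:<14}{r.abundance:.4f}")
print(
    "\nAbundance mass of matched taxa is conserved exactly: "
    f"sum = {profile.total():.4f} vs input sum of matched = "
    f"{sum(ab for t, ab in rows if any(r.source_taxon == t for r in profile.rows)):.4f}"
)
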