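import numpy as np
import pytest

from mgsim.fixtures import generate_full_fixture, generate_taxonomy, random_sequence
from mgsim.genomes import GenomeCollection, GenomeRecord
from mgsim.taxonomy import TaxNode, TaxonomyDB


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_db():
    """Four-rank toy lineage: Bacteria > F1 > G1 > S1."""
    nodes = {
        "1": TaxNode("1", "1", "no rank", "root"),
        "B": TaxNode("B", "1", "superkingdom", "Bacteria"),
        "F1": TaxNode("F1", "B", "family", "Escherichiaceae"),
        "G1": TaxNode("G1", "F1", "genus", "Escherichia"),
        "S1": TaxNode("S1", "G1", "species", "Escherichia coli", ["E. coli synonym"]),
    }
    return TaxonomyDB(nodes=nodes, root="1")


@pytest.fixture(scope="session")
def fixture_db(tmp_path_factory):
    """A generated toy taxonomy: 3 families x 2 genera x 2 species."""
    d = tmp_path_factory.mktemp("tax")
    nodes, names = generate_taxonomy(d, n_families=3, genera_per_family=2, species_per_genus=2)
    return TaxonomyDB.from_tsv(nodes, names)


def make_collection(db, genome_length=2000, seed=0, quality="complete"):
    """One random genome per species of a taxonomy."""
    rng = np.random.default_rng(seed)
    coll = GenomeCollection()
    species = sorted((t for t, n in db.nodes.items() if n.rank == "species"), key=str)
    for i, tid in enumerate(species):
        coll.add(
            GenomeRecord(
                genome_id=f"g{i}",
                taxid=tid,
                sequences={f"g{i}_c0": random_sequence(genome_length, rng)},
                quality=quality,
            )
        )
    return coll


@pytest.fixture
def fixture_collection(fixture_db):
    return make_collection(fixture_db)


@pytest.fixture
def full_fixture(tmp_path):
    """A complete runnable input tree (profile mode, 1 sample)."""
    return generate_full_fixture(tmp_path / "fx", seed=7, n_unresolvable=1)
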