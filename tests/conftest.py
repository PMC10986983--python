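import pytest

from beemeta.concordance import load_packaged_taxonomy
from beemeta.synthetic import DEFAULT_POOL, GenusSpec, make_references


@pytest.fixture(scope="session")
def regional_tree():
    """The packaged regional bee taxonomy."""
    return load_packaged_taxonomy()


@pytest.fixture(scope="session")
def toy_tree():
    """Small hand-built tree: two genera in one family, one in another."""
    from beemeta.taxonomy import TaxonomyTree

    rows = [
        (1, "root", "no_rank", 1),
        (2, "Arthropoda", "phylum", 1),
        (3, "Insecta", "class", 2),
        (4, "Hymenoptera", "order", 3),
        (10, "Apidae", "family", 4),
        (11, "Halictidae", "family", 4),
        (20, "Bombus", "genus", 10),
        (21, "Apis", "genus", 10),
        (22, "Halictus", "genus", 11),
        (30, "Bombus impatiens", "species", 20),
        (31, "Bombus griseocollis", "species", 20),
        (32, "Apis mellifera", "species", 21),
        (33, "Halictus ligatus", "species", 22),
    ]
    return TaxonomyTree.build(rows)


@pytest.fixture(scope="session")
def small_pool():
    """Three-genus pool for fast end-to-end simulations."""
    return (
        GenusSpec("Bombus", 0.5, "large", 2, focal=True),
        GenusSpec("Halictus", 0.3, "small", 1),
        GenusSpec("Lasioglossum", 0.2, "small", 2),
    )


@pytest.fixture(scope="session")
def small_bundle(small_pool):
    return make_references(pool=small_pool, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    return make_references(pool=DEFAULT_POOL, seed=5)
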