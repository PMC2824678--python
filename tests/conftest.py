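import pytest

from xrefbridge import (
    DataSource,
    SyntheticGraphSpec,
    default_registry,
    generate_mapping_world,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def gene_world():
    """A modest gene-mapping world shared by read-only tests."""
    return generate_mapping_world(
        SyntheticGraphSpec(
            n_datasources=4,
            n_entities=25,
            xrefs_per_entity_range=(2, 4),
            missing_edge_prob=0.15,
            n_shards=2,
            seed=101,
        )
    )


@pytest.fixture(scope="session")
def metabolite_world():
    return generate_mapping_world(
        SyntheticGraphSpec(
            n_datasources=5,
            n_entities=25,
            xrefs_per_entity_range=(1, 5),
            missing_edge_prob=0.0,
            n_shards=1,
            seed=202,
            entity_category="metabolite",
        )
    )


@pytest.fixture
def toy_sources(registry):
    """(custom probe source, Entrez Gene, Ensembl) used by stacking tests."""
    custom = DataSource(syscode="Zz", full_name="Custom Array", entity_category="probe")
    return custom, registry.by_syscode("L"), registry.by_syscode("En")
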