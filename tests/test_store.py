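"""Embedded single-file mapping database: schema round-trip, bidirectional
queries, attributes, versioning and atomic writes."""

import sqlite3

import pytest

from xrefbridge import (
    AttributeRecord,
    DataNodeRecord,
    DbInfo,
    LinkRecord,
    SyntheticGraphSpec,
    generate_mapping_world,
    open_db,
    write_db,
    world_to_db,
)
from xrefbridge.errors import (
    DatabaseOpenError,
    ReferentialIntegrityError,
    SchemaVersionError,
)
from xrefbridge.store import records_from_links


@pytest.fixture
def tiny_records():
    nodes = [
        DataNodeRecord("ENSG01", "En"),
        DataNodeRecord("1234", "L"),
        DataNodeRecord("P62158", "S"),
    ]
    links = [
        LinkRecord("ENSG01", "En", "1234", "L"),
        LinkRecord("ENSG01", "En", "P62158", "S"),
    ]
    attrs = [
        AttributeRecord("ENSG01", "En", "Symbol", "CALM1"),
        AttributeRecord("ENSG01", "En", "Symbol", "Calmodulin"),
    ]
    return nodes, links, attrs


class TestRoundTrip:
    def test_write_then_read_reproduces_records(self, tmp_path, tiny_records, registry):
        nodes, links, attrs = tiny_records
        info = DbInfo(species_name="Human", provenance="tiny fixture")
        path = write_db(tmp_path / "tiny.xdb", nodes, links, attrs, info)
        with open_db(path, registry) as mapper:
            assert sorted(mapper.read_datanodes(), key=str) == sorted(nodes, key=str)
            assert sorted(mapper.read_links(), key=str) == sorted(links, key=str)
            assert mapper.read_attributes() == attrs
            got = mapper.dbinfo()
            assert (got.schema_version, got.species_name, got.provenance) == (
                1, "Human", "tiny fixture",
            )

    def test_empty_database_roundtrips_and_maps_nothing(self, tmp_path, registry):
        path = write_db(tmp_path / "empty.xdb", [], [], [], DbInfo())
        with open_db(path, registry) as mapper:
            assert mapper.read_datanodes() == []
            assert mapper.read_links() == []
            assert mapper.map_id(registry.xref("En", "anything")) == frozenset()
            assert mapper.capabilities().source_datasources == frozenset()

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixture_roundtrip_exact(self, tmp_path, seed):
        world = generate_mapping_world(
            SyntheticGraphSpec(n_datasources=4, n_entities=12, n_shards=1,
                               missing_edge_prob=0.2, seed=3000 + seed)
        )
        datanodes, links, attrs = records_from_links(
            world.shards[0], world.symbol_attributes()
        )
        path = write_db(tmp_path / f"w{seed}.xdb", datanodes, links, attrs)
        with open_db(path) as mapper:
            assert sorted(mapper.read_datanodes(), key=str) == sorted(datanodes, key=str)
            assert sorted(mapper.read_links(), key=str) == sorted(links, key=str)
            assert sorted(mapper.read_attributes(), key=str) == sorted(attrs, key=str)


class TestIntegrityAndVersioning:
    def test_link_to_missing_datanode_rejected(self, tmp_path):
        nodes = [DataNodeRecord("ENSG01", "En")]
        links = [LinkRecord("ENSG01", "En", "ghost", "L")]
        with pytest.raises(ReferentialIntegrityError):
            write_db(tmp_path / "bad.xdb", nodes, links)

    def test_attribute_owner_must_exist(self, tmp_path):
        attrs = [AttributeRecord("ghost", "En", "Symbol", "X")]
        with pytest.raises(ReferentialIntegrityError):
            write_db(tmp_path / "bad.xdb", [], [], attrs)

    def test_failed_write_leaves_no_file(self, tmp_path):
        target = tmp_path / "never.xdb"
        with pytest.raises(ReferentialIntegrityError):
            write_db(target, [], [LinkRecord("a", "En", "b", "L")])
        assert not target.exists()
        assert list(tmp_path.iterdir()) == []  # no partial temp files either

    def test_wrong_schema_version_is_hard_error(self, tmp_path, tiny_records, registry):
        nodes, links, attrs = tiny_records
        path = write_db(tmp_path / "v.xdb", nodes, links, attrs)
        con = sqlite3.connect(path)
        con.execute("UPDATE dbinfo SET schema_version = 99")
        con.commit()
        con.close()
        with pytest.raises(SchemaVersionError):
            open_db(path, registry)

    def test_corrupt_file_raises_open_error(self, tmp_path, registry):
        path = tmp_path / "garbage.xdb"
        path.write_text("this is not a database")
        with pytest.raises(DatabaseOpenError):
            open_db(path, registry)

    def test_missing_file_raises_open_error(self, tmp_path, registry):
        with pytest.raises(DatabaseOpenError):
            open_db(tmp_path / "absent.xdb", registry)


class TestQueries:
    def test_links_are_queried_bidirectionally(self, tmp_path, tiny_records, registry):
        nodes, links, attrs = tiny_records
        path = write_db(tmp_path / "t.xdb", nodes, links, attrs)
        with open_db(path, registry) as mapper:
            en = registry.by_syscode("En")
            left = registry.xref("En", "ENSG01")
            right = registry.xref("L", "1234")
            assert mapper.map_id(left, frozenset({right.datasource})) == {right}
            assert mapper.map_id(right, frozenset({en})) == {left}

    def test_map_id_agrees_with_brute_force_scan(self, tmp_path):
        world = generate_mapping_world(
            SyntheticGraphSpec(n_datasources=5, n_entities=30, n_shards=1,
                               missing_edge_prob=0.1, seed=77)
        )
        path = world_to_db(world, 0, tmp_path / "big.xdb")
        links = world.shards[0]
        with open_db(path) as mapper:
            nodes = {x for pair in links for x in pair}
            for x in nodes:
                expected = {r for l, r in links if l == x} | {
                    l for l, r in links if r == x
                }
                assert mapper.map_id(x) == expected

    def test_free_search_consults_identifiers_and_symbols(self, tmp_path, gene_world):
        path = world_to_db(gene_world, 0, tmp_path / "g.xdb")
        with open_db(path) as mapper:
            some = gene_world.shards[0][0][0]
            assert some in mapper.free_search(some.identifier.lower(), 10)
            entity_idx = int(some.identifier[-5:])
            symbol = gene_world.entity_symbols[entity_idx][0]
            hits = mapper.free_search(symbol, 50)
            present = {x for pair in gene_world.shards[0] for x in pair}
            expected = {x for x in gene_world.entities[entity_idx] if x in present}
            assert expected <= hits


class TestAttributes:
    def test_values_returned_in_insertion_order(self, tmp_path, tiny_records, registry):
        nodes, links, attrs = tiny_records
        path = write_db(tmp_path / "a.xdb", nodes, links, attrs)
        with open_db(path, registry) as mapper:
            x = registry.xref("En", "ENSG01")
            assert mapper.get_attributes(x, "Symbol") == ["CALM1", "Calmodulin"]

    def test_unknown_xref_gives_empty(self, tmp_path, tiny_records, registry):
        nodes, links, attrs = tiny_records
        path = write_db(tmp_path / "a.xdb", nodes, links, attrs)
        with open_db(path, registry) as mapper:
            assert mapper.get_attributes(registry.xref("En", "nope"), "Symbol") == []
            assert mapper.get_attributes(registry.xref("En", "nope")) == {}

    def test_all_attributes_match_full_table_scan(self, tmp_path, gene_world):
        path = world_to_db(gene_world, 0, tmp_path / "g.xdb")
        with open_db(path) as mapper:
            rows = mapper.read_attributes()
            present = {x for pair in gene_world.shards[0] for x in pair}
            for x in sorted(present)[:20]:
                expected: dict = {}
                for rec in rows:
                    if (rec.identifier, rec.syscode) == (x.identifier, x.syscode):
                        expected.setdefault(rec.attr_name, []).append(rec.attr_value)
                assert mapper.get_attributes(x) == expected
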