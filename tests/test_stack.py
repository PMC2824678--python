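"""Stacking mapping services: union mode, transitive inference, and the
brute-force closure oracle."""

import itertools

import pytest

from xrefbridge import (
    DataSource,
    MemoryLinkMapper,
    SyntheticGraphSpec,
    Xref,
    generate_mapping_world,
    stack,
    transitive_closure_oracle,
)
from xrefbridge.errors import InvalidStackError


def random_stack(seed, n_shards=2, missing=0.3):
    world = generate_mapping_world(
        SyntheticGraphSpec(n_datasources=4, n_entities=12, n_shards=n_shards,
                           missing_edge_prob=missing, seed=seed)
    )
    members = [MemoryLinkMapper(shard) for shard in world.shards]
    pooled = [link for shard in world.shards for link in shard]
    nodes = sorted({x for link in pooled for x in link})
    return world, members, pooled, nodes


class TestStackConstruction:
    def test_empty_member_list_rejected(self):
        with pytest.raises(InvalidStackError):
            stack([])

    @pytest.mark.parametrize("degree", [0, 4])
    def test_max_degree_outside_1_to_3_rejected(self, degree):
        with pytest.raises(InvalidStackError):
            stack([MemoryLinkMapper([])], transitive=True, max_degree=degree)

    def test_closed_member_rejected(self):
        m = MemoryLinkMapper([])
        m.close()
        with pytest.raises(InvalidStackError):
            stack([m])

    @pytest.mark.parametrize("transitive", [False, True])
    def test_single_member_stack_behaves_like_member(self, transitive):
        world, members, pooled, nodes = random_stack(seed=11, n_shards=1)
        combined = stack([members[0]], transitive=transitive, max_degree=1)
        for x in nodes:
            assert combined.map_id(x) == members[0].map_id(x)


class TestUnionMode:
    @pytest.mark.parametrize("seed", range(8))
    def test_union_of_member_results(self, seed):
        world, members, pooled, nodes = random_stack(seed=2000 + seed)
        combined = stack(members, transitive=False)
        for x in nodes:
            expected = frozenset().union(*(m.map_id(x) for m in members))
            assert combined.map_id(x) == expected


class TestTransitiveInference:
    def test_custom_probe_maps_to_ensembl_through_entrez(self, toy_sources):
        """A custom annotation file plus a gene database infer the
        custom-probe ↔ Ensembl mapping neither member stores."""
        custom, entrez, ensembl = toy_sources
        gene_db = MemoryLinkMapper([(Xref(ensembl, "ENSG01"), Xref(entrez, "1234"))])
        annotation = MemoryLinkMapper([(Xref(custom, "C1"), Xref(entrez, "1234"))])
        combined = stack([gene_db, annotation], transitive=True, max_degree=2)
        assert combined.map_id(Xref(custom, "C1"), frozenset({ensembl})) == {
            Xref(ensembl, "ENSG01")
        }
        # without transitivity no member holds the link directly
        flat = stack([gene_db, annotation], transitive=False)
        assert flat.map_id(Xref(custom, "C1"), frozenset({ensembl})) == frozenset()

    def test_intermediate_sources_are_traversal_only(self, toy_sources):
        custom, entrez, ensembl = toy_sources
        gene_db = MemoryLinkMapper([(Xref(ensembl, "ENSG01"), Xref(entrez, "1234"))])
        annotation = MemoryLinkMapper([(Xref(custom, "C1"), Xref(entrez, "1234"))])
        combined = stack([gene_db, annotation], transitive=True, max_degree=2)
        hits = combined.map_id(Xref(custom, "C1"), frozenset({ensembl}))
        assert all(h.datasource == ensembl for h in hits)

    def test_cyclic_links_terminate_and_exclude_query(self):
        a = DataSource("A", "Source A")
        b = DataSource("B", "Source B")
        m1 = MemoryLinkMapper([(Xref(a, "1"), Xref(b, "2"))])
        m2 = MemoryLinkMapper([(Xref(b, "2"), Xref(a, "1"))])
        combined = stack([m1, m2], transitive=True, max_degree=3)
        result = combined.map_id(Xref(a, "1"))
        assert result == {Xref(b, "2")}
        assert Xref(a, "1") not in result

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_equals_closure_oracle_on_random_worlds(self, seed, degree):
        world, members, pooled, nodes = random_stack(seed=4000 + seed, n_shards=3)
        combined = stack(members, transitive=True, max_degree=degree)
        for x in nodes:
            assert combined.map_id(x) == transitive_closure_oracle(pooled, x, degree)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_degree_and_over_union_mode(self, seed):
        world, members, pooled, nodes = random_stack(seed=5000 + seed)
        union = stack(members, transitive=False)
        by_degree = {
            k: stack(members, transitive=True, max_degree=k) for k in (1, 2, 3)
        }
        for x in nodes:
            assert union.map_id(x) == by_degree[1].map_id(x)
            assert by_degree[1].map_id(x) <= by_degree[2].map_id(x)
            assert by_degree[2].map_id(x) <= by_degree[3].map_id(x)
            assert union.map_id(x) <= by_degree[3].map_id(x)

    def test_member_order_never_affects_results(self):
        world, members, pooled, nodes = random_stack(seed=99, n_shards=3)
        for perm in itertools.permutations(members):
            combined = stack(list(perm), transitive=True, max_degree=2)
            for x in nodes[:10]:
                assert combined.map_id(x) == transitive_closure_oracle(pooled, x, 2)

    def test_provenance_flags_direct_vs_inferred(self, toy_sources):
        custom, entrez, ensembl = toy_sources
        gene_db = MemoryLinkMapper([(Xref(ensembl, "ENSG01"), Xref(entrez, "1234"))])
        annotation = MemoryLinkMapper([(Xref(custom, "C1"), Xref(entrez, "1234"))])
        combined = stack([gene_db, annotation], transitive=True, max_degree=2)
        tags = {
            r.xref: r.provenance
            for r in combined.map_id_with_provenance(Xref(custom, "C1"))
        }
        assert tags[Xref(entrez, "1234")] == "direct"
        assert tags[Xref(ensembl, "ENSG01")] == "inferred"


class TestClosureOracle:
    def test_hand_checkable_chain(self):
        ds = DataSource("A", "Source A")
        a, b, c, d = (Xref(ds, s) for s in "abcd")
        links = [(a, b), (b, c), (c, d)]
        assert transitive_closure_oracle(links, a, 2) == {b, c}
        assert transitive_closure_oracle(links, a, 1) == {b}
        assert transitive_closure_oracle(links, a, 3) == {b, c, d}

    def test_unknown_query_gives_empty_set(self):
        ds = DataSource("A", "Source A")
        assert transitive_closure_oracle([], Xref(ds, "x"), 2) == frozenset()

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_one_equals_pooled_direct_mapping(self, seed):
        world, members, pooled, nodes = random_stack(seed=6000 + seed)
        direct = MemoryLinkMapper(pooled)
        for x in nodes:
            assert transitive_closure_oracle(pooled, x, 1) == direct.map_id(x)


class TestStackCapabilities:
    def test_transitive_capabilities_include_composed_pairs(self, toy_sources):
        custom, entrez, ensembl = toy_sources
        gene_db = MemoryLinkMapper([(Xref(ensembl, "ENSG01"), Xref(entrez, "1234"))])
        annotation = MemoryLinkMapper([(Xref(custom, "C1"), Xref(entrez, "9999"))])
        flat = stack([gene_db, annotation], transitive=False)
        assert not flat.capabilities().is_mapping_supported(custom, ensembl)
        combined = stack([gene_db, annotation], transitive=True, max_degree=2)
        caps = combined.capabilities()
        assert caps.is_mapping_supported(custom, ensembl)
        assert caps.is_mapping_supported(custom, entrez)

    def test_union_capabilities_cover_all_members(self):
        world, members, pooled, nodes = random_stack(seed=123)
        caps = stack(members).capabilities()
        for m in members:
            assert m.capabilities().source_datasources <= caps.source_datasources
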