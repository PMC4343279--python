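"""Annotation store: hierarchy closure, SELECT semantics, round-trips."""

import numpy as np
import pytest

import meshora as m
from meshora import io as mio

from conftest import bfs_reachability, random_dag


class TestHierarchy:
    def test_chain_closure(self, chain_store):
        assert chain_store.aor_edges == {("X", "Y"), ("X", "Z"), ("Y", "Z")}
        assert chain_store.parents("Z") == {"Y"}
        assert chain_store.parents("X") == set()
        assert chain_store.ancestors("Z") == {"X", "Y"}
        assert chain_store.ancestors("X") == set()
        assert chain_store.offspring("X") == {"Y", "Z"}
        assert chain_store.children("X") == {"Y"}

    def test_empty_edge_list_gives_empty_closure(self):
        terms = [m.MeshTerm("A1", "a", "A"), m.MeshTerm("A2", "b", "A")]
        store = m.create_store(terms, [], [])
        assert store.aor_edges == frozenset()

    def test_multi_parent_node(self, diamond_store):
        assert diamond_store.parents("C") == {"P1", "P2"}
        assert diamond_store.ancestors("C") == {"R", "P1", "P2"}

    def test_closure_matches_bfs_oracle_on_random_dags(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 31))
            terms, edges = random_dag(rng, n)
            store = m.create_store(terms, edges, [])
            oracle = bfs_reachability(n, edges)
            for node, reachable in oracle.items():
                assert store.offspring(node) == reachable
                assert node not in store.ancestors(node)  # strict ancestors

    def test_cycle_rejected_naming_a_member(self):
        terms = [m.MeshTerm(t, t, "A") for t in ("U", "V")]
        with pytest.raises(m.ValidationError, match="cycle"):
            m.create_store(terms, [("U", "V"), ("V", "U")], [])

    def test_dangling_ids_rejected(self):
        terms = [m.MeshTerm("U", "u", "A")]
        with pytest.raises(m.ValidationError, match="GHOST"):
            m.create_store(terms, [("U", "GHOST")], [])
        with pytest.raises(m.ValidationError, match="GHOST"):
            m.create_store(terms, [], [m.GeneMeshLink(1, "GHOST", "gendoo")])

    def test_unknown_term_query_rejected(self, chain_store):
        with pytest.raises(m.ValidationError):
            chain_store.parents("nope")


class TestSelect:
    def test_single_record(self, chain_store):
        res = chain_store.select([101], ["MESHID"], "GENEID")
        assert res.columns == ("MESHID",)
        assert res.rows == (("Z",),)

    def test_empty_keys_yield_zero_rows(self, chain_store):
        assert len(chain_store.select([], ["MESHID"], "GENEID")) == 0

    def test_missing_keys_yield_no_rows_not_errors(self, chain_store):
        assert len(chain_store.select([999], ["MESHID"], "GENEID")) == 0

    def test_term_attributes_joined(self, chain_store):
        res = chain_store.select(
            ["Z"], ["MESHTERM", "MESHCATEGORY", "QUALIFIER", "SYNONYM", "PUBMEDID"],
            "MESHID",
        )
        assert res.rows == (("leaf", "A", "metabolism", "leafish", 70001),)

    def test_select_by_pubmedid_and_category(self, chain_store):
        res = chain_store.select([70001], ["GENEID"], "PUBMEDID")
        assert res.rows == ((101,),)
        res = chain_store.select(["A"], ["MESHID"], "MESHCATEGORY")
        assert {r[0] for r in res.rows} == {"X", "Y", "Z"}

    def test_unknown_keytype_and_cols_listed(self, chain_store):
        with pytest.raises(m.ValidationError, match="GENEID"):
            chain_store.select([1], ["MESHID"], "WAT")
        with pytest.raises(m.ValidationError, match="MESHTERM"):
            chain_store.select([1], ["WAT"], "GENEID")
        with pytest.raises(m.ValidationError, match="non-empty"):
            chain_store.select([1], [], "GENEID")

    def test_roundtrip_recovers_inserted_links(self, rng):
        terms = [m.MeshTerm(f"T{i:02d}", f"t{i}", "D") for i in range(10)]
        inserted = set()
        while len(inserted) < 50:
            inserted.add(
                (int(rng.integers(1, 30)), f"T{int(rng.integers(10)):02d}")
            )
        links = [
            m.GeneMeshLink(g, t, "gendoo", {int(rng.integers(1, 10**6))})
            for g, t in inserted
        ]
        store = m.create_store(terms, [], links)
        recovered = set()
        for g in {g for g, _ in inserted}:
            res = store.select([g], ["GENEID", "MESHID"], "GENEID")
            recovered |= {(int(a), b) for a, b in res.rows}
        assert recovered == inserted

    def test_keytypes_and_columns_fixed(self, chain_store):
        assert chain_store.keytypes() == list(m.KEYTYPES)
        assert len(chain_store.keytypes()) == 6
        assert chain_store.columns() == list(m.COLUMNS)
        assert len(chain_store.columns()) == 8
        assert chain_store.keytypes() == chain_store.keytypes()

    def test_deterministic_row_order(self, rng):
        terms = [m.MeshTerm(f"T{i}", f"t{i}", "D") for i in range(5)]
        links = [
            m.GeneMeshLink(7, f"T{i}", src, {i + 1})
            for i in range(5)
            for src in ("gendoo", "RBBH")
        ]
        store = m.create_store(terms, [], links)
        first = store.select([7], ["MESHID", "SOURCEID"], "GENEID")
        again = store.select([7], ["MESHID", "SOURCEID"], "GENEID")
        assert first.rows == again.rows
        assert list(first.rows) == sorted(first.rows)


class TestDiskRoundTrip:
    def test_store_roundtrip_identical_select(self, chain_store, tmp_path):
        mio.write_store(chain_store, tmp_path / "store")
        reloaded = mio.read_store(tmp_path / "store")
        assert reloaded.metadata == dict(chain_store.metadata)
        assert reloaded.aor_edges == chain_store.aor_edges
        for keytype, keys in [("GENEID", [101]), ("MESHID", ["X", "Y", "Z"])]:
            a = chain_store.select(keys, list(m.COLUMNS), keytype)
            b = reloaded.select(keys, list(m.COLUMNS), keytype)
            assert a == b

    def test_rewrite_is_byte_identical(self, chain_store, tmp_path):
        mio.write_store(chain_store, tmp_path / "s1")
        mio.write_store(mio.read_store(tmp_path / "s1"), tmp_path / "s2")
        for name in ("vocabulary.tsv", "edges.tsv", "links.tsv", "manifest.txt"):
            assert (tmp_path / "s1" / name).read_bytes() == (
                tmp_path / "s2" / name
            ).read_bytes()
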