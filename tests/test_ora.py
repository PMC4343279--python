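"""Hypergeometric test and the enrichment workflow."""

import itertools

import numpy as np
import pytest
from scipy import stats

import meshora as m
from meshora.ora import ContingencyCounts, read_report, write_report


def enumeration_pvalue(N, k, M, x):
    """Exhaustive oracle: draw every k-subset of an N-gene urn with M
    marked genes; P(X >= x) is the fraction of draws with >= x marks."""
    marked = set(range(M))
    draws = hits = 0
    for subset in itertools.combinations(range(N), k):
        draws += 1
        if len(marked.intersection(subset)) >= x:
            hits += 1
    return hits / draws


class TestHypergeom:
    def test_worked_point_mass(self):
        c = ContingencyCounts(N=10, k=4, M=5, x=4)
        assert m.hypergeom_pmf(c) == pytest.approx(1 / 42, abs=1e-15)
        assert m.hypergeom_pvalue(c) == pytest.approx(1 / 42, abs=1e-15)

    def test_forced_outcomes(self):
        assert m.hypergeom_pmf(ContingencyCounts(N=8, k=3, M=0, x=0)) == pytest.approx(1.0)
        assert m.hypergeom_pvalue(ContingencyCounts(N=8, k=3, M=5, x=0)) == 1.0

    def test_pmf_normalizes(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 40))
            k = int(rng.integers(1, N + 1))
            M = int(rng.integers(0, N + 1))
            total = sum(
                m.hypergeom_pmf(ContingencyCounts(N=N, k=k, M=M, x=x))
                for x in range(max(0, k + M - N), min(k, M) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_tail_matches_enumeration_small(self):
        for N in range(2, 9):
            for k in range(1, N + 1):
                for M in range(0, N + 1):
                    for x in range(max(0, k + M - N), min(k, M) + 1):
                        c = ContingencyCounts(N=N, k=k, M=M, x=x)
                        assert m.hypergeom_pvalue(c) == pytest.approx(
                            enumeration_pvalue(N, k, M, x), abs=1e-12
                        )

    def test_tail_matches_scipy_cross_check(self, rng):
        for _ in range(100):
            N = int(rng.integers(5, 500))
            k = int(rng.integers(1, N + 1))
            M = int(rng.integers(0, N + 1))
            lo = max(0, k + M - N)
            x = int(rng.integers(lo, min(k, M) + 1))
            c = ContingencyCounts(N=N, k=k, M=M, x=x)
            assert m.hypergeom_pvalue(c) == pytest.approx(
                stats.hypergeom.sf(x - 1, N, M, k), rel=1e-10, abs=1e-14
            )

    def test_invariant_violations_named(self):
        with pytest.raises(m.ValidationError, match="M <= N"):
            ContingencyCounts(N=5, k=2, M=6, x=1)
        with pytest.raises(m.ValidationError, match="min"):
            ContingencyCounts(N=10, k=2, M=5, x=3)


def planted_fixture(seed=11, effect=10.0):
    spec = m.FixtureSpec(
        n_genes=500, n_terms=40, categories=("D",), density=0.08,
        planted_term=m.synthetic.term_id(3), planted_effect=effect, seed=seed,
    )
    terms, edges = m.make_vocabulary(spec)
    links = m.make_annotations(spec, terms)
    store = m.create_store(terms, edges, links)
    study = m.make_study(spec, links)
    return spec, store, study


class TestMeshHyperGTest:
    def test_planted_term_ranks_first(self):
        spec, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.selected,
            m.OraParams(category="D", correction="BH"),
        )
        assert rows[0].mesh_id == spec.planted_term
        assert rows[0].p_raw == min(r.p_raw for r in rows)

    def test_selected_equals_universe_gives_all_p_one(self):
        _, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.universe,
            m.OraParams(category="D", correction="none"),
        )
        assert rows
        for r in rows:
            assert r.counts.x == r.counts.M
            assert r.p_raw == pytest.approx(1.0)

    def test_counts_match_independent_recount(self):
        spec, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.selected,
            m.OraParams(category="D", correction="none"),
        )
        # recount from the raw link table, independently of the engine
        links = [l for l in store.links
                 if store.terms[l.mesh_id].category.code == "D"]
        universe = set(study.universe)
        annotated = {l.gene_id for l in links if l.gene_id in universe}
        selected = set(study.selected) & annotated
        for r in rows:
            genes = {l.gene_id for l in links
                     if l.mesh_id == r.mesh_id and l.gene_id in universe}
            c = ContingencyCounts(
                N=len(annotated), k=len(selected), M=len(genes),
                x=len(genes & selected),
            )
            assert (r.counts.N, r.counts.k, r.counts.M, r.counts.x) == (c.N, c.k, c.M, c.x)
            assert r.p_raw == pytest.approx(m.hypergeom_pvalue(c), abs=1e-14)
            assert set(r.gene_ids) == genes & selected
            assert len(r.gene_ids) == r.counts.x

    def test_adjusted_ge_raw_under_bh(self):
        _, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.selected,
            m.OraParams(category="D", correction="BH"),
        )
        for r in rows:
            assert r.p_adjusted >= r.p_raw - 1e-12

    def test_nothing_testable_returns_empty_with_warning(self, chain_store):
        with pytest.warns(UserWarning, match="nothing testable"):
            rows = m.mesh_hyper_g_test(
                chain_store, [101, 102], [102],
                m.OraParams(category="A", correction="none"),
            )
        assert rows == []

    def test_selected_outside_universe_rejected(self, chain_store):
        with pytest.raises(m.ValidationError, match="universe"):
            m.mesh_hyper_g_test(
                chain_store, [101], [999], m.OraParams(category="A")
            )

    def test_rows_sorted_by_p_then_mesh_id(self):
        _, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.selected, m.OraParams(category="D")
        )
        keys = [(r.p_raw, r.mesh_id) for r in rows]
        assert keys == sorted(keys)


class TestWeightsAndReports:
    def test_term_weights(self):
        rows = [
            m.OraResultRow("D1", "t", "D", ContingencyCounts(10, 2, 2, 1),
                           0.01, 0.05, "BH", True),
            m.OraResultRow("D2", "t", "D", ContingencyCounts(10, 2, 2, 0),
                           1.0, 1.0, "BH", False),
        ]
        weights = m.term_weights(rows)
        assert weights == {"D1": pytest.approx(2.0), "D2": 0.0}

    def test_weights_monotone_in_p(self):
        ps = [0.001, 0.01, 0.5, 1.0]
        rows = [
            m.OraResultRow(f"D{i}", "t", "D", ContingencyCounts(10, 2, 2, 0),
                           p, p, "none", False)
            for i, p in enumerate(ps)
        ]
        w = m.term_weights(rows)
        values = [w[f"D{i}"] for i in range(len(ps))]
        assert values == sorted(values, reverse=True)

    def test_nonpositive_p_rejected(self):
        row = m.OraResultRow("D1", "t", "D", ContingencyCounts(10, 2, 2, 0),
                             0.0, 0.0, "none", False)
        with pytest.raises(m.ValidationError):
            m.term_weights([row])

    def test_empty_rows_give_header_only_file(self, tmp_path):
        write_report([], tmp_path / "r.tsv", format="tsv")
        text = (tmp_path / "r.tsv").read_text()
        assert text.splitlines() == ["\t".join(m.ora.REPORT_COLUMNS)]

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_roundtrip_byte_identical(self, tmp_path, fmt):
        _, store, study = planted_fixture()
        rows = m.mesh_hyper_g_test(
            store, study.universe, study.selected, m.OraParams(category="D")
        )
        p1 = tmp_path / f"r1.{fmt}"
        p2 = tmp_path / f"r2.{fmt}"
        write_report(rows, p1, format=fmt)
        write_report(read_report(p1, format=fmt), p2, format=fmt)
        assert p1.read_bytes() == p2.read_bytes()
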