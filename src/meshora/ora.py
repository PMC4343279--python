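"""Per-term hypergeometric over-representation analysis.

Given a gene universe, a list of interesting genes (typically DEGs) and
an annotation store, each MeSH term of a chosen category is tested for
enrichment with the hypergeometric distribution. With N annotated
universe genes, k of them interesting, M annotated to the term and x
both, the point probability is

    P(X = x) = C(M, x) * C(N-M, k-x) / C(N, k)

and the reported enrichment p-value is the upper tail P(X >= x). The
point mass alone is exposed as :func:`hypergeom_pmf`; standard ORA
practice (GOstats and kin) tests the tail, and that convention is
followed here — the single most consequential interpretation choice in
this module.

The universe is category- and source-restricted: N counts only genes
carrying at least one link of the requested category/source, so the
multiple-testing family is the set of tested terms within one category
per run. Annotations are NOT propagated up the hierarchy: a term counts
only its direct links.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._errors import ValidationError
from . import fdr as fdr_mod
from .categories import VALID_CATEGORY_CODES
from .store import VALID_SOURCES, MeshStore, links_for


@dataclass(frozen=True)
class ContingencyCounts:
    """The (N, k, M, x) quadruple of one enrichment test.

    N: universe size; k: interesting genes; M: universe genes annotated
    to the term; x: interesting genes annotated to the term.
    """

    N: int
    k: int
    M: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N):
            raise ValidationError(f"violated bound 0 <= M <= N: M={self.M}, N={self.N}")
        if not (0 <= self.k <= self.N):
            raise ValidationError(f"violated bound 0 <= k <= N: k={self.k}, N={self.N}")
        if not (0 <= self.x <= min(self.k, self.M)):
            raise ValidationError(
                f"violated bound 0 <= x <= min(k, M): x={self.x}, k={self.k}, M={self.M}"
            )
        if self.k - self.x > self.N - self.M:
            raise ValidationError(
                f"violated bound k - x <= N - M: "
                f"k={self.k}, x={self.x}, N={self.N}, M={self.M}"
            )


@dataclass(frozen=True)
class OraParams:
    """Test configuration: one category, a source filter, a correction
    method and the significance threshold applied to adjusted values."""

    category: str = "D"
    source: frozenset[str] = frozenset(VALID_SOURCES)
    correction: str = "QV"
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORY_CODES:
            raise ValidationError(f"invalid category code {self.category!r}")
        src = frozenset(self.source) if not isinstance(self.source, str) else frozenset({self.source})
        if not src or not src <= VALID_SOURCES:
            raise ValidationError(f"source must be a non-empty subset of {sorted(VALID_SOURCES)}")
        object.__setattr__(self, "source", src)
        if self.correction not in fdr_mod.ENGINES:
            raise ValidationError(
                f"correction must be one of {sorted(fdr_mod.ENGINES)}, got {self.correction!r}"
            )
        if not 0 < self.threshold < 1:
            raise ValidationError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class OraResultRow:
    """One tested term with its counts, raw and adjusted p-values and the
    x overlapping genes."""

    mesh_id: str
    term: str
    category: str
    counts: ContingencyCounts
    p_raw: float
    p_adjusted: float
    method: str
    significant: bool
    gene_ids: tuple[int, ...] = field(default_factory=tuple)


def _log_comb(n: int, r: int) -> float:
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_pmf(counts: ContingencyCounts) -> float:
    """Exact point probability P(X = x), via log-factorial arithmetic."""
    c = counts
    log_p = (
        _log_comb(c.M, c.x)
        + _log_comb(c.N - c.M, c.k - c.x)
        - _log_comb(c.N, c.k)
    )
    return float(math.exp(log_p))


def hypergeom_pvalue(counts: ContingencyCounts) -> float:
    """Upper-tail enrichment p-value P(X >= x) = sum_{j>=x} P(X = j)."""
    c = counts
    if c.x <= max(0, c.k + c.M - c.N):
        return 1.0  # whole support: the tail is exact, not a rounded sum
    upper = min(c.k, c.M)
    total = 0.0
    for j in range(c.x, upper + 1):
        total += hypergeom_pmf(ContingencyCounts(N=c.N, k=c.k, M=c.M, x=j))
    return float(min(total, 1.0))


def mesh_hyper_g_test(
    store: MeshStore,
    universe: Iterable[int],
    selected: Iterable[int],
    params: OraParams,
    fdr_engine: Callable | None = None,
) -> list[OraResultRow]:
    """Run the per-term hypergeometric test over one category of a store.

    ``fdr_engine`` overrides the correction chosen by ``params``; by
    default the engine matching ``params.correction`` is used. Rows are
    sorted by raw p-value ascending, ties by mesh_id, and flagged
    significant when the adjusted value falls below ``params.threshold``.
    Returns an empty list (with a warning) when no selected gene carries
    a qualifying annotation — nothing is testable.
    """
    universe_set = {int(g) for g in universe}
    selected_set = {int(g) for g in selected}
    if not universe_set or not selected_set:
        raise ValidationError("universe and selected gene lists must be non-empty")
    if not selected_set <= universe_set:
        extra = sorted(selected_set - universe_set)[:5]
        raise ValidationError(f"selected genes not in universe, e.g. {extra}")

    filtered = links_for(store, category=params.category, sources=params.source)
    term_genes: dict[str, set[int]] = {}
    for link in filtered:
        if link.gene_id in universe_set:
            term_genes.setdefault(link.mesh_id, set()).add(link.gene_id)

    annotated = set().union(*term_genes.values()) if term_genes else set()
    N = len(annotated)
    k_genes = selected_set & annotated
    k = len(k_genes)
    if k == 0:
        warnings.warn(
            "nothing testable: no selected gene carries an annotation in "
            f"category {params.category!r} for sources {sorted(params.source)}"
        )
        return []

    tested: list[tuple[str, ContingencyCounts, tuple[int, ...]]] = []
    for mesh_id in sorted(term_genes):
        genes = term_genes[mesh_id]
        M = len(genes)
        overlap = tuple(sorted(genes & k_genes))
        counts = ContingencyCounts(N=N, k=k, M=M, x=len(overlap))
        tested.append((mesh_id, counts, overlap))

    p_raw = np.array([hypergeom_pvalue(c) for _, c, _ in tested])
    engine = fdr_engine
    if engine is None:
        engine = fdr_mod.ENGINES[params.correction]
    if engine is None:  # correction == "none"
        p_adj = p_raw.copy()
        method = "none"
    else:
        adj = engine(p_raw, alpha=params.threshold)
        p_adj = np.asarray(adj.values, dtype=float)
        method = adj.method

    rows = [
        OraResultRow(
            mesh_id=mesh_id,
            term=store.terms[mesh_id].term,
            category=params.category,
            counts=counts,
            p_raw=float(p),
            p_adjusted=float(q),
            method=method,
            significant=bool(q < params.threshold),
            gene_ids=overlap,
        )
        for (mesh_id, counts, overlap), p, q in zip(tested, p_raw, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_raw, r.mesh_id))
    return rows


def term_weights(rows: Iterable[OraResultRow]) -> dict[str, float]:
    """Tag-cloud weights: -log10 of the raw p-value per term (p = 1 maps
    to weight 0)."""
    weights = {}
    for row in rows:
        if row.p_raw <= 0:
            raise ValidationError(f"non-positive p-value for {row.mesh_id}")
        weights[row.mesh_id] = -math.log10(row.p_raw)
    return weights


REPORT_COLUMNS = [
    "mesh_id",
    "term",
    "category",
    "N",
    "k",
    "M",
    "x",
    "p_raw",
    "p_adjusted",
    "method",
    "significant",
    "gene_ids",
]


def _rows_to_frame(rows: Iterable[OraResultRow]) -> pd.DataFrame:
    records = [
        {
            "mesh_id": r.mesh_id,
            "term": r.term,
            "category": r.category,
            "N": r.counts.N,
            "k": r.counts.k,
            "M": r.counts.M,
            "x": r.counts.x,
            "p_raw": repr(r.p_raw),
            "p_adjusted": repr(r.p_adjusted),
            "method": r.method,
            "significant": r.significant,
            "gene_ids": "|".join(str(g) for g in r.gene_ids),
        }
        for r in rows
    ]
    return pd.DataFrame(records, columns=REPORT_COLUMNS)


def write_report(
    rows: Iterable[OraResultRow], path: str | os.PathLike, format: str = "tsv"
) -> None:
    """Serialize result rows as TSV or JSON with a stable column order.

    Floats are written with ``repr`` so a parse/serialize cycle is
    byte-identical.
    """
    frame = _rows_to_frame(rows)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"format must be 'tsv' or 'json', got {format!r}")


def read_report(path: str | os.PathLike, format: str = "tsv") -> list[OraResultRow]:
    """Parse a report written by :func:`write_report`."""
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif format == "json":
        with open(path) as fh:
            frame = pd.DataFrame(json.load(fh), columns=REPORT_COLUMNS, dtype=str)
    else:
        raise ValidationError(f"format must be 'tsv' or 'json', got {format!r}")
    rows = []
    for rec in frame.itertuples(index=False):
        rows.append(
            OraResultRow(
                mesh_id=rec.mesh_id,
                term=rec.term,
                category=rec.category,
                counts=ContingencyCounts(
                    N=int(rec.N), k=int(rec.k), M=int(rec.M), x=int(rec.x)
                ),
                p_raw=float(rec.p_raw),
                p_adjusted=float(rec.p_adjusted),
                method=rec.method,
                significant=str(rec.significant) == "True",
                gene_ids=tuple(
                    int(g) for g in str(rec.gene_ids).split("|") if g
                ),
            )
        )
    return rows
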