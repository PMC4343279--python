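"""Gene-to-MeSH annotation store with a SELECT retrieval contract.

The store holds three relations — the term vocabulary, the parent-child
hierarchy and the gene-to-term links — and answers SQL-SELECT-style
queries over their join. The hierarchy is a multi-parent DAG: a MeSH
heading may sit at several positions of the tree, so parent-child edges
(PCR) form a poly-hierarchy, and ancestor-offspring relations (AOR) are
derived at build time as the transitive closure of PCR. Deriving AOR
rather than storing it independently makes the closure invariant
checkable and removes a consistency failure mode.

Gene identifiers are Entrez-style positive integers throughout; document
identifiers are PubMed-style positive integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from ._errors import ValidationError
from .categories import VALID_CATEGORY_CODES, MeshCategory

#: Valid ``keytype`` names for :func:`select`.
KEYTYPES: tuple[str, ...] = (
    "GENEID",
    "MESHID",
    "MESHTERM",
    "MESHCATEGORY",
    "SOURCEID",
    "PUBMEDID",
)

#: Valid ``cols`` names for :func:`select`.
COLUMNS: tuple[str, ...] = (
    "GENEID",
    "MESHID",
    "MESHTERM",
    "MESHCATEGORY",
    "QUALIFIER",
    "SYNONYM",
    "SOURCEID",
    "PUBMEDID",
)

#: Allowed provenance labels for gene-term links.
VALID_SOURCES: frozenset[str] = frozenset({"gendoo", "gene2pubmed", "RBBH"})


@dataclass(frozen=True)
class MeshTerm:
    """A vocabulary entry: a MeSH heading with its category, qualifiers
    (sub-headings such as *genetics* or *pathology*) and synonyms."""

    mesh_id: str
    term: str
    category: MeshCategory
    qualifiers: frozenset[str] = frozenset()
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.mesh_id:
            raise ValidationError("mesh_id must be non-empty")
        if not self.term:
            raise ValidationError(f"term label for {self.mesh_id!r} must be non-empty")
        if isinstance(self.category, str):  # accept bare codes for convenience
            object.__setattr__(self, "category", MeshCategory(self.category))
        object.__setattr__(self, "qualifiers", frozenset(self.qualifiers))
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))


@dataclass(frozen=True)
class HierarchyEdge:
    """A directed parent -> child relation. ``relation`` distinguishes the
    stored direct edges (PCR) from the derived closure edges (AOR)."""

    parent: str
    child: str
    relation: str = "PCR"

    def __post_init__(self) -> None:
        if self.relation not in ("PCR", "AOR"):
            raise ValidationError(f"relation must be PCR or AOR, got {self.relation!r}")
        if self.parent == self.child:
            raise ValidationError(f"self-edge on {self.parent!r} is not allowed")


@dataclass(frozen=True)
class GeneMeshLink:
    """One gene-to-term annotation with its provenance and the PubMed
    documents supporting it. The atom of the store."""

    gene_id: int
    mesh_id: str
    source: str
    document_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if int(self.gene_id) <= 0:
            raise ValidationError(f"gene_id must be a positive integer, got {self.gene_id}")
        object.__setattr__(self, "gene_id", int(self.gene_id))
        if self.source not in VALID_SOURCES:
            raise ValidationError(
                f"source must be one of {sorted(VALID_SOURCES)}, got {self.source!r}"
            )
        docs = frozenset(int(d) for d in self.document_ids)
        if any(d <= 0 for d in docs):
            raise ValidationError(f"document ids must be positive, got {sorted(docs)}")
        object.__setattr__(self, "document_ids", docs)


@dataclass(frozen=True)
class QueryResult:
    """A long-format relational answer: ordered columns plus aligned rows.
    Duplicate rows are preserved, mirroring SQL SELECT semantics."""

    columns: tuple[str, ...]
    rows: tuple[tuple, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows), columns=list(self.columns))


@dataclass(frozen=True)
class MeshStore:
    """Immutable annotation store. Build through :func:`create_store`."""

    terms: Mapping[str, MeshTerm]
    pcr_edges: frozenset[tuple[str, str]]
    aor_edges: frozenset[tuple[str, str]]
    links: tuple[GeneMeshLink, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    # --- hierarchy -------------------------------------------------------

    def _require_term(self, mesh_id: str) -> None:
        if mesh_id not in self.terms:
            raise ValidationError(f"unknown mesh_id {mesh_id!r}")

    def parents(self, mesh_id: str) -> set[str]:
        """Direct parents of a term (PCR only)."""
        self._require_term(mesh_id)
        return {p for (p, c) in self.pcr_edges if c == mesh_id}

    def children(self, mesh_id: str) -> set[str]:
        """Direct children of a term (PCR only)."""
        self._require_term(mesh_id)
        return {c for (p, c) in self.pcr_edges if p == mesh_id}

    def ancestors(self, mesh_id: str) -> set[str]:
        """All strict ancestors of a term (AOR closure; the term itself
        is excluded)."""
        self._require_term(mesh_id)
        return {p for (p, c) in self.aor_edges if c == mesh_id}

    def offspring(self, mesh_id: str) -> set[str]:
        """All strict descendants of a term (AOR closure)."""
        self._require_term(mesh_id)
        return {c for (p, c) in self.aor_edges if p == mesh_id}

    # --- SELECT ----------------------------------------------------------

    def _master(self) -> pd.DataFrame:
        """Long-format join of terms and links, exploded over every
        multi-valued attribute. Cached on first use."""
        cached = getattr(self, "_master_cache", None)
        if cached is not None:
            return cached
        term_rows = [
            {
                "MESHID": t.mesh_id,
                "MESHTERM": t.term,
                "MESHCATEGORY": t.category.code,
                "QUALIFIER": sorted(t.qualifiers) or [None],
                "SYNONYM": sorted(t.synonyms) or [None],
            }
            for t in self.terms.values()
        ]
        terms_df = pd.DataFrame(
            term_rows,
            columns=["MESHID", "MESHTERM", "MESHCATEGORY", "QUALIFIER", "SYNONYM"],
        )
        link_rows = [
            {
                "GENEID": l.gene_id,
                "MESHID": l.mesh_id,
                "SOURCEID": l.source,
                "PUBMEDID": sorted(l.document_ids) or [None],
            }
            for l in self.links
        ]
        links_df = pd.DataFrame(
            link_rows, columns=["GENEID", "MESHID", "SOURCEID", "PUBMEDID"]
        )
        master = terms_df.merge(links_df, on="MESHID", how="left")
        for col in ("QUALIFIER", "SYNONYM", "PUBMEDID"):
            master = master.explode(col, ignore_index=True)
        # unlinked terms leave PUBMEDID as NaN rather than the [None] list
        master["GENEID"] = master["GENEID"].astype("Int64")
        master["PUBMEDID"] = master["PUBMEDID"].astype("Int64")
        object.__setattr__(self, "_master_cache", master)
        return master

    def keytypes(self) -> list[str]:
        """Valid ``keytype`` names accepted by :meth:`select`."""
        return list(KEYTYPES)

    def columns(self) -> list[str]:
        """Valid ``cols`` names accepted by :meth:`select`."""
        return list(COLUMNS)

    def select(
        self, keys: Sequence, cols: Sequence[str], keytype: str
    ) -> QueryResult:
        """Retrieve rows of the joined term/link relation.

        Rows where the ``keytype`` column matches any of ``keys`` are
        returned, projected onto ``cols``, in deterministic order (sorted
        by the keytype column, then by the projected columns). Keys absent
        from the store yield no rows; only malformed ``keytype``/``cols``
        names raise.
        """
        if keytype not in KEYTYPES:
            raise ValidationError(
                f"unknown keytype {keytype!r}; valid keytypes: {', '.join(KEYTYPES)}"
            )
        cols = list(cols)
        if not cols:
            raise ValidationError(f"cols must be non-empty; valid cols: {', '.join(COLUMNS)}")
        bad = [c for c in cols if c not in COLUMNS]
        if bad:
            raise ValidationError(
                f"unknown column name(s) {bad}; valid cols: {', '.join(COLUMNS)}"
            )
        master = self._master()
        if keytype in ("GENEID", "PUBMEDID"):
            keys = [int(k) for k in keys]
        matched = master[master[keytype].isin(keys)]
        sort_cols = [keytype] + [c for c in cols if c != keytype]
        projected = matched.sort_values(
            sort_cols, kind="mergesort", na_position="last"
        )[cols]
        rows = tuple(
            tuple(None if pd.isna(v) else v for v in row)
            for row in projected.itertuples(index=False, name=None)
        )
        return QueryResult(columns=tuple(cols), rows=rows)


def select(store: MeshStore, keys: Sequence, cols: Sequence[str], keytype: str) -> QueryResult:
    """Functional alias for :meth:`MeshStore.select`."""
    return store.select(keys, cols, keytype)


def create_store(
    terms: Iterable[MeshTerm],
    edges_pcr: Iterable[HierarchyEdge | tuple[str, str]],
    links: Iterable[GeneMeshLink],
    metadata: Mapping[str, str] | None = None,
) -> MeshStore:
    """Validate the three relations and build an immutable store.

    The PCR edge set must be acyclic and every edge endpoint and link
    term must resolve to a vocabulary entry; AOR edges are computed here
    as the transitive closure of PCR.
    """
    term_map: dict[str, MeshTerm] = {}
    for t in terms:
        if t.mesh_id in term_map:
            raise ValidationError(f"duplicate mesh_id {t.mesh_id!r}")
        term_map[t.mesh_id] = t

    pcr: set[tuple[str, str]] = set()
    for e in edges_pcr:
        if isinstance(e, tuple):
            e = HierarchyEdge(parent=e[0], child=e[1])
        for endpoint in (e.parent, e.child):
            if endpoint not in term_map:
                raise ValidationError(f"edge references unknown mesh_id {endpoint!r}")
        pcr.add((e.parent, e.child))

    graph = nx.DiGraph()
    graph.add_nodes_from(term_map)
    graph.add_edges_from(pcr)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(
            f"hierarchy contains a cycle through mesh_id {cycle[0][0]!r}"
        )

    aor = {
        (anc, node)
        for node in graph.nodes
        for anc in nx.ancestors(graph, node)
    }

    link_list: list[GeneMeshLink] = []
    seen: set[tuple[int, str, str]] = set()
    for l in links:
        if l.mesh_id not in term_map:
            raise ValidationError(f"link references unknown mesh_id {l.mesh_id!r}")
        key = (l.gene_id, l.mesh_id, l.source)
        if key in seen:
            raise ValidationError(f"duplicate link (gene_id, mesh_id, source)={key}")
        seen.add(key)
        link_list.append(l)
    link_list.sort(key=lambda l: (l.gene_id, l.mesh_id, l.source))

    return MeshStore(
        terms=term_map,
        pcr_edges=frozenset(pcr),
        aor_edges=frozenset(aor),
        links=tuple(link_list),
        metadata=dict(metadata or {}),
    )


def links_for(
    store: MeshStore,
    category: str | None = None,
    sources: Iterable[str] | None = None,
) -> list[GeneMeshLink]:
    """Links filtered by term category and/or provenance source."""
    if category is not None and category not in VALID_CATEGORY_CODES:
        raise ValidationError(f"invalid category code {category!r}")
    src = None if sources is None else set(sources)
    if src is not None and not src <= VALID_SOURCES:
        raise ValidationError(f"invalid source(s) {sorted(src - VALID_SOURCES)}")
    out = []
    for l in store.links:
        if category is not None and store.terms[l.mesh_id].category.code != category:
            continue
        if src is not None and l.source not in src:
            continue
        out.append(l)
    return out
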