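"""Builders for gene-to-MeSH link tables.

Two construction routes are supported. The literature route joins a
gene-to-PubMed table (gene2pubmed-style curation) with a PubMed-to-MeSH
table, after discarding publications indexed to implausibly many genes
— genome papers and database releases that would link every gene to the
same headings. The projection route copies the links of well-annotated
("major") organisms onto poorly annotated ("minor") organisms through
reciprocal-best-hit ortholog pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._errors import ValidationError
from .store import VALID_SOURCES, GeneMeshLink, MeshStore
from . import io as mio


@dataclass(frozen=True)
class BuildConfig:
    """Literature-join settings.

    ``max_genes_per_paper`` drops any publication linked to strictly more
    than this many distinct genes before the join (default 1000, a strict
    "more than" threshold: a paper with exactly 1000 genes is kept).
    """

    max_genes_per_paper: int = 1000
    source_label: str = "gene2pubmed"

    def __post_init__(self) -> None:
        if self.max_genes_per_paper < 1:
            raise ValidationError("max_genes_per_paper must be >= 1")
        if self.source_label not in VALID_SOURCES:
            raise ValidationError(
                f"source_label must be one of {sorted(VALID_SOURCES)}"
            )


def join_gene_pubmed_mesh(
    g2p: Iterable[tuple[int, int]],
    p2m: Iterable[tuple[int, str]],
    config: BuildConfig | None = None,
) -> list[GeneMeshLink]:
    """Join gene->PubMed with PubMed->MeSH records into annotation links.

    The over-large-paper filter is applied to the gene->PubMed input
    alone, before the join: every pubmed_id associated with more than
    ``config.max_genes_per_paper`` distinct genes is dropped entirely.
    Surviving records are inner-joined on pubmed_id and aggregated to one
    link per (gene, term), carrying the set of contributing documents.
    """
    config = config or BuildConfig()
    g2p_df = pd.DataFrame(list(g2p), columns=["gene_id", "pubmed_id"]).drop_duplicates()
    p2m_df = pd.DataFrame(list(p2m), columns=["pubmed_id", "mesh_id"]).drop_duplicates()
    if g2p_df.empty or p2m_df.empty:
        return []

    genes_per_paper = g2p_df.groupby("pubmed_id")["gene_id"].nunique()
    keep = genes_per_paper[genes_per_paper <= config.max_genes_per_paper].index
    g2p_df = g2p_df[g2p_df["pubmed_id"].isin(keep)]

    joined = g2p_df.merge(p2m_df, on="pubmed_id", how="inner")
    if joined.empty:
        return []
    grouped = joined.groupby(["gene_id", "mesh_id"])["pubmed_id"].agg(frozenset)
    return [
        GeneMeshLink(
            gene_id=int(gene),
            mesh_id=str(mesh),
            source=config.source_label,
            document_ids=frozenset(int(d) for d in docs),
        )
        for (gene, mesh), docs in sorted(grouped.items())
    ]


def transfer_by_rbbh(
    major_links: Iterable[GeneMeshLink],
    rbbh_pairs: Iterable[tuple[int, int]],
) -> list[GeneMeshLink]:
    """Project major-organism links onto minor-organism genes.

    ``rbbh_pairs`` are (minor_gene, major_gene) orthology pairs. Every
    link of the major gene is copied to the minor gene with source
    ``RBBH`` and document ids preserved; when a minor gene has reciprocal
    hits in several major organisms the term sets are unioned and the
    document sets merged per (gene, term). Pairs whose major gene has no
    links contribute nothing. Output terms are always a subset of the
    input terms.
    """
    by_major: dict[int, list[GeneMeshLink]] = {}
    for link in major_links:
        by_major.setdefault(link.gene_id, []).append(link)

    merged: dict[tuple[int, str], set[int]] = {}
    for minor, major in rbbh_pairs:
        for link in by_major.get(int(major), []):
            key = (int(minor), link.mesh_id)
            merged.setdefault(key, set()).update(link.document_ids)

    return [
        GeneMeshLink(
            gene_id=gene, mesh_id=mesh, source="RBBH", document_ids=frozenset(docs)
        )
        for (gene, mesh), docs in sorted(merged.items())
    ]


def build_custom_store(
    links_tsv: str | os.PathLike,
    vocabulary_tsv: str | os.PathLike,
    edges_tsv: str | os.PathLike,
    metadata: Mapping[str, str] | None = None,
    out_dir: str | os.PathLike | None = None,
) -> MeshStore:
    """Build a validated store from user-supplied TSV tables.

    Schema violations are reported with file and line number. When
    ``out_dir`` is given the store is also serialized there, in the same
    layout :func:`meshora.io.read_store` loads.
    """
    terms = mio.read_vocabulary(vocabulary_tsv)
    edges = mio.read_edges(edges_tsv)
    links = mio.read_links(links_tsv)
    term_ids = {t.mesh_id for t in terms}
    for idx, link in enumerate(links, start=2):
        if link.mesh_id not in term_ids:
            raise ValidationError(
                f"{links_tsv}:{idx}: link references unknown mesh_id {link.mesh_id!r}"
            )
    from .store import create_store

    store = create_store(terms, edges, links, metadata)
    if out_dir is not None:
        mio.write_store(store, out_dir)
    return store
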