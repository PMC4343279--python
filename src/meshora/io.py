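"""Readers and writers for the package's plain-text formats.

All tables are tab-separated with a header row; multi-valued fields
(qualifiers, synonyms, PubMed ids) are ``|``-separated within a cell.
A store on disk is a directory of three TSV tables plus a ``key=value``
manifest carrying the metadata.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import StoreFormatError, ValidationError
from .store import GeneMeshLink, HierarchyEdge, MeshStore, MeshTerm, create_store

VOCAB_COLUMNS = ["mesh_id", "term", "category", "qualifiers", "synonyms"]
EDGE_COLUMNS = ["parent_id", "child_id"]
LINK_COLUMNS = ["gene_id", "mesh_id", "source", "pubmed_ids"]


def _split_multi(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(part for part in cell.split("|") if part)


def _join_multi(values: Iterable) -> str:
    return "|".join(str(v) for v in sorted(values))


def _read_table(path: str | os.PathLike, expected: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise StoreFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if list(df.columns) != expected:
        raise StoreFormatError(
            f"{path}:1: expected header {expected}, got {list(df.columns)}"
        )
    return df


# --- vocabulary / edges / links -----------------------------------------


def read_vocabulary(path: str | os.PathLike) -> list[MeshTerm]:
    df = _read_table(path, VOCAB_COLUMNS)
    terms = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            terms.append(
                MeshTerm(
                    mesh_id=row.mesh_id,
                    term=row.term,
                    category=row.category,
                    qualifiers=_split_multi(row.qualifiers),
                    synonyms=_split_multi(row.synonyms),
                )
            )
        except ValidationError as exc:
            raise StoreFormatError(f"{path}:{idx}: {exc}") from exc
    return terms


def write_vocabulary(terms: Iterable[MeshTerm], path: str | os.PathLike) -> None:
    rows = [
        {
            "mesh_id": t.mesh_id,
            "term": t.term,
            "category": t.category.code,
            "qualifiers": _join_multi(t.qualifiers),
            "synonyms": _join_multi(t.synonyms),
        }
        for t in sorted(terms, key=lambda t: t.mesh_id)
    ]
    pd.DataFrame(rows, columns=VOCAB_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edges(path: str | os.PathLike) -> list[HierarchyEdge]:
    df = _read_table(path, EDGE_COLUMNS)
    edges = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            edges.append(HierarchyEdge(parent=row.parent_id, child=row.child_id))
        except ValidationError as exc:
            raise StoreFormatError(f"{path}:{idx}: {exc}") from exc
    return edges


def write_edges(
    edges: Iterable[HierarchyEdge | tuple[str, str]], path: str | os.PathLike
) -> None:
    pairs = sorted(
        (e.parent, e.child) if isinstance(e, HierarchyEdge) else tuple(e)
        for e in edges
    )
    pd.DataFrame(pairs, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_links(path: str | os.PathLike) -> list[GeneMeshLink]:
    df = _read_table(path, LINK_COLUMNS)
    links = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            links.append(
                GeneMeshLink(
                    gene_id=int(row.gene_id),
                    mesh_id=row.mesh_id,
                    source=row.source,
                    document_ids=frozenset(int(d) for d in _split_multi(row.pubmed_ids)),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise StoreFormatError(f"{path}:{idx}: {exc}") from exc
    return links


def write_links(links: Iterable[GeneMeshLink], path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_id": l.gene_id,
            "mesh_id": l.mesh_id,
            "source": l.source,
            "pubmed_ids": _join_multi(l.document_ids),
        }
        for l in sorted(links, key=lambda l: (l.gene_id, l.mesh_id, l.source))
    ]
    pd.DataFrame(rows, columns=LINK_COLUMNS).to_csv(path, sep="\t", index=False)


# --- store directory -----------------------------------------------------


def write_store(store: MeshStore, directory: str | os.PathLike) -> None:
    """Serialize a store as vocabulary/edges/links TSVs plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_vocabulary(store.terms.values(), directory / "vocabulary.tsv")
    write_edges(store.pcr_edges, directory / "edges.tsv")
    write_links(store.links, directory / "links.tsv")
    with open(directory / "manifest.txt", "w") as fh:
        for key in sorted(store.metadata):
            fh.write(f"{key}={store.metadata[key]}\n")


def read_store(directory: str | os.PathLike) -> MeshStore:
    """Load a store written by :func:`write_store`; AOR is recomputed."""
    directory = Path(directory)
    terms = read_vocabulary(directory / "vocabulary.tsv")
    edges = read_edges(directory / "edges.tsv")
    links = read_links(directory / "links.tsv")
    metadata: dict[str, str] = {}
    manifest = directory / "manifest.txt"
    if manifest.exists():
        for line in manifest.read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                metadata[key] = value
    return create_store(terms, edges, links, metadata)


# --- gene lists, p-values, FASTA, pairs ----------------------------------


def read_gene_list(path: str | os.PathLike) -> list[int]:
    """Plain-text gene list, one positive integer id per line."""
    genes = []
    for idx, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            gid = int(line)
        except ValueError as exc:
            raise StoreFormatError(f"{path}:{idx}: not an integer gene id: {line!r}") from exc
        if gid <= 0:
            raise StoreFormatError(f"{path}:{idx}: gene id must be positive: {gid}")
        genes.append(gid)
    return genes


def write_gene_list(genes: Iterable[int], path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_pvalues(path: str | os.PathLike) -> pd.DataFrame:
    """p-value table with columns (id, p)."""
    df = _read_table(path, ["id", "p"])
    df["p"] = df["p"].astype(float)
    return df


def write_pvalues(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """FASTA records as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_pairs(pairs, path: str | os.PathLike) -> None:
    """Reciprocal-best-hit pairs TSV: id_a, id_b, score_ab, score_ba."""
    rows = [
        {
            "id_a": p.id_a,
            "id_b": p.id_b,
            "score_ab": p.score_ab,
            "score_ba": p.score_ba,
        }
        for p in sorted(pairs, key=lambda p: (str(p.id_a), str(p.id_b)))
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "score_ab", "score_ba"]).to_csv(
        path, sep="\t", index=False
    )
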