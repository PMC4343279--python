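"""Local organization of literature tied to enriched (gene, term) pairs.

Once an enrichment run flags terms as significant, the PubMed documents
behind each contributing gene-term link can be fetched and filed on
disk, keyed by gene, term or document id. Retrieval itself is an
injected callable — the core never opens a network connection — so the
same machinery works with a cached corpus, a stub in tests, or a real
fetcher supplied by the caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from ._errors import ValidationError
from .ora import OraResultRow
from .store import MeshStore

ORGANIZE_KEYS = ("GENEID", "MESHID", "PUBMEDID")

#: A fetcher maps a PubMed id to (payload text, file extension).
Fetcher = Callable[[int], tuple[str, str]]


@dataclass(frozen=True)
class DocRecord:
    """One (document, gene, term) triple backing a significant result."""

    pubmed_id: int
    gene_id: int
    mesh_id: str
    payload_path: str = ""

    def __post_init__(self) -> None:
        if self.pubmed_id <= 0:
            raise ValidationError(f"pubmed_id must be positive, got {self.pubmed_id}")


def collect_doc_records(
    ora_rows: Iterable[OraResultRow], store: MeshStore
) -> list[DocRecord]:
    """Document records for every significant row: one per (gene in the
    row's overlap) x (document supporting that gene-term link),
    deduplicated across sources."""
    docs_by_pair: dict[tuple[int, str], set[int]] = {}
    for link in store.links:
        docs_by_pair.setdefault((link.gene_id, link.mesh_id), set()).update(
            link.document_ids
        )
    seen: set[tuple[int, int, str]] = set()
    records = []
    for row in ora_rows:
        if not row.significant:
            continue
        for gene in row.gene_ids:
            for doc in sorted(docs_by_pair.get((gene, row.mesh_id), ())):
                key = (doc, gene, row.mesh_id)
                if key not in seen:
                    seen.add(key)
                    records.append(
                        DocRecord(pubmed_id=doc, gene_id=gene, mesh_id=row.mesh_id)
                    )
    records.sort(key=lambda r: (r.pubmed_id, r.gene_id, r.mesh_id))
    return records


MANIFEST_COLUMNS = ["pubmed_id", "gene_id", "mesh_id", "path", "status"]


def organize(
    records: Sequence[DocRecord],
    root: str | os.PathLike,
    by: str,
    fetcher: Fetcher,
) -> pd.DataFrame:
    """Fetch and file documents under ``root/<key>/<pubmed_id>.<ext>``.

    ``by`` chooses the directory key (GENEID, MESHID or PUBMEDID). A
    fetcher failure for one id is recorded as ``missing`` in the
    manifest and the run continues. Re-running over the same records is
    idempotent. The manifest is returned and also written to
    ``root/manifest.tsv``.
    """
    if by not in ORGANIZE_KEYS:
        raise ValidationError(f"by must be one of {ORGANIZE_KEYS}, got {by!r}")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        key = {"GENEID": rec.gene_id, "MESHID": rec.mesh_id, "PUBMEDID": rec.pubmed_id}[by]
        try:
            payload, ext = fetcher(rec.pubmed_id)
        except Exception:
            rows.append(
                {
                    "pubmed_id": rec.pubmed_id,
                    "gene_id": rec.gene_id,
                    "mesh_id": rec.mesh_id,
                    "path": "",
                    "status": "missing",
                }
            )
            continue
        target_dir = root / str(key)
        target_dir.mkdir(parents=True, exist_ok=True)
        target = target_dir / f"{rec.pubmed_id}.{ext.lstrip('.')}"
        target.write_text(payload)
        rows.append(
            {
                "pubmed_id": rec.pubmed_id,
                "gene_id": rec.gene_id,
                "mesh_id": rec.mesh_id,
                "path": str(target.relative_to(root)),
                "status": "ok",
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = manifest.sort_values(MANIFEST_COLUMNS[:3], kind="mergesort").reset_index(
        drop=True
    )
    manifest.to_csv(root / "manifest.tsv", sep="\t", index=False)
    return manifest
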