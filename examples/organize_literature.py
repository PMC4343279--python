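"""File the literature behind significant enrichment results.

Runs a small enrichment, collects one document record per (gene,
supporting PubMed id) of each significant term, and organizes payloads
on disk keyed by MeSH id. Retrieval is an injected callable — here an
offline stub; swap in a real fetcher to download abstracts.
"""

import tempfile
from pathlib import Path

import meshora as m
from meshora.synthetic import term_id

spec = m.FixtureSpec(n_genes=600, n_terms=50, categories=("D",), density=0.08,
                     planted_term=term_id(7), planted_effect=10.0, seed=42)
terms, edges = m.make_vocabulary(spec)
links = m.make_annotations(spec, terms)
store = m.create_store(terms, edges, links)
study = m.make_study(spec, links)
rows = m.mesh_hyper_g_test(store, study.universe, study.selected,
                           m.OraParams(category="D", correction="QV"))

records = m.collect_doc_records(rows, store)
print(f"{sum(r.significant for r in rows)} significant terms -> "
      f"{len(records)} document records")

with tempfile.TemporaryDirectory() as root:
    manifest = m.organize(
        records, root, by="MESHID",
        fetcher=lambda pmid: (f"[stub abstract for PubMed {pmid}]\n", "txt"),
    )
    n_ok = (manifest["status"] == "ok").sum()
    dirs = sorted(p.name for p in Path(root).iterdir() if p.is_dir())
    print(f"{n_ok} documents filed under {len(dirs)} term directories: {dirs}")
# Each significant term gets a directory holding one text payload per
# supporting PubMed record; the manifest TSV lists every path written.
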