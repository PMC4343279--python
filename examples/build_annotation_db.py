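"""Build a gene-to-MeSH annotation store from literature links and
project it onto a second organism through ortholog pairs.

Mimics the two construction routes: joining a gene-to-PubMed table with
a PubMed-to-MeSH table (dropping over-large papers), then copying the
resulting links onto another organism's genes via reciprocal best hits.
"""

import meshora as m

# literature route: gene2pubmed-style records join pubmed->term records
g2p = [(1, 11), (1, 12), (2, 12), (3, 13)]
p2m = [(11, "D000001"), (12, "D000002"), (13, "D000001")]
links = m.join_gene_pubmed_mesh(g2p, p2m, m.BuildConfig(source_label="gene2pubmed"))
print(f"{len(links)} literature links:")
for l in links:
    print(f"  gene {l.gene_id} -> {l.mesh_id}  docs={sorted(l.document_ids)}")

# projection route: minor-organism genes 501/502 are orthologs of 1/3
projected = m.transfer_by_rbbh(links, [(501, 1), (502, 3)])
print(f"{len(projected)} projected links (source=RBBH):")
for l in projected:
    print(f"  gene {l.gene_id} -> {l.mesh_id}  docs={sorted(l.document_ids)}")

# assemble a store and query it through the SELECT contract
terms = [
    m.MeshTerm("D000001", "Heading One", "D"),
    m.MeshTerm("D000002", "Heading Two", "D", qualifiers={"metabolism"}),
]
store = m.create_store(terms, [("D000001", "D000002")], links + projected,
                       {"organism": "demo"})
res = store.select([501], ["MESHID", "MESHTERM", "SOURCEID"], "GENEID")
print(f"SELECT for projected gene 501: {res.rows}")
print(f"ancestors of D000002: {store.ancestors('D000002')}")
# Gene 501 inherits gene 1's annotations tagged RBBH; the hierarchy
# query walks the derived ancestor closure.
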