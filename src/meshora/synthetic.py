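"""Synthetic fixtures: vocabulary, annotations, study designs, p-value
mixtures and proteome pairs.

Every generator is a pure function of its parameters and seed, so any
module in the package can be exercised without downloading vocabulary,
literature or sequence data. The generated objects use the exact
formats the other modules consume.

What is emulated and what is not: the vocabulary is a random DAG over
the 16 real category codes, not real MeSH headings; annotations are
independent Bernoulli links with no literature co-occurrence structure;
study gene lists are drawn with a planted enrichment odds multiplier on
one chosen term, giving ground truth for recovery tests; p-value
mixtures follow the standard two-groups model (Uniform nulls,
Beta(shape, 1) alternatives); proteomes are point-mutated copies of
random ancestor sequences, giving ground-truth orthology with none of
the domain structure of real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import ValidationError
from .categories import CATEGORY_LABELS
from .store import GeneMeshLink, HierarchyEdge, MeshTerm

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic annotation fixture.

    ``density`` is the independent probability of each (gene, term)
    link; ``planted_effect`` multiplies the selection odds of genes
    annotated to ``planted_term`` when a study is drawn (1 = null).
    """

    n_genes: int = 2000
    n_terms: int = 200
    categories: tuple[str, ...] = tuple(sorted(CATEGORY_LABELS))
    density: float = 0.05
    planted_term: str | None = None
    planted_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_terms < 1:
            raise ValidationError("n_genes and n_terms must be positive")
        if not 0 < self.density < 1:
            raise ValidationError(f"density must lie in (0, 1), got {self.density}")
        if self.planted_effect < 1:
            raise ValidationError(f"planted_effect must be >= 1, got {self.planted_effect}")
        bad = [c for c in self.categories if c not in CATEGORY_LABELS]
        if bad:
            raise ValidationError(f"invalid category code(s) {bad}")
        object.__setattr__(self, "categories", tuple(self.categories))


def term_id(i: int) -> str:
    """Synthetic MeSH-style identifier for term index i."""
    return f"D{i:06d}"


def make_vocabulary(spec: FixtureSpec) -> tuple[list[MeshTerm], list[HierarchyEdge]]:
    """A random vocabulary DAG.

    Terms are created in index order; each non-root term receives one
    parent among earlier terms, and ~10% receive a second parent, so the
    hierarchy is a genuine multi-parent DAG, not a tree. Categories are
    drawn uniformly from ``spec.categories``.
    """
    rng = np.random.default_rng(spec.seed)
    terms = []
    for i in range(spec.n_terms):
        code = spec.categories[int(rng.integers(len(spec.categories)))]
        terms.append(
            MeshTerm(
                mesh_id=term_id(i),
                term=f"Synthetic Heading {i}",
                category=code,
                qualifiers=frozenset({"metabolism"} if i % 3 == 0 else set()),
                synonyms=frozenset({f"synonym-{i}"} if i % 4 == 0 else set()),
            )
        )
    edges = []
    for i in range(1, spec.n_terms):
        parent = int(rng.integers(i))
        edges.append(HierarchyEdge(parent=term_id(parent), child=term_id(i)))
        if i >= 2 and rng.random() < 0.10:
            second = int(rng.integers(i))
            if second != parent:
                edges.append(HierarchyEdge(parent=term_id(second), child=term_id(i)))
    return terms, edges


def make_annotations(
    spec: FixtureSpec, vocabulary: Sequence[MeshTerm]
) -> list[GeneMeshLink]:
    """Independent Bernoulli(density) gene-term links with small random
    PubMed document sets. Genes are numbered 1..n_genes."""
    rng = np.random.default_rng(spec.seed + 1)
    mask = rng.random((spec.n_genes, len(vocabulary))) < spec.density
    links = []
    gene_idx, term_idx = np.nonzero(mask)
    n_docs = rng.integers(1, 4, size=gene_idx.size)
    for (gi, ti, nd) in zip(gene_idx, term_idx, n_docs):
        docs = frozenset(int(d) for d in rng.integers(10_000, 99_999, size=int(nd)))
        links.append(
            GeneMeshLink(
                gene_id=int(gi) + 1,
                mesh_id=vocabulary[int(ti)].mesh_id,
                source="gene2pubmed",
                document_ids=docs,
            )
        )
    return links


@dataclass(frozen=True)
class StudyDesign:
    """A synthetic gene study with ground truth retained."""

    universe: tuple[int, ...]
    selected: tuple[int, ...]
    planted_term: str | None
    planted_genes: frozenset[int] = frozenset()


def make_study(
    spec: FixtureSpec,
    annotations: Sequence[GeneMeshLink],
    base_rate: float = 0.1,
) -> StudyDesign:
    """Draw an interesting-gene list over the universe 1..n_genes.

    Each gene is selected independently with probability ``base_rate``,
    except that genes annotated to ``spec.planted_term`` have their
    selection odds multiplied by ``spec.planted_effect``. With effect 1
    selection is independent of annotation (the null study).
    """
    rng = np.random.default_rng(spec.seed + 2)
    universe = tuple(range(1, spec.n_genes + 1))
    planted_genes: frozenset[int] = frozenset()
    if spec.planted_term is not None:
        planted_genes = frozenset(
            l.gene_id for l in annotations if l.mesh_id == spec.planted_term
        )
        if not planted_genes and not any(
            l.mesh_id == spec.planted_term for l in annotations
        ):
            term_ids = {l.mesh_id for l in annotations}
            if spec.planted_term not in term_ids:
                raise ValidationError(
                    f"planted term {spec.planted_term!r} absent from annotations"
                )
    base_odds = base_rate / (1.0 - base_rate)
    boosted = (base_odds * spec.planted_effect) / (1.0 + base_odds * spec.planted_effect)
    probs = np.full(spec.n_genes, base_rate)
    if planted_genes:
        idx = np.array(sorted(planted_genes)) - 1
        probs[idx] = boosted
    selected_mask = rng.random(spec.n_genes) < probs
    selected = tuple(int(g) for g in np.nonzero(selected_mask)[0] + 1)
    return StudyDesign(
        universe=universe,
        selected=selected,
        planted_term=spec.planted_term,
        planted_genes=planted_genes,
    )


@dataclass(frozen=True)
class PvalueMixture:
    """p-values from the two-groups model with their ground-truth labels
    (True = null)."""

    pvalues: np.ndarray
    is_null: np.ndarray
    pi0: float


def make_pvalue_mixture(
    m: int, pi0: float, alt_shape: float = 0.1, seed: int = 0
) -> PvalueMixture:
    """Nulls are Uniform(0,1), alternatives Beta(alt_shape, 1); each
    hypothesis is null independently with probability pi0."""
    if not 0 <= pi0 <= 1:
        raise ValidationError(f"pi0 must lie in [0, 1], got {pi0}")
    if m < 1:
        raise ValidationError("m must be positive")
    rng = np.random.default_rng(seed)
    is_null = rng.random(m) < pi0
    p = np.where(
        is_null,
        rng.uniform(size=m),
        rng.beta(alt_shape, 1.0, size=m),
    )
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # keep within (0, 1]
    return PvalueMixture(pvalues=p, is_null=is_null, pi0=pi0)


@dataclass(frozen=True)
class ProteomePair:
    """Two synthetic proteomes with the true ortholog pairing."""

    set_a: tuple[tuple[str, str], ...]
    set_b: tuple[tuple[str, str], ...]
    true_pairs: tuple[tuple[str, str], ...]


def make_proteomes(
    n_pairs: int,
    n_decoys: int,
    seed: int = 0,
    length: int = 120,
    mutation_rate: float = 0.05,
) -> ProteomePair:
    """Ortholog pairs by independent point mutation of shared ancestors.

    For each of ``n_pairs`` ancestors (random length-``length`` amino
    acid sequences), both sides receive an independently mutated copy
    (per-site substitution probability ``mutation_rate``); ``n_decoys``
    unrelated random sequences are added to each side. Records are
    (id, sequence) pairs ready for FASTA serialization; the true pairing
    is returned for recovery scoring.
    """
    rng = np.random.default_rng(seed)

    def random_seq(n: int) -> str:
        return "".join(_AA[i] for i in rng.integers(len(_AA), size=n))

    def mutate(seq: str) -> str:
        out = []
        for ch in seq:
            if rng.random() < mutation_rate:
                out.append(_AA[int(rng.integers(len(_AA)))])
            else:
                out.append(ch)
        return "".join(out)

    set_a, set_b, truth = [], [], []
    for i in range(n_pairs):
        ancestor = random_seq(length)
        a_id, b_id = f"A{i:04d}", f"B{i:04d}"
        set_a.append((a_id, mutate(ancestor)))
        set_b.append((b_id, mutate(ancestor)))
        truth.append((a_id, b_id))
    for i in range(n_decoys):
        set_a.append((f"AD{i:04d}", random_seq(length)))
        set_b.append((f"BD{i:04d}", random_seq(length)))
    return ProteomePair(
        set_a=tuple(set_a), set_b=tuple(set_b), true_pairs=tuple(truth)
    )
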