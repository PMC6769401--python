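"""Over-representation analysis with bootstrap reranking and gene
prioritization.

Candidate gene lists (the genes encoding outlier proteins) are tested for
term over-representation with an exact upper-tail hypergeometric test over
the annotated universe.  Instead of an analytic multiple-testing
correction, terms are reranked by bootstrap resampling: B random gene sets
of the query's size are drawn from the universe and each term's bootstrap
score is the (add-one) fraction of resamples achieving a p-value at least
as extreme as the observed one.  Significant terms are clustered into
systemic processes by Jaccard similarity of their query overlaps, and query
genes are ranked as hubs by the number of processes they participate in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import networkx as nx

from .io_formats import ancestors
from .seeding import stream_rng


@dataclass
class AnnotationSet:
    """Term -> gene-set annotations with an optional is_a parent DAG.

    The universe is the union of all annotated genes (standard
    over-representation practice: unannotated genes are invisible to the
    test and must not deflate p-values).
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    dag: Optional[dict[str, frozenset[str]]] = None
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(genes for _, genes in self.terms.values())
            )
        if self.dag is not None:
            g = nx.DiGraph(
                (child, parent)
                for child, parents in self.dag.items()
                for parent in parents
            )
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError("annotation DAG contains a cycle")

    def gene_set(self, term: str) -> frozenset[str]:
        return self.terms[term][1]


def propagate_annotations(ann: AnnotationSet) -> AnnotationSet:
    """True-path closure: each term's gene set becomes the union over itself
    and all of its is_a descendants.  Identity when no DAG is present."""
    if ann.dag is None:
        return ann
    closed: dict[str, set[str]] = {
        t: set(genes) for t, (_, genes) in ann.terms.items()
    }
    for term in ann.terms:
        for anc in ancestors(ann.dag, term):
            if anc in closed:
                closed[anc] |= ann.terms[term][1]
    new_terms = {
        t: (ann.terms[t][0], frozenset(closed[t])) for t in ann.terms
    }
    return AnnotationSet(terms=new_terms, dag=ann.dag)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int          # overlap with the query
    K: int          # term size in the universe
    n: int          # query size
    N: int          # universe size
    p_hyper: float
    boot_score: float = math.nan
    significant: bool = False


@lru_cache(maxsize=1 << 20)
def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Evaluated with integer combinatorics (exact rational arithmetic,
    converted to float at the end), so it is accurate to the last bit.
    Results are memoised: repeated bootstrap runs over a fixed universe
    revisit the same (k, K, n, N) tuples constantly.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    denom = math.comb(N, n)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(num, denom))


def enrich_terms(
    query_genes: Sequence[str], ann: AnnotationSet
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every term in the query.

    Query genes outside the universe are dropped (they carry no
    annotation); the effective query size n is the post-intersection count.
    """
    query = frozenset(query_genes) & ann.universe
    n = len(query)
    N = len(ann.universe)
    if n == 0:
        raise ValueError("no query gene is in the annotated universe")
    results = []
    for term, (name, genes) in ann.terms.items():
        K = len(genes)
        k = len(genes & query)
        results.append(
            EnrichmentResult(
                term_id=term, name=name, k=k, K=K, n=n, N=N,
                p_hyper=hypergeometric_test(k, K, n, N),
            )
        )
    return results


def bootstrap_prioritize(
    results: Sequence[EnrichmentResult],
    ann: AnnotationSet,
    n_query: int,
    B: int = 1000,
    seed: int = 0,
    p_cut: float = 0.05,
    corrected_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Rerank terms by how rarely random queries reach their p-value.

    Draws B gene sets of size ``n_query`` uniformly without replacement
    from the universe; for each term,
    ``boot_score = (1 + #{b : p_b <= p_obs}) / (B + 1)`` (add-one estimator,
    so no score is ever 0).  A term is significant iff both
    ``p_hyper <= p_cut`` and ``boot_score <= corrected_cut``.  The returned
    list is sorted by boot_score ascending, ties by p_hyper ascending, then
    term id.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    universe = sorted(ann.universe)
    N = len(universe)
    if n_query > N:
        raise ValueError(f"query size {n_query} exceeds universe size {N}")
    gene_index = {g: i for i, g in enumerate(universe)}
    terms = list(results)
    T = len(terms)
    mask = np.zeros((T, N), dtype=bool)
    for t, res in enumerate(terms):
        for g in ann.gene_set(res.term_id):
            mask[t, gene_index[g]] = True
    # exact p-value lookup per term: p_table[t][k] for k = 0..K
    max_K = max((res.K for res in terms), default=0)
    p_table = np.ones((T, max_K + 1))
    for t, res in enumerate(terms):
        for k in range(res.K + 1):
            if k <= n_query:
                p_table[t, k] = hypergeometric_test(k, res.K, n_query, N)
            else:
                p_table[t, k] = p_table[t, n_query]
    rng = stream_rng(seed, "bootstrap")
    idx = np.empty((B, n_query), dtype=np.int64)
    for b in range(B):
        idx[b] = rng.choice(N, size=n_query, replace=False)
    counts = mask[:, idx].sum(axis=2)  # (T, B)
    p_boot = np.take_along_axis(
        p_table, counts, axis=1
    )  # p_table[t, counts[t, b]]
    p_obs = np.array([res.p_hyper for res in terms])
    exceed = (p_boot <= p_obs[:, np.newaxis]).sum(axis=1)
    boot = (1 + exceed) / (B + 1)
    out = [
        replace(
            res,
            boot_score=float(boot[t]),
            significant=bool(res.p_hyper <= p_cut and boot[t] <= corrected_cut),
        )
        for t, res in enumerate(terms)
    ]
    return sorted(out, key=lambda r: (r.boot_score, r.p_hyper, r.term_id))


@dataclass(frozen=True)
class SystemicProcess:
    """A cluster of significant terms treated as one biological module."""

    process_id: str           # lowest-p member term
    name: str
    member_terms: frozenset[str]
    genes: frozenset[str]     # union of member overlaps with the query
    p_hyper: float            # best member p


def cluster_terms_to_processes(
    significant: Sequence[EnrichmentResult],
    ann: AnnotationSet,
    query_genes: Sequence[str],
) -> list[SystemicProcess]:
    """Single-linkage clustering of significant terms at Jaccard >= 0.5 of
    their query-overlap gene sets; each component becomes one process
    labeled by its lowest-p member term."""
    query = frozenset(query_genes) & ann.universe
    terms = list(significant)
    overlaps = [ann.gene_set(r.term_id) & query for r in terms]
    g = nx.Graph()
    g.add_nodes_from(range(len(terms)))
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            union = overlaps[i] | overlaps[j]
            inter = overlaps[i] & overlaps[j]
            jac = len(inter) / len(union) if union else 0.0
            if jac >= 0.5:
                g.add_edge(i, j)
    processes = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda i: (terms[i].p_hyper, terms[i].term_id))
        rep = terms[members[0]]
        genes = frozenset().union(*(overlaps[i] for i in comp))
        processes.append(
            SystemicProcess(
                process_id=rep.term_id,
                name=rep.name,
                member_terms=frozenset(terms[i].term_id for i in comp),
                genes=genes,
                p_hyper=rep.p_hyper,
            )
        )
    return sorted(processes, key=lambda p: (p.p_hyper, p.process_id))


@dataclass(frozen=True)
class GenePriority:
    gene_symbol: str
    process_count: int
    rank: int


def prioritize_genes(
    processes: Sequence[SystemicProcess], query_genes: Sequence[str]
) -> list[GenePriority]:
    """Rank query genes as regulatory hubs by process participation.

    Order: process_count descending, then the sum of -log10(p) over the
    gene's processes descending, then alphabetical.  Genes participating in
    no process are omitted.
    """
    rows = []
    for gene in sorted(set(query_genes)):
        procs = [p for p in processes if gene in p.genes]
        if not procs:
            continue
        weight = sum(-math.log10(max(p.p_hyper, 1e-300)) for p in procs)
        rows.append((gene, len(procs), weight))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return [
        GenePriority(gene_symbol=g, process_count=c, rank=i + 1)
        for i, (g, c, _) in enumerate(rows)
    ]


def gene_process_matrix(
    processes: Sequence[SystemicProcess], priorities: Sequence[GenePriority]
):
    """Binary membership matrix: rows = processes, columns = genes in rank
    order.  Returns a pandas DataFrame."""
    import pandas as pd

    if not priorities:
        raise ValueError("no prioritized genes")
    genes = [p.gene_symbol for p in priorities]
    data = {
        proc.process_id: [1 if g in proc.genes else 0 for g in genes]
        for proc in processes
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=genes)


def plot_gene_process_heatmap(matrix, path) -> None:
    """Render the gene x process membership matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.5 * matrix.shape[0]))
    )
    ax.imshow(matrix.values, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.shape[1]), labels=matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), labels=matrix.index, fontsize=7)
    ax.set_xlabel("prioritized genes")
    ax.set_ylabel("systemic processes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
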