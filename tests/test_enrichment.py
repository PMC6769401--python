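"""Hypergeometric exactness, bootstrap reranking, processes, gene ranks."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from pepmimic.enrichment import (
    AnnotationSet,
    EnrichmentResult,
    bootstrap_prioritize,
    cluster_terms_to_processes,
    gene_process_matrix,
    hypergeometric_test,
    prioritize_genes,
    propagate_annotations,
    enrich_terms,
)


def _ann(term_sets, dag=None):
    return AnnotationSet(
        terms={t: (t.lower(), frozenset(g)) for t, g in term_sets.items()},
        dag=dag,
    )


class TestPropagation:
    def test_child_genes_flow_up(self):
        ann = _ann({"A": {"g1"}, "B": {"g2"}}, dag={"A": frozenset({"B"})})
        out = propagate_annotations(ann)
        assert out.gene_set("B") == {"g1", "g2"}
        assert out.gene_set("A") == {"g1"}

    def test_dagless_identity(self):
        ann = _ann({"A": {"g1"}})
        assert propagate_annotations(ann) is ann

    def test_matches_reachability_oracle(self, rng):
        # random small DAG over 8 terms (edges only from lower to higher index)
        terms = [f"T{i}" for i in range(8)]
        genes = {t: {f"g{rng.integers(0, 12)}"} for t in terms}
        dag = {}
        for i, t in enumerate(terms[:-1]):
            parents = [terms[j] for j in range(i + 1, 8) if rng.random() < 0.3]
            if parents:
                dag[t] = frozenset(parents)
        out = propagate_annotations(_ann(genes, dag=dag))
        # oracle: explicit transitive closure by repeated expansion
        reach = {t: {t} for t in terms}
        changed = True
        while changed:
            changed = False
            for t in terms:
                for p in dag.get(t, ()):
                    if not reach[t] <= reach[p]:
                        reach[p] |= reach[t]
                        changed = True
        for t in terms:
            expected = set().union(*(genes[d] for d in reach[t]))
            assert out.gene_set(t) == expected


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_test(0, 5, 4, 10) == 1.0

    def test_exact_small_case(self):
        assert hypergeometric_test(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_certain_event(self):
        assert hypergeometric_test(6, 6, 6, 6) == 1.0

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeometric_test(5, 4, 10, 8)

    def test_against_scipy_oracle(self):
        # exhaustive over a modest grid (full N <= 60 sweep in acceptance)
        for N in (5, 12, 25):
            for K, n in itertools.product(range(N + 1), repeat=2):
                for k in range(min(K, n) + 1):
                    ours = hypergeometric_test(k, K, n, N)
                    ref = float(hypergeom.sf(k - 1, N, K, n))
                    assert ours == pytest.approx(ref, abs=1e-12)


class TestBootstrap:
    def _setup(self, rng, n_terms=10, n_genes=60):
        genes = [f"g{i}" for i in range(n_genes)]
        sets = {
            f"T{t}": set(rng.choice(genes, size=8, replace=False))
            for t in range(n_terms)
        }
        return _ann(sets)

    def test_p_obs_one_gives_score_one(self, rng):
        ann = self._setup(rng)
        query = list(rng.choice(sorted(ann.universe), 10, replace=False))
        results = enrich_terms(query, ann)
        boosted = bootstrap_prioritize(results, ann, n_query=results[0].n, B=200, seed=4)
        for r in boosted:
            if r.p_hyper == 1.0:
                assert r.boot_score == 1.0
            assert 1 / 201 <= r.boot_score <= 1.0

    def test_deterministic_given_seed(self, rng):
        ann = self._setup(rng)
        query = list(rng.choice(sorted(ann.universe), 10, replace=False))
        results = enrich_terms(query, ann)
        a = bootstrap_prioritize(results, ann, n_query=results[0].n, B=150, seed=9)
        b = bootstrap_prioritize(results, ann, n_query=results[0].n, B=150, seed=9)
        assert [(r.term_id, r.boot_score) for r in a] == [
            (r.term_id, r.boot_score) for r in b
        ]

    def test_small_B_rejected(self, rng):
        ann = self._setup(rng)
        results = enrich_terms(sorted(ann.universe)[:5], ann)
        with pytest.raises(ValueError):
            bootstrap_prioritize(results, ann, n_query=5, B=50)

    def test_null_calibration_rough(self, rng):
        """Random queries should flag ~<= alpha of terms at boot <= alpha."""
        ann = self._setup(rng, n_terms=20, n_genes=120)
        universe = sorted(ann.universe)
        flagged = total = 0
        for rep in range(25):
            query = list(rng.choice(universe, 12, replace=False))
            results = enrich_terms(query, ann)
            boosted = bootstrap_prioritize(
                results, ann, n_query=results[0].n, B=400, seed=100 + rep
            )
            flagged += sum(1 for r in boosted if r.boot_score <= 0.05)
            total += len(boosted)
        # permutation p-values are valid: Monte-Carlo band around <= 0.05
        se = math.sqrt(0.05 * 0.95 / total)
        assert flagged / total <= 0.05 + 4 * se


class TestProcessesAndGenes:
    def _results(self, ann, query):
        return enrich_terms(query, ann)

    def test_identical_overlaps_merge(self):
        ann = _ann({"A": {"g1", "g2"}, "B": {"g1", "g2", "g9"}, "Z": {"g5"}})
        res = [r for r in self._results(ann, ["g1", "g2"]) if r.term_id in "AB"]
        procs = cluster_terms_to_processes(res, ann, ["g1", "g2"])
        assert len(procs) == 1
        assert procs[0].member_terms == {"A", "B"}

    def test_disjoint_overlaps_split(self):
        ann = _ann({"A": {"g1"}, "B": {"g2"}, "Z": {"g9"}})
        res = [r for r in self._results(ann, ["g1", "g2"]) if r.term_id in "AB"]
        procs = cluster_terms_to_processes(res, ann, ["g1", "g2"])
        assert len(procs) == 2

    def test_matches_jaccard_graph_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        sets = {f"T{t}": set(rng.choice(genes, size=5, replace=False)) for t in range(8)}
        ann = _ann(sets)
        query = list(rng.choice(genes, 10, replace=False))
        res = self._results(ann, query)
        procs = cluster_terms_to_processes(res, ann, query)
        # oracle: explicit union-find on the pairwise-Jaccard graph
        qset = set(query) & ann.universe
        ov = {r.term_id: ann.gene_set(r.term_id) & qset for r in res}
        parent = {t: t for t in ov}

        def find(t):
            while parent[t] != t:
                t = parent[t]
            return t

        for a, b in itertools.combinations(ov, 2):
            u = ov[a] | ov[b]
            if u and len(ov[a] & ov[b]) / len(u) >= 0.5:
                parent[find(a)] = find(b)
        oracle_comps = {}
        for t in ov:
            oracle_comps.setdefault(find(t), set()).add(t)
        assert {frozenset(c) for c in oracle_comps.values()} == {
            p.member_terms for p in procs
        }

    def test_gene_ranking_rules(self):
        from pepmimic.enrichment import SystemicProcess

        procs = [
            SystemicProcess("P1", "p1", frozenset({"P1"}), frozenset({"gA", "gB"}), 1e-4),
            SystemicProcess("P2", "p2", frozenset({"P2"}), frozenset({"gA"}), 1e-3),
            SystemicProcess("P3", "p3", frozenset({"P3"}), frozenset({"gA", "gC"}), 1e-2),
        ]
        pri = prioritize_genes(procs, ["gA", "gB", "gC", "gD"])
        assert [p.gene_symbol for p in pri] == ["gA", "gB", "gC"]  # gD omitted
        assert pri[0].process_count == 3 and pri[0].rank == 1
        # gB (p 1e-4 process) outranks gC (1e-2) on the -log10 p tiebreak
        assert pri[1].gene_symbol == "gB"

    def test_single_process_alphabetical(self):
        from pepmimic.enrichment import SystemicProcess

        procs = [SystemicProcess("P", "p", frozenset({"P"}), frozenset({"gB", "gA"}), 0.01)]
        pri = prioritize_genes(procs, ["gB", "gA"])
        assert [p.gene_symbol for p in pri] == ["gA", "gB"]

    def test_matrix_consistency(self, rng):
        from pepmimic.enrichment import SystemicProcess

        genes = [f"g{i}" for i in range(6)]
        procs = [
            SystemicProcess(
                f"P{j}", f"p{j}", frozenset({f"P{j}"}),
                frozenset(rng.choice(genes, size=3, replace=False)), 0.01,
            )
            for j in range(4)
        ]
        pri = prioritize_genes(procs, genes)
        mat = gene_process_matrix(procs, pri)
        for p in pri:
            assert mat[p.gene_symbol].sum() == p.process_count
        for proc in procs:
            assert mat.loc[proc.process_id].sum() == len(
                proc.genes & {p.gene_symbol for p in pri}
            )

    def test_single_cell_matrix(self):
        from pepmimic.enrichment import SystemicProcess

        procs = [SystemicProcess("P", "p", frozenset({"P"}), frozenset({"g"}), 0.01)]
        pri = prioritize_genes(procs, ["g"])
        mat = gene_process_matrix(procs, pri)
        assert mat.shape == (1, 1) and mat.iloc[0, 0] == 1
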