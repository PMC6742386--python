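"""Hypergeometric GO-term enrichment of target gene sets.

For each GO term present in the study set, the upper-tail probability
P(X >= k) with X ~ Hypergeometric(N, K, n) is computed, where N is the
annotated population, K the term's population genes, n the study size and
k the term's study genes. Raw p < alpha defines significance (no
multiple-testing correction by default, Benjamini-Hochberg behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io import ValidationError


@dataclass
class GOResult:
    term: str
    category: str      # BP | MF | CC
    k: int             # study genes with the term
    n: int             # study size (annotated)
    K: int             # population genes with the term
    N: int             # population size
    p_value: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted q-values, order preserved."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def go_enrich(
    study_genes: set[str],
    annotation: dict[str, set[str]],
    categories: dict[str, str] | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[GOResult]:
    """Enrichment of every term present in the study set.

    The population is every gene with at least one annotation; study genes
    without annotation are dropped. Results sorted by (p, term).
    """
    categories = categories or {}
    population = set(annotation)
    study = study_genes & population
    N = len(population)
    n = len(study)

    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene, terms in annotation.items():
        for term in terms:
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    results = [
        GOResult(
            term=term,
            category=categories.get(term, "BP"),
            k=k,
            n=n,
            K=term_pop[term],
            N=N,
            p_value=hypergeom_upper_tail(k, term_pop[term], n, N),
            significant=False,
        )
        for term, k in term_study.items()
    ]
    pvals = [r.p_value for r in results]
    effective = benjamini_hochberg(pvals) if bh_correct else pvals
    for r, p in zip(results, effective):
        r.significant = p < alpha
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def category_summary(results: list[GOResult]) -> dict[str, int]:
    """Significant-term counts per GO category (bar-plot ready)."""
    out: dict[str, int] = {"BP": 0, "MF": 0, "CC": 0}
    for r in results:
        if r.significant:
            out[r.category] = out.get(r.category, 0) + 1
    return out
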