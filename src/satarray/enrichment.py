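"""Hypergeometric over-representation of functional categories.

Given a study gene set (e.g. the differentially expressed genes) drawn from
a population (the genes on the array), each functional category is scored
with the upper-tail hypergeometric probability of observing at least the
study's count of category members, and a Bonferroni-corrected e-score
(p times the number of categories tested, capped at 1).  Categories with
no study member are not reported.  Genes may belong to several categories;
uncategorized genes still count in the population total.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size, K: category members in the population, n: study-set
    size, k: category members in the study set.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise EnrichmentError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes the tail in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_categories(
    study: Iterable[str],
    population: Iterable[str],
    categories: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Rank categories by over-representation in the study set.

    ``categories`` maps gene -> categories (or a DataFrame with ``gene`` and
    ``category`` columns).  Returns one row per category with at least one
    study member, sorted ascending by e-score then category label, with
    columns N, K, n, k, p_hyper and e_score.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        missing = sorted(study - population)[:5]
        raise EnrichmentError(f"study genes absent from population: {missing}")

    if isinstance(categories, pd.DataFrame):
        pairs = categories[["gene", "category"]].itertuples(index=False)
        gene_cats: dict[str, set[str]] = {}
        for g, c in pairs:
            gene_cats.setdefault(g, set()).add(c)
    else:
        gene_cats = {g: set(cs) for g, cs in categories.items()}

    N = len(population)
    n = len(study)
    cat_pop: dict[str, int] = {}
    cat_study: dict[str, int] = {}
    for g in population:
        for c in gene_cats.get(g, ()):
            cat_pop[c] = cat_pop.get(c, 0) + 1
            if g in study:
                cat_study[c] = cat_study.get(c, 0) + 1

    tested = sorted(c for c, k in cat_study.items() if k >= 1)
    m = len(tested)
    rows = []
    for c in tested:
        K = cat_pop[c]
        k = cat_study[c]
        p = hypergeom_tail(N, K, n, k)
        rows.append({"category": c, "N": N, "K": K, "n": n, "k": k,
                     "p_hyper": p, "e_score": min(1.0, p * m)})
    out = pd.DataFrame(rows, columns=["category", "N", "K", "n", "k", "p_hyper", "e_score"])
    return out.sort_values(["e_score", "category"], kind="mergesort").reset_index(drop=True)
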