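"""Hypergeometric enrichment and depletion of probe subsets across
CpG-density classes.

Conventions match R's ``phyper``: for an observed overlap of k probes, the
enrichment p-value is the exclusive upper tail P(X > k) (``phyper(k, ...,
lower.tail = FALSE)``) and the depletion p-value the inclusive lower tail
P(X <= k). The two are exact complements, P(X > k) + P(X <= k) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .datamodel import CPG_CLASSES


@dataclass
class EnrichmentResult:
    """One hypergeometric test of a probe subset against one category.

    population_n (N): analyzed probe universe; category_k (K): probes in the
    category; sample_n (n): tested subset size; overlap (k): subset probes in
    the category. ``direction`` is chosen by comparing k with its expectation
    n*K/N.
    """

    category: str
    population_n: int
    category_k: int
    sample_n: int
    overlap: int
    direction: str
    p: float
    expected: float
    degenerate: bool = False


def hypergeom_tail(k: int, K: int, N: int, n: int, direction: str) -> float:
    """One-tailed hypergeometric probability for an overlap of k.

    ``enrichment``: P(X > k); ``depletion``: P(X <= k), where
    X ~ Hypergeometric(N, K, n). Evaluated through scipy's log-space
    survival/distribution functions.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if direction == "enrichment":
        return float(hypergeom.sf(k, N, K, n))
    if direction == "depletion":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError(f"direction must be 'enrichment' or 'depletion', got {direction!r}")


def enrichment_scan(
    subset,
    annotation: pd.DataFrame,
    categories=("LC", "IC", "HC"),
) -> list[EnrichmentResult]:
    """Test a probe subset for enrichment/depletion in each CpG-density class.

    Uncategorized probes are never a tested category but do count in the
    population N. Direction is auto-selected per category: an overlap above
    its expectation is tested for enrichment, below for depletion; exactly at
    expectation the enrichment tail is reported with a degenerate flag.
    """
    subset = pd.Index(subset)
    if len(subset) == 0:
        raise ValueError("empty probe subset")
    stray = subset.difference(annotation.index)
    if len(stray):
        raise ValueError(f"subset contains probes outside the analyzed universe: {list(stray[:3])}")
    for cat in categories:
        if cat not in CPG_CLASSES or cat == "uncategorized":
            raise ValueError(f"invalid test category {cat!r}")
    N = len(annotation)
    n = len(subset)
    classes = annotation["cpg_class"]
    sub_classes = classes.loc[subset]
    results = []
    for cat in categories:
        K = int((classes == cat).sum())
        k = int((sub_classes == cat).sum())
        expected = n * K / N
        if k > expected:
            direction, degenerate = "enrichment", False
        elif k < expected:
            direction, degenerate = "depletion", False
        else:
            direction, degenerate = "enrichment", True
        p = hypergeom_tail(k, K, N, n, direction)
        results.append(
            EnrichmentResult(cat, N, K, n, k, direction, p, expected, degenerate)
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "population_n": r.population_n,
                "category_k": r.category_k,
                "sample_n": r.sample_n,
                "overlap": r.overlap,
                "expected": r.expected,
                "direction": r.direction,
                "p": r.p,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
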