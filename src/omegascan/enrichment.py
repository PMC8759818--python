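"""Category overrepresentation among outlier genes.

A fixed-cutoff hypergeometric test: given N genes in the tested universe
(all genes surviving the saturation filter in that scope), K of them in a
category, n outliers, and k outliers in the category, the upper-tail
p-value is P(X >= k) for X ~ Hypergeometric(N, K, n), with
Benjamini–Hochberg adjustment across categories within the scope. The fold
enrichment is (k/n)/(K/N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import OmegascanError


@dataclass
class EnrichmentResult:
    category: str
    scope: str
    k: int  # outlier genes in category
    K: int  # genes in category (within universe)
    n: int  # outlier genes total
    N: int  # genes in universe
    enrichment: float
    p: float
    q: float = float("nan")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_test(
    outliers: set[str],
    universe: set[str],
    categories: Mapping[str, set[str]],
    scope: str,
    underrepresentation: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each category among outliers.

    Every category set is intersected with the universe before testing;
    categories empty after intersection are omitted. Results are BH-
    adjusted across categories within the scope and sorted by q then
    category. With ``underrepresentation`` the lower tail P(X <= k) is
    tested instead.
    """
    if not universe:
        raise OmegascanError("enrichment_test: empty universe")
    if not outliers <= universe:
        raise OmegascanError("enrichment_test: outliers must be a subset of the universe")
    N = len(universe)
    n = len(outliers)
    results: list[EnrichmentResult] = []
    for category in sorted(categories):
        members = categories[category] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & outliers)
        if underrepresentation:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        else:
            p = hypergeom_upper_tail(k, N, K, n)
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        results.append(EnrichmentResult(category, scope, k, K, n, N, fold, p))
    if results:
        _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q = float(qv)
    results.sort(key=lambda r: (r.q, r.category))
    return results


def enrichment_to_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "category": r.category,
            "scope": r.scope,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "enrichment": r.enrichment,
            "p": r.p,
            "q": r.q,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["category", "scope", "k", "K", "n", "N", "enrichment", "p", "q"]
    )
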