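"""Hypergeometric enriched-term analysis of predicted target genes.

For a pathway with K genes in a universe of N, and n_sel selected genes of
which k fall in the pathway, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n_sel), unadjusted for multiple
comparisons by default (Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io import PathwayDB


@dataclass
class PathwayResult:
    pathway_id: str
    description: str
    k: int          # selected genes in the pathway
    K: int          # pathway genes in the universe
    n_sel: int      # selected genes in the universe
    N: int          # universe size
    p: float
    p_adj: float | None = None

    @property
    def fraction(self) -> str:
        return f"{self.k}/{self.K}"


def hypergeom_upper(k: int, K: int, n_sel: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= K <= N and 0 <= k <= n_sel <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} K={K} n_sel={n_sel} N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
    return min(max(p, 0.0), 1.0)


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def enrich_pathways(
    selected: set[str],
    pathways: PathwayDB,
    universe: set[str] | None = None,
    min_size: int = 3,
    adjust: bool = False,
) -> list[PathwayResult]:
    """Test each pathway for over-representation of the selected genes.

    ``universe`` defaults to the union of all pathway genes and the selected
    set; pathways are intersected with the universe and those with fewer than
    ``min_size`` universe genes are skipped.  Results are sorted by p-value.
    """
    if universe is None:
        universe = pathways.genes() | set(selected)
    if not universe:
        raise ValueError("empty gene universe")
    if not set(selected) <= set(universe):
        raise ValueError("selected genes must be a subset of the universe")
    sel = set(selected) & set(universe)
    N = len(universe)
    n_sel = len(sel)
    results = []
    for pw in sorted(pathways.sets):
        genes = pathways.sets[pw] & universe
        K = len(genes)
        if K < min_size:
            continue
        k = len(genes & sel)
        p = hypergeom_upper(k, K, n_sel, N)
        results.append(
            PathwayResult(pw, pathways.descriptions.get(pw, ""), k, K, n_sel, N, p)
        )
    if adjust:
        for r, a in zip(results, benjamini_hochberg([r.p for r in results])):
            r.p_adj = a
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results
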