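"""Over-representation analysis of gene sets against a flat annotation.

One-sided hypergeometric test per term with Benjamini-Hochberg correction
and the rich factor ``k / K`` (fraction of a term's annotated genes present
in the query set). Two threshold presets mirror the conventions of GO-style
(raw p < 0.01) and KEGG-style (BH q <= 0.05) reporting; the engine is the
same. The background universe defaults to all genes carrying at least one
annotation. No term-graph (GO DAG) propagation is performed: the annotation
is taken as given, flat sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

logger = logging.getLogger(__name__)

MODES = {
    # (alpha, use_adjusted, strict)
    "go": (0.01, False, True),     # raw p < 0.01
    "kegg": (0.05, True, False),   # BH q <= 0.05
}


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P[X >= k].

    ``k`` query genes in the term, query size ``n``, ``K`` universe genes in
    the term, universe size ``N``. Computed via the stable survival function.
    """
    if not (0 <= k <= min(n, K) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric configuration k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_set(
    genes: set[str] | list[str],
    annotation: AnnotationMap,
    universe: set[str] | None = None,
    *,
    alpha: float | None = None,
    use_adjusted: bool | None = None,
    mode: str = "kegg",
) -> pd.DataFrame:
    """Term over-representation of ``genes`` against ``annotation``.

    Returns one row per term with K >= 1 members in the universe, sorted by
    p-value then term id, with columns k, n, K, N, rich_factor, pvalue,
    qvalue and ``significant`` under the chosen mode (or explicit
    ``alpha``/``use_adjusted`` overrides).
    """
    if not annotation.term_to_genes:
        raise ValueError("empty annotation")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {sorted(MODES)}; got {mode!r}")
    mode_alpha, mode_adj, strict = MODES[mode]
    alpha = mode_alpha if alpha is None else alpha
    use_adjusted = mode_adj if use_adjusted is None else use_adjusted

    if universe is None:
        universe = annotation.universe
    query = set(genes)
    outside = query - universe
    if outside:
        logger.info("%d query genes outside the universe dropped", len(outside))
        query &= universe
    N = len(universe)
    n = len(query)

    rows = []
    for term in annotation.terms:
        members = annotation.term_to_genes[term] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "rich_factor": k / K,
                "pvalue": hypergeom_test(k, n, K, N),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no term overlaps the universe")
    out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    crit = out["qvalue"] if use_adjusted else out["pvalue"]
    out["significant"] = (crit < alpha) if strict else (crit <= alpha)
    out = out.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)
    return out


def hypergeom_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """Independent log-space combinatorial sum of the upper tail.

    Reference oracle: sums C(K,i) C(N−K,n−i) / C(N,n) for i = k..min(n,K)
    directly from log-gamma, with no shared code path with
    :func:`hypergeom_test`.
    """
    from scipy.special import gammaln

    def logc(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    hi = min(n, K)
    if k > hi:
        raise ValueError("k exceeds min(n, K)")
    terms = []
    for i in range(k, hi + 1):
        if n - i > N - K:
            continue
        terms.append(logc(K, i) + logc(N - K, n - i) - logc(N, n))
    if not terms:
        return 0.0
    m = max(terms)
    return float(np.exp(m) * np.sum(np.exp(np.array(terms) - m)))
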