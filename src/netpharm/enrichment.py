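"""Over-representation analysis: hypergeometric upper tail, BH-FDR,
rich factor.

For a query of n annotated genes against a term of K genes in a background
of N genes, the p-value is P(X >= k) with X ~ Hypergeometric(N, K, n) —
the one-sided Fisher test.  FDR is controlled by Benjamini–Hochberg,
separately within each annotation category (BP, MF, CC, pathway), because
GO and pathway screens are separate analyses.  The rich factor of a term
is k/K — overlap size over term size.

The EASE-style deflated variant (testing k-1 successes) is available
behind the ``ease`` flag, default off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netpharm.model import GeneSet, ValidationError, normalize_symbol


@dataclass
class EnrichmentRow:
    """One tested term."""

    term_id: str
    term_name: str
    category: str
    k: int           # overlap: query ∩ term
    n: int           # annotated query size
    K: int           # term size within background
    N: int           # background size
    p_value: float
    fdr: float
    genes: frozenset  # the overlapping genes

    @property
    def rich_factor(self) -> float:
        return self.k / self.K

    @property
    def fold_enrichment(self) -> float:
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters follow the sampling picture: N background genes of which K
    belong to the term; n genes drawn (the query); k observed successes.
    """
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"k={k} outside [0, min(n={n}, K={K})]")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy evaluates the tail stably
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    sets: Iterable[GeneSet],
    background: Optional[Iterable[str]] = None,
    fdr_max: float = 0.01,
    ease: bool = False,
) -> list:
    """Test every term with at least one query hit; return rows passing
    ``fdr < fdr_max`` sorted by (fdr, p, term id).

    Parameters
    ----------
    query
        Gene symbols of interest (case-insensitive).
    sets
        The annotation collection.
    background
        Explicit background gene universe; defaults to the union of all
        genes in ``sets`` (annotation-wide background).
    fdr_max
        Significance cutoff on the BH q-value (default 0.01).
    ease
        If True, apply the EASE deflation (test k-1 successes).
    """
    sets = list(sets)
    if not (0.0 < fdr_max <= 1.0):
        raise ValidationError("fdr_max must be in (0, 1]")
    query = {normalize_symbol(g) for g in query}
    if not query:
        raise ValidationError("empty query gene list")
    annotated = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
    if background is None:
        bg = set(annotated)
    else:
        bg = {normalize_symbol(g) for g in background} & set(annotated)
    if not bg:
        raise ValidationError("empty background gene universe")
    N = len(bg)
    effective_query = query & bg
    n = len(effective_query)
    if n == 0:
        return []

    rows = []
    for s in sets:
        term_genes = s.genes & bg
        hit = effective_query & term_genes
        k, K = len(hit), len(term_genes)
        if k == 0 or K == 0:
            continue
        k_test = max(k - 1, 1) if ease else k
        p = hypergeom_upper_tail(k_test, K, n, N)
        rows.append(
            EnrichmentRow(
                term_id=s.term_id,
                term_name=s.term_name,
                category=s.category,
                k=k, n=n, K=K, N=N,
                p_value=p, fdr=np.nan,
                genes=frozenset(hit),
            )
        )

    # BH within each category separately (GO screens vs pathway screen)
    for category in {r.category for r in rows}:
        group = [r for r in rows if r.category == category]
        qvals = bh_fdr([r.p_value for r in group])
        for r, q in zip(group, qvals):
            r.fdr = float(q)

    if fdr_max >= 1.0:  # no filtering: keep every tested term
        significant = rows
    else:
        significant = [r for r in rows if r.fdr < fdr_max]
    significant.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return significant
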