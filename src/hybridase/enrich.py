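"""Gene-set overrepresentation by one-sided Fisher's exact test.

For each term with at least one annotated population gene, the p-value is
the hypergeometric upper tail P(X >= k) of drawing k term-annotated genes
in a study set of size n from a population of N genes of which K carry the
term.  P-values are BH-adjusted over all tested terms; terms are reported
significant at FDR < 0.05.  Annotations are taken as given: no term-graph
(parent-term) propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study genes annotated to the term
    n: int  # study size
    K: int  # population genes annotated
    N: int  # population size
    fold_enrichment: float
    p_value: float
    fdr: float


def fisher_overrep(
    study: Iterable[str],
    population: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotation term for overrepresentation in the study set.

    ``annotations`` maps term -> gene set; genes outside the population are
    ignored, terms with no population gene are untestable and skipped.
    The default tail is one-sided (greater); ``two_sided`` switches to the
    two-sided Fisher exact p.
    """
    study_set = set(study)
    pop = set(population)
    stray = study_set - pop
    if stray:
        raise ValueError(
            f"{len(stray)} study genes absent from population: "
            f"{sorted(stray)[:5]}"
        )
    n, N = len(study_set), len(pop)
    rows = []
    for term in sorted(annotations):
        term_genes = set(annotations[term]) & pop
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study_set)
        if two_sided:
            tbl = [[k, n - k], [K - k, (N - K) - (n - k)]]
            p = float(stats.fisher_exact(tbl, alternative="two-sided")[1])
        else:
            # hypergeometric upper tail P(X >= k)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append((term, k, K, p, fold))
    fdrs = adjust_bh([r[3] for r in rows]) if rows else []
    return [
        EnrichmentResult(term, k, n, K, N, fold, p, float(fdr))
        for (term, k, K, p, fold), fdr in zip(rows, fdrs)
    ]


def term_report(
    results: Iterable[EnrichmentResult], alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """Significant terms (FDR strictly below alpha), sorted by p then term."""
    results = list(results)
    if not results:
        raise ValueError("no enrichment results to report")
    keep = [r for r in results if r.fdr < alpha_fdr]
    keep.sort(key=lambda r: (r.p_value, r.term_id))
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in keep
        ],
        columns=["term_id", "k", "n", "K", "N", "fold_enrichment", "p_value", "fdr"],
    )
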