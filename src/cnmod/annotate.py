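"""Module annotation by gene-set over-representation.

Each detected module is tested against every gene set of a GMT collection
with a hypergeometric upper-tail test.  The background ("universe") defaults
to all genes of the reference interactome, so enrichment is judged against
what the interactome could have produced, not against the whole genome.
Results are BH-adjusted across all module x term tests.  The collection is
deliberately generic: any GMT file works (GO slims, Reactome, planted
synthetic modules), keeping the analysis independent of a particular
annotation-database release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .association import bh_fdr
from .modules import ModulePartition

__all__ = ["EnrichmentResult", "enrich_modules"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one term in one module."""

    module: int
    term: str
    k: int  # module genes carrying the term
    K: int  # term size within the background
    module_size: int  # module genes within the background
    p_hyper: float
    q: float


def enrich_modules(
    partition: ModulePartition,
    gene_sets: dict[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each gene set in each module.

    Module genes outside the background are dropped with a warning, as are
    terms with no background overlap.  For a module of size n within a
    background of size N, a term covering K background genes and overlapping
    the module in k genes, p = P(X >= k) under Hypergeometric(N, K, n).
    Results are sorted by q then p.
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    stray = set(partition.assignment) - background
    if stray:
        warnings.warn(
            f"{len(stray)} module genes outside the background were dropped",
            stacklevel=2,
        )
    usable_sets = {}
    for term, genes in gene_sets.items():
        in_bg = genes & background
        if not in_bg:
            warnings.warn(f"term {term!r} disjoint from background: dropped", stacklevel=2)
            continue
        usable_sets[term] = in_bg

    N = len(background)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for module_id in sorted(set(partition.assignment.values())):
        members = {
            g for g, c in partition.assignment.items() if c == module_id
        } & background
        n = len(members)
        if n == 0:
            continue
        for term in sorted(usable_sets):
            in_bg = usable_sets[term]
            k = len(members & in_bg)
            p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, len(in_bg), n))
            results.append(
                EnrichmentResult(
                    module=module_id, term=term, k=k, K=len(in_bg),
                    module_size=n, p_hyper=p, q=float("nan"),
                )
            )
            pvals.append(p)
    if not results:
        return []
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            module=r.module, term=r.term, k=r.k, K=r.K,
            module_size=r.module_size, p_hyper=r.p_hyper, q=float(q),
        )
        for r, q in zip(results, qvals)
    ]
    return sorted(results, key=lambda r: (r.q, r.p_hyper, r.module, r.term))


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results."""
    return pd.DataFrame(
        {
            "module": [r.module for r in results],
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "module_size": [r.module_size for r in results],
            "p": [r.p_hyper for r in results],
            "q": [r.q for r in results],
        }
    )
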