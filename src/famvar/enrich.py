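"""Gene-set and network-edge enrichment.

Term enrichment is hypergeometric over-representation against an
annotated background with Benjamini-Hochberg control across the tested
terms; significance is declared at q <= 0.01. Edge enrichment tests
whether a query gene set is more internally connected than expected
under a density-based null: the observed within-query edge count is
compared to a hypergeometric draw of C(|query|, 2) gene pairs from the
population of all C(N, 2) pairs, of which the graph's edges are the
successes (a one-tailed test). The fold is observed over expected
(expected = pair count x global edge density).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EdgeEnrichmentResult:
    n_genes: int
    observed_edges: int
    expected_edges: float
    fold: float
    p_value: float

    @classmethod
    def from_counts(cls, observed: int, expected: float, n_genes: int = 0, p_value: float = float("nan")) -> "EdgeEnrichmentResult":
        fold = observed / expected if expected > 0 else (np.inf if observed else 0.0)
        return cls(n_genes=n_genes, observed_edges=observed, expected_edges=expected,
                   fold=fold, p_value=p_value)


def term_enrichment(
    query: set[str],
    background: set[str],
    terms: list[dict],
    fdr_q: float = 0.01,
) -> pd.DataFrame:
    """Per-term over-representation of ``query`` against ``background``.

    ``terms`` rows carry term/label/domain/parent/genes. Genes outside
    the background are ignored; the universe for each test is the
    background. Returns fold, hypergeometric p, BH q and a significance
    flag per term.
    """
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for t in terms:
        annotated = set(t["genes"]) & background
        k = len(query & annotated)
        m = len(annotated)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=m, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, m, n_query)) if m else 1.0
        expected = n_query * m / n_bg if n_bg else 0.0
        fold = (k / expected) if expected > 0 else (np.inf if k else 0.0)
        rows.append(
            dict(term=t["term"], label=t.get("label", ""), domain=t.get("domain", ""),
                 parent=t.get("parent"), term_size=m, hits=k, expected=expected,
                 fold=fold, p_value=p)
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["q_value"] = q
        out["significant"] = out["q_value"] <= fdr_q
        out = out.sort_values(["p_value", "term"]).reset_index(drop=True)
    return out


def edge_enrichment(query: set[str], edges: list[tuple[str, str]], background: set[str]) -> EdgeEnrichmentResult:
    """One-tailed hypergeometric test of within-query edge count."""
    bad = [e for e in edges if e[0] not in background or e[1] not in background]
    if bad:
        raise ValueError(f"{len(bad)} edges have endpoints outside the background")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    q = len(query)
    if q < 2:
        return EdgeEnrichmentResult(n_genes=q, observed_edges=0, expected_edges=0.0, fold=0.0, p_value=1.0)
    edge_set = {frozenset(e) for e in edges if e[0] != e[1]}
    observed = sum(1 for e in edge_set if e <= query)
    n_pairs = comb(len(background), 2)
    n_edges = len(edge_set)
    draws = comb(q, 2)
    expected = draws * n_edges / n_pairs if n_pairs else 0.0
    p = float(stats.hypergeom.sf(observed - 1, n_pairs, n_edges, draws)) if observed else 1.0
    fold = observed / expected if expected > 0 else (np.inf if observed else 0.0)
    return EdgeEnrichmentResult(n_genes=q, observed_edges=observed, expected_edges=expected,
                                fold=fold, p_value=p)
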