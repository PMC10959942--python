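"""Cohort-level descriptive and inferential statistics.

Conventions chosen to match the original analyses: Pearson chi-square on
2x2 tables WITHOUT Yates continuity correction (the uncorrected statistic
is the one that reproduces the published carrier and sex-stratified
comparisons); two-sided Fisher exact tests with the sample odds ratio
ad/bc; Welch (unequal-variance) two-sided t-tests for group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pedigree import Pedigree


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class BurdenSummary:
    group: str
    n_individuals: int
    n_variants: int
    mean_per_individual: float
    carrier_count: int
    carrier_fraction: float
    per_bin: dict[str, int]


def chi2_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square, 1 df, no continuity correction."""
    m = table.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for a zero margin")
    stat, p, _, _ = sps.chi2_contingency(m, correction=False)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (sample odds ratio, p).

    The odds ratio is ad/bc (infinite when bc = 0); the p-value sums the
    hypergeometric tables whose point probability does not exceed the
    observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = sps.fisher_exact(table.matrix, alternative="two-sided")
    return float(odds), float(p)


def group_mean_test(values_a, values_b) -> tuple[float, float]:
    """Welch two-sided t-test on two samples."""
    va, vb = np.asarray(values_a, dtype=float), np.asarray(values_b, dtype=float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = sps.ttest_ind(va, vb, equal_var=False)
    return float(t), float(p)


def denovo_rates(carriers: pd.DataFrame, pedigree: Pedigree) -> dict[str, BurdenSummary]:
    """Per-group de novo burden: totals, mean per child, carrier fraction.

    ``carriers`` is the per-individual carrier table; de novo rows have
    origin "de_novo". Groups: affected children vs unaffected children.
    """
    dn = carriers[carriers["origin"] == "de_novo"]
    out = {}
    for group, members in (
        ("cases", pedigree.affected_children),
        ("unaffected_siblings", pedigree.unaffected_children),
    ):
        ids = {m.iid for m in members}
        sub = dn[dn["individual"].isin(ids)]
        n_ind = len(ids)
        n_var = len(sub)
        carriers_n = sub["individual"].nunique()
        per_bin = sub["bin"].value_counts().to_dict() if "bin" in sub else {}
        out[group] = BurdenSummary(
            group=group,
            n_individuals=n_ind,
            n_variants=n_var,
            mean_per_individual=round(n_var / n_ind, 2) if n_ind else 0.0,
            carrier_count=int(carriers_n),
            carrier_fraction=carriers_n / n_ind if n_ind else 0.0,
            per_bin={k: int(v) for k, v in per_bin.items()},
        )
    return out


def carrier_table(
    carriers: pd.DataFrame,
    group_a: set[str],
    group_b: set[str],
) -> ContingencyTable2x2:
    """2x2 carrier table: rows group A/B, columns carrier yes/no."""
    carrier_ids = set(carriers["individual"])
    a = len(group_a & carrier_ids)
    c = len(group_b & carrier_ids)
    return ContingencyTable2x2(a=a, b=len(group_a) - a, c=c, d=len(group_b) - c)


def genelist_burden(
    carriers: pd.DataFrame,
    gene_lists: dict[str, set[str]],
    pedigree: Pedigree,
    variant_classes: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Carrier 2x2 tables (cases vs unaffected sibs) per gene list and
    variant class, with Fisher exact tests.

    ``variant_classes`` maps a class label to a boolean mask over
    ``carriers`` (defaults: all pdSNVs and de novo pdSNVs only).
    """
    cases = {c.iid for c in pedigree.affected_children}
    sibs = {c.iid for c in pedigree.unaffected_children}
    if variant_classes is None:
        variant_classes = {
            "pdsnv": carriers["pdsnv"],
            "de_novo_pdsnv": carriers["pdsnv"] & (carriers["origin"] == "de_novo"),
        }
    rows = []
    for list_name, genes in gene_lists.items():
        for cls, mask in variant_classes.items():
            sub = carriers[mask & carriers["gene"].isin(genes)]
            tab = carrier_table(sub, cases, sibs)
            odds, p = fisher_exact(tab)
            rows.append(
                dict(
                    gene_list=list_name, variant_class=cls,
                    case_carriers=tab.a, case_total=len(cases),
                    sib_carriers=tab.c, sib_total=len(sibs),
                    odds_ratio=odds, p_value=p,
                )
            )
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Round for reporting: two decimals, or two significant figures
    below 0.01."""
    if p >= 0.01:
        return f"{p:.2f}"
    return f"{p:.2g}"
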