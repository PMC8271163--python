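"""Bound vs unbound transcript comparisons on half-life and expression.

"Bound" is the top-N head of the FPKM-normalized target ranking; "Not
bound" is every gene with no retained peak in either replicate. Genes that
carry peaks but fall outside the top-N belong to neither group. Group
differences are scored with a two-sided Mann-Whitney U test (exact for
small tie-free groups, normal approximation with tie correction
otherwise), alongside medians, quartiles and empirical CDFs.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import DecayFit, FitStatus

BOUND = "Bound"
NOT_BOUND = "Not bound"


def assign_groups(
    ranking_table: pd.DataFrame,
    top_n: int,
    genes_with_peaks: Iterable[str],
    all_genes: Iterable[str],
) -> dict[str, str]:
    """Map genes to Bound / Not bound; mid-ranked peak-bearing genes drop out."""
    bound = set(ranking_table.head(top_n)["gene_id"])
    peaky = set(genes_with_peaks)
    groups: dict[str, str] = {}
    for gene in all_genes:
        if gene in bound:
            groups[gene] = BOUND
        elif gene not in peaky:
            groups[gene] = NOT_BOUND
    assert not (bound - set(groups)), "bound genes must all be assigned"
    return groups


@dataclass
class GroupComparison:
    quantity: str
    n_bound: int
    n_not_bound: int
    median_bound: float
    median_not_bound: float
    quartiles_bound: tuple[float, float]
    quartiles_not_bound: tuple[float, float]
    u_statistic: float
    p_value: float
    ecdf_bound: tuple[np.ndarray, np.ndarray]
    ecdf_not_bound: tuple[np.ndarray, np.ndarray]


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF points (x sorted, F(x)); F reaches 1."""
    x = np.sort(np.asarray(values, dtype=float))
    f = np.arange(1, x.size + 1) / x.size
    return x, f


def mann_whitney(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null for small tie-free groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # fully tied data carry no ordering information
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (max(a.size, b.size) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _compare(values: Mapping[str, float], groups: Mapping[str, str], quantity: str) -> GroupComparison:
    bound = np.array(
        [v for g, v in values.items() if groups.get(g) == BOUND], dtype=float
    )
    unbound = np.array(
        [v for g, v in values.items() if groups.get(g) == NOT_BOUND], dtype=float
    )
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = mann_whitney(bound, unbound)
    return GroupComparison(
        quantity=quantity,
        n_bound=int(bound.size),
        n_not_bound=int(unbound.size),
        median_bound=float(np.median(bound)),
        median_not_bound=float(np.median(unbound)),
        quartiles_bound=(
            float(np.quantile(bound, 0.25)),
            float(np.quantile(bound, 0.75)),
        ),
        quartiles_not_bound=(
            float(np.quantile(unbound, 0.25)),
            float(np.quantile(unbound, 0.75)),
        ),
        u_statistic=u,
        p_value=p,
        ecdf_bound=_ecdf(bound),
        ecdf_not_bound=_ecdf(unbound),
    )


def compare_half_lives(
    fits: Sequence[DecayFit], groups: Mapping[str, str]
) -> GroupComparison:
    """Bound vs unbound comparison of fitted half-lives (status-ok fits only)."""
    values = {
        f.gene_id: f.t_half for f in fits if f.status is FitStatus.ok
    }
    for label in (BOUND, NOT_BOUND):
        n = sum(1 for g in values if groups.get(g) == label)
        if n < 3:
            raise ValueError(f"group {label!r} has fewer than 3 usable fits")
    return _compare(values, groups, "t_half_min")


def compare_fold_change(
    expression_a: pd.DataFrame,
    expression_b: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = 1.0,
) -> GroupComparison:
    """Bound vs unbound comparison of log2((A + pc) / (B + pc)) per gene.

    A is the perturbed condition (e.g. RBP overexpression), B the
    reference; replicate-mean FPKM is used on both sides and the
    pseudocount guards genes at zero.
    """
    a = expression_a.set_index("gene_id")[["fpkm_rep1", "fpkm_rep2"]].mean(axis=1)
    b = expression_b.set_index("gene_id")[["fpkm_rep1", "fpkm_rep2"]].mean(axis=1)
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared genes between the two expression tables")
    log2fc = np.log2((a.loc[shared] + pseudocount) / (b.loc[shared] + pseudocount))
    return _compare(dict(zip(shared, log2fc)), groups, "log2_fold_change")


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quantity": c.quantity,
                "n_bound": c.n_bound,
                "n_not_bound": c.n_not_bound,
                "median_bound": c.median_bound,
                "median_not_bound": c.median_not_bound,
                "q1_bound": c.quartiles_bound[0],
                "q3_bound": c.quartiles_bound[1],
                "q1_not_bound": c.quartiles_not_bound[0],
                "q3_not_bound": c.quartiles_not_bound[1],
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
            }
            for c in comparisons
        ]
    )
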