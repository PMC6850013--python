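"""Diversity indices, recovery rates, dissimilarity and correlations.

Conventions: natural logarithms throughout; the abundance floor keeps rows
strictly above 0.01% of a sample's reads; sample (n-1) standard deviation
for the coefficient of variation.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau

__all__ = [
    "abundance_floor",
    "diversity_indices",
    "recovery_rate",
    "bray_curtis",
    "single_link_tree",
    "kendall_tau",
    "coefficient_of_variation",
    "diversity_report",
]

#: returned when an index is undefined (e.g. Pielou at S=1, tau on a
#: constant covariate)
UNDEFINED = float("nan")

DEFAULT_RENYI_ALPHAS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)


def abundance_floor(table: pd.DataFrame, min_frac: float = 1e-4) -> pd.DataFrame:
    """Zero out rows at or below ``min_frac`` of each column's total.

    The retention rule is strict: a row is kept only when
    count / column total > min_frac. Returns a floored copy.
    """
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every column must have a positive total")
    floored = table.where(table.div(totals, axis=1) > min_frac, 0)
    return floored.astype(table.dtypes.iloc[0] if len(table.dtypes) else int)


def _proportions(counts) -> np.ndarray:
    p = np.asarray(counts, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("no positive counts")
    return p / p.sum()


def shannon(counts) -> float:
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def renyi_entropy(counts, alpha: float) -> float:
    """Renyi entropy H_a = ln(sum p^a)/(1-a); H_1 is Shannon, H_inf = -ln max p."""
    p = _proportions(counts)
    if alpha == 1.0:
        return float(-(p * np.log(p)).sum())
    if np.isinf(alpha):
        return float(-np.log(p.max()))
    return float(np.log((p ** alpha).sum()) / (1.0 - alpha))


def diversity_indices(counts, renyi_alphas=DEFAULT_RENYI_ALPHAS) -> dict:
    """Shannon, Simpson (1 - sum p^2), inverse Simpson, Pielou and Renyi
    entropies for one sample (rows with zero count are ignored)."""
    p = _proportions(counts)
    s = p.size
    h = float(-(p * np.log(p)).sum())
    simpson_sum = float((p ** 2).sum())
    out = {
        "richness": s,
        "shannon": h,
        "simpson": 1.0 - simpson_sum,
        "inv_simpson": 1.0 / simpson_sum,
        "pielou": h / math.log(s) if s > 1 else UNDEFINED,
    }
    for alpha in renyi_alphas:
        out[f"renyi_{alpha:g}"] = renyi_entropy(p, alpha)
    return out


def recovery_rate(
    counts: pd.Series, expected_ids, criterion: str = "any_read",
) -> float:
    """Fraction of expected ids recovered in one sample.

    criterion="any_read": one or more reads. criterion="frac_gt_1e-4":
    strictly more than 0.01% of the sample's reads.
    """
    expected = list(expected_ids)
    if not expected:
        raise ValueError("expected_ids is empty")
    present = counts.reindex(expected, fill_value=0).astype(float)
    if criterion == "any_read":
        hits = (present >= 1).sum()
    elif criterion == "frac_gt_1e-4":
        total = float(counts.sum())
        hits = (present / total > 1e-4).sum() if total > 0 else 0
    else:
        raise ValueError(f"unknown recovery criterion {criterion!r}")
    return float(hits) / len(expected)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity between columns of ``table``."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    dm = squareform(pdist(table.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


def _newick(node, labels: list[str], parent_height: float) -> str:
    length = max(parent_height - node.dist, 0.0) / 2
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick(node.get_left(), labels, node.dist)
    right = _newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def single_link_tree(dist: pd.DataFrame) -> str:
    """Single-linkage dendrogram of a square dissimilarity matrix, serialized
    as a rooted newick string with branch heights. Tie-breaks follow column
    order (scipy's deterministic agglomeration)."""
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    z = linkage(squareform(dist.to_numpy(), checks=False), method="single")
    root = to_tree(z)
    labels = list(dist.columns)
    left = _newick(root.get_left(), labels, root.dist)
    right = _newick(root.get_right(), labels, root.dist)
    return f"({left},{right});"


def kendall_tau(read_counts, covariate) -> tuple[float, float]:
    """Kendall tau-b (tie corrected) with its normal-approximation p-value.

    Returns (nan, nan) when either variable is constant.
    """
    x = np.asarray(read_counts, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return UNDEFINED, UNDEFINED
    result = kendalltau(x, y, method="asymptotic")
    return float(result.statistic), float(result.pvalue)


def coefficient_of_variation(counts, floor_frac: float | None = 1e-4) -> float:
    """sd/mean of per-row counts (sample sd), after the abundance floor."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty count vector")
    if floor_frac is not None and x.sum() > 0:
        x = np.where(x / x.sum() > floor_frac, x, 0.0)
        x = x[x > 0]
    if x.size == 0:
        raise ValueError("no counts survive the abundance floor")
    if x.size == 1:
        return 0.0
    return float(x.std(ddof=1) / x.mean())


def diversity_report(
    table: pd.DataFrame,
    expected_ids=None,
    min_frac: float = 1e-4,
    renyi_alphas=DEFAULT_RENYI_ALPHAS,
) -> pd.DataFrame:
    """Per-sample report: indices on the floored table, cv, and recovery at
    both criteria (recovery on the raw table, where the criteria live)."""
    floored = abundance_floor(table, min_frac=min_frac)
    rows = []
    for sample in table.columns:
        row = {"sample": sample}
        row.update(diversity_indices(floored[sample], renyi_alphas=renyi_alphas))
        row["cv"] = coefficient_of_variation(table[sample], floor_frac=min_frac)
        if expected_ids is not None:
            row["recovery_any_read"] = recovery_rate(
                table[sample], expected_ids, "any_read")
            row["recovery_frac"] = recovery_rate(
                table[sample], expected_ids, "frac_gt_1e-4")
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
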