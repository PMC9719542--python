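"""Group-level statistics on per-cell curvature or expression.

Differential testing uses the two-sided Wilcoxon rank-sum test per gene
with Benjamini-Hochberg correction; classifier-style evaluation of
global network scores uses the rank-based (Mann-Whitney) AUC and the
DeLong test for paired AUC differences; gene-set overrepresentation is
a one-sided hypergeometric tail over GMT collections, annotated with
the mean curvature shift of the overlapping genes.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "differential_table",
    "overlap_counts",
    "roc_auc",
    "delong_compare",
    "enrichment",
    "read_gmt",
    "read_labels",
]


def differential_table(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-group comparison of curvature (or expression) values.

    Both inputs are genes × samples frames over the same gene set.
    Returns a frame indexed by gene with columns ``statistic`` (the
    Mann-Whitney U of group A), ``p_value`` (exact two-sided rank-sum
    when sample sizes allow, normal approximation otherwise),
    ``q_value`` (Benjamini-Hochberg), ``delta`` (mean(A) − mean(B)),
    ``direction`` (sign of delta) and ``significant`` (q < alpha).
    Genes constant across both groups are recorded with p = 1.
    """
    if set(values_a.index) != set(values_b.index):
        raise ValueError("the two groups must cover the same gene set")
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise ValueError("need at least two samples per group")
    values_b = values_b.loc[values_a.index]
    a = values_a.to_numpy(float)
    b = values_b.to_numpy(float)
    n_genes = a.shape[0]
    stat = np.empty(n_genes)
    pval = np.ones(n_genes)
    const = np.array(
        [np.ptp(np.concatenate([a[i], b[i]])) == 0 for i in range(n_genes)]
    )
    if const.any():
        logger.info("%d genes constant across both groups; p = 1 recorded", int(const.sum()))
    ok = ~const
    if ok.any():
        res = stats.mannwhitneyu(
            a[ok], b[ok], axis=1, alternative="two-sided", method="auto"
        )
        stat[ok] = res.statistic
        pval[ok] = res.pvalue
    stat[const] = a.shape[1] * b.shape[1] / 2.0
    qval = multipletests(pval, method="fdr_bh")[1]
    delta = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_value": pval,
            "q_value": qval,
            "delta": delta,
            "direction": np.where(delta >= 0, "+", "-"),
            "significant": qval < alpha,
        },
        index=values_a.index,
    )
    table.index.name = "gene"
    return table


def overlap_counts(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every exclusive intersection region (Venn regions).

    Keys are tuples of set names the region belongs to; counts cover
    each element exactly once, so they sum to the size of the union.
    """
    named = {k: set(v) for k, v in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named[c] for c in combo))
            outside = set.union(set(), *(named[c] for c in names if c not in combo))
            regions[combo] = len(inside - outside)
    return regions


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(score⁺ > score⁻) with ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-sample placement values of DeLong's method."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa, ties half
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same samples.  Returns
    (auc_1, auc_2, two-sided p).  When the two scores induce identical
    rankings the difference and its variance are both zero and p = 1;
    a zero variance with a nonzero difference is degenerate and raises.
    """
    s1 = np.asarray(scores_1, float)
    s2 = np.asarray(scores_2, float)
    labels = np.asarray(labels)
    if s1.shape != s2.shape or s1.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must be paired on identical samples")
    auc1, v10_1, v01_1 = _delong_placements(s1, labels)
    auc2, v10_2, v01_2 = _delong_placements(s2, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]))
    s01 = np.cov(np.stack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc1 - auc2
    if var_diff <= 1e-16:
        if abs(diff) < 1e-12:
            return auc1, auc2, 1.0
        raise ValueError("degenerate variance with nonzero AUC difference")
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc1, auc2, float(p)


def enrichment(
    hits: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    deltas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a hit list in gene sets.

    Each set is intersected with the background universe; the one-sided
    tail P(X ≥ n_overlap) is computed from the hypergeometric
    distribution and corrected across sets by Benjamini-Hochberg.
    ``mean_delta`` averages a per-gene shift (e.g. ΔRic) over the
    overlapping genes.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        if not members:
            logger.info("gene set %r has no overlap with the background; skipped", name)
            continue
        overlap = sorted(hits & members)
        k, M, n, N = len(overlap), len(background), len(members), len(hits)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        mean_delta = (
            float(np.mean([deltas[g] for g in overlap])) if deltas and overlap else np.nan
        )
        rows.append(
            {
                "name": name,
                "set_size": n,
                "n_overlap": k,
                "p_value": p,
                "mean_delta": mean_delta,
                "genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["name", "set_size", "n_overlap", "p_value", "fdr", "mean_delta", "genes"]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table[["name", "set_size", "n_overlap", "p_value", "fdr", "mean_delta", "genes"]]
    return table.sort_values(["fdr", "p_value", "name"]).reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample → group TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
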