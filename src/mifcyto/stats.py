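"""Cohort statistics: Spearman matrix, Kruskal–Wallis + uncorrected Dunn,
Mann–Whitney, and count summaries.

The battery mirrors common practice in tissue-cytometry cohort studies:
nonparametric throughout, pairwise-complete Spearman rank correlations across
the parameter matrix, Kruskal–Wallis across ≥3 groups followed by the
*uncorrected* Dunn post hoc only when the omnibus p < 0.05, and the
Mann–Whitney U test for two-group contrasts. Leaving the Dunn test uncorrected
reproduces the source battery faithfully; a Holm correction is available
behind a switch and off by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (presentation rounding for reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# correlation

@dataclass
class CorrelationMatrix:
    parameters: list[str]
    rho: pd.DataFrame        # Spearman rho, pairwise-complete; NaN if undefined
    n: pd.DataFrame          # pairwise-complete sample sizes


def spearman_matrix(matrix: pd.DataFrame, min_n: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation across a samples × parameters
    matrix.

    Ties get average ranks; pairs with fewer than ``min_n`` complete
    observations, or involving a constant column, are NaN (undefined, not 0).
    """
    rho = matrix.corr(method="spearman", min_periods=min_n)
    notna = matrix.notna().astype(int)
    n = notna.T @ notna
    np.fill_diagonal(rho.values, 1.0)
    # a constant column correlates with nothing, including itself
    for col in matrix.columns:
        vals = matrix[col].dropna()
        if len(vals) and vals.nunique() == 1:
            rho.loc[col, :] = np.nan
            rho.loc[:, col] = np.nan
    return CorrelationMatrix(list(matrix.columns), rho, n)


def correlation_heatmap(cm: CorrelationMatrix, path) -> None:
    """Export the rho matrix as a heatmap image (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(0.22 * len(cm.parameters) + 2,) * 2)
    im = ax.imshow(cm.rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.parameters)), cm.parameters,
                  rotation=90, fontsize=5)
    ax.set_yticks(range(len(cm.parameters)), cm.parameters, fontsize=5)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    p: float
    statistic: float
    method: str


@dataclass
class GroupComparison:
    parameter: str
    groups: list[str]
    kw_p: float | None
    pairwise: list[PairwiseTest]
    method: str


def mannwhitney_p(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact when both n ≤ 8 and tie-free, else the
    tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney requires non-empty groups")
    exact = (len(a) <= 8 and len(b) <= 8
             and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b))
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def dunn_pairwise(values: Sequence[float], labels: Sequence,
                  correction: str | None = None) -> list[PairwiseTest]:
    """Dunn's post-hoc z tests on the joint ranks, with tie correction.

    Two-sided p-values; uncorrected by default (``correction="holm"`` applies
    a Holm step-down across the pairs).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("Dunn test requires at least 2 groups")
    n_total = len(values)
    ranks = sps.rankdata(values)  # average ranks for ties
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {g: float(ranks[labels == g].mean()) for g in groups}
    n = {g: int((labels == g).sum()) for g in groups}
    out = []
    for ga, gb in itertools.combinations(groups, 2):
        se = math.sqrt(var_base * (1.0 / n[ga] + 1.0 / n[gb]))
        z = (mean_rank[ga] - mean_rank[gb]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(PairwiseTest(str(ga), str(gb), float(p), float(z), "dunn"))
    if correction == "holm":
        order = np.argsort([t.p for t in out])
        m = len(out)
        running = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, (m - rank) * out[i].p)
            running = max(running, adj)
            out[i].p = running
            out[i].method = "dunn_holm"
    return out


def group_compare(values: Sequence[float], group_labels: Sequence,
                  paired_tests: str = "dunn_if_kw",
                  parameter: str = "", alpha: float = 0.05,
                  correction: str | None = None) -> GroupComparison:
    """Kruskal–Wallis omnibus with Dunn post hoc, or direct Mann–Whitney.

    ``dunn_if_kw`` runs Kruskal–Wallis and populates pairwise Dunn tests only
    when the omnibus p < ``alpha``; ``mannwhitney`` compares exactly two
    groups directly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[labels == g] for g in groups]
    if any(len(v) == 0 for v in by_group):
        raise ValueError("empty group")
    if paired_tests == "mannwhitney":
        if len(groups) != 2:
            raise ValueError("mannwhitney mode requires exactly 2 groups")
        stat, p = mannwhitney_p(by_group[0], by_group[1])
        pw = [PairwiseTest(str(groups[0]), str(groups[1]), p, stat,
                           "mannwhitney")]
        return GroupComparison(parameter, [str(g) for g in groups], None, pw,
                               "mannwhitney")
    if paired_tests != "dunn_if_kw":
        raise ValueError(f"unknown paired_tests {paired_tests!r}")
    kw = sps.kruskal(*by_group)
    pairwise: list[PairwiseTest] = []
    if kw.pvalue < alpha:
        pairwise = dunn_pairwise(values, labels, correction=correction)
    return GroupComparison(parameter, [str(g) for g in groups],
                           float(kw.pvalue), pairwise, "kruskal_dunn")


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        if not c.pairwise:
            rows.append({"parameter": c.parameter, "kw_p": c.kw_p,
                         "group_a": None, "group_b": None,
                         "pairwise_p": None, "method": c.method})
        for t in c.pairwise:
            rows.append({"parameter": c.parameter, "kw_p": c.kw_p,
                         "group_a": t.group_a, "group_b": t.group_b,
                         "pairwise_p": t.p, "method": t.method})
    return pd.DataFrame(rows, columns=["parameter", "kw_p", "group_a",
                                       "group_b", "pairwise_p", "method"])


# ---------------------------------------------------------------------------
# count summaries

def summarize_counts(counts: Mapping[str, int] | Sequence[int]
                     ) -> dict | list:
    """Percentages of the total at 1-decimal half-up rounding."""
    if isinstance(counts, Mapping):
        vals = list(counts.values())
    else:
        vals = list(counts)
    if any(v < 0 for v in vals):
        raise ValueError("counts must be non-negative")
    total = sum(vals)
    if total <= 0:
        raise ValueError("total count must be positive")
    pcts = [round_half_up(100.0 * v / total, 1) for v in vals]
    if isinstance(counts, Mapping):
        return dict(zip(counts.keys(), pcts))
    return pcts


def response_rate(best_responses: Mapping[str, int]) -> float:
    """Overall response rate (%): complete + partial responses over all cases."""
    total = sum(best_responses.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    responders = best_responses.get("CR", 0) + best_responses.get("PR", 0)
    return round_half_up(100.0 * responders / total, 1)
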