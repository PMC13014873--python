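"""Nonparametric group comparisons: Kruskal-Wallis with tie correction,
Dunn's post-hoc pairwise z tests and significance labelling."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    groups: tuple[str, str] | None = None
    label: str | None = None


def _check_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        arrays.append(a)
    return arrays


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected H statistic with a chi-square p-value on k-1 df.

    Identical groups (zero rank variance) return H = 0, p = 1.
    """
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0)
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p))


def dunn_posthoc(groups, labels=None, adjustment: str = "bonferroni") -> list[TestResult]:
    """Dunn's pairwise z tests from pooled mean ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p with
    optional Bonferroni or Holm inflation. All k(k-1)/2 pairs are reported.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    arrays = _check_groups(groups)
    k = len(arrays)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match group count")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        results.append(TestResult(statistic=float(z), p_value=float(min(p, 1.0)),
                                  groups=(labels[i], labels[j])))

    m = len(results)
    if adjustment == "none":
        for r in results:
            r.adjusted_p = r.p_value
    elif adjustment == "bonferroni":
        for r in results:
            r.adjusted_p = min(1.0, r.p_value * m)
    else:  # holm step-down
        order = np.argsort([r.p_value for r in results])
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_value)
            running = max(running, adj)
            results[idx].adjusted_p = running
    for r in results:
        r.label = significance_label(r.adjusted_p)
    return results


def significance_label(p: float) -> str:
    """Map a p-value to {ns, *, **, ***} at 0.05 / 0.01 / 0.005 thresholds."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_mean_sd(values) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


def kw_dunn_table(df: pd.DataFrame, by: str, value: str, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Tidy Kruskal-Wallis + Dunn output over a long-format table."""
    groups, labels = [], []
    for name, g in df.groupby(by, sort=False):
        labels.append(str(name))
        groups.append(g[value].to_numpy(float))
    kw = kruskal_wallis(groups)
    rows = [
        {
            "group_a": r.groups[0],
            "group_b": r.groups[1],
            "z": r.statistic,
            "p": r.p_value,
            "adjusted_p": r.adjusted_p,
            "label": r.label,
            "kw_H": kw.statistic,
            "kw_p": kw.p_value,
        }
        for r in dunn_posthoc(groups, labels, adjustment)
    ]
    return pd.DataFrame(rows)
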