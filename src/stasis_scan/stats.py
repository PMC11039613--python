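"""Rank-based group comparisons shared by the divergence and redundancy layers.

Two-sample comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test, multi-group comparisons Kruskal-Wallis, matching the nonparametric
toolkit of the study design. Pairwise p-values are reported raw and
Holm-adjusted.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["wilcoxon_rank_sum", "compare_groups"]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W statistic, p-value).

    Uses the Mann-Whitney U formulation with an exact null for small,
    tie-free samples and a normal approximation otherwise, mirroring R's
    ``wilcox.test`` defaults.
    """
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_groups(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests across named groups.

    Groups with fewer than 2 values are excluded with a warning. When three
    or more groups remain, a Kruskal-Wallis row (``group_b == "(all)"``) is
    included. Returns a tidy frame with raw and Holm-adjusted p-values.
    """
    usable = {}
    for name, vals in groups.items():
        vals = [v for v in vals if np.isfinite(v)]
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has <2 values; excluded", stacklevel=2)
            continue
        usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least two usable groups")

    rows = []
    for a, b in combinations(sorted(usable), 2):
        w, p = wilcoxon_rank_sum(usable[a], usable[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "test": "wilcoxon_rank_sum",
                "statistic": w,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    if len(usable) > 2:
        h, p = sps.kruskal(*usable.values())
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    [
                        {
                            "group_a": "(all)",
                            "group_b": "(all)",
                            "test": "kruskal_wallis",
                            "statistic": float(h),
                            "p_value": float(p),
                            "p_holm": float("nan"),
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return out
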