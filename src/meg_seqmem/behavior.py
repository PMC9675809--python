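"""Behavioral statistics for the old/new recognition task.

One-way ANOVAs (alpha = 0.05) compare response accuracy and mean reaction
time across the four conditions, treating the condition cells as independent
groups (so a 71-subject cohort yields df = (3, 280)); post-hoc pairwise
t-tests use a Bonferroni-adjusted alpha of 0.05 / 4 = 0.0125. The divisor 4
follows the published analysis although six pairs exist; see the methods
note for the caveat.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .megsim import CONDITIONS

__all__ = ["AnovaResult", "one_way_anova", "posthoc_bonferroni"]

log = logging.getLogger(__name__)

MEASURES = {"accuracy": "n_correct", "rt": "mean_rt_ms"}


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def _groups(table: pd.DataFrame, measure: str) -> dict[str, np.ndarray]:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {sorted(MEASURES)}")
    col = MEASURES[measure]
    present = [c for c in CONDITIONS if (table["condition"] == c).any()]
    present += [c for c in table["condition"].unique() if c not in present]
    if len(present) < 2:
        raise ValueError("need at least two condition groups")
    groups = {}
    for cond in present:
        vals = table.loc[table["condition"] == cond, col].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"condition '{cond}' has fewer than 2 observations")
        groups[cond] = vals
    return groups


def one_way_anova(table: pd.DataFrame, measure: str = "accuracy") -> AnovaResult:
    """Classical one-way ANOVA across the four condition groups.

    A degenerate result (all groups constant, 0/0 F) is flagged rather than
    returned as inf/nan silently.
    """
    groups = list(_groups(table, measure).values())
    k = len(groups)
    n = sum(g.size for g in groups)
    if all(np.allclose(g.var(ddof=1), 0.0) for g in groups):
        return AnovaResult(np.nan, k - 1, n - k, np.nan, degenerate=True)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(float(F), k - 1, n - k, float(p))


def posthoc_bonferroni(
    table: pd.DataFrame,
    measure: str = "accuracy",
    family_alpha: float = 0.05,
    divisor: int = 4,
    omnibus: AnovaResult | None = None,
) -> pd.DataFrame:
    """All six pairwise two-sample t-tests at adjusted alpha = family/divisor.

    Returns mean differences, raw p-values, and significance at the adjusted
    alpha (0.0125 by default). Warns when run without a significant omnibus
    ANOVA.
    """
    if omnibus is not None and (omnibus.degenerate or omnibus.p > family_alpha):
        log.warning("post-hoc tests requested although the omnibus ANOVA is "
                    "not significant (p=%.3f)", omnibus.p)
    groups = _groups(table, measure)
    adj_alpha = family_alpha / divisor
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ga, gb = groups[a], groups[b]
        if np.allclose(ga, gb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ga, gb)
        rows.append({"condition_a": a, "condition_b": b,
                     "mean_diff": float(ga.mean() - gb.mean()),
                     "t": float(t), "p_raw": float(p),
                     "adjusted_alpha": adj_alpha,
                     "significant": bool(p < adj_alpha)})
    return pd.DataFrame(rows)
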