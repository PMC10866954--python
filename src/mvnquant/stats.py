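"""Study-level tables, control normalization and group statistics.

Groups are compared with a one-way ANOVA followed by pairwise comparisons
with Šidák multiple-comparison adjustment, matching the convention used for
per-network morphology readouts (mean ± s.d., adjusted p per pair). Pairwise
t statistics use the pooled ANOVA mean-square error.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError


def normalize_to_control(
    table: pd.DataFrame,
    metric: str,
    control_condition: str,
    control_day: str | int | None = None,
    *,
    condition_col: str = "condition",
    day_col: str = "day",
) -> pd.DataFrame:
    """Add a percent-of-control column for ``metric``: each row divided by
    the control-group mean, ×100. Column name: ``{metric}_pct_control``."""
    sel = table[condition_col] == control_condition
    if control_day is not None and day_col in table.columns:
        sel &= table[day_col] == control_day
    control = table.loc[sel, metric]
    if control.empty:
        raise ConfigError(
            f"empty control group ({control_condition!r}, day {control_day!r})"
        )
    mean = float(control.mean())
    if mean == 0:
        raise ConfigError("control-group mean is zero; normalization undefined")
    out = table.copy()
    out[f"{metric}_pct_control"] = out[metric] / mean * 100.0
    return out


def group_stats(
    table: pd.DataFrame,
    metric: str,
    groups: list[str],
    *,
    group_col: str = "group",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across the listed groups plus Šidák-adjusted pairwise
    comparisons.

    Returns {"anova": {F, p}, "groups": DataFrame(mean, sd, n),
    "pairwise": DataFrame(group1, group2, t, p_raw, p_adj, significant)}.
    """
    samples = []
    for g in groups:
        vals = table.loc[table[group_col] == g, metric].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ConfigError(f"group {g!r} has fewer than 2 rows")
        samples.append(vals)
    if len(samples) < 2:
        raise ConfigError("need at least 2 groups")

    f_stat, p_anova = sps.f_oneway(*samples)

    n_total = sum(len(s) for s in samples)
    k = len(samples)
    grand_sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_err = n_total - k
    mse = grand_sse / df_err if df_err > 0 else np.nan

    rows = []
    for g, s in zip(groups, samples):
        rows.append({"group": g, "mean": s.mean(), "sd": s.std(ddof=1), "n": len(s)})
    gtable = pd.DataFrame(rows)

    pair_rows = []
    raw_ps = []
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        si, sj = samples[i], samples[j]
        if mse > 0:
            se = np.sqrt(mse * (1.0 / len(si) + 1.0 / len(sj)))
            t = (si.mean() - sj.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df_err)
        else:
            t, p = 0.0, 1.0
        raw_ps.append(p)
        pair_rows.append({"group1": gi, "group2": gj, "t": t, "p_raw": p})
    reject, p_adj, *_ = multipletests(raw_ps, alpha=alpha, method="sidak")
    for row, pa, rej in zip(pair_rows, p_adj, reject):
        row["p_adj"] = pa
        row["significant"] = bool(rej)
    return {
        "anova": {"F": float(f_stat), "p": float(p_anova)},
        "groups": gtable,
        "pairwise": pd.DataFrame(pair_rows),
    }
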