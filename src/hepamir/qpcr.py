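"""ddCT relative quantification of qPCR data with multi-reference normalization.

Per replicate, dCT = CT_target - mean(CT of the endogenous reference miRNAs)
(arithmetic mean of CTs = geometric-mean normalization in linear space).
ddCT = mean dCT(group) - mean dCT(control group); relative expression
(fold change) = 2^(-ddCT), so the control group's own fold change is exactly 1.
Group comparisons use an unpaired two-sided t-test on the replicate dCT
values (pooled-variance Student by default, Welch optional), with the usual
significance stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_qpcr_table

logger = logging.getLogger("hepamir")

_LN2 = np.log(2.0)

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return "ns"


def delta_ct(table: pd.DataFrame, ref_targets: Sequence[str]) -> pd.DataFrame:
    """Per-replicate dCT table (columns: group, target, replicate, dct).

    Every (group, replicate) must carry a CT for each reference miRNA.
    """
    table = validate_qpcr_table(table)
    if not ref_targets:
        raise ValueError("at least one reference target is required")
    refs = list(ref_targets)
    missing_refs = set(refs) - set(table["target"])
    if missing_refs:
        raise ValueError(f"reference targets absent from table: {sorted(missing_refs)}")
    ref_ct = (table[table["target"].isin(refs)]
              .pivot_table(index=["group", "replicate"], columns="target", values="ct"))
    rows = []
    for row in table.itertuples(index=False):
        key = (row.group, row.replicate)
        if key not in ref_ct.index:
            raise ValueError(f"no reference wells for group {row.group!r}, replicate {row.replicate}")
        ref_vals = ref_ct.loc[key, refs]
        if ref_vals.isna().any():
            bad = list(ref_vals.index[ref_vals.isna()])
            raise ValueError(
                f"missing reference well: group {row.group!r}, replicate {row.replicate}, "
                f"reference {bad[0]!r}")
        rows.append((row.group, row.target, row.replicate, row.ct - float(ref_vals.mean())))
    return pd.DataFrame(rows, columns=["group", "target", "replicate", "dct"])


def group_ttest(dct: pd.DataFrame, group_a: str, group_b: str, target: str,
                welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test on replicate dCT values; returns (t, df, p).

    Degenerate case (zero variance in both groups, equal means) reports
    p = 1 with t = 0.
    """
    a = dct.loc[(dct["group"] == group_a) & (dct["target"] == target), "dct"].to_numpy()
    b = dct.loc[(dct["group"] == group_b) & (dct["target"] == target), "dct"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("degenerate t-test for %r: zero variance, equal means; p = 1", target)
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = (len(a) + len(b) - 2) if not welch else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class DdctResults:
    """Per (target, group) dCT summaries, fold changes vs control, and tests."""

    table: pd.DataFrame
    control_group: str
    ref_targets: tuple[str, ...]

    def fold_change(self, target: str, group: str) -> float:
        row = self.table[(self.table["target"] == target) & (self.table["group"] == group)]
        if row.empty:
            raise KeyError(f"no result for target {target!r}, group {group!r}")
        return float(row["fold_change"].iloc[0])

    def summary(self) -> str:
        lines = [f"ddCT relative quantification (control = {self.control_group}; "
                 f"references: {', '.join(self.ref_targets)})"]
        for row in self.table.itertuples(index=False):
            lines.append(
                f"  {row.target} [{row.group}]: fold change {row.fold_change:.3g} "
                f"+/- {row.fold_change_se:.2g} (n={row.n}), p={row.p:.3g} {row.stars}")
        return "\n".join(lines)


class DeltaDeltaCT:
    """ddCT model for a CT table: ``DeltaDeltaCT(table, refs, "untreated").fit()``."""

    def __init__(self, table: pd.DataFrame, ref_targets: Sequence[str],
                 control_group: str, welch: bool = False):
        self.table = validate_qpcr_table(table)
        self.ref_targets = tuple(ref_targets)
        self.control_group = control_group
        self.welch = welch

    def fit(self) -> DdctResults:
        dct = delta_ct(self.table, self.ref_targets)
        targets = [t for t in dct["target"].unique() if t not in self.ref_targets]
        groups = list(dct["group"].unique())
        if self.control_group not in groups:
            raise ValueError(f"control group {self.control_group!r} absent from table")
        rows = []
        for target in targets:
            sub = dct[dct["target"] == target]
            ctrl = sub.loc[sub["group"] == self.control_group, "dct"].to_numpy()
            if ctrl.size == 0:
                raise ValueError(f"control group missing for target {target!r}")
            ctrl_mean = ctrl.mean()
            ctrl_se2 = ctrl.var(ddof=1) / ctrl.size if ctrl.size > 1 else 0.0
            for group in groups:
                vals = sub.loc[sub["group"] == group, "dct"].to_numpy()
                n = vals.size
                mean_dct = vals.mean()
                se_dct = float(np.sqrt(vals.var(ddof=1) / n)) if n > 1 else np.nan
                if group == self.control_group:
                    ddct, fc = 0.0, 1.0
                    se_ddct = np.sqrt(2 * ctrl_se2) if n > 1 else np.nan
                else:
                    ddct = mean_dct - ctrl_mean
                    fc = float(2.0 ** (-ddct))
                    se_ddct = np.sqrt((vals.var(ddof=1) / n if n > 1 else 0.0) + ctrl_se2)
                fc_se = float(_LN2 * fc * se_ddct) if np.isfinite(se_ddct) else np.nan
                if group == self.control_group or n < 2 or ctrl.size < 2:
                    t, dfree, p = np.nan, np.nan, np.nan
                else:
                    t, dfree, p = group_ttest(dct, group, self.control_group, target,
                                              welch=self.welch)
                rows.append((target, group, n, mean_dct, se_dct, ddct, fc, fc_se,
                             t, dfree, p, stars(p) if np.isfinite(p) else ""))
        table = pd.DataFrame(rows, columns=[
            "target", "group", "n", "mean_dct", "se_dct", "ddct", "fold_change",
            "fold_change_se", "t", "df", "p", "stars"])
        return DdctResults(table, self.control_group, self.ref_targets)


def ddct_fold_change(table: pd.DataFrame, ref_targets: Sequence[str],
                     control_group: str) -> DdctResults:
    """Functional form of :class:`DeltaDeltaCT`."""
    return DeltaDeltaCT(table, ref_targets, control_group).fit()
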