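"""Comparative pattern count (COMPACT) analysis of time-course expression.

Each miRNA's log2 fold change versus the baseline time is computed within
each condition, discretized against a threshold tau into U (>= tau),
D (<= -tau) or 0, and the resulting per-condition pattern codes are
cross-tabulated into a 3^T x 3^T count matrix (T = number of non-baseline
times) whose cells partition the analyzed miRNA set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

ALPHABET = ("D", "0", "U")


def code_from_steps(steps: Sequence[int]) -> str:
    """Render a (-1, 0, +1) step tuple as a pattern code string, e.g. "0UU"."""
    symbols = {-1: "D", 0: "0", 1: "U"}
    return "".join(symbols[int(s)] for s in steps)


def all_pattern_codes(n_times: int) -> list[str]:
    """All 3^T codes in lexicographic (D < 0 < U) order."""
    return ["".join(p) for p in product(ALPHABET, repeat=n_times)]


@dataclass
class FoldChangeCube:
    """log2 fold changes vs baseline: DataFrame indexed by miRNA with
    (condition, time) MultiIndex columns; baseline time excluded."""

    data: pd.DataFrame
    baseline_time: float
    aggregation: str = "mean_log2"

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def times(self) -> list[float]:
        return list(self.data.columns.get_level_values(1).unique())


def fold_change_vs_baseline(expr: ExpressionMatrix,
                            baseline_time: float = 0,
                            condition: str = "diet",
                            time_col: str = "time_h") -> FoldChangeCube:
    """Replicate-mean log2 fold change at each (condition, time) vs baseline.

    log2FC = mean log-cpm over replicates at (condition, t) minus the mean at
    (condition, baseline).  Every condition level must have baseline samples
    and every (condition, time) cell must be populated.
    """
    meta = expr.samples
    levels = list(dict.fromkeys(meta[condition]))
    times = sorted(set(meta[time_col]) - {baseline_time})
    if baseline_time not in set(meta[time_col]):
        raise ValueError(f"no samples at baseline time {baseline_time!r}")
    blocks: dict[tuple[str, float], pd.Series] = {}
    for lev in levels:
        base_ids = meta.loc[(meta[condition] == lev) & (meta[time_col] == baseline_time), "sample_id"]
        if base_ids.empty:
            raise ValueError(f"missing baseline samples for condition {lev!r}")
        base_mean = expr.values[list(base_ids)].mean(axis=1)
        for t in times:
            ids = meta.loc[(meta[condition] == lev) & (meta[time_col] == t), "sample_id"]
            if ids.empty:
                raise ValueError(f"missing samples for condition {lev!r} at time {t!r}")
            blocks[(lev, t)] = expr.values[list(ids)].mean(axis=1) - base_mean
    data = pd.DataFrame(blocks)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=[condition, time_col])
    return FoldChangeCube(data, baseline_time)


def discretize(cube: FoldChangeCube, tau: float = 1.5) -> dict[str, pd.Series]:
    """Discretize the cube into per-condition pattern codes.

    |log2FC| >= tau is regulated (boundary inclusive); the code string runs
    over non-baseline times in increasing order.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    out: dict[str, pd.Series] = {}
    for lev in cube.conditions:
        block = cube.data[lev].to_numpy()
        steps = np.where(block >= tau, 1, np.where(block <= -tau, -1, 0))
        codes = ["".join("D0U"[s + 1] for s in row) for row in steps]
        out[lev] = pd.Series(codes, index=cube.data.index, name=lev)
    return out


@dataclass
class CompactResult:
    """Two-condition pattern-count matrix with cell memberships."""

    counts: pd.DataFrame  # index = pattern in condition A, columns = pattern in condition B
    membership: dict[tuple[str, str], list[str]]
    condition_a: str
    condition_b: str
    tau: float

    def cluster(self, pattern_a: str, pattern_b: str) -> list[str]:
        """miRNAs with ``pattern_a`` in condition A and ``pattern_b`` in B."""
        n = len(self.counts.index[0])
        for code in (pattern_a, pattern_b):
            if len(code) != n or any(c not in ALPHABET for c in code):
                raise ValueError(f"malformed pattern code {code!r}")
        return list(self.membership.get((pattern_a, pattern_b), []))

    def summary(self) -> str:
        occupied = {k: v for k, v in self.membership.items() if v}
        lines = [
            f"COMPACT pattern counts: {self.condition_a} (rows) x {self.condition_b} (cols), "
            f"tau = {self.tau} log2 units",
            f"miRNAs analyzed: {int(self.counts.to_numpy().sum())}; occupied cells: {len(occupied)}",
        ]
        top = sorted(occupied.items(), key=lambda kv: -len(kv[1]))[:10]
        for (a, b), members in top:
            lines.append(f"  {self.condition_a}={a} / {self.condition_b}={b}: {len(members)} miRNAs")
        return "\n".join(lines)


def pattern_counts(patterns_a: pd.Series, patterns_b: pd.Series,
                   condition_a: str = "A", condition_b: str = "B",
                   tau: float = 1.5) -> CompactResult:
    """Cross-tabulate two per-condition pattern maps over the same miRNAs."""
    set_a, set_b = set(patterns_a.index), set(patterns_b.index)
    if set_a != set_b:
        raise ValueError(
            "pattern maps cover different miRNA universes; symmetric difference: "
            f"{sorted(set_a ^ set_b)}"
        )
    n_times = len(patterns_a.iloc[0]) if len(patterns_a) else 1
    codes = all_pattern_codes(n_times)
    counts = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    membership: dict[tuple[str, str], list[str]] = {}
    for m in patterns_a.index:
        key = (patterns_a.loc[m], patterns_b.loc[m])
        counts.loc[key] += 1
        membership.setdefault(key, []).append(m)
    return CompactResult(counts, membership, condition_a, condition_b, tau)


class CompactAnalysis:
    """COMPACT model: discretized trajectory cross-tabulation of two conditions.

    Parameters
    ----------
    expr : ExpressionMatrix
        log-cpm values; restrict samples beforehand (or via ``where``) to the
        arm whose time course is analyzed (untreated, typically).
    condition : str
        Sample-table column defining the two conditions (default "diet").
    baseline_time : float
        The within-condition reference time.
    tau : float
        Discretization threshold in log2 units; the study rule is
        |log2FC| >= 1.5.
    where : mapping, optional
        Column -> value filters applied to the sample table first.
    """

    def __init__(self, expr: ExpressionMatrix, condition: str = "diet",
                 baseline_time: float = 0, tau: float = 1.5,
                 where: Mapping[str, object] | None = None):
        if where:
            meta = expr.samples
            mask = np.ones(len(meta), dtype=bool)
            for col, val in where.items():
                mask &= (meta[col] == val).to_numpy()
            expr = expr.subset_samples(list(meta.loc[mask, "sample_id"]))
        self.expr = expr
        self.condition = condition
        self.baseline_time = baseline_time
        self.tau = tau

    def fit(self) -> CompactResult:
        cube = fold_change_vs_baseline(self.expr, self.baseline_time, self.condition)
        pats = discretize(cube, self.tau)
        levels = cube.conditions
        if len(levels) != 2:
            raise ValueError(f"COMPACT compares exactly 2 conditions, found {levels}")
        a, b = levels
        result = pattern_counts(pats[a], pats[b], a, b, self.tau)
        result.cube = cube  # keep for inspection/plots
        return result
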