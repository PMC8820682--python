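"""Pearson correlation screen of all miRNAs against a reference miRNA.

Correlations are computed on normalized log-cpm values across a chosen
sample subset; two-sided p-values come from t = r*sqrt((n-2)/(1-r^2)) with
n-2 degrees of freedom.  The headline significance rule is raw p < 0.05
(matching the study's reporting); BH-adjusted p-values are also provided,
with the multiplicity caveat noted in the result summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh
from .io import ExpressionMatrix


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r and two-sided p of every row of Y against x; zero-variance rows -> NaN."""
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((Yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / (sy * sx)
    r = np.where((sy == 0) | (sx == 0), np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


@dataclass
class CorrelationScreenResults:
    """Per-miRNA r, p, adjusted p and sign class versus the reference."""

    table: pd.DataFrame  # columns: r, n, p, adj_p, sign_class
    reference: str
    n_samples: int

    def partners(self, alpha: float = 0.05, use_adjusted: bool = False
                 ) -> tuple[list[str], list[str]]:
        """(positively, negatively) correlated miRNAs at the chosen level."""
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        pcol = self.table["adj_p"] if use_adjusted else self.table["p"]
        ok = pcol.notna()
        sig = ok & ((pcol < alpha) | (alpha == 1))
        pos = list(self.table.index[sig & (self.table["r"] > 0)])
        neg = list(self.table.index[sig & (self.table["r"] < 0)])
        return pos, neg

    def summary(self, alpha: float = 0.05) -> str:
        pos, neg = self.partners(alpha)
        return (
            f"Correlation screen vs {self.reference} over {self.n_samples} samples\n"
            f"  {len(pos)} positively / {len(neg)} negatively correlated at raw p < {alpha}\n"
            f"  (raw-p rule; BH-adjusted p available in .table['adj_p'] — with "
            f"{len(self.table)} tests expect ~{alpha * len(self.table):.0f} false positives "
            f"under the null)"
        )


def correlate_to_reference(expr: ExpressionMatrix, ref_id: str,
                           sample_subset: Sequence[str] | None = None
                           ) -> CorrelationScreenResults:
    """Screen every miRNA for Pearson correlation with ``ref_id``.

    Zero-variance miRNAs get r = NaN, are flagged in ``sign_class`` as
    "undefined" and are excluded from BH adjustment.  Needs >= 3 samples.
    """
    if ref_id not in expr.values.index:
        raise ValueError(f"reference miRNA {ref_id!r} not in expression matrix")
    ids = list(sample_subset) if sample_subset is not None else expr.sample_ids
    if len(ids) < 3:
        raise ValueError(f"correlation needs >= 3 samples, got {len(ids)}")
    vals = expr.values.loc[:, ids]
    x = vals.loc[ref_id].to_numpy(dtype=float)
    others = vals.drop(index=ref_id)
    r, p = _pearson_with_p(x, others.to_numpy(dtype=float))
    adj = np.full_like(p, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        adj[defined] = adjust_bh(p[defined])
    sign_class = np.where(np.isnan(r), "undefined",
                          np.where((p < 0.05) & (r > 0), "pos",
                                   np.where((p < 0.05) & (r < 0), "neg", "ns")))
    table = pd.DataFrame({"r": r, "n": len(ids), "p": p, "adj_p": adj,
                          "sign_class": sign_class}, index=others.index)
    return CorrelationScreenResults(table, ref_id, len(ids))


def significant_partners(res: CorrelationScreenResults, alpha: float = 0.05,
                         use_adjusted: bool = False) -> tuple[list[str], list[str]]:
    return res.partners(alpha, use_adjusted)


def pairwise_matrix(expr: ExpressionMatrix,
                    sample_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Full symmetric miRNA-by-miRNA Pearson correlation matrix."""
    ids = list(sample_subset) if sample_subset is not None else expr.sample_ids
    if len(ids) < 3:
        raise ValueError(f"correlation needs >= 3 samples, got {len(ids)}")
    vals = expr.values.loc[:, ids].to_numpy(dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    sd = np.sqrt((vc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ vc.T) / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0  # enforce exact symmetry against rounding
    return pd.DataFrame(r, index=expr.values.index, columns=expr.values.index)


class CorrelationScreen:
    """Model-style wrapper: ``CorrelationScreen(expr, "rno-miR-21").fit()``."""

    def __init__(self, expr: ExpressionMatrix, reference: str,
                 sample_subset: Sequence[str] | None = None):
        self.expr = expr
        self.reference = reference
        self.sample_subset = sample_subset

    def fit(self) -> CorrelationScreenResults:
        return correlate_to_reference(self.expr, self.reference, self.sample_subset)
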