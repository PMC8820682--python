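"""Per-miRNA linear models with empirical-Bayes variance moderation.

Each miRNA is fitted by (optionally weighted) least squares against a common
design matrix; contrast estimates are linear combinations of coefficients.
Residual variances s_g^2 with d_g degrees of freedom are shrunk toward a
prior (s0^2, d0) estimated by the closed-form moment estimator on log s^2
(digamma/trigamma inversion); the moderated t-statistic uses the posterior
variance (d0*s0^2 + d*s^2)/(d0 + d) and d0 + d degrees of freedom.
Benjamini-Hochberg step-up adjustment is implemented here because the study's
signature-derivation rule depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

logger = logging.getLogger("hepamir")


# ---------------------------------------------------------------------------
# design and contrast helpers
# ---------------------------------------------------------------------------

def group_design(samples: pd.DataFrame,
                 factors: Sequence[str] = ("diet", "time_h", "treatment")) -> pd.DataFrame:
    """Group-means (cell-means) design: one indicator column per combination."""
    labels = samples[list(factors)].astype(str).agg("_".join, axis=1)
    X = pd.get_dummies(labels, dtype=float)
    X.index = samples["sample_id"]
    return X


def make_contrast(design_columns: Sequence[str], expression: str) -> np.ndarray:
    """Parse a contrast like ``"EtOH_24_untreated - EtOH_0_untreated"``.

    Supports signed terms with optional numeric multipliers, e.g.
    ``"0.5*A + 0.5*B - C"``.
    """
    cols = {c: i for i, c in enumerate(design_columns)}
    vec = np.zeros(len(cols))
    expr = expression.replace("-", "+-").replace(" ", "")
    for term in expr.split("+"):
        if not term:
            continue
        sign = 1.0
        if term.startswith("-"):
            sign, term = -1.0, term[1:]
        if "*" in term:
            coef_str, name = term.split("*", 1)
            coef = float(coef_str)
        else:
            coef, name = 1.0, term
        if name not in cols:
            raise ValueError(f"contrast term {name!r} is not a design column "
                             f"(available: {sorted(cols)})")
        vec[cols[name]] += sign * coef
    return vec


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    coefficients: pd.DataFrame          # miRNA x design columns, log2 units
    contrast_estimates: pd.DataFrame    # miRNA x contrast
    contrast_stdev_unscaled: pd.DataFrame  # sqrt(c'(X'WX)^-1 c)
    s2: pd.Series                       # residual variance per miRNA
    df_residual: float
    ave_expr: pd.Series                 # average log2-cpm


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    keep: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def fit_models(expr: ExpressionMatrix, design_matrix: pd.DataFrame,
               contrasts: Mapping[str, np.ndarray | str] | None = None,
               use_weights: bool = True) -> FitResult:
    """(Weighted) least-squares fit of every miRNA against a shared design."""
    X = design_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n != len(expr.sample_ids):
        raise ValueError("design matrix rows must match samples")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient; aliased columns: "
                         f"{_aliased_columns(X, list(design_matrix.columns))}")
    if n <= p:
        raise ValueError("more coefficients than samples")
    y = expr.values.to_numpy()
    G = y.shape[0]
    names = list(design_matrix.columns)
    cvecs: dict[str, np.ndarray] = {}
    for cname, c in (contrasts or {}).items():
        cvecs[cname] = make_contrast(names, c) if isinstance(c, str) else np.asarray(c, float)

    W = expr.weights.to_numpy() if (use_weights and expr.weights is not None) else None
    beta = np.empty((G, p))
    s2 = np.empty(G)
    cu = {cname: np.empty(G) for cname in cvecs}  # unscaled stdev per contrast
    if W is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = (xtx_inv @ X.T @ y.T).T
        resid = y - beta @ X.T
        s2 = (resid ** 2).sum(axis=1) / (n - p)
        for cname, c in cvecs.items():
            cu[cname][:] = np.sqrt(c @ xtx_inv @ c)
    else:
        for g in range(G):
            w = W[g]
            xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
            b = xtwx_inv @ X.T @ (w * y[g])
            beta[g] = b
            r = y[g] - X @ b
            s2[g] = np.sum(w * r * r) / (n - p)
            for cname, c in cvecs.items():
                cu[cname][g] = np.sqrt(c @ xtwx_inv @ c)

    idx = expr.values.index
    est = pd.DataFrame({cname: beta @ c for cname, c in cvecs.items()}, index=idx)
    return FitResult(
        coefficients=pd.DataFrame(beta, index=idx, columns=names),
        contrast_estimates=est,
        contrast_stdev_unscaled=pd.DataFrame(cu, index=idx),
        s2=pd.Series(s2, index=idx),
        df_residual=float(n - p),
        ave_expr=pd.Series(y.mean(axis=1), index=idx),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class ModerationParams:
    s0_squared: float
    d0: float  # prior degrees of freedom, may be inf


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment estimator of (d0, s0^2) from log residual variances.

    Fits a scaled-F model to the s^2 distribution via the mean and variance
    of e = log(s^2) - digamma(d/2) + log(d/2); zero variances are excluded
    from estimation (they are still shrunk afterwards).
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need >= 2 positive residual variances to moderate")
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    evar_resid = evar - special.polygamma(1, df / 2.0)
    if evar_resid > 0:
        d0 = 2.0 * trigamma_inverse(evar_resid)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess dispersion in log s^2: complete pooling
        d0 = np.inf
        s0 = pos.mean()
    return ModerationParams(float(s0), float(d0))


def posterior_variance(s2: np.ndarray, df: float, prior: ModerationParams) -> np.ndarray:
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_squared, dtype=float)
    return (prior.d0 * prior.s0_squared + df * s2) / (prior.d0 + df)


def moderate(fit: FitResult, d0_override: float | None = None
             ) -> tuple[ModerationParams, pd.DataFrame, pd.DataFrame, float]:
    """Moderated t and two-sided p per contrast.

    Returns (prior, t table, p table, total df).  ``d0_override`` forces the
    prior df (0 recovers the ordinary t exactly).  If every residual variance
    is zero, moderation is skipped with a warning and the ordinary t is
    reported.
    """
    s2 = fit.s2.to_numpy(dtype=float)
    d = fit.df_residual
    if d0_override is not None:
        s0 = float(s2[s2 > 0].mean()) if (s2 > 0).any() else 1.0
        prior = ModerationParams(s0, float(d0_override))
    elif not (s2 > 0).any():
        logger.warning("all residual variances are zero; moderation skipped, ordinary t reported")
        prior = ModerationParams(0.0, 0.0)
    else:
        prior = estimate_prior(s2, d)
    post = posterior_variance(s2, d, prior)
    df_total = d + prior.d0
    if np.isinf(df_total):
        df_total = np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        se = fit.contrast_stdev_unscaled.to_numpy() * np.sqrt(post)[:, None]
        t = fit.contrast_estimates.to_numpy() / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), np.nan, p)
    cols = fit.contrast_estimates.columns
    idx = fit.contrast_estimates.index
    return (prior,
            pd.DataFrame(t, index=idx, columns=cols),
            pd.DataFrame(p, index=idx, columns=cols),
            float(df_total) if not np.isinf(df_total) else np.inf)


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MiRNALinearModel:
    """Moderated-t differential expression model for a log-cpm matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        log-cpm values (with optional precision weights).
    design_matrix : DataFrame
        samples x coefficients, full rank.
    contrasts : mapping of name -> contrast vector or expression string.
    """

    def __init__(self, expr: ExpressionMatrix, design_matrix: pd.DataFrame,
                 contrasts: Mapping[str, np.ndarray | str], use_weights: bool = True):
        self.expr = expr
        self.design_matrix = design_matrix
        self.contrasts = dict(contrasts)
        self.use_weights = use_weights

    @classmethod
    def from_formula(cls, formula: str, expr: ExpressionMatrix,
                     contrasts: Mapping[str, np.ndarray | str], **kwargs) -> "MiRNALinearModel":
        """Build the design matrix from a formula over the sample table."""
        import patsy

        X = patsy.dmatrix(formula, expr.samples, return_type="dataframe")
        X.index = expr.samples["sample_id"]
        return cls(expr, X, contrasts, **kwargs)

    def fit(self, moderate_variances: bool = True, d0_override: float | None = None) -> "DEResults":
        fitres = fit_models(self.expr, self.design_matrix, self.contrasts, self.use_weights)
        if moderate_variances:
            prior, t, p, df_total = moderate(fitres, d0_override=d0_override)
        else:
            prior, t, p, df_total = moderate(fitres, d0_override=0.0)
        adj = p.apply(lambda col: adjust_bh(col.fillna(1.0)), axis=0)
        return DEResults(self, fitres, prior, t, p, adj, df_total)


@dataclass
class DEResults:
    """Estimates, moderated statistics and adjusted p-values per contrast."""

    model: MiRNALinearModel
    fit: FitResult
    prior: ModerationParams
    t: pd.DataFrame
    p: pd.DataFrame
    adj_p: pd.DataFrame
    df_total: float

    @property
    def log2fc(self) -> pd.DataFrame:
        return self.fit.contrast_estimates

    def table(self, contrast: str) -> pd.DataFrame:
        """Tidy per-miRNA result table for one contrast."""
        return pd.DataFrame({
            "log2fc": self.log2fc[contrast],
            "ave_expr": self.fit.ave_expr,
            "t": self.t[contrast],
            "p": self.p[contrast],
            "adj_p": self.adj_p[contrast],
        })

    def call(self, lfc_min: float = 1.5, alpha: float = 0.05,
             fc_only: bool = False) -> dict[str, dict[str, list[str]]]:
        """Up/down calls per contrast: |log2FC| >= lfc_min (boundary included)
        and, unless ``fc_only``, BH-adjusted p <= alpha."""
        if lfc_min < 0 or alpha < 0:
            raise ValueError("thresholds must be >= 0")
        out: dict[str, dict[str, list[str]]] = {}
        for c in self.log2fc.columns:
            lfc = self.log2fc[c]
            sig = pd.Series(True, index=lfc.index) if fc_only else (self.adj_p[c] <= alpha)
            out[c] = {
                "up": list(lfc.index[(lfc >= lfc_min) & sig]),
                "down": list(lfc.index[(lfc <= -lfc_min) & sig]),
            }
        return out

    def summary(self, lfc_min: float = 1.5, alpha: float = 0.05) -> str:
        calls = self.call(lfc_min, alpha)
        lines = [
            "Moderated-t differential expression",
            f"  miRNAs: {len(self.fit.s2)}; residual df: {self.fit.df_residual:g}; "
            f"prior df d0: {self.prior.d0:g}; prior variance s0^2: {self.prior.s0_squared:.4g}",
            f"  calls at |log2FC| >= {lfc_min} and BH p <= {alpha}:",
        ]
        for c, d in calls.items():
            lines.append(f"    {c}: {len(d['up'])} up, {len(d['down'])} down")
        return "\n".join(lines)
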