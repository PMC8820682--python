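"""Weighted Kolmogorov-Smirnov signature enrichment with permutation nulls.

The enrichment score of a miRNA set S in a ranked list of N scored miRNAs is
the extremum (by absolute value) of a running sum that increments by
|score|^p / sum_{hits}|score|^p at members of S and decrements by 1/(N-|S|)
elsewhere; the leading edge is the members encountered at or before (positive
ES) / at or after (negative ES) the extremum.  Nominal p-values come from a
permutation null: "gene_set" mode draws random member sets uniformly from the
panel, "phenotype" mode permutes sample labels and re-ranks.  With n = 3 per
group the phenotype null has at most C(6,3) = 20 distinct relabellings, so
gene-set permutation is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Signature, normalize_mirna_id

logger = logging.getLogger("hepamir")


@dataclass
class OverlapReport:
    signature: str
    overlapping: tuple[str, ...]
    nonoverlapping: tuple[str, ...]

    @property
    def n_overlapping(self) -> int:
        return len(self.overlapping)

    @property
    def n_nonoverlapping(self) -> int:
        return len(self.nonoverlapping)


def signature_overlap(sig: Signature, panel: Sequence[str]) -> OverlapReport:
    """Split signature members into panel-overlapping and nonoverlapping."""
    if panel is None:
        raise ValueError("panel must be provided")
    canon = {normalize_mirna_id(m) for m in panel}
    over = tuple(m for m in sig.members if normalize_mirna_id(m) in canon)
    non = tuple(m for m in sig.members if normalize_mirna_id(m) not in canon)
    return OverlapReport(sig.name, over, non)


def rank_mirnas(scores: pd.Series) -> pd.Series:
    """Sort scores descending; ties broken by id lexicographic order."""
    if scores.nunique() == 1 and len(scores) > 1:
        logger.warning("all ranking scores are equal; order is lexicographic")
    df = pd.DataFrame({"score": scores.astype(float), "id": scores.index.astype(str)})
    df = df.sort_values(["score", "id"], ascending=[False, True], kind="stable")
    return pd.Series(df["score"].to_numpy(), index=df["id"].to_numpy())


def signal_to_noise(expr: ExpressionMatrix, labels: pd.Series,
                    group_a: str, group_b: str) -> pd.Series:
    """Per-miRNA (mean_a - mean_b) / (sd_a + sd_b) over the labelled samples."""
    ids_a = list(labels.index[labels == group_a])
    ids_b = list(labels.index[labels == group_b])
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("signal-to-noise needs >= 2 samples per group")
    a = expr.values[ids_a]
    b = expr.values[ids_b]
    return (a.mean(axis=1) - b.mean(axis=1)) / (a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1))


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("signature has no members in the ranked list")
    if n_hits == n:
        raise ValueError("signature covers the entire ranked list (miss denominator is zero)")
    w = np.abs(scores) ** weight_p
    hit_total = w[hit_mask].sum()
    if hit_total == 0:
        # all member scores are exactly zero: fall back to unweighted hits
        step_hit = hit_mask / n_hits
    else:
        step_hit = np.where(hit_mask, w / hit_total, 0.0)
    step = step_hit - (~hit_mask) / (n - n_hits)
    return np.cumsum(step)


def enrichment_score(ranked: pd.Series, sig: Signature, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray, list[str]]:
    """(ES, running sum, leading edge) for a signature in a ranked list."""
    members = {normalize_mirna_id(m) for m in sig.members}
    ids = [normalize_mirna_id(i) for i in ranked.index]
    hit = np.array([i in members for i in ids])
    run = _running_sum(ranked.to_numpy(dtype=float), hit, weight_p)
    i_ext = int(np.argmax(np.abs(run)))
    es = float(run[i_ext])
    if es >= 0:
        leading = [m for m, h in zip(ranked.index[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [m for m, h in zip(ranked.index[i_ext:], hit[i_ext:]) if h]
    return es, run, leading


def _perm_es_gene_set(scores: np.ndarray, n_hits: int, weight_p: float,
                      n_perm: int, rng: np.random.Generator,
                      chunk: int = 250) -> np.ndarray:
    """Vectorized ES of random member sets drawn uniformly over the panel."""
    n = scores.size
    w = np.abs(scores) ** weight_p
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        mask = np.zeros((b, n), dtype=bool)
        for i in range(b):
            mask[i, rng.choice(n, size=n_hits, replace=False)] = True
        hit_tot = (mask * w).sum(axis=1)
        hit_tot = np.where(hit_tot == 0, 1.0, hit_tot)  # degenerate all-zero scores
        step = np.where(mask, w[None, :] / hit_tot[:, None], -1.0 / (n - n_hits))
        run = np.cumsum(step, axis=1)
        idx = np.argmax(np.abs(run), axis=1)
        out[done:done + b] = run[np.arange(b), idx]
        done += b
    return out


@dataclass
class EnrichmentResults:
    signature: str
    es: float
    nes: float
    p: float
    mode: str
    n_perm: int
    seed: int | None
    leading_edge: tuple[str, ...]
    running_sum: np.ndarray
    perm_es: np.ndarray

    def summary(self) -> str:
        return (
            f"Signature enrichment: {self.signature}\n"
            f"  ES = {self.es:+.3f}, NES = {self.nes:+.3f}, nominal p = {self.p:.4g}\n"
            f"  {self.mode} permutation null, n_perm = {self.n_perm}, seed = {self.seed}\n"
            f"  leading edge ({len(self.leading_edge)}): {', '.join(self.leading_edge)}"
        )


class SignatureEnrichment:
    """GSEA model: a signature tested against a ranked miRNA list.

    Use the constructor with a precomputed ranking (gene_set mode), or
    :meth:`from_expression` with labelled samples for phenotype mode.
    """

    def __init__(self, ranking: pd.Series, signature: Signature,
                 weight_p: float = 1.0, mode: str = "gene_set",
                 n_perm: int = 1000, seed: int | None = None):
        if mode not in {"gene_set", "phenotype"}:
            raise ValueError(f"unknown permutation mode {mode!r}")
        if mode == "phenotype":
            raise ValueError("phenotype mode requires from_expression()")
        if seed is None:
            raise ValueError("a seed is required for the permutation null")
        self.ranking = rank_mirnas(ranking)
        self.signature = signature
        self.weight_p = weight_p
        self.mode = mode
        self.n_perm = n_perm
        self.seed = seed
        self._expr = None

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, labels: pd.Series,
                        group_a: str, group_b: str, signature: Signature,
                        weight_p: float = 1.0, mode: str = "phenotype",
                        n_perm: int = 1000, seed: int | None = None) -> "SignatureEnrichment":
        ranking = signal_to_noise(expr, labels, group_a, group_b)
        obj = cls(ranking, signature, weight_p, "gene_set", n_perm, seed)
        obj.mode = mode
        if mode == "phenotype":
            obj._expr = (expr, labels.copy(), group_a, group_b)
        return obj

    def fit(self) -> EnrichmentResults:
        es, run, leading = enrichment_score(self.ranking, self.signature, self.weight_p)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        if self.mode == "gene_set":
            n_hits = sum(
                1 for i in self.ranking.index
                if normalize_mirna_id(i) in {normalize_mirna_id(m) for m in self.signature.members}
            )
            perm = _perm_es_gene_set(self.ranking.to_numpy(dtype=float), n_hits,
                                     self.weight_p, self.n_perm, rng)
        else:
            perm = self._phenotype_perm_es(rng)
        # nominal p conditions on the sign of the observed ES, as in the
        # canonical two-tailed enrichment null
        same_sign = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
        n_perm_eff = perm.size
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + same_sign.size)
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        return EnrichmentResults(self.signature.name, es, float(nes), float(p),
                                 self.mode, n_perm_eff, self.seed,
                                 tuple(leading), run, perm)

    def _phenotype_perm_es(self, rng: np.random.Generator) -> np.ndarray:
        expr, labels, ga, gb = self._expr
        members = {normalize_mirna_id(m) for m in self.signature.members}
        samp = list(labels.index)
        n_a = int((labels == ga).sum())
        n_distinct = int(_comb(len(samp), n_a))
        vals = expr.values[samp]

        def es_for(ids_a: Sequence[str]) -> float:
            ids_b = [s for s in samp if s not in set(ids_a)]
            a, b = vals[list(ids_a)], vals[ids_b]
            s2n = (a.mean(axis=1) - b.mean(axis=1)) / (a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1))
            ranked = rank_mirnas(s2n)
            hit = np.array([normalize_mirna_id(i) in members for i in ranked.index])
            run = _running_sum(ranked.to_numpy(dtype=float), hit, self.weight_p)
            return float(run[int(np.argmax(np.abs(run)))])

        if n_distinct < 10:
            logger.warning(
                "only %d distinct label permutations; reporting the exact-permutation p",
                n_distinct)
            return np.array([es_for(list(c)) for c in combinations(samp, n_a)])
        out = np.empty(self.n_perm)
        for i in range(self.n_perm):
            out[i] = es_for(list(rng.choice(samp, size=n_a, replace=False)))
        return out


def _comb(n: int, k: int) -> int:
    from math import comb
    return comb(n, k)


def derive_signature(de_table: pd.DataFrame, fdr_max: float = 0.1, top_k: int = 20,
                     name: str = "derived", cell_type: str = "other",
                     direction: str = "enriched") -> Signature | None:
    """Signature from a DE table: FDR < ``fdr_max``, top ``top_k`` by |log2FC|.

    ``de_table`` needs columns "log2fc" and "adj_p" indexed by miRNA id.
    Returns None (with a warning) when nothing passes the FDR filter.
    """
    passed = de_table[de_table["adj_p"] < fdr_max].copy()
    if passed.empty:
        logger.warning("no miRNAs pass FDR < %g; signature %r is empty", fdr_max, name)
        return None
    passed["abs_lfc"] = passed["log2fc"].abs()
    passed = passed.sort_values(["abs_lfc", "log2fc"], ascending=[False, False], kind="stable")
    members = tuple(passed.index[:top_k])
    if len(members) < top_k:
        logger.warning("signature %r has only %d members (< top_k = %d)",
                       name, len(members), top_k)
    return Signature(name, members, cell_type, direction)
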