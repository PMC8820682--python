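"""Synthetic NanoString-like miRNA counts and qPCR CT tables with ground truth.

The generator emulates the statistical situation the downstream analysis
assumes: an overdispersed count panel (negative binomial via a gamma-Poisson
mixture; dispersion phi = 0 degenerates to Poisson, variance = mu + phi*mu^2),
baseline abundances spanning several orders of magnitude (log-normal),
per-diet temporal fold-change patterns planted on selected miRNAs, a set of
miRNAs positively/negatively coupled to a designated reference miRNA
("miR-21" analog) through a shared per-sample latent factor, and an AM21
treatment modeled as a fixed log2 knockdown of the reference that propagates
to its partners through the same factor.

All randomness flows from a single integer seed through deterministic
substreams, so equal (design, config, seed) give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compact import code_from_steps
from .design import UNTREATED, StudyDesign, generate_design
from .io import CountMatrix, validate_qpcr_table

REFERENCE_MIRNA = "miR-21"
POS_PARTNERS = ("miR-340-5p",)
NEG_PARTNERS = ("miR-365", "let-7a", "miR-1224", "miR-146a")


@dataclass(frozen=True)
class PlantedPattern:
    """Per-diet discrete trajectory (one step in {-1,0,+1} per non-baseline
    time) and the per-step log2 effect size delta."""

    steps_by_diet: Mapping[str, tuple[int, ...]]
    delta: float

    def effect(self, diet: str, time_index: int) -> float:
        steps = self.steps_by_diet.get(diet)
        if steps is None:
            return 0.0
        return steps[time_index] * self.delta


def default_planted_patterns(design: StudyDesign, delta: float = 2.0) -> dict[str, PlantedPattern]:
    """The study-condition plant: 25 miRNAs upregulated and 6 downregulated
    at 24 and 72 h in EtOH livers, 10 of the upregulated ones additionally
    decreased at 6 h in CHO livers; everything else null.

    The reference miRNA (miR-21 analog) is one of the EtOH-upregulated set.
    """
    t = len(design.times_h) - 1  # non-baseline steps
    if t < 1:
        raise ValueError("design needs at least one non-baseline time")

    def steps(*vals: int) -> tuple[int, ...]:
        out = list(vals) + [0] * (t - len(vals))
        return tuple(out[:t])

    up_late = steps(0, 1, 1)
    down_late = steps(0, -1, -1)
    cho_dip = steps(-1, 0, 0)
    flat = steps()
    diets = list(design.diets)
    cho, etoh = diets[0], diets[-1] if len(diets) > 1 else diets[0]

    planted: dict[str, PlantedPattern] = {}
    planted[REFERENCE_MIRNA] = PlantedPattern({cho: flat, etoh: up_late}, delta)
    for i in range(14):
        planted[f"miR-sim-up{i+1:02d}"] = PlantedPattern({cho: flat, etoh: up_late}, delta)
    for i in range(10):
        planted[f"miR-sim-upd{i+1:02d}"] = PlantedPattern({cho: cho_dip, etoh: up_late}, delta)
    for i in range(6):
        planted[f"miR-sim-dn{i+1:02d}"] = PlantedPattern({cho: flat, etoh: down_late}, delta)
    return planted


@dataclass
class SyntheticConfig:
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 2.5
    dispersion_phi: float = 0.05
    library_size_range: tuple[float, float] = (5e5, 1.5e6)
    planted_patterns: Mapping[str, PlantedPattern] | None = None  # None -> study defaults
    reference_mirna: str = REFERENCE_MIRNA
    n_pos_corr: int = len(POS_PARTNERS)
    n_neg_corr: int = len(NEG_PARTNERS)
    corr_strength: float = 0.9
    latent_sd_log2: float = 1.0
    am21_knockdown_log2: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_phi < 0:
            raise ValueError("dispersion_phi must be >= 0")
        if not 0 < self.corr_strength <= 1:
            raise ValueError("corr_strength must be in (0, 1]")
        if self.n_pos_corr < 0 or self.n_neg_corr < 0:
            raise ValueError("partner counts must be >= 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < min <= max")

    @classmethod
    def null(cls, **kwargs) -> "SyntheticConfig":
        """A configuration with no planted structure at all."""
        kwargs.setdefault("planted_patterns", {})
        kwargs.setdefault("n_pos_corr", 0)
        kwargs.setdefault("n_neg_corr", 0)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed so recovery tests can score it."""

    pattern_by_mirna_diet: dict[str, dict[str, str]]  # miRNA -> diet -> code e.g. "0UU"
    corr_class: dict[str, str]  # miRNA -> {"pos", "neg"}; reference excluded
    de_effects: dict[tuple[str, str, float], float]  # (miRNA, diet, time_h) -> log2 effect
    reference_mirna: str
    am21_knockdown_log2: float
    loadings: dict[str, float] = field(default_factory=dict)


def _partner_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    pos = [POS_PARTNERS[i] if i < len(POS_PARTNERS) else f"miR-sim-pos{i+1:02d}"
           for i in range(cfg.n_pos_corr)]
    neg = [NEG_PARTNERS[i] if i < len(NEG_PARTNERS) else f"miR-sim-neg{i+1:02d}"
           for i in range(cfg.n_neg_corr)]
    return pos, neg


def panel_mirna_ids(design: StudyDesign, cfg: SyntheticConfig) -> list[str]:
    """Panel id list: planted ids first (reference, partners, pattern
    miRNAs), then null fillers up to ``design.panel_size``."""
    planted = cfg.planted_patterns
    if planted is None:
        planted = default_planted_patterns(design)
    pos, neg = _partner_ids(cfg)
    ids: list[str] = []
    for mid in [cfg.reference_mirna, *pos, *neg, *planted]:
        if mid not in ids:
            ids.append(mid)
    if design.panel_size < len(ids):
        raise ValueError(
            f"panel_size {design.panel_size} is smaller than the "
            f"{len(ids)} planted miRNAs"
        )
    ids += [f"miR-sim-null{i+1:04d}" for i in range(design.panel_size - len(ids))]
    return ids


def generate_counts(design: StudyDesign, cfg: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a NanoString-like count matrix for the full study design.

    Expected count of miRNA i in sample s, conditional on the sample's latent
    factor z_s, is lib_s * p_i * 2^(delta_{i,s} + loading_i * z_s), with
    negative-binomial (gamma-Poisson) sampling noise of dispersion phi.
    """
    samples = generate_design(design)
    planted = cfg.planted_patterns
    if planted is None:
        planted = default_planted_patterns(design)
    pos, neg = _partner_ids(cfg)
    mirnas = panel_mirna_ids(design, cfg)
    n_mir, n_smp = len(mirnas), len(samples)
    nonbase_times = list(design.times_h[1:])

    ss = np.random.SeedSequence(cfg.seed)
    rng_base, rng_lib, rng_latent, rng_noise = (np.random.default_rng(c) for c in ss.spawn(4))

    base_log2 = rng_base.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, size=n_mir)
    w = np.exp2(base_log2)
    p = w / w.sum()

    lo, hi = cfg.library_size_range
    libs = np.round(rng_lib.uniform(lo, hi, size=n_smp))
    z = rng_latent.normal(0.0, cfg.latent_sd_log2, size=n_smp)

    loading = np.zeros(n_mir)
    idx = {m: i for i, m in enumerate(mirnas)}
    loading[idx[cfg.reference_mirna]] = 1.0
    for m in pos:
        loading[idx[m]] = cfg.corr_strength
    for m in neg:
        loading[idx[m]] = -cfg.corr_strength

    # planted diet/time effects (zero at baseline and for unplanted miRNAs)
    delta = np.zeros((n_mir, n_smp))
    de_effects: dict[tuple[str, str, float], float] = {}
    time_index = {t: k for k, t in enumerate(nonbase_times)}
    for m, pat in planted.items():
        i = idx[m]
        for s, row in enumerate(samples.itertuples(index=False)):
            if row.time_h == design.baseline_time:
                continue
            eff = pat.effect(row.diet, time_index[row.time_h])
            delta[i, s] = eff
        for diet in design.diets:
            for t in nonbase_times:
                de_effects[(m, diet, t)] = pat.effect(diet, time_index[t])

    # AM21 knockdown enters through the latent channel so that partners respond
    kd = np.where(samples["treatment"].to_numpy() == "AM21", cfg.am21_knockdown_log2, 0.0)
    log2_mu = np.log2(libs * p[:, None]) + delta + loading[:, None] * (z + kd)[None, :]
    mu = np.exp2(log2_mu)

    if cfg.dispersion_phi > 0:
        lam = rng_noise.gamma(1.0 / cfg.dispersion_phi, mu * cfg.dispersion_phi)
    else:
        lam = mu
    counts = rng_noise.poisson(lam).astype(np.int64)

    cm = CountMatrix(pd.DataFrame(counts, index=mirnas, columns=list(samples["sample_id"])),
                     samples)
    truth = GroundTruth(
        pattern_by_mirna_diet={
            m: {diet: code_from_steps(pat.steps_by_diet.get(diet, (0,) * len(nonbase_times)))
                for diet in design.diets}
            for m, pat in planted.items()
        },
        corr_class={**{m: "pos" for m in pos}, **{m: "neg" for m in neg}},
        de_effects=de_effects,
        reference_mirna=cfg.reference_mirna,
        am21_knockdown_log2=cfg.am21_knockdown_log2,
        loadings={m: float(loading[idx[m]]) for m in [cfg.reference_mirna, *pos, *neg]},
    )
    return cm, truth


def nb_mean_variance(mu: float, phi: float) -> tuple[float, float]:
    """Mean and variance of the generator's count law: var = mu + phi*mu^2."""
    return mu, mu + phi * mu * mu


def generate_qpcr(groups: Sequence[str],
                  effects_log2: Mapping[tuple[str, str], float],
                  ref_mirnas: Sequence[str],
                  n_reps: int = 4,
                  ct_noise_sd: float = 0.2,
                  seed: int = 0,
                  base_ct_range: tuple[float, float] = (22.0, 30.0)) -> pd.DataFrame:
    """Simulate a qPCR CT table with stable endogenous reference miRNAs.

    A planted log2 change of +x for (target, group) lowers that group's mean
    CT by x cycles (one cycle per doubling).  Reference miRNAs must have no
    planted effect in any group.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if not ref_mirnas:
        raise ValueError("at least one reference miRNA is required")
    for (target, group), eff in effects_log2.items():
        if target in ref_mirnas and eff != 0:
            raise ValueError(f"reference miRNA {target!r} has a planted effect in {group!r}")
        if group not in groups:
            raise ValueError(f"effect group {group!r} not in groups")
    targets = list(dict.fromkeys([*ref_mirnas, *(t for t, _ in effects_log2)]))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base_ct = {t: rng.uniform(*base_ct_range) for t in targets}
    rows = []
    for group in groups:
        for target in targets:
            eff = effects_log2.get((target, group), 0.0)
            noise = rng.normal(0.0, ct_noise_sd, size=n_reps) if ct_noise_sd > 0 else np.zeros(n_reps)
            for rep in range(1, n_reps + 1):
                rows.append((group, target, rep, base_ct[target] - eff + noise[rep - 1]))
    return validate_qpcr_table(pd.DataFrame(rows, columns=["group", "target", "replicate", "ct"]))
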