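"""TMM factors, log-cpm and precision weights against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from hepamir import StudyDesign, SyntheticConfig, generate_counts, log_cpm, tmm_factors
from hepamir.normalize import precision_weights

from conftest import make_count_matrix


# ---------------------------------------------------------------------------
# independent step-by-step oracle: plain-loop evaluation of the published
# TMM definition, written without reference to the implementation
# ---------------------------------------------------------------------------

def _avg_rank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _oracle_pair_factor(obs, ref, lib_o, lib_r, m_trim=0.30, a_trim=0.05):
    M, A, V = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lib_o, r / lib_r
            M.append(np.log2(po / pr))
            A.append(0.5 * np.log2(po * pr))
            V.append((lib_o - o) / (lib_o * o) + (lib_r - r) / (lib_r * r))
    if not M or max(abs(m) for m in M) < 1e-6:
        return 1.0
    n = len(M)
    rm, ra = _avg_rank(M), _avg_rank(A)
    lo_m, hi_m = int(np.floor(n * m_trim) + 1), n - int(np.floor(n * m_trim))
    lo_a, hi_a = int(np.floor(n * a_trim) + 1), n - int(np.floor(n * a_trim))
    num = den = 0.0
    for i in range(n):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += M[i] / V[i]
            den += 1.0 / V[i]
    return 2.0 ** (num / den) if den > 0 else 1.0


def oracle_tmm(x, m_trim=0.30, a_trim=0.05):
    libs = x.sum(axis=0).astype(float)
    uq = [np.quantile(x[:, j], 0.75) / libs[j] for j in range(x.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(uq)) for q in uq]))
    raw = [_oracle_pair_factor(x[:, j], x[:, ref], libs[j], libs[ref], m_trim, a_trim)
           for j in range(x.shape[1])]
    geo = np.exp(np.mean(np.log(raw)))
    return np.array(raw) / geo, ref


def oracle_log_cpm(x, libs, factors, prior=0.5):
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = np.log2((x[i, j] + prior) / (libs[j] * factors[j] + 2 * prior) * 1e6)
    return out


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 200, 35, 4, 1000, 60])
        cm = make_count_matrix(np.tile(col[:, None], (1, 4)))
        assert np.allclose(tmm_factors(cm).factors, 1.0)

    def test_scaled_library_gives_unit_factors(self):
        """Doubling every count of one sample changes no M-value, so both
        factors stay 1 (scale invariance of TMM)."""
        col = np.array([10, 200, 35, 4, 1000, 60])
        cm = make_count_matrix(np.column_stack([col, 2 * col, col, col]))
        assert np.allclose(tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_matches_stepwise_oracle_on_toy(self, toy_counts):
        mine = tmm_factors(toy_counts).factors.to_numpy()
        want, _ = oracle_tmm(toy_counts.counts.to_numpy())
        assert np.allclose(mine, want, atol=1e-10)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            x = rng.poisson(rng.uniform(2, 500, size=(20, 1))
                            * rng.uniform(0.5, 2.0, size=(1, 6)))
            if (x.sum(axis=0) == 0).any():
                continue
            cm = make_count_matrix(x)
            mine = tmm_factors(cm).factors.to_numpy()
            want, ref = oracle_tmm(x)
            assert tmm_factors(cm).reference_sample == f"S{ref}"
            assert np.max(np.abs(mine - want)) < 1e-10

    def test_geometric_mean_is_one(self, toy_counts):
        f = tmm_factors(toy_counts).factors.to_numpy()
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_single_sample_rejected(self):
        cm = make_count_matrix([[1], [2]])
        with pytest.raises(ValueError, match="2 samples"):
            tmm_factors(cm)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        cm = make_count_matrix([[0, 0], [999_998, 999_998],
                                [1, 1], [1, 1]])
        # library is exactly 1e6 per sample; count 0, prior .5 -> ~ -1.000
        em = log_cpm(cm, None, prior=0.5)
        assert em.values.iloc[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-12)
        assert em.values.iloc[0, 0] == pytest.approx(-1.0, abs=2e-6)

    def test_matches_formula_oracle(self, toy_counts):
        f = tmm_factors(toy_counts)
        em = log_cpm(toy_counts, f)
        want = oracle_log_cpm(toy_counts.counts.to_numpy(),
                              toy_counts.library_sizes.to_numpy(dtype=float),
                              f.factors.to_numpy())
        assert np.max(np.abs(em.values.to_numpy() - want)) < 1e-12

    def test_library_doubling_shift_bounded_by_prior_effect(self, rng):
        """For libraries >= 1e5, doubling all counts of a sample moves its
        log-cpm by at most 0.01 (the prior's O(1/lib) effect)."""
        x = rng.poisson(50, size=(40, 3)) + 1
        x[0] = [40_000, 40_000, 40_000]  # push library over 1e5
        cm = make_count_matrix(x)
        cm2 = make_count_matrix(np.column_stack([x[:, 0] * 2, x[:, 1], x[:, 2]]))
        a = log_cpm(cm, None).values.iloc[:, 0]
        b = log_cpm(cm2, None).values.iloc[:, 0]
        assert np.max(np.abs(a - b)) < 0.01

    def test_monotone_within_sample(self, toy_counts):
        em = log_cpm(toy_counts, None)
        col = toy_counts.counts.iloc[:, 0]
        vals = em.values.iloc[:, 0]
        for i in range(len(col)):
            for j in range(len(col)):
                if col.iloc[i] > col.iloc[j]:
                    assert vals.iloc[i] > vals.iloc[j]

    def test_nonpositive_prior_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="prior"):
            log_cpm(toy_counts, None, prior=0.0)


class TestPrecisionWeights:
    @staticmethod
    def _design(samples):
        groups = samples["diet"].astype(str)
        X = pd.get_dummies(groups, dtype=float)
        X.index = samples["sample_id"]
        return X

    def test_weights_positive_finite(self):
        design = StudyDesign(times_h=(0, 24), treatments=("untreated",),
                             treatment_times_h=(0,), n_reps=4, panel_size=80)
        cm, _ = generate_counts(design, SyntheticConfig.null(seed=2))
        f = tmm_factors(cm)
        em = precision_weights(cm, f, self._design(cm.samples))
        w = em.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()

    def test_homoskedastic_data_gets_near_uniform_weights(self):
        """Equal-abundance Poisson panel: weights vary < 20% across deciles."""
        design = StudyDesign(times_h=(0, 24), treatments=("untreated",),
                             treatment_times_h=(0,), n_reps=6, panel_size=200)
        cfg = SyntheticConfig.null(dispersion_phi=0.0, baseline_sd_log2=0.05,
                                   library_size_range=(1e6, 1e6), seed=4)
        cm, _ = generate_counts(design, cfg)
        em = precision_weights(cm, tmm_factors(cm), self._design(cm.samples))
        w = em.weights.to_numpy().mean(axis=1)
        order = np.argsort(em.values.to_numpy().mean(axis=1))
        lo = w[order[:20]].mean()
        hi = w[order[-20:]].mean()
        assert abs(hi / lo - 1) < 0.2

    def test_low_abundance_overdispersed_mirnas_downweighted(self):
        design = StudyDesign(times_h=(0, 24), treatments=("untreated",),
                             treatment_times_h=(0,), n_reps=6, panel_size=300)
        cfg = SyntheticConfig.null(dispersion_phi=0.2, baseline_sd_log2=2.5, seed=6)
        cm, _ = generate_counts(design, cfg)
        em = precision_weights(cm, tmm_factors(cm), self._design(cm.samples))
        mean_w = em.weights.to_numpy().mean(axis=1)
        abundance = em.values.to_numpy().mean(axis=1)
        order = np.argsort(abundance)
        dec = len(order) // 10
        assert np.median(mean_w[order[:dec]]) < np.median(mean_w[order[-dec:]])

    def test_no_replication_rejected(self):
        cm = make_count_matrix(np.ones((5, 2), dtype=int),
                               diets=["CHO", "EtOH"])
        X = self._design(cm.samples)
        with pytest.raises(ValueError, match="replication"):
            precision_weights(cm, tmm_factors(cm), X)
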