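"""Generator tests: template library, Poisson sampler, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import trapezoid

from taskphase import synthetic as syn


class TestTemplateLibrary:
    def test_unit_peak_normalization(self, templates):
        assert templates.profiles.shape == (5, 251)
        assert np.all(templates.profiles >= 0)
        np.testing.assert_allclose(templates.profiles.max(axis=1), 1.0)

    def test_peak_times_strictly_increasing(self, templates):
        assert np.all(np.diff(templates.peak_times_ms) > 0)

    def test_ramp_peaks_at_expected_switch(self, templates):
        # middle template rises toward the 1000 ms stimulus switch, then decays
        ramp = templates.profiles[2]
        peak = syn.GRID_MS[np.argmax(ramp)]
        assert 800 <= peak <= 1200
        pre = ramp[syn.GRID_MS <= 900]
        assert np.all(np.diff(pre) > 0)  # monotone rise before the switch

    def test_wrong_grid_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.make_template_library(np.arange(0, 1000, 8.0))


class TestPoissonSampler:
    def test_zero_rate_gives_no_spikes(self):
        assert syn.sample_inhomogeneous_poisson(np.zeros(251), rng=0).size == 0

    def test_determinism_under_fixed_seed(self):
        rate = np.full(251, 7.0)
        a = syn.sample_inhomogeneous_poisson(rate, gain=1.3, rng=99)
        b = syn.sample_inhomogeneous_poisson(rate, gain=1.3, rng=99)
        np.testing.assert_array_equal(a, b)

    def test_counts_match_analytic_poisson_mean(self):
        # constant 10 spikes/s over 2 s -> mean 20, var 20 (closed form)
        rate = np.full(251, 10.0)
        rng = np.random.default_rng(5)
        counts = [syn.sample_inhomogeneous_poisson(rate, rng=rng).size
                  for _ in range(1000)]
        mean = np.mean(counts)
        se = np.sqrt(20.0 / 1000)
        assert abs(mean - 20.0) < 3 * se
        # variance should also be Poisson-like
        assert 0.8 * 20 < np.var(counts) < 1.2 * 20

    def test_spikes_stay_inside_window(self):
        rate = np.full(251, 30.0)
        s = syn.sample_inhomogeneous_poisson(rate, rng=3)
        assert s.min() >= 0 and s.max() <= 2000

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.sample_inhomogeneous_poisson(np.full(251, -1.0), rng=0)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        syn.SyntheticConfig().validate()

    @pytest.mark.parametrize("kwargs", [
        {"trials_per_condition": 1},
        {"baseline_rate": -1.0},
        {"coupling_same_group": 1.5},
        {"coupling_cross_population": 0.5, "coupling_same_group": 0.3},
        {"peak_jitter_sd_ms": -5.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(syn.ConfigurationError):
            syn.SyntheticConfig(**kwargs).validate()


def _counts_by_unit(spikes, cfg):
    """units x (4 * trials) full-window count matrix, conditions concatenated."""
    units = sorted(spikes["unit_id"].unique())
    out = np.zeros((len(units), 4 * cfg.trials_per_condition))
    grouped = spikes.groupby(["unit_id", "condition_code", "trial_index"]).size()
    for i, u in enumerate(units):
        for c, cond in enumerate(syn.CONDITIONS):
            for t in range(cfg.trials_per_condition):
                out[i, c * cfg.trials_per_condition + t] = grouped.get((u, cond, t), 0)
    return units, out


class TestSamplePopulation:
    def test_determinism_identical_tables(self):
        cfg = syn.SyntheticConfig(phase_tuned_per_template=3, n_stimulus_selective=2,
                                  n_junk=1, trials_per_condition=4, seed=7)
        s1, t1 = syn.sample_population(cfg)
        s2, t2 = syn.sample_population(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.units, t2.units)

    def test_every_unit_has_ground_truth(self, small_population):
        cfg, spikes, truth = small_population
        expected = cfg.n_sessions * (
            cfg.phase_tuned_per_template * len(cfg.template_ids)
            + cfg.n_stimulus_selective + cfg.n_junk)
        assert len(truth.units) == expected
        assert truth.units["unit_id"].is_unique

    def test_phase_tuned_rate_profiles_condition_invariant(self, small_population):
        cfg, _, truth = small_population
        tuned = truth.units[truth.units["unit_class"] == "phase_tuned"]
        profs = syn.unit_rate_profile(tuned.iloc[0], cfg)
        ref = profs[syn.CONDITIONS[0]]
        for cond in syn.CONDITIONS[1:]:
            np.testing.assert_array_equal(profs[cond], ref)

    def test_uncoupled_units_have_near_zero_count_correlation(self):
        cfg = syn.SyntheticConfig(
            phase_tuned_per_template=4, n_stimulus_selective=0, n_junk=0,
            trials_per_condition=60, template_ids=(0, 1, 2, 3, 4),
            coupling_same_group=0.0, coupling_cross_population=0.0,
            gain_sd=0.0, peak_jitter_sd_ms=0.0, amplitude_sd=0.0, seed=21,
        )
        spikes, _ = syn.sample_population(cfg)
        _, counts = _counts_by_unit(spikes, cfg)
        C = np.corrcoef(counts)
        rs = C[np.triu_indices_from(C, k=1)]
        assert rs.size >= 100
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) < 3 * se

    def test_planted_coupling_orders_count_correlations(self):
        # same-template pairs must correlate more than temporal-distance-2 pairs
        cfg = syn.SyntheticConfig(
            phase_tuned_per_template=8, n_stimulus_selective=0, n_junk=0,
            trials_per_condition=200, template_ids=(0, 1, 2),
            coupling_same_group=0.3, coupling_decay=0.5, gain_sd=0.4,
            peak_jitter_sd_ms=0.0, amplitude_sd=0.0, seed=22,
        )
        spikes, truth = syn.sample_population(cfg)
        units, counts = _counts_by_unit(spikes, cfg)
        tpl = truth.units.set_index("unit_id")["template_id"]
        C = np.corrcoef(counts)
        same, far = [], []
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                d = abs(int(tpl[units[i]]) - int(tpl[units[j]]))
                (same if d == 0 else far if d == 2 else []).append(C[i, j])
        assert np.mean(same) > np.mean(far)
        # Monte-Carlo oracle at 10x trials on the latent/count model agrees
        oracle_same, oracle_far = _count_correlation_oracle(cfg, truth, n_trials=2000)
        assert oracle_same > oracle_far
        assert abs(np.mean(same) - oracle_same) < 0.03

    def test_infeasible_covariance_reported(self):
        cfg = syn.SyntheticConfig(coupling_same_group=0.0,
                                  coupling_cross_population=0.2)
        with pytest.raises(syn.ConfigurationError):
            syn.sample_population(cfg)


def _count_correlation_oracle(cfg, truth, n_trials):
    """Independent count-level oracle: sample counts directly from the
    latent-gain model (no spike times) and return mean correlations for
    same-template and distance-2 pairs."""
    rng = np.random.default_rng(999)
    tuned = truth.units[truth.units["unit_class"] == "phase_tuned"]
    mus = []
    tpls = []
    for _, row in tuned.iterrows():
        prof = syn.unit_rate_profile(row, cfg)[syn.CONDITIONS[0]]
        mus.append(trapezoid(prof, syn.GRID_MS) / 1000.0)
        tpls.append(int(row["template_id"]))
    mus, tpls = np.array(mus), np.array(tpls)
    s = np.sqrt(cfg.coupling_same_group)
    groups = sorted(set(tpls))
    G = np.array([[cfg.coupling_decay ** abs(a - b) for b in groups] for a in groups])
    evals, evecs = np.linalg.eigh(G)
    A = evecs * np.sqrt(np.clip(evals, 0, None))
    z = rng.standard_normal((n_trials, len(groups))) @ A.T
    eps = rng.standard_normal((n_trials, len(mus)))
    latent = s * z[:, [groups.index(t) for t in tpls]] + np.sqrt(1 - s**2) * eps
    gains = np.exp(cfg.gain_sd * latent - 0.5 * cfg.gain_sd**2)
    counts = rng.poisson(gains * mus[None, :])
    C = np.corrcoef(counts.T)
    same, far = [], []
    for i in range(len(mus)):
        for j in range(i + 1, len(mus)):
            d = abs(tpls[i] - tpls[j])
            (same if d == 0 else far if d == 2 else []).append(C[i, j])
    return float(np.mean(same)), float(np.mean(far))
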