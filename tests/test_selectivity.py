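"""Poisson-GLM selectivity: LOO oracle, permutation calibration, assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from egoallo.selectivity import (
    KEY_WINDOWS,
    CountMatrix,
    assign_best_variable,
    count_spikes,
    fit_variable_glm,
    loo_cv_loglik,
    permutation_test,
    selectivity_timecourse,
    sliding_windows,
    warped_windows,
)
from egoallo.simulate import SpikeData, TuningSpec, generate_neuron


def _cm(counts, start=None, direction=None, target=None):
    n = len(counts)
    labels = pd.DataFrame({
        "start_port": start if start is not None else np.zeros(n, int),
        "direction": direction if direction is not None else np.zeros(n, int),
        "target_port": target if target is not None else np.zeros(n, int),
    })
    return CountMatrix(neuron_id=0, window=("t_go", 0.0, 0.3),
                       counts=np.asarray(counts), labels=labels,
                       trial_ids=np.arange(n))


def brute_force_loo(y, codes):
    """Oracle: refit level means with trial i held out, accumulate Poisson LL."""
    y = np.asarray(y, float)
    ll = 0.0
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        same = mask & (codes == codes[i])
        pred = y[same].mean()
        pred = max(pred, 1e-6)
        ll += y[i] * np.log(pred) - pred - gammaln(y[i] + 1)
    return ll


class TestLooOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 50)
        codes = rng.integers(0, 4, n)
        # ensure every level has >= 2 trials
        codes[:8] = np.repeat(np.arange(4), 2)
        y = rng.poisson(3.0, n)
        assert np.isclose(loo_cv_loglik(y.astype(float), codes, 4),
                          brute_force_loo(y, codes), rtol=0, atol=1e-10)

    def test_level_with_one_trial_rejected(self):
        y = np.array([1.0, 2.0, 3.0])
        codes = np.array([0, 0, 1])
        with pytest.raises(ValueError):
            loo_cv_loglik(y, codes, 2)


class TestCounting:
    def test_direct_count(self, reference_trials):
        tr = reference_trials.iloc[0]
        spikes = SpikeData(0, [np.array([tr.t_go + 0.1, tr.t_go + 0.2])]
                           + [np.empty(0)] * (len(reference_trials) - 1))
        cm = count_spikes(spikes, reference_trials, ("t_go", 0.0, 0.3))
        assert cm.counts[0] == 2
        assert cm.counts[1:].sum() == 0

    def test_causal_convention_half_open(self, reference_trials):
        """(t0, t1]: a spike exactly at window start is excluded, at end included."""
        tr = reference_trials.iloc[0]
        spikes = SpikeData(0, [np.array([tr.t_go, tr.t_go + 0.3])]
                           + [np.empty(0)] * (len(reference_trials) - 1))
        cm = count_spikes(spikes, reference_trials, ("t_go", 0.0, 0.3))
        assert cm.counts[0] == 1

    def test_sliding_window_at_zero_equals_fixed_precue(self, reference_trials):
        w = sliding_windows("t_cue", 0.0, 0.0)[0]
        assert w == ("t_cue", -0.3, 0.0)

    def test_warped_window_layout(self, reference_trials):
        w = warped_windows(reference_trials.iloc[0])
        assert len(w) == 14
        starts = [a for a, b in w]
        assert all(np.diff(starts) > 0)
        tr = reference_trials.iloc[0]
        assert np.isclose(w[3][0], tr.t_cue)        # first cue->go window
        assert np.isclose(w[6][0], tr.t_go)
        assert np.isclose(w[10][1], tr.t_arrival)


class TestGlmAndPermutation:
    def test_constant_counts_per_level(self):
        # all counts equal within level -> LOO mean equals level mean
        counts = np.array([2, 2, 2, 5, 5, 5], float)
        codes = np.array([0, 0, 0, 1, 1, 1])
        ll = loo_cv_loglik(counts, codes, 2)
        expected = sum(c * np.log(m) - m - gammaln(c + 1)
                       for c, m in zip(counts, [2, 2, 2, 5, 5, 5]))
        assert np.isclose(ll, expected)

    def test_independent_counts_r2_near_zero(self, rng):
        r2s = []
        for _ in range(50):
            cm = _cm(rng.poisson(4, 96), direction=np.tile(np.arange(6), 16))
            r2s.append(fit_variable_glm(cm, "direction").r2)
        assert np.mean(r2s) < 0.1    # ~(L-1)/n upward bias only

    def test_deterministic_tuning_p_zero(self):
        direction = np.tile(np.arange(6), 10)
        counts = direction * 5      # counts a noiseless function of the label
        cm = _cm(counts, direction=direction)
        res = permutation_test(cm, "direction", n_perm=200, seed=0)
        assert res.p_perm == 0.0

    def test_type_i_error_controlled(self, rng):
        """Null neurons: permutation p < alpha in about alpha of cases."""
        alpha = 0.05
        hits, n_sim = 0, 120
        for _ in range(n_sim):
            cm = _cm(rng.poisson(3, 96), direction=np.tile(np.arange(6), 16))
            res = permutation_test(cm, "direction", n_perm=200, seed=rng)
            if res.p_perm < alpha:
                hits += 1
        # binomial 99% upper bound around alpha
        from scipy import stats
        ub = stats.binom.ppf(0.995, n_sim, alpha)
        assert hits <= ub

    def test_permutation_reproducible(self):
        cm = _cm(np.random.default_rng(0).poisson(3, 48),
                 direction=np.tile(np.arange(6), 8))
        p1 = permutation_test(cm, "direction", n_perm=300, seed=42).p_perm
        p2 = permutation_test(cm, "direction", n_perm=300, seed=42).p_perm
        assert p1 == p2


class TestAssignment:
    def _res(self, p, ll=0.0):
        from egoallo.selectivity import GlmResult
        return GlmResult("x", np.arange(2), np.zeros(2), 0.0, ll, p_perm=p)

    def test_unique_minimum(self):
        glms = {"start": self._res(0.002), "direction": self._res(0.5),
                "target": self._res(0.5)}
        assert assign_best_variable(glms) == "start"

    def test_tie_broken_by_cv_loglik(self):
        glms = {"start": self._res(0.0, ll=-100.0),
                "direction": self._res(0.0, ll=-90.0),
                "target": self._res(0.3, ll=-80.0)}
        assert assign_best_variable(glms) == "direction"

    def test_below_threshold_is_none(self):
        glms = {"start": self._res(0.2), "direction": self._res(0.9),
                "target": self._res(0.05)}
        assert assign_best_variable(glms, alpha=0.01) == "none"


class TestTimecourse:
    def test_direction_neuron_best_post_cue(self, reference_trials):
        spec = TuningSpec("direction", baseline_hz=6.0,
                          params={"pref_deg": 0.0, "sigma_deg": 40.0,
                                  "depth": 3.0})
        nrn = generate_neuron(spec, reference_trials, seed=2)
        tc = selectivity_timecourse(
            nrn, reference_trials,
            alignments={"t_go": (0.0, 0.3)}, step=0.15)
        assert (tc.best == "direction").mean() > 0.5
        assert (tc.r2_direction > tc.r2_start).all()

    def test_strong_direction_glm_beats_others(self, reference_trials):
        spec = TuningSpec("direction", baseline_hz=8.0,
                          params={"pref_deg": 120.0, "sigma_deg": 40.0,
                                  "depth": 3.0})
        nrn = generate_neuron(spec, reference_trials, seed=3)
        cm = count_spikes(nrn, reference_trials, KEY_WINDOWS["go"])
        r2 = {v: fit_variable_glm(cm, v).r2
              for v in ("start", "direction", "target")}
        assert r2["direction"] > r2["start"]
        assert r2["direction"] > r2["target"]


class TestPopulationFractions:
    def test_sequential_fractions_ordered(self, small_mixed_population):
        """Start neurons dominate pre-cue, direction at go, target at arrival."""
        from egoallo.selectivity import population_selectivity_fractions
        trials, neurons = small_mixed_population
        tab = population_selectivity_fractions(neurons, trials, n_perm=300,
                                               seed=3)
        f = tab.set_index(["window", "variable"]).fraction
        assert f[("pre_cue", "start")] > f[("pre_cue", "target")]
        assert f[("go", "direction")] >= f[("go", "target")]
        assert f[("arrival", "target")] > f[("arrival", "start")]
        assert ((tab.ci_low <= tab.fraction)
                & (tab.fraction <= tab.ci_high)).all()
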