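"""Tuning geometry: preferred direction/position, correlations, switch time."""

import numpy as np
import pytest

from egoallo.selectivity import KEY_WINDOWS
from egoallo.simulate import SpikeData, TuningSpec, generate_neuron
from egoallo.tuning import (
    TuningCurve,
    causal_half_gaussian_kernel,
    fisher_z_population_test,
    is_downward,
    is_horizontal,
    map_rate_heatmap,
    peth,
    preferred_direction,
    preferred_position,
    start_target_correlation,
    switch_time,
    tuning_curve,
)

DIRS = np.array([0, 60, 120, 180, 240, 300])


def _curve(rates, levels=DIRS, variable="direction"):
    rates = np.asarray(rates, float)
    return TuningCurve(variable=variable, levels=np.asarray(levels),
                       rates_hz=rates, n_trials=np.full(len(rates), 10))


class TestPreferredDirection:
    def test_single_active_direction(self):
        ang, norm = preferred_direction(_curve([5, 0, 0, 0, 0, 0]))
        assert np.isclose(ang % 360, 0.0)

    def test_symmetric_rates_undefined(self):
        ang, norm = preferred_direction(_curve([2, 2, 2, 2, 2, 2]))
        assert np.isnan(ang) and norm == 0.0

    def test_explicit_vector_sum(self):
        # rates 2 at 0 deg, 1 at each of +/-60 deg -> resultant along 0 deg
        ang, _ = preferred_direction(_curve([2, 1, 0, 0, 0, 1]))
        assert np.isclose(ang % 360, 0.0, atol=1e-9)

    def test_equivariance_under_rotation(self):
        rates = np.array([3.0, 2.0, 1.0, 0.5, 1.0, 2.0])
        ang0, _ = preferred_direction(_curve(rates))
        rotated = np.roll(rates, 1)      # rates move to labels + 60 deg
        ang1, _ = preferred_direction(_curve(rotated))
        assert np.isclose((ang1 - ang0) % 360, 60.0, atol=1e-9)

    def test_classifiers(self):
        assert is_horizontal(10) and is_horizontal(170)
        assert not is_horizontal(90)
        assert is_downward(270) and is_downward(200)
        assert not is_downward(90)


class TestPreferredPosition:
    def test_argmax_port(self):
        c = _curve([1, 2, 9, 3, 1, 0, 2], levels=np.arange(7),
                   variable="start")
        assert preferred_position(c) == 2

    def test_tie_goes_to_lowest_id(self):
        c = _curve([5, 5, 1, 1, 1, 1, 1], levels=np.arange(7),
                   variable="start")
        assert preferred_position(c) == 0

    def test_recovers_generative_port(self, reference_trials):
        hits = 0
        for seed in range(10):
            spec = TuningSpec("start", baseline_hz=8.0,
                              params={"pref_port": 3, "sigma_mm": 40.0,
                                      "depth": 3.0})
            nrn = generate_neuron(spec, reference_trials, seed=seed)
            c = tuning_curve(nrn, reference_trials, KEY_WINDOWS["pre_cue"],
                             "start")
            hits += preferred_position(c) == 3
        assert hits >= 9


class TestStartTargetCorrelation:
    @staticmethod
    def _current_position_neuron(trials, pref_port, seed, depth=3.0,
                                 base=10.0):
        """Same spatial map applied to the occupied port: start tuning before
        the go sound, target tuning after it."""
        params = {"pref_port": pref_port, "sigma_mm": 40.0, "depth": depth}
        a = generate_neuron(
            TuningSpec("start", base, dict(params)), trials, seed=seed,
            epochs={"start": ("t_start", 0.0, "t_go", 0.0)})
        b = generate_neuron(
            TuningSpec("target", base, dict(params)), trials, seed=seed + 1,
            epochs={"target": ("t_go", 0.0, "t_end", 0.0)})
        trains = [np.sort(np.concatenate([x[x <= g], y[y > g]]))
                  for x, y, g in zip(a.trains, b.trains, trials.t_go)]
        return SpikeData(0, trains)

    def test_identical_spatial_map_high_r(self, reference_trials):
        nrn = self._current_position_neuron(reference_trials, 2, seed=1)
        r = start_target_correlation(nrn, reference_trials)
        assert r > 0.8

    def test_split_half_positive_for_position_neurons(self, reference_trials):
        rs = []
        for seed in range(8):
            nrn = self._current_position_neuron(reference_trials, seed % 7,
                                                seed=10 * seed)
            rs.append(start_target_correlation(nrn, reference_trials,
                                               split_half=True, seed=seed))
        p = fisher_z_population_test(np.array(rs), n_boot=2000, seed=0)
        assert p < 0.01

    def test_independent_tunings_near_zero(self, reference_trials, rng):
        rs = []
        for seed in range(20):
            spec_s = TuningSpec("start", baseline_hz=8.0,
                                params={"pref_port": int(rng.integers(7)),
                                        "sigma_mm": 40.0, "depth": 2.0})
            nrn = generate_neuron(spec_s, reference_trials, seed=seed)
            # target window activity is baseline only -> uncorrelated tuning
            rs.append(start_target_correlation(nrn, reference_trials,
                                               split_half=True, seed=seed))
        assert abs(np.nanmean(rs)) < 0.25


class TestFisherZTest:
    def test_all_strong_positive(self):
        p = fisher_z_population_test(np.full(50, 0.9), n_boot=1000, seed=0)
        assert p == 1.0 / 1000     # floor: no bootstrap mean at or below zero

    def test_symmetric_null_p_near_half(self, rng):
        r = rng.normal(0, 0.2, 200)
        r = np.concatenate([r, -r])      # exactly symmetric around 0
        p = fisher_z_population_test(r, n_boot=2000, seed=1)
        assert 0.3 < p < 0.7

    def test_type_i_error_nominal(self, rng):
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            r = rng.normal(0, 0.3, 30)
            r -= np.tanh(np.arctanh(np.clip(r, -0.99, 0.99)).mean())  # center
            if fisher_z_population_test(r, n_boot=500, seed=rng) < 0.05:
                hits += 1
        assert hits <= 14

    def test_extreme_r_clipped(self):
        p = fisher_z_population_test(np.array([1.0, 0.5, 0.8]), n_boot=500,
                                     seed=0)
        assert 0 < p <= 1


class TestSwitchTime:
    def _switching_neuron(self, trials, t_switch=0.4, seed=0):
        """Start-tuned until go + t_switch, target-tuned afterwards."""
        spec_s = TuningSpec("start", baseline_hz=6.0,
                            params={"pref_port": 1, "sigma_mm": 40.0,
                                    "depth": 3.0})
        spec_t = TuningSpec("target", baseline_hz=6.0,
                            params={"pref_port": 4, "sigma_mm": 40.0,
                                    "depth": 3.0})
        a = generate_neuron(spec_s, trials, seed=seed,
                            epochs={"start": ("t_start", 0.0, "t_go", t_switch)})
        b = generate_neuron(spec_t, trials, seed=seed + 1,
                            epochs={"target": ("t_go", t_switch, "t_end", 0.0)})
        trains = [np.sort(np.concatenate([x, y]))
                  for x, y in zip(a.trains, b.trains)]
        return SpikeData(0, trains)

    def test_recovers_switch_within_tolerance(self, reference_trials):
        """Causal 300 ms windows lag the true switch by about half a width;
        the bias-corrected estimate should sit within ~2 steps of truth."""
        hits = 0
        for seed in range(5):
            nrn = self._switching_neuron(reference_trials, 0.4, seed=2 * seed)
            t = switch_time(nrn, reference_trials, t_range=(0.0, 0.9))
            if t is not None and abs((t - 0.15) - 0.4) <= 0.1:
                hits += 1
        assert hits >= 4

    def test_pure_start_neuron_no_crossing(self, reference_trials):
        spec = TuningSpec("start", baseline_hz=8.0,
                          params={"pref_port": 2, "sigma_mm": 40.0,
                                  "depth": 3.0})
        nrn = generate_neuron(spec, reference_trials, seed=4,
                              epochs={"start": ("t_start", 0.0, "t_end", 0.0)})
        assert switch_time(nrn, reference_trials, t_range=(0.0, 0.6)) is None


class TestMapHeatmap:
    def test_high_n_estimate_near_sample_mean(self, reference_trials):
        spec = TuningSpec("direction", baseline_hz=10.0,
                          params={"pref_deg": 0.0, "sigma_deg": 50.0,
                                  "depth": 2.0})
        nrn = generate_neuron(spec, reference_trials, seed=7)
        out = map_rate_heatmap(nrn, reference_trials)
        assert out.n_trials.min() >= 8
        assert (out.rate_hz > 0).all()

    def test_missing_trajectory_marked_absent(self, reference_trials,
                                              reference_design):
        from egoallo.geometry import session_design
        spec = TuningSpec("none", baseline_hz=5.0)
        nrn = generate_neuron(spec, reference_trials, seed=1)
        full = session_design("distance")   # has long trajectories not run here
        out = map_rate_heatmap(nrn, reference_trials, design=full)
        absent = out[out.n_trials == 0]
        assert len(absent) > 0
        assert absent.rate_hz.isna().all()

    def test_shrinkage_reduces_variance(self, reference_trials, rng):
        """Equal true rates: MAP estimates vary less than raw means."""
        spec = TuningSpec("none", baseline_hz=6.0)
        var_map, var_raw = [], []
        for seed in range(10):
            nrn = generate_neuron(spec, reference_trials, seed=seed)
            shrunk = map_rate_heatmap(nrn, reference_trials, pseudo_trials=10.0)
            raw = map_rate_heatmap(nrn, reference_trials, pseudo_trials=1e-9)
            var_map.append(shrunk.rate_hz.var())
            var_raw.append(raw.rate_hz.var())
        assert np.mean(var_map) < np.mean(var_raw)


class TestPeth:
    def test_kernel_unit_integral_and_causal(self):
        lags, k = causal_half_gaussian_kernel(sd=0.4, dt=0.005)
        assert np.isclose(k.sum() * 0.005, 1.0, atol=0.01)
        assert lags[0] == 0.0          # no mass at negative lags

    def test_delta_spike_causality(self, reference_trials):
        """A single spike contributes no rate before its own time."""
        tr = reference_trials.iloc[0]
        spikes = SpikeData(0, [np.array([tr.t_go + 0.2])]
                           + [np.empty(0)] * (len(reference_trials) - 1))
        grid = np.array([0.0, 0.1, 0.19, 0.21, 0.5])
        out = peth(spikes, reference_trials.head(1), "t_go", grid,
                   group_by="direction")
        rates = out.rate_hz.to_numpy()
        assert np.allclose(rates[:3], 0.0)
        assert rates[3] > 0
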