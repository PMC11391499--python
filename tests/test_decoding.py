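"""Pseudopopulation construction and 2D decoding."""

import numpy as np
import pytest

from egoallo.decoding import (
    build_pseudopopulation,
    chance_error,
    decode_window,
    delta_error_timecourse,
    window_counts,
)
from egoallo.geometry import build_port_wall
from egoallo.selectivity import KEY_WINDOWS
from egoallo.simulate import SpikeData, generate_population, generate_session


@pytest.fixture(scope="module")
def population():
    return generate_population(
        {"start": 25, "direction": 25, "target": 25, "none": 5},
        design="reference", n_trials=480, seed=41,
    )


class TestConstruction:
    def test_pseudo_trial_counts(self, population):
        trials, neurons = population
        for var, n_expected in (("start", 224), ("target", 224),
                                ("direction", 192)):
            pp = build_pseudopopulation(trials, neurons, var, seed=1)
            assert pp.n_per_fold == n_expected
            assert pp.trial_index.shape[1] == 2
            assert pp.trial_index.shape[3] == 32

    def test_bootstrap_unique_fraction(self, population):
        trials, neurons = population
        fracs = [build_pseudopopulation(trials, neurons, "direction",
                                        seed=s).unique_neuron_fraction()
                 for s in range(30)]
        # expected 1-(1-1/n)^n ~ 0.632 for n=80; very loose bounds at small n
        assert 0.5 < np.mean(fracs) < 0.75

    def test_resampling_preserves_condition_means(self, population):
        """Pseudo-trial means per condition track the neuron's true means."""
        trials, neurons = population
        pp = build_pseudopopulation(trials, neurons, "direction", seed=3,
                                    bootstrap_neurons=False)
        counts = window_counts(neurons, trials, KEY_WINDOWS["go"])
        X = np.vstack([c for c in _pseudo(pp, counts)])
        lab = np.concatenate([pp.pseudo_labels()] * 2)
        correct = trials[trials.outcome.eq("correct")]
        for c, d in enumerate(pp.conditions[:3]):
            true_mean = counts[correct.index[correct.direction == d]].mean(0)
            pseudo_mean = X[lab == c].mean(0)
            # bootstrap error scales ~ sqrt(mean/64); allow wide agreement
            resid = np.abs(pseudo_mean - true_mean)
            assert np.median(resid) < 0.5

    def test_ineligible_condition_raises(self, population):
        trials, neurons = population
        bad = trials[trials.direction != 0].reset_index(drop=True)
        sub = [SpikeData(n.neuron_id,
                         [t for i, t in enumerate(n.trains)
                          if trials.direction.iloc[i] != 0], n.meta)
               for n in neurons[:3]]
        small = bad[bad.direction == 60].head(4).reset_index(drop=True)
        tiny = [SpikeData(0, [np.empty(0)] * 4)]
        with pytest.raises(ValueError, match="condition"):
            build_pseudopopulation(small, tiny, "direction")


def _pseudo(pp, counts):
    from egoallo.decoding import pseudo_counts
    X = pseudo_counts(pp, counts)
    return X[0], X[1]


class TestDecoding:
    def test_noiseless_linear_population_decodes_exactly(self):
        """Neurons whose counts are exact linear functions of (x, y) decode
        with error at float tolerance."""
        trials = generate_session("reference", 480, seed=2)
        wall = build_port_wall()
        xy = wall.coordinates()
        rng = np.random.default_rng(0)
        neurons = []
        W = rng.normal(size=(12, 2))
        for k in range(12):
            vals = 5.0 + 0.04 * (xy[trials.start_port.to_numpy()] @ W[k])
            # encode the exact value as a deterministic "count"
            trains = [np.full(max(int(round(v * 100)), 0), tr.t_cue + 0.1)
                      for v, (_, tr) in zip(vals, trials.iterrows())]
            neurons.append(SpikeData(k, trains))
        pp = build_pseudopopulation(trials, neurons, "start", seed=5,
                                    bootstrap_neurons=False)
        res = decode_window(pp, KEY_WINDOWS["post_cue"], n_pcs=4)
        assert res.mean_error < 1e-6 * wall.spacing

    def test_shuffled_labels_at_chance(self, population):
        trials, neurons = population
        rng = np.random.default_rng(7)
        shuffled = trials.copy()
        cols = ["start_port", "direction", "target_port"]
        shuffled[cols] = shuffled[cols].sample(frac=1.0, random_state=3) \
            .to_numpy()
        pp = build_pseudopopulation(shuffled, neurons, "start", seed=9)
        res = decode_window(pp, KEY_WINDOWS["pre_cue"])
        assert res.mean_error > 0.75 * chance_error(pp)

    def test_tuned_population_beats_chance(self, population):
        trials, neurons = population
        pp = build_pseudopopulation(trials, neurons, "direction", seed=11)
        res = decode_window(pp, KEY_WINDOWS["go"])
        assert res.mean_error < 0.75 * chance_error(pp)

    def test_rotation_equivariance(self, population):
        """Rotating the port wall rotates predictions but not errors."""
        trials, neurons = population
        pp = build_pseudopopulation(trials, neurons, "start", seed=13)
        res = decode_window(pp, KEY_WINDOWS["pre_cue"])
        rot = np.deg2rad(60)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        pp.coords = pp.coords @ R.T
        res_rot = decode_window(pp, KEY_WINDOWS["pre_cue"])
        assert np.isclose(res.mean_error, res_rot.mean_error, rtol=1e-6)

    def test_noise_correlations_removed(self, population):
        """Independent per-neuron resampling: near-zero pseudo-trial noise
        correlations between neurons."""
        trials, neurons = population
        pp = build_pseudopopulation(trials, neurons, "direction", seed=17,
                                    bootstrap_neurons=False)
        counts = window_counts(neurons, trials, KEY_WINDOWS["go"])
        X0, _ = _pseudo(pp, counts)
        lab = pp.pseudo_labels()
        resid = np.vstack([X0[lab == c] - X0[lab == c].mean(0)
                           for c in range(len(pp.conditions))])
        C = np.corrcoef(resid.T)
        off = C[np.triu_indices_from(C, k=1)]
        assert abs(np.nanmean(off)) < 0.02


class TestDeltaTimecourse:
    def test_sign_antisymmetry_and_null(self, population):
        trials, neurons = population
        kw = dict(n_pseudo=6, align="t_go", t_range=(0.0, 0.2), step=0.1,
                  n_shuffle=500)
        ab = delta_error_timecourse(trials, neurons, ("direction", "target"),
                                    seed=5, **kw)
        ba = delta_error_timecourse(trials, neurons, ("target", "direction"),
                                    seed=5, **kw)
        assert np.allclose(ab.mean_delta, -ba.mean_delta)
        assert (ab.p_perm >= 1 / 500).all()


class TestCrossWindow:
    def test_diagonal_matches_decode_window_and_null_is_empty(self, population):
        from egoallo.decoding import cross_window_matrix
        trials, neurons = population
        windows = [KEY_WINDOWS["pre_cue"], KEY_WINDOWS["arrival"]]
        mean_map, sig, null = cross_window_matrix(
            trials, neurons, "start", windows, n_pseudo=1, seed=3)
        assert mean_map.shape == (2, 2)
        assert null.shape == (1,)
        # diagonal cells reproduce the plain single-window decoding for the
        # same pseudopopulation draw (shared rng stream)
        rng_check = np.random.default_rng(3)
        pp = build_pseudopopulation(trials, neurons, "start", seed=rng_check)
        res = decode_window(pp, windows[0])
        assert np.isclose(mean_map[0, 0], res.mean_error, rtol=1e-9)
        assert mean_map[0, 0] < chance_error(pp)   # start decodes pre-cue
        assert np.isfinite(mean_map).all()

    def test_shuffled_population_has_empty_contour(self, population):
        from egoallo.decoding import cross_window_matrix
        trials, neurons = population
        shuffled = trials.copy()
        cols = ["start_port", "direction", "target_port"]
        shuffled[cols] = shuffled[cols].sample(frac=1.0, random_state=1) \
            .to_numpy()
        windows = [KEY_WINDOWS["pre_cue"], KEY_WINDOWS["go"]]
        mean_map, sig, _ = cross_window_matrix(
            shuffled, neurons, "start", windows, n_pseudo=5, seed=9)
        assert not sig.any()
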