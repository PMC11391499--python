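"""Pseudopopulation decoding of 2D spatial variables.

Neurons recorded in different sessions are combined into pseudopopulations:
for each neuron, trials are split into 2 folds per condition of the decoded
variable and 32 pseudo-trials per fold per condition are resampled with
replacement, with an independent random stream per neuron so trial-by-trial
noise correlations are destroyed.  With 7 position conditions this yields
224 pseudo-trials per fold, with 6 direction conditions 192.  Neurons are
additionally resampled with replacement (so each pseudopopulation contains
about 63.2% of the unique neurons).

Decoding: spike counts of both folds are combined, z-scored and projected on
the first 4 principal components (fit on train+test jointly, as the source
procedure specifies — a leakage-free variant is available behind a flag);
a multivariate linear regression maps PC scores to the condition's (x, y)
coordinates with 2-fold cross-validation.  The decoding error of a
pseudo-trial is the Euclidean distance between predicted and true
coordinates; central-port ((0,0)-coordinate) conditions are excluded from
mean position-decoding errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .geometry import PortWall, build_port_wall, direction_unit
from .simulate import SpikeData

N_PER_FOLD_PER_CONDITION = 32
N_FOLDS = 2


def variable_conditions(variable: str, trials: pd.DataFrame,
                        wall: PortWall) -> tuple[np.ndarray, np.ndarray]:
    """Condition values and their (x, y) coordinates (mm) for one variable."""
    if variable in ("start", "target"):
        col = "start_port" if variable == "start" else "target_port"
        vals = np.unique(trials[col])
        coords = wall.coordinates()[vals]
    elif variable == "direction":
        vals = np.unique(trials.direction)
        coords = np.stack([wall.spacing * direction_unit(int(d)) for d in vals])
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return vals, coords


@dataclass
class Pseudopopulation:
    variable: str
    conditions: np.ndarray           # condition values
    coords: np.ndarray               # (n_cond, 2) mm
    neuron_draw: np.ndarray          # bootstrap indices into the neuron list
    trial_index: np.ndarray          # (n_neurons, 2, n_cond, 32) trial rows
    neurons: list = field(repr=False, default=None)
    trials: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_per_fold(self) -> int:
        return len(self.conditions) * N_PER_FOLD_PER_CONDITION

    def pseudo_labels(self) -> np.ndarray:
        """Condition index of each pseudo-trial within a fold."""
        return np.repeat(np.arange(len(self.conditions)),
                         N_PER_FOLD_PER_CONDITION)

    def unique_neuron_fraction(self) -> float:
        return len(np.unique(self.neuron_draw)) / len(self.neuron_draw)


def build_pseudopopulation(
    trials: pd.DataFrame, neurons: list[SpikeData], variable: str,
    seed: int | np.random.Generator = 0,
    bootstrap_neurons: bool = True,
    min_trials_per_condition: int = 8,
    wall: PortWall | None = None,
) -> Pseudopopulation:
    """Resample trials per condition into 2 folds of 32 pseudo-trials each.

    Every neuron gets its own random stream for the trial resampling.
    Neurons whose session lacks ``min_trials_per_condition`` correct trials
    in any condition of the variable are ineligible (here all neurons share
    the session, so the check is made once).
    """
    wall = wall or build_port_wall()
    rng = np.random.default_rng(seed)
    correct = trials[trials.outcome.eq("correct")]
    vals, coords = variable_conditions(variable, correct, wall)
    col = {"start": "start_port", "direction": "direction",
           "target": "target_port"}[variable]
    cond_rows = [correct.index[correct[col] == v].to_numpy() for v in vals]
    for v, rows in zip(vals, cond_rows):
        if len(rows) < min_trials_per_condition:
            raise ValueError(
                f"condition {variable}={v} has {len(rows)} "
                f"(<{min_trials_per_condition}) correct trials"
            )
    n = len(neurons)
    draw = bootstrap_draw(rng, n) if bootstrap_neurons else np.arange(n)
    trial_index = np.empty(
        (n, N_FOLDS, len(vals), N_PER_FOLD_PER_CONDITION), dtype=int
    )
    for k in range(n):
        nrng = np.random.default_rng(rng.integers(0, 2**31))  # per-neuron seed
        for c, rows in enumerate(cond_rows):
            perm = nrng.permutation(rows)
            halves = perm[: len(rows) // 2], perm[len(rows) // 2:]
            for f, h in enumerate(halves):
                trial_index[k, f, c] = nrng.choice(
                    h, size=N_PER_FOLD_PER_CONDITION, replace=True
                )
    return Pseudopopulation(variable=variable, conditions=vals, coords=coords,
                            neuron_draw=draw, trial_index=trial_index,
                            neurons=neurons, trials=trials)


def bootstrap_draw(rng: np.random.Generator, n: int) -> np.ndarray:
    """Neuron resampling with replacement; about 1-(1-1/n)^n ~ 63.2% of the
    unique neurons enter each pseudopopulation."""
    return rng.integers(0, n, size=n)


def mean_unique_fraction(n: int, n_resamples: int, seed: int = 0) -> float:
    """Mean unique-neuron fraction over repeated bootstrap draws."""
    rng = np.random.default_rng(seed)
    return float(np.mean([len(np.unique(bootstrap_draw(rng, n))) / n
                          for _ in range(n_resamples)]))


def window_counts(neurons: list[SpikeData], trials: pd.DataFrame,
                  window: tuple) -> np.ndarray:
    """(n_trials, n_neurons) spike counts in (event+o0, event+o1] per trial."""
    event, o0, o1 = window
    t0 = (trials[event] + o0).to_numpy()
    t1 = (trials[event] + o1).to_numpy()
    out = np.zeros((len(trials), len(neurons)))
    for j, nrn in enumerate(neurons):
        for i in range(len(trials)):
            tr = nrn.trains[i]
            out[i, j] = np.searchsorted(tr, t1[i], "right") \
                - np.searchsorted(tr, t0[i], "right")
    return out


def pseudo_counts(pp: Pseudopopulation, counts: np.ndarray) -> np.ndarray:
    """(2, n_pseudo_trials, n_neurons) count tensor for one window."""
    n, _, n_cond, m = pp.trial_index.shape
    out = np.empty((N_FOLDS, n_cond * m, n))
    for k_out, k_src in enumerate(pp.neuron_draw):
        idx = pp.trial_index[k_src]                  # (2, n_cond, 32)
        out[:, :, k_out] = counts[idx.reshape(N_FOLDS, -1), k_src]
    return out


@dataclass
class DecodingResult:
    variable: str
    predicted: np.ndarray        # (2, n_pseudo_trials, 2) xy per fold
    errors: np.ndarray           # (2, n_pseudo_trials)
    mean_error: float            # central-port conditions excluded for positions
    condition_index: np.ndarray


def decode_window(
    pp: Pseudopopulation, window: tuple | np.ndarray, n_pcs: int = 4,
    leakage_free: bool = False,
) -> DecodingResult:
    """2-fold cross-validated linear decoding of (x, y) from one time window.

    ``window`` may be a (event, offset0, offset1) tuple or a precomputed
    (n_trials, n_neurons) count matrix.
    """
    counts = window_counts(pp.neurons, pp.trials, window) \
        if isinstance(window, tuple) else window
    X = pseudo_counts(pp, counts)             # (2, n_pt, N)
    lab = pp.pseudo_labels()
    target = pp.coords[lab]
    preds = np.empty((N_FOLDS, X.shape[1], 2))
    for test in range(N_FOLDS):
        train = 1 - test
        if leakage_free:
            ref = X[train]
        else:
            ref = np.vstack([X[0], X[1]])     # joint z-score + PCA
        mu, sd = ref.mean(0), ref.std(0)
        sd[sd == 0] = 1.0
        pca = PCA(n_components=n_pcs).fit((ref - mu) / sd)
        Ztr = pca.transform((X[train] - mu) / sd)
        Zte = pca.transform((X[test] - mu) / sd)
        reg = LinearRegression().fit(Ztr, target)
        preds[test] = reg.predict(Zte)
    errors = np.linalg.norm(preds - target[None], axis=-1)
    keep = np.ones(X.shape[1], dtype=bool)
    if pp.variable in ("start", "target"):
        keep = np.linalg.norm(target, axis=1) > 1e-9   # drop (0,0) conditions
    return DecodingResult(variable=pp.variable, predicted=preds, errors=errors,
                          mean_error=float(errors[:, keep].mean()),
                          condition_index=lab)


def chance_error(pp: Pseudopopulation) -> float:
    """Mean error of always predicting the centroid of the used conditions."""
    keep = np.ones(len(pp.coords), dtype=bool)
    if pp.variable in ("start", "target"):
        keep = np.linalg.norm(pp.coords, axis=1) > 1e-9
    c = pp.coords[keep]
    return float(np.linalg.norm(c - pp.coords.mean(0), axis=1).mean())


# ---------------------------------------------------------------------------
# time courses and cross-window generalization
# ---------------------------------------------------------------------------

def error_timecourse(
    trials: pd.DataFrame, neurons: list[SpikeData], variable: str,
    n_pseudo: int = 100, align: str = "t_go",
    t_range: tuple[float, float] = (-0.6, 0.9),
    step: float = 0.05, width: float = 0.3,
    n_pcs: int = 4, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_pseudo, n_windows) mean decoding errors in sliding windows."""
    times = np.round(np.arange(t_range[0], t_range[1] + 1e-9, step), 10)
    windows = [(align, t - width, t) for t in times]
    counts = [window_counts(neurons, trials, w) for w in windows]
    rng = np.random.default_rng(seed)
    errs = np.empty((n_pseudo, len(windows)))
    for i in range(n_pseudo):
        pp = build_pseudopopulation(trials, neurons, variable, seed=rng)
        for j, c in enumerate(counts):
            errs[i, j] = decode_window(pp, c, n_pcs=n_pcs).mean_error
    return errs, times


def delta_error_timecourse(
    trials: pd.DataFrame, neurons: list[SpikeData],
    variable_pair: tuple[str, str] = ("direction", "target"),
    n_pseudo: int = 100, n_shuffle: int = 5000, seed: int = 0, **kw,
) -> pd.DataFrame:
    """Paired difference of decoding errors between two spatial variables.

    delta(t) = error_A(t) - error_B(t) per pseudopopulation; positive values
    mean the second variable decodes better.  Significance per window is a
    paired sign-flip permutation across pseudopopulations (two-sided).
    """
    a, b = variable_pair
    # per-variable seeds independent of argument order, so that
    # delta(A, B) == -delta(B, A) exactly
    offs = {"start": 0, "direction": 1, "target": 2}
    err_a, times = error_timecourse(trials, neurons, a, n_pseudo=n_pseudo,
                                    seed=seed * 8 + offs[a], **kw)
    err_b, _ = error_timecourse(trials, neurons, b, n_pseudo=n_pseudo,
                                seed=seed * 8 + offs[b], **kw)
    delta = err_a - err_b
    rng = np.random.default_rng(seed + 2)
    signs = rng.choice([-1.0, 1.0], size=(n_shuffle, n_pseudo))
    null = signs @ delta / n_pseudo                  # (n_shuffle, n_windows)
    obs = delta.mean(0)
    p = (np.abs(null) >= np.abs(obs)[None]).mean(0)
    p = np.maximum(p, 1.0 / n_shuffle)
    return pd.DataFrame({"t": times, "mean_delta": obs, "sd_delta": delta.std(0),
                         "p_perm": p})


def cross_window_matrix(
    trials: pd.DataFrame, neurons: list[SpikeData], variable: str,
    windows: list[tuple], n_pseudo: int = 100, n_pcs: int = 4,
    test_variable: str | None = None, seed: int = 0, alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean decoding error for decoders trained at one window, tested at another.

    Returns (observed W x W mean-error map, significance mask, null extremes).
    With ``test_variable`` the decoder is trained on the pseudopopulation of
    ``variable`` and tested on that of ``test_variable`` (sharing the neuron
    bootstrap), e.g. train on start position, decode target position.

    Significance uses the extreme-pixel permutation test: one label-shuffled
    map per pseudopopulation; because smaller error is better, the extreme
    statistic of each shuffled map is its minimum, and a pixel is significant
    when the observed mean error beats the (1 - alpha) fraction of those null
    extremes.
    """
    rng = np.random.default_rng(seed)
    W = len(windows)
    counts = [window_counts(neurons, trials, w) for w in windows]
    obs = np.zeros((n_pseudo, W, W))
    null_extreme = np.zeros(n_pseudo)
    for i in range(n_pseudo):
        pp_tr = build_pseudopopulation(trials, neurons, variable, seed=rng)
        if test_variable is None:
            pp_te = pp_tr
        else:
            pp_te = build_pseudopopulation(trials, neurons, test_variable,
                                           seed=rng)
            pp_te.neuron_draw = pp_tr.neuron_draw
        shuf = np.zeros((W, W))
        lab = pp_te.pseudo_labels()
        perm = rng.permutation(len(lab))
        for wi in range(W):
            Xtr = pseudo_counts(pp_tr, counts[wi])
            for wj in range(W):
                Xte = pseudo_counts(pp_te, counts[wj])
                obs[i, wi, wj] = _train_test_error(Xtr, Xte, pp_tr, pp_te,
                                                   n_pcs, None)
                shuf[wi, wj] = _train_test_error(Xtr, Xte, pp_tr, pp_te,
                                                 n_pcs, perm)
        null_extreme[i] = shuf.min()
    mean_map = obs.mean(0)
    thresh = np.quantile(null_extreme, alpha)
    sig = mean_map < thresh
    return mean_map, sig, null_extreme


def _train_test_error(Xtr, Xte, pp_tr, pp_te, n_pcs, perm):
    """2-fold error training on Xtr fold f, testing on Xte's other fold."""
    target_tr = pp_tr.coords[pp_tr.pseudo_labels()]
    lab_te = pp_te.pseudo_labels()
    if perm is not None:
        lab_te = lab_te[perm]
    target_te = pp_te.coords[lab_te]
    keep = np.ones(len(lab_te), dtype=bool)
    if pp_te.variable in ("start", "target"):
        keep = np.linalg.norm(target_te, axis=1) > 1e-9
    errs = []
    for test in range(N_FOLDS):
        train = 1 - test
        ref = np.vstack([Xtr[train], Xte[test]])
        mu, sd = ref.mean(0), ref.std(0)
        sd[sd == 0] = 1.0
        pca = PCA(n_components=n_pcs).fit((ref - mu) / sd)
        Ztr = pca.transform((Xtr[train] - mu) / sd)
        Zte = pca.transform((Xte[test] - mu) / sd)
        reg = LinearRegression().fit(Ztr, target_tr)
        pred = reg.predict(Zte)
        e = np.linalg.norm(pred - target_te, axis=1)
        errs.append(e[keep].mean())
    return float(np.mean(errs))
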