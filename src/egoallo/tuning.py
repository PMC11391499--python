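"""Single-neuron tuning descriptions and their population statistics.

Covers peri-event time histograms (causal half-Gaussian smoothing), preferred
direction (rate-weighted vector sum over the six movement directions),
preferred position (argmax port), the start-target tuning correlation and its
cross-time generalization, the start->target encoding switch time, and
shrinkage (MAP) per-trajectory rate maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DIRECTIONS, SessionDesign, direction_unit
from .selectivity import (
    KEY_WINDOWS,
    WARPED_WINDOW_NAMES,
    count_spikes,
    fit_variable_glm,
    sliding_windows,
    warped_rate_matrix,
)
from .simulate import SpikeData

logger = logging.getLogger(__name__)


@dataclass
class TuningCurve:
    variable: str
    levels: np.ndarray
    rates_hz: np.ndarray
    n_trials: np.ndarray


def tuning_curve(spikes: SpikeData, trials: pd.DataFrame, window: tuple,
                 variable: str, trial_mask: np.ndarray | None = None) -> TuningCurve:
    """Mean firing rate (Hz) per level of one spatial variable."""
    cm = count_spikes(spikes, trials, window)
    duration = window[2] - window[1]
    codes, levels = cm.variable_codes(variable)
    y = cm.counts.astype(float)
    if trial_mask is not None:
        y, codes = y[trial_mask], codes[trial_mask]
    n = np.bincount(codes, minlength=len(levels))
    s = np.bincount(codes, weights=y, minlength=len(levels))
    with np.errstate(invalid="ignore"):
        rates = s / n / duration
    return TuningCurve(variable=variable, levels=levels, rates_hz=rates,
                       n_trials=n)


# ---------------------------------------------------------------------------
# spatial preference
# ---------------------------------------------------------------------------

def preferred_direction(curve: TuningCurve) -> tuple[float, float]:
    """Angle (deg) of the rate-weighted vector sum of the six directions.

    Returns (angle, resultant length in Hz).  A zero resultant (e.g. equal
    rates in all directions) leaves the angle undefined: returns (nan, 0).
    """
    if len(curve.levels) != 6:
        raise ValueError("preferred_direction needs all 6 direction levels")
    vec = sum(r * direction_unit(int(d))
              for d, r in zip(curve.levels, curve.rates_hz))
    norm = float(np.linalg.norm(vec))
    if norm < 1e-12:
        logger.warning("zero resultant: preferred direction undefined")
        return float("nan"), 0.0
    return float(np.rad2deg(np.arctan2(vec[1], vec[0])) % 360.0), norm


def is_horizontal(angle_deg: float) -> bool:
    """Within +/-45 deg of rightward (0) or leftward (180)."""
    a = angle_deg % 180.0
    return a <= 45.0 or a >= 135.0


def is_downward(angle_deg: float) -> bool:
    """Within +/-90 deg of straight down (270)."""
    return 180.0 < angle_deg % 360.0 < 360.0


def preferred_position(curve: TuningCurve) -> int:
    """Port with the highest mean rate; ties go to the lowest port id."""
    best = np.flatnonzero(curve.rates_hz == np.nanmax(curve.rates_hz))
    if len(best) > 1:
        logger.info("preferred position tie among ports %s",
                    curve.levels[best].tolist())
    return int(curve.levels[best[0]])


# ---------------------------------------------------------------------------
# start-target tuning correlation
# ---------------------------------------------------------------------------

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        logger.warning("tuning correlation undefined (zero variance)")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def start_target_correlation(
    spikes: SpikeData, trials: pd.DataFrame,
    window_pair: tuple = (KEY_WINDOWS["pre_cue"], KEY_WINDOWS["arrival"]),
    split_half: bool = False,
    seed: int | np.random.Generator = 0,
) -> float:
    """Pearson r between start-port tuning (first window) and target-port
    tuning (second window).

    With ``split_half``, trials are randomly halved; start tuning from one
    half is correlated with target tuning from the other (both directions,
    averaged) so that shared trial noise cannot inflate the correlation.
    """
    w_start, w_target = window_pair
    if not split_half:
        c_s = tuning_curve(spikes, trials, w_start, "start")
        c_t = tuning_curve(spikes, trials, w_target, "target")
        return _safe_corr(c_s.rates_hz, c_t.rates_hz)
    rng = np.random.default_rng(seed)
    n = int(trials.outcome.eq("correct").sum())
    half = rng.permutation(n) < n // 2
    rs = []
    for m_s, m_t in ((half, ~half), (~half, half)):
        c_s = tuning_curve(spikes, trials, w_start, "start", trial_mask=m_s)
        c_t = tuning_curve(spikes, trials, w_target, "target", trial_mask=m_t)
        rs.append(_safe_corr(c_s.rates_hz, c_t.rates_hz))
    return float(np.nanmean(rs))


def fisher_z_population_test(
    r_values: np.ndarray, n_boot: int = 10_000,
    seed: int | np.random.Generator = 0, bonferroni: int = 1,
) -> float:
    """One-sided bootstrap test that the population mean atanh(r) exceeds 0.

    p is the fraction of bootstrap means lying at or below zero, floored at
    1/n_boot (the minimum reportable p), then Bonferroni-multiplied.
    """
    rng = np.random.default_rng(seed)
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    clip = 1 - 1e-10
    if np.any(np.abs(r) >= 1):
        logger.warning("clipping %d correlation(s) at +/-1",
                       int(np.sum(np.abs(r) >= 1)))
    z = np.arctanh(np.clip(r, -clip, clip))
    idx = rng.integers(0, len(z), size=(n_boot, len(z)))
    means = z[idx].mean(axis=1)
    p = max(float(np.mean(means <= 0)), 1.0 / n_boot) * bonferroni
    return min(p, 1.0)


def tuning_correlation_matrix(
    neurons: list[SpikeData], trials: pd.DataFrame,
    var_row: str = "start", var_col: str = "target",
    n_boot: int = 1000, alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-time mean split-half tuning correlation over the warped windows.

    Entry (i, j) is the mean over neurons of the correlation between
    ``var_row`` tuning at warped window i (one half of trials) and
    ``var_col`` tuning at window j (the other half), averaged over the two
    half assignments.  The second return is a boolean significance mask from
    the Fisher-z bootstrap with Bonferroni correction over all cells.
    """
    rng = np.random.default_rng(seed)
    T = len(WARPED_WINDOW_NAMES)
    col = {"start": "start_port", "direction": "direction",
           "target": "target_port"}
    per_neuron = np.full((len(neurons), T, T), np.nan)
    for k, nrn in enumerate(neurons):
        rates, labels = warped_rate_matrix(nrn, trials)
        n = rates.shape[1]
        half = rng.permutation(n) < n // 2
        curves = {}
        for var in {var_row, var_col}:
            vals = labels[col[var]].to_numpy()
            levels, codes = np.unique(vals, return_inverse=True)
            c = np.zeros((2, T, len(levels)))
            for h, mask in enumerate((half, ~half)):
                cnt = np.array([np.bincount(codes[mask], minlength=len(levels))])
                for t in range(T):
                    s = np.bincount(codes[mask], weights=rates[t, mask],
                                    minlength=len(levels))
                    c[h, t] = s / np.maximum(cnt, 1)
            curves[var] = c
        a, b = curves[var_row], curves[var_col]
        for i in range(T):
            for j in range(T):
                r1 = _safe_corr(a[0, i], b[1, j])
                r2 = _safe_corr(a[1, i], b[0, j])
                per_neuron[k, i, j] = np.nanmean([r1, r2])
    mean_mat = np.nanmean(per_neuron, axis=0)
    sig = np.zeros((T, T), dtype=bool)
    for i in range(T):
        for j in range(T):
            rs = per_neuron[:, i, j]
            p = fisher_z_population_test(rs, n_boot=n_boot, seed=rng,
                                         bonferroni=T * T)
            sig[i, j] = p < alpha
    return mean_mat, sig


def direction_stability_matrix(neurons, trials, **kw):
    """Cross-time stability of direction tuning (split-half, warped windows)."""
    return tuning_correlation_matrix(neurons, trials, "direction", "direction",
                                     **kw)


# ---------------------------------------------------------------------------
# start -> target switch time
# ---------------------------------------------------------------------------

def switch_time(
    spikes: SpikeData, trials: pd.DataFrame, align: str = "t_go",
    t_range: tuple[float, float] = (-0.3, 0.9),
    step: float = 0.05, width: float = 0.3,
) -> float | None:
    """First window after the positive peak of R2_start - R2_target where the
    difference goes negative.

    Both R2 curves are smoothed with a 3-bin moving average first.  Returns
    the window time (s relative to the alignment event) or None when there is
    no positive peak or no subsequent crossing.
    """
    windows = sliding_windows(align, *t_range, step=step, width=width)
    if len(windows) < 3:
        raise ValueError("too few windows for switch-time estimation")
    times, diffs = [], []
    for w in windows:
        cm = count_spikes(spikes, trials, w)
        diffs.append(fit_variable_glm(cm, "start").r2
                     - fit_variable_glm(cm, "target").r2)
        times.append(w[2])
    d = np.convolve(diffs, np.ones(3) / 3, mode="same")
    pos = np.flatnonzero(d > 0)
    if len(pos) == 0:
        logger.info("no positive start-target R2 peak: switch undefined")
        return None
    peak = pos[np.argmax(d[pos])]
    after = np.flatnonzero(d[peak:] < 0)
    if len(after) == 0:
        logger.info("start tuning never yields to target: no crossing")
        return None
    return float(times[peak + after[0]])


# ---------------------------------------------------------------------------
# per-trajectory MAP rate map
# ---------------------------------------------------------------------------

def map_rate_heatmap(
    spikes: SpikeData, trials: pd.DataFrame,
    window: tuple = ("t_cue", 0.0, 0.5),
    design: SessionDesign | None = None,
    pseudo_trials: float = 1.0,
) -> pd.DataFrame:
    """Shrinkage estimate of the firing rate of each movement trajectory.

    The per-trajectory estimate is a conjugate-style (gamma-prior) posterior
    mean that pulls low-n trajectory means toward the grand mean rate over
    all trials, with a prior weight of ``pseudo_trials`` trials.  Trajectories
    in the design with no trials are reported with rate NaN (absent).
    """
    cm = count_spikes(spikes, trials, window)
    duration = window[2] - window[1]
    y = cm.counts.astype(float)
    grand = y.mean()
    key = list(zip(cm.labels.start_port, cm.labels.direction,
                   cm.labels.target_port))
    rows = {}
    for (s, d, t), grp in pd.DataFrame({"k": key, "y": y}).groupby("k"):
        n = len(grp)
        post = (grand * pseudo_trials + grp.y.sum()) / (pseudo_trials + n)
        rows[(s, d, t)] = (post / duration, n)
    if design is not None:
        for traj in design.trajectories:
            rows.setdefault(
                (traj.start_port, traj.direction, traj.target_port),
                (np.nan, 0))
    out = pd.DataFrame(
        [{"start_port": s, "direction": d, "target_port": t,
          "rate_hz": r, "n_trials": n}
         for (s, d, t), (r, n) in sorted(rows.items())]
    )
    return out


# ---------------------------------------------------------------------------
# PETHs
# ---------------------------------------------------------------------------

def causal_half_gaussian_kernel(sd: float = 0.4, dt: float = 0.01,
                                n_sd: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Causal half-Gaussian kernel (unit integral) on a lag grid.

    The kernel is nonzero only at non-negative lags, so the smoothed rate at
    time t is contributed only by spikes at or before t.  The truncation
    makes the effective smoothing comparable to a full Gaussian of half the
    standard deviation.
    """
    lags = np.arange(0.0, n_sd * sd + dt / 2, dt)
    k = np.exp(-lags**2 / (2 * sd**2))
    k /= k.sum() * dt
    return lags, k


def peth(
    spikes: SpikeData, trials: pd.DataFrame, align: str,
    t_grid: np.ndarray, group_by: str = "direction",
    kernel_sd: float = 0.4, correct_only: bool = True,
) -> pd.DataFrame:
    """Trial-averaged smoothed firing rate per condition on a time grid.

    Returns tidy rows (group, t, rate_hz, sem_hz).
    """
    keep = trials.outcome.eq("correct") if correct_only \
        else pd.Series(True, index=trials.index)
    sub = trials[keep]
    per_trial = np.zeros((len(sub), len(t_grid)))
    groups = sub[group_by].to_numpy()
    # K(lag) = exp(-lag^2/2sd^2) for lag >= 0, scaled to unit integral
    norm = kernel_sd * np.sqrt(2 * np.pi) / 2
    for row, (i, tr) in enumerate(sub.iterrows()):
        rel = spikes.trains[i] - tr[align]
        lag = t_grid[:, None] - rel[None, :]
        per_trial[row] = np.where(
            lag >= 0, np.exp(-lag**2 / (2 * kernel_sd**2)), 0.0
        ).sum(axis=1) / norm
    rows = []
    for g in np.unique(groups):
        m = per_trial[groups == g]
        rows += [{"group": g, "t": t, "rate_hz": mu, "sem_hz": se}
                 for t, mu, se in zip(t_grid, m.mean(0),
                                      m.std(0, ddof=1) / np.sqrt(len(m)))]
    return pd.DataFrame(rows)
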