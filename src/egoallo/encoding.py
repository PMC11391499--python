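"""Encoding-model comparison: pure vs mixed direction/position selectivity.

Four models of a neuron's firing rate f over trial conditions, with theta the
movement direction relative to the neuron's preferred direction (degrees,
wrapped to (-180, 180]) and (x, y) the start-port coordinates in mm:

* direction:    f = b0 + b1 * N(theta; sigma)
* start_plane:  f = b0 + b1*x + b2*y
* gain_field:   f = b0 + (b1*x + b2*y) * N(theta; sigma)
* additive:     f = b0 + (b1*x + b2*y) + b3 * N(theta; sigma)

N is the normalized Gaussian density exp(-theta^2/2 sigma^2)/(sigma sqrt(2 pi))
with sigma in degrees, so the amplitude coefficients multiplying N carry
Hz*degree units.  The gain-field model is the multiplicative combination of
position and direction tuning; the additive model the additive one.  The
preferred direction is fixed beforehand from the rate-weighted vector sum
(see :mod:`egoallo.tuning`), not co-fit.

Models are fit by maximum likelihood for Poisson spike counts with a bounded
local optimizer and random multi-start; f >= 0 over the condition set is kept
by clipping plus a quadratic penalty on negative rates.  Fit quality is the
cross-validated R^2 under 20-fold CV (stratified by trial condition), which
can legitimately be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import PortWall, build_port_wall
from .selectivity import KEY_WINDOWS, CountMatrix, count_spikes
from .simulate import SpikeData, _wrap_deg
from .tuning import preferred_direction, tuning_curve

MODEL_KINDS = ("direction", "start_plane", "gain_field", "additive")
PARAM_NAMES = {
    "direction": ("b0", "b1", "sigma_deg"),
    "start_plane": ("b0", "b1", "b2"),
    "gain_field": ("b0", "b1", "b2", "sigma_deg"),
    "additive": ("b0", "b1", "b2", "b3", "sigma_deg"),
}

SIGMA_BOUNDS = (10.0, 180.0)
B0_BOUNDS = (0.0, 100.0)
ENCODING_WINDOW = ("t_cue", 0.0, 0.5)     # 500 ms after the visual cue

_RATE_EPS = 1e-6
_NEG_PENALTY = 1e3


def _gauss(theta, sigma):
    return np.exp(-theta**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))


def model_rate(kind: str, theta: np.ndarray, x: np.ndarray, y: np.ndarray,
               params: dict) -> np.ndarray:
    """Predicted firing rate (Hz) of one model over trial conditions."""
    b0 = params["b0"]
    if kind == "direction":
        return b0 + params["b1"] * _gauss(theta, params["sigma_deg"])
    if kind == "start_plane":
        return b0 + params["b1"] * x + params["b2"] * y
    if kind == "gain_field":
        return b0 + (params["b1"] * x + params["b2"] * y) \
            * _gauss(theta, params["sigma_deg"])
    if kind == "additive":
        return b0 + params["b1"] * x + params["b2"] * y \
            + params["b3"] * _gauss(theta, params["sigma_deg"])
    raise ValueError(f"unknown model kind {kind!r}")


def _rate_and_jac(kind, p, theta, x, y):
    """f and df/dp for the parameter vector p (PARAM_NAMES order)."""
    n = len(theta)
    if kind == "start_plane":
        f = p[0] + p[1] * x + p[2] * y
        J = np.stack([np.ones(n), x, y], axis=1)
        return f, J
    sigma = p[-1]
    G = _gauss(theta, sigma)
    dG = G * (theta**2 / sigma**3 - 1.0 / sigma)
    if kind == "direction":
        f = p[0] + p[1] * G
        J = np.stack([np.ones(n), G, p[1] * dG], axis=1)
    elif kind == "gain_field":
        plane = p[1] * x + p[2] * y
        f = p[0] + plane * G
        J = np.stack([np.ones(n), x * G, y * G, plane * dG], axis=1)
    else:  # additive
        f = p[0] + p[1] * x + p[2] * y + p[3] * G
        J = np.stack([np.ones(n), x, y, G, p[3] * dG], axis=1)
    return f, J


@dataclass
class EncodingModelFit:
    kind: str
    params: dict
    pref_deg: float
    nll: float
    cv_r2: float | None = None
    converged: bool = True


def condition_arrays(cm: CountMatrix, pref_deg: float,
                     wall: PortWall | None = None):
    """(theta, x, y, counts) arrays for encoding-model fits."""
    wall = wall or build_port_wall()
    xy = wall.coordinates()
    theta = _wrap_deg(cm.labels.direction.to_numpy() - pref_deg)
    pos = xy[cm.labels.start_port.to_numpy()]
    return theta, pos[:, 0], pos[:, 1], cm.counts.astype(float)


def _nll(p, kind, theta, x, y, counts, duration):
    f, J = _rate_and_jac(kind, p, theta, x, y)
    mu = np.maximum(f * duration, _RATE_EPS)
    nll = float(np.sum(mu - counts * np.log(mu)))
    dmu = duration * (1.0 - counts / mu) * (f * duration > _RATE_EPS)
    neg = np.minimum(f, 0.0)
    nll += _NEG_PENALTY * float(np.sum(neg**2))
    df = dmu + 2 * _NEG_PENALTY * neg
    return nll, J.T @ df


def _bounds(kind, scale_hz, span_mm):
    amp = max(20 * scale_hz, 10.0)           # Hz*deg amplitudes on N(theta)
    slope = max(2 * scale_hz / span_mm, 0.1)  # Hz/mm plane slopes
    gf = amp / span_mm                        # Hz*deg/mm gain-field slopes
    table = {
        "direction": [B0_BOUNDS, (-amp * 50, amp * 50), SIGMA_BOUNDS],
        "start_plane": [B0_BOUNDS, (-slope * 5, slope * 5),
                        (-slope * 5, slope * 5)],
        "gain_field": [B0_BOUNDS, (-gf * 50, gf * 50), (-gf * 50, gf * 50),
                       SIGMA_BOUNDS],
        "additive": [B0_BOUNDS, (-slope * 5, slope * 5), (-slope * 5, slope * 5),
                     (-amp * 50, amp * 50), SIGMA_BOUNDS],
    }
    return table[kind]


def _initial_points(kind, bounds, scale_hz, rng, n_restarts):
    names = PARAM_NAMES[kind]
    pts = []
    base = np.zeros(len(names))
    base[0] = scale_hz
    if "sigma_deg" in names:
        base[-1] = 60.0
    pts.append(base)
    for _ in range(n_restarts - 1):
        p = np.array([rng.uniform(lo / 10 if lo < 0 else lo,
                                  hi / 10 if hi > 0 else hi)
                      for lo, hi in bounds])
        p[0] = rng.uniform(0.1, 2.0) * scale_hz
        if "sigma_deg" in names:
            p[-1] = rng.uniform(20, 120)
        pts.append(p)
    return pts


def _fit_once(kind, theta, x, y, counts, duration, p0, bounds):
    return minimize(_nll, p0, args=(kind, theta, x, y, counts, duration),
                    jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": 200})


def _stratified_folds(labels: pd.DataFrame, k: int, rng) -> np.ndarray:
    """Fold ids balanced within each (direction, start) condition."""
    cond = labels.direction.astype(str) + "/" + labels.start_port.astype(str)
    fold = np.empty(len(cond), dtype=int)
    offset = 0
    for _, idx in cond.groupby(cond).groups.items():
        idx = rng.permutation(np.asarray(idx))
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return fold


def fit_encoding_model(
    cm: CountMatrix, kind: str, pref_deg: float,
    k_folds: int = 20, n_restarts: int = 10,
    seed: int | np.random.Generator = 0,
    wall: PortWall | None = None,
) -> EncodingModelFit:
    """Constrained Poisson MLE of one model plus its k-fold CV R^2.

    The full-data fit uses ``n_restarts`` random multi-starts; each CV fold
    is then refit from the full-data optimum (warm start).  Predictions for
    held-out trials are max(f, 0) * window duration.
    """
    rng = np.random.default_rng(seed)
    duration = cm.window[2] - cm.window[1]
    theta, x, y, counts = condition_arrays(cm, pref_deg, wall)
    if len(counts) < k_folds:
        raise ValueError(f"need at least {k_folds} trials for {k_folds}-fold CV")
    scale = max(counts.mean() / duration, 0.5)
    bounds = _bounds(kind, scale, span_mm=(wall or build_port_wall()).spacing)

    best = None
    for p0 in _initial_points(kind, bounds, scale, rng, n_restarts):
        r = _fit_once(kind, theta, x, y, counts, duration, p0, bounds)
        if best is None or r.fun < best.fun:
            best = r
    params = dict(zip(PARAM_NAMES[kind], best.x))

    fold = _stratified_folds(cm.labels, k_folds, rng)
    yhat = np.empty_like(counts)
    for f_id in range(k_folds):
        tr = fold != f_id
        r = _fit_once(kind, theta[tr], x[tr], y[tr], counts[tr], duration,
                      best.x, bounds)
        te = ~tr
        f_te, _ = _rate_and_jac(kind, r.x, theta[te], x[te], y[te])
        yhat[te] = np.maximum(f_te, 0.0) * duration
    sst = np.sum((counts - counts.mean()) ** 2)
    cv_r2 = float(1.0 - np.sum((counts - yhat) ** 2) / sst) if sst > 0 else 0.0
    return EncodingModelFit(kind=kind, params=params, pref_deg=pref_deg,
                            nll=float(best.fun), cv_r2=cv_r2,
                            converged=bool(best.success))


def fit_all_models(
    spikes: SpikeData, trials: pd.DataFrame,
    window: tuple = ENCODING_WINDOW, k_folds: int = 20, n_restarts: int = 10,
    seed: int | np.random.Generator = 0, wall: PortWall | None = None,
) -> dict[str, EncodingModelFit]:
    """Fit the four encoding models to one neuron's windowed counts.

    The preferred direction is computed first from the direction tuning curve
    in the same window (vector sum); if undefined, 0 deg is used.
    """
    rng = np.random.default_rng(seed)
    curve = tuning_curve(spikes, trials, window, "direction")
    pref, _norm = preferred_direction(curve)
    if np.isnan(pref):
        pref = 0.0
    cm = count_spikes(spikes, trials, window)
    return {kind: fit_encoding_model(cm, kind, pref, k_folds=k_folds,
                                     n_restarts=n_restarts, seed=rng, wall=wall)
            for kind in MODEL_KINDS}


# ---------------------------------------------------------------------------
# population model comparison
# ---------------------------------------------------------------------------

def _fisher_z(r):
    return np.arctanh(np.clip(r, -1 + 1e-10, 1 - 1e-10))


@dataclass
class ModelComparison:
    pairwise: pd.DataFrame          # model pair, mean dz, CI, bootstrap p
    best_fractions: pd.Series       # fraction of included neurons per model
    n_included: int
    included: np.ndarray = field(repr=False, default=None)


def compare_models(cv_r2: pd.DataFrame, n_boot: int = 100_000,
                   include_threshold: float = 0.05,
                   seed: int | np.random.Generator = 0) -> ModelComparison:
    """Pairwise bootstrap comparison of the four models over a population.

    ``cv_r2`` has one row per neuron, one column per model kind.  Neurons
    whose mean CV R^2 over the four models exceeds ``include_threshold``
    are included.  For each ordered pair (M1, M2) the statistic is the mean
    of atanh(R^2_M1) - atanh(R^2_M2); p is the fraction of neuron-resampled
    bootstrap means at or below zero, floored at 1/n_boot.
    """
    rng = np.random.default_rng(seed)
    inc = cv_r2[list(MODEL_KINDS)].mean(axis=1) > include_threshold
    sub = cv_r2.loc[inc, list(MODEL_KINDS)]
    n = len(sub)
    if n < 2:
        raise ValueError("fewer than 2 neurons pass the inclusion threshold")
    z = _fisher_z(sub.to_numpy())
    idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for i, m1 in enumerate(MODEL_KINDS):
        for j, m2 in enumerate(MODEL_KINDS):
            if i == j:
                continue
            dz = z[:, i] - z[:, j]
            boot = dz[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            rows.append({
                "model_1": m1, "model_2": m2,
                "mean_dz": float(dz.mean()),
                "ci_low": float(lo), "ci_high": float(hi),
                "p_boot": max(float(np.mean(boot <= 0)), 1.0 / n_boot),
            })
    best = sub.idxmax(axis=1).value_counts(normalize=True) \
        .reindex(MODEL_KINDS, fill_value=0.0)
    return ModelComparison(pairwise=pd.DataFrame(rows), best_fractions=best,
                           n_included=n, included=inc.to_numpy())


def best_fraction_sweep(cv_r2: pd.DataFrame,
                        thresholds: np.ndarray) -> pd.DataFrame:
    """Best-model fractions as the mean-CV-R^2 inclusion threshold sweeps."""
    rows = []
    mean_r2 = cv_r2[list(MODEL_KINDS)].mean(axis=1)
    best = cv_r2[list(MODEL_KINDS)].idxmax(axis=1)
    for th in thresholds:
        inc = mean_r2 > th
        if inc.sum() == 0:
            continue
        frac = best[inc].value_counts(normalize=True) \
            .reindex(MODEL_KINDS, fill_value=0.0)
        rows.append({"threshold": th, "n": int(inc.sum()),
                     **{f"frac_{m}": frac[m] for m in MODEL_KINDS}})
    return pd.DataFrame(rows)


def recovery_harness(
    n_per_class: int = 50, design: str = "reference", n_trials: int = 480,
    seed: int = 0, k_folds: int = 20, n_restarts: int = 5,
) -> pd.DataFrame:
    """Fit all four models to synthetic additive- and gain-field populations.

    Returns one row per neuron: generative kind, the four CV R^2s, and the
    best-fitting model.
    """
    from .simulate import generate_population

    trials, neurons = generate_population(
        {"additive": n_per_class, "gain_field": n_per_class},
        design=design, n_trials=n_trials, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    rows = []
    for nrn in neurons:
        fits = fit_all_models(nrn, trials, k_folds=k_folds,
                              n_restarts=n_restarts, seed=rng)
        r2s = {k: f.cv_r2 for k, f in fits.items()}
        rows.append({"neuron_id": nrn.neuron_id,
                     "generative": nrn.meta["kind"],
                     **r2s, "best": max(r2s, key=r2s.get),
                     "mean_cv_r2": float(np.mean(list(r2s.values())))})
    return pd.DataFrame(rows)
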