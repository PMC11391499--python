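"""Synthetic behavioural sessions and Poisson-spiking neurons with known tuning.

The generator emulates the statistical structure of the orienting task that
every downstream analysis assumes:

* trials drawn from one of the session designs (reference / distance /
  four-direction), balanced so that every trajectory — and therefore every
  start port, direction and target port — has at least the required minimum
  number of trials;
* a trial timeline of fixation-in, visual cue (0-0.29 s after fixation
  onset), go sound (fixation 0.5-1.2 s), fixation-out, and target arrival;
* per-neuron spike trains from an inhomogeneous Poisson process whose rate is
  piecewise constant within a trial: a baseline rate plus a condition-tuned
  component active during a tuning-kind-specific epoch.  Start tuning is
  active from trial start until shortly after the go sound, direction tuning
  from cue onset to arrival, target tuning from the go sound to trial end,
  so that the three spatial variables dominate different trial epochs.

Synthetic neurons carry their generative tuning in ``SpikeData.meta`` so that
recovery analyses can score themselves against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .geometry import (
    PortWall,
    SessionDesign,
    build_port_wall,
    direction_unit,
    session_design,
)

TUNING_KINDS = ("start", "direction", "target", "additive", "gain_field", "none")

#: trial events (all times in seconds from trial start)
EVENT_COLUMNS = (
    "t_start", "t_fix_in", "t_cue", "t_go", "t_fix_out", "t_arrival", "t_end",
)


@dataclass
class TuningSpec:
    """Generative tuning of a synthetic neuron.

    ``params`` holds the parameters of the rate function for the given kind:

    - start/target: ``pref_port``, ``sigma_mm``, ``depth`` (peak modulation as
      a multiple of baseline); rate = baseline + depth*baseline*
      exp(-d^2 / 2 sigma^2) with d the distance from the preferred port.
    - direction: ``pref_deg``, ``sigma_deg``, ``depth``; Gaussian in the
      angular distance from the preferred direction.
    - additive / gain_field: ``b0``, ``b1``, ``b2`` (+ ``b3`` for additive),
      ``sigma_deg``, ``pref_deg`` — the encoding-model functional forms with
      the normalized angular Gaussian (see :mod:`egoallo.encoding`).
    - none: no parameters.
    """

    kind: str
    baseline_hz: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in TUNING_KINDS:
            raise ValueError(f"unknown tuning kind {self.kind!r}")

    def rate_hz(self, start_port: int, direction: int, target_port: int,
                wall: PortWall) -> float:
        """Tuned firing rate (Hz) for one trial condition, active epoch only."""
        xy = wall.coordinates()
        if self.kind == "none":
            return self.baseline_hz
        if self.kind in ("start", "target"):
            port = start_port if self.kind == "start" else target_port
            p = self.params
            d = np.linalg.norm(xy[port] - xy[p["pref_port"]])
            return self.baseline_hz * (
                1.0 + p["depth"] * np.exp(-d**2 / (2 * p["sigma_mm"] ** 2))
            )
        if self.kind == "direction":
            p = self.params
            dth = _wrap_deg(direction - p["pref_deg"])
            return self.baseline_hz * (
                1.0 + p["depth"] * np.exp(-dth**2 / (2 * p["sigma_deg"] ** 2))
            )
        # mixed kinds: encoding-model functional forms on (theta, x, y)
        from .encoding import model_rate

        p = self.params
        x, y = xy[start_port]
        theta = _wrap_deg(direction - p["pref_deg"])
        return float(model_rate(self.kind, np.array([theta]), np.array([x]),
                                np.array([y]), p)[0])

    def validate(self, design: SessionDesign, wall: PortWall) -> None:
        rates = [
            self.rate_hz(t.start_port, t.direction, t.target_port, wall)
            for t in design.trajectories
        ]
        if min(rates) < 0:
            raise ValueError(
                f"{self.kind} spec predicts negative rate ({min(rates):.3f} Hz)"
            )


@dataclass
class SpikeData:
    """Per-trial spike timestamps (s from trial start) for one neuron."""

    neuron_id: int
    trains: list            # list of sorted float arrays, one per trial
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.trains)


def _wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# behavioural session
# ---------------------------------------------------------------------------

def generate_session(
    design: SessionDesign | str,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    error_rate: float = 0.0,
    violation_rate: float = 0.0,
    wall: PortWall | None = None,
) -> pd.DataFrame:
    """Generate a trial table for one session.

    Trials are allocated to the design's trajectories in balanced blocks
    (floor(n/K) per trajectory plus a random remainder) and shuffled, which
    guarantees the minimum-trials-per-condition requirement whenever
    ``n_trials >= min_trials * n_trajectories``.
    """
    if isinstance(design, str):
        design = session_design(design, wall)
    rng = np.random.default_rng(seed)
    trajs = design.trajectories
    k = len(trajs)
    per, rem = divmod(n_trials, k)
    if per < design.min_trials_per_condition:
        raise ValueError(
            f"n_trials={n_trials} cannot give {design.min_trials_per_condition} "
            f"trials to each of the {k} trajectories of design {design.name!r} "
            f"(first deficient condition: start={trajs[0].start_port}, "
            f"direction={trajs[0].direction}, target={trajs[0].target_port})"
        )
    idx = np.repeat(np.arange(k), per)
    if rem:
        idx = np.concatenate([idx, rng.choice(k, size=rem, replace=False)])
    rng.shuffle(idx)

    n = len(idx)
    t_fix_in = rng.uniform(1.0, 1.3, n)
    t_cue = t_fix_in + rng.uniform(0.0, 0.29, n)
    t_go = t_fix_in + rng.uniform(0.5, 1.2, n)
    t_fix_out = t_go + rng.uniform(0.1, 0.3, n)
    t_arrival = t_fix_out + rng.uniform(0.15, 0.4, n)

    u = rng.uniform(size=n)
    outcome = np.where(
        u < violation_rate, "violation",
        np.where(u < violation_rate + error_rate, "error", "correct"),
    )

    rows = {
        "trial_id": np.arange(n),
        "start_port": [trajs[i].start_port for i in idx],
        "target_port": [trajs[i].target_port for i in idx],
        "direction": [trajs[i].direction for i in idx],
        "distance_class": [trajs[i].distance_class for i in idx],
        "outcome": outcome,
        "t_start": np.zeros(n),
        "t_fix_in": t_fix_in,
        "t_cue": t_cue,
        "t_go": t_go,
        "t_fix_out": t_fix_out,
        "t_arrival": t_arrival,
        "t_end": t_arrival + 1.0,
    }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spiking neurons
# ---------------------------------------------------------------------------

#: tuning kind -> (epoch start event, offset s, epoch end event, offset s)
DEFAULT_EPOCHS = {
    "start": ("t_start", 0.0, "t_go", 0.3),
    "direction": ("t_cue", 0.0, "t_arrival", 0.0),
    "target": ("t_go", 0.0, "t_end", 0.0),
    "additive": ("t_cue", 0.0, "t_end", 0.0),
    "gain_field": ("t_cue", 0.0, "t_end", 0.0),
    "none": ("t_start", 0.0, "t_end", 0.0),
}


def _poisson_segment(rng, rate_hz, t0, t1):
    if t1 <= t0 or rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def generate_neuron(
    spec: TuningSpec,
    trials: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    epochs: dict | None = None,
    wall: PortWall | None = None,
    neuron_id: int = 0,
) -> SpikeData:
    """Poisson spike trains for one synthetic neuron over a trial table.

    Within the tuning epoch the rate is the spec's condition rate; outside it
    the rate is the baseline.  For the mixed kinds (additive, gain-field) the
    condition rate already contains its own offset b0, which doubles as the
    out-of-epoch baseline.
    """
    wall = wall or build_port_wall()
    rng = np.random.default_rng(seed)
    ep = (epochs or DEFAULT_EPOCHS)[spec.kind]
    trains = []
    for _, tr in trials.iterrows():
        rate = spec.rate_hz(tr.start_port, tr.direction, tr.target_port, wall)
        if rate < 0:
            raise ValueError("negative predicted rate")
        e0 = tr[ep[0]] + ep[1]
        e1 = tr[ep[2]] + ep[3]
        e0, e1 = max(e0, tr.t_start), min(e1, tr.t_end)
        segs = [
            _poisson_segment(rng, spec.baseline_hz, tr.t_start, e0),
            _poisson_segment(rng, rate, e0, e1),
            _poisson_segment(rng, spec.baseline_hz, e1, tr.t_end),
        ]
        trains.append(np.sort(np.concatenate(segs)))
    meta = {"kind": spec.kind, "baseline_hz": spec.baseline_hz,
            "params": dict(spec.params)}
    return SpikeData(neuron_id=neuron_id, trains=trains, meta=meta)


def random_tuning_spec(
    kind: str,
    rng: np.random.Generator,
    wall: PortWall | None = None,
    design: SessionDesign | None = None,
    baseline_range_hz: tuple[float, float] = (1.0, 20.0),
    depth_range: tuple[float, float] = (0.5, 3.0),
    max_tries: int = 100,
) -> TuningSpec:
    """Draw a realistic tuning spec.

    Baselines are log-normal (median ~5 Hz) clipped to ``baseline_range_hz``;
    modulation depths are uniform in ``depth_range`` (peak modulation as a
    multiple of baseline).  Parameter draws whose predicted rate would be
    negative anywhere on the design's condition set are rejected and redrawn.
    """
    wall = wall or build_port_wall()
    design = design or session_design("reference", wall)
    for _ in range(max_tries):
        base = float(np.clip(rng.lognormal(np.log(5.0), 0.6), *baseline_range_hz))
        depth = float(rng.uniform(*depth_range))
        if kind == "none":
            spec = TuningSpec("none", base)
        elif kind in ("start", "target"):
            spec = TuningSpec(kind, base, {
                "pref_port": int(rng.integers(0, 7)),
                "sigma_mm": float(rng.uniform(0.6, 1.2) * wall.spacing),
                "depth": depth,
            })
        elif kind == "direction":
            spec = TuningSpec(kind, base, {
                "pref_deg": float(rng.uniform(0, 360)),
                "sigma_deg": float(rng.uniform(30, 80)),
                "depth": depth,
            })
        elif kind in ("additive", "gain_field"):
            sigma = float(rng.uniform(30, 80))
            # the angular Gaussian is the normalized density (peak 1/(sigma
            # sqrt(2 pi))), so amplitudes carry a sigma*sqrt(2 pi) factor to
            # reach a peak modulation of depth*b0 on the condition set
            gauss_peak_inv = sigma * np.sqrt(2 * np.pi)
            ang = rng.uniform(0, 2 * np.pi)
            params = {
                "b0": base,
                "sigma_deg": sigma,
                "pref_deg": float(rng.uniform(0, 360)),
            }
            if kind == "gain_field":
                slope = depth * base * gauss_peak_inv / wall.spacing
                params["b1"] = float(slope * np.cos(ang))
                params["b2"] = float(slope * np.sin(ang))
            else:
                slope = depth * base / wall.spacing
                params["b1"] = float(slope * np.cos(ang))
                params["b2"] = float(slope * np.sin(ang))
                params["b3"] = float(depth * base * gauss_peak_inv)
            spec = TuningSpec(kind, base, params)
        else:
            raise ValueError(f"unknown tuning kind {kind!r}")
        try:
            spec.validate(design, wall)
            return spec
        except ValueError:
            continue
    raise RuntimeError(f"could not draw a valid {kind} spec in {max_tries} tries")


def generate_population(
    mixture: dict[str, int],
    design: SessionDesign | str = "reference",
    n_trials: int = 480,
    seed: int = 0,
    wall: PortWall | None = None,
    **spec_kwargs,
) -> tuple[pd.DataFrame, list[SpikeData]]:
    """A session plus ``sum(mixture.values())`` synthetic neurons.

    ``mixture`` maps tuning kind to neuron count, e.g.
    ``{"start": 100, "direction": 100, "target": 100, "none": 100}``.
    Deterministic under ``seed``.
    """
    wall = wall or build_port_wall()
    if isinstance(design, str):
        design = session_design(design, wall)
    rng = np.random.default_rng(seed)
    trials = generate_session(design, n_trials, rng, wall=wall)
    neurons = []
    nid = 0
    for kind, count in mixture.items():
        for _ in range(count):
            spec = random_tuning_spec(kind, rng, wall, design, **spec_kwargs)
            neurons.append(generate_neuron(spec, trials, rng, wall=wall,
                                           neuron_id=nid))
            nid += 1
    return trials, neurons


# ---------------------------------------------------------------------------
# session files
# ---------------------------------------------------------------------------

def write_session(path: str | Path, trials: pd.DataFrame,
                  neurons: list[SpikeData]) -> None:
    """Write a session as plain-text files: trials.csv, spikes.csv, neurons.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path / "trials.csv", index=False)
    rows = []
    for nrn in neurons:
        for trial_id, train in enumerate(nrn.trains):
            for t in train:
                rows.append((nrn.neuron_id, trial_id, t))
    pd.DataFrame(rows, columns=["neuron_id", "trial_id", "t_spike"]).to_csv(
        path / "spikes.csv", index=False
    )
    meta = {str(n.neuron_id): n.meta for n in neurons}
    (path / "neurons.json").write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> tuple[pd.DataFrame, list[SpikeData]]:
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    missing = set(EVENT_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing event columns: {sorted(missing)}")
    spikes = pd.read_csv(path / "spikes.csv")
    meta = json.loads((path / "neurons.json").read_text())
    n_trials = len(trials)
    neurons = []
    for nid_str, m in meta.items():
        nid = int(nid_str)
        sub = spikes[spikes.neuron_id == nid]
        trains = [np.empty(0)] * n_trials
        for trial_id, grp in sub.groupby("trial_id"):
            trains[int(trial_id)] = np.sort(grp.t_spike.to_numpy())
        neurons.append(SpikeData(neuron_id=nid, trains=trains, meta=m))
    return trials, neurons
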