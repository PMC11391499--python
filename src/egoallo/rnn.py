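"""Reference-frame RNN simulations of the orienting task.

Four input/output contingencies are simulated (ego-ego, ego-allo, allo-ego,
allo-allo).  The input on each of 11 time frames is a 100x100-pixel scene —
visual-frame border, world-frame border (50x50 px, world origin at its
center), start port, transient target port (4th frame only), and static
distractors — area-downsampled to 40x40 and flattened to 1600 inputs.  In
ego-input tasks the start port is pinned to the center of the visual frame
(the world frame shifts); in allo-input tasks the world frame is pinned to
the center.  At frame 11 the network must report 2D coordinates: the
movement vector (target - start, world frame) for ego output, or the target
position (world frame) for allo output.

The network is a vanilla recurrent layer of 100 tanh units with a linear
2-unit readout, trained by stochastic gradient descent (Adam) on the mean
squared readout error at frame 11, with gradients computed by
backpropagation through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .simulate import _wrap_deg

TASKS = ("ego-ego", "ego-allo", "allo-ego", "allo-allo")

N_TIME_FRAMES = 11
TARGET_FRAME = 4                 # 1-based; target visible only on this frame
IMAGE_PX = 100
DOWNSAMPLED_PX = 40
WORLD_PX = 50                    # world frame is 50x50, centered at (0, 0)
INTENSITY = {"start": 0.7, "target": 1.0, "distractor": 0.2,
             "world_frame": 0.4, "visual_frame": 0.3}
PORT_HALF_PX = 3          # ports render as 7x7 blocks at the 100-px scale
DISTRACTOR_HALF_PX = 1

#: frame <-> task-epoch correspondence used when comparing with neural data
FRAME_WINDOWS = {3: "pre_cue", 7: "post_cue", 11: "go"}


@dataclass
class FrameTask:
    input_frame: str             # "ego" | "allo"
    output_frame: str            # "ego" | "allo"
    n_distractors: int = 3

    @classmethod
    def from_name(cls, name: str, **kw) -> "FrameTask":
        i, o = name.split("-")
        return cls(input_frame=i, output_frame=o, **kw)

    @property
    def name(self) -> str:
        return f"{self.input_frame}-{self.output_frame}"


def _draw_square(img: np.ndarray, cx: float, cy: float, half: int,
                 value: float) -> None:
    """Max-composite a (2*half+1)^2 block at visual coords (cx, cy)."""
    col = int(round(cx)) + IMAGE_PX // 2
    row = IMAGE_PX // 2 - int(round(cy))
    r0, r1 = max(row - half, 0), min(row + half + 1, IMAGE_PX)
    c0, c1 = max(col - half, 0), min(col + half + 1, IMAGE_PX)
    img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], value)


def _draw_frame_outline(img, cx, cy, size, value):
    col = int(round(cx)) + IMAGE_PX // 2
    row = IMAGE_PX // 2 - int(round(cy))
    h = size // 2
    r0, r1 = max(row - h, 0), min(row + h, IMAGE_PX)
    c0, c1 = max(col - h, 0), min(col + h, IMAGE_PX)
    img[r0, c0:c1] = np.maximum(img[r0, c0:c1], value)
    img[r1 - 1, c0:c1] = np.maximum(img[r1 - 1, c0:c1], value)
    img[r0:r1, c0] = np.maximum(img[r0:r1, c0], value)
    img[r0:r1, c1 - 1] = np.maximum(img[r0:r1, c1 - 1], value)


def _downsample(img: np.ndarray) -> np.ndarray:
    """Exact area-average pooling 100 -> 40 px (2.5-px blocks via 2x upsample)."""
    up = np.repeat(np.repeat(img, 2, axis=0), 2, axis=1)       # 200x200
    return up.reshape(DOWNSAMPLED_PX, 5, DOWNSAMPLED_PX, 5).mean(axis=(1, 3))


def render_trial(
    task: FrameTask, start_xy, target_xy,
    n_distractors: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """(11, 1600) flattened input frames for one trial.

    Coordinates are in world-frame px.  The world-frame origin sits at the
    visual-frame center for allo input; for ego input the start port sits at
    the center and the world frame shifts by -start.
    """
    start_xy = np.asarray(start_xy, float)
    target_xy = np.asarray(target_xy, float)
    half_w = WORLD_PX / 2
    for name, p in (("start", start_xy), ("target", target_xy)):
        if np.any(np.abs(p) > half_w):
            raise ValueError(f"{name} {p} outside the 50x50 world frame")
    rng = np.random.default_rng(seed)
    offset = -start_xy if task.input_frame == "ego" else np.zeros(2)

    base = np.zeros((IMAGE_PX, IMAGE_PX))
    _draw_frame_outline(base, 0, 0, IMAGE_PX, INTENSITY["visual_frame"])
    _draw_frame_outline(base, *(offset), WORLD_PX, INTENSITY["world_frame"])
    nd = task.n_distractors if n_distractors is None else n_distractors
    for _ in range(nd):
        d = rng.uniform(-IMAGE_PX / 2 + 3, IMAGE_PX / 2 - 3, size=2)
        _draw_square(base, d[0], d[1], DISTRACTOR_HALF_PX,
                     INTENSITY["distractor"])
    _draw_square(base, *(start_xy + offset), PORT_HALF_PX, INTENSITY["start"])
    with_target = base.copy()
    _draw_square(with_target, *(target_xy + offset), PORT_HALF_PX,
                 INTENSITY["target"])

    frames = np.empty((N_TIME_FRAMES, DOWNSAMPLED_PX**2))
    flat_base = _downsample(base).ravel()
    flat_tgt = _downsample(with_target).ravel()
    for t in range(N_TIME_FRAMES):
        frames[t] = flat_tgt if t == TARGET_FRAME - 1 else flat_base
    return frames


def trial_output(task: FrameTask, start_xy, target_xy) -> np.ndarray:
    """Demanded readout at frame 11: movement vector (ego) or target (allo)."""
    start_xy, target_xy = np.asarray(start_xy, float), np.asarray(target_xy, float)
    return target_xy - start_xy if task.output_frame == "ego" else target_xy


def sample_trials(task: FrameTask, n: int,
                  rng: np.random.Generator, margin: float = 2.0):
    """Random start/target coordinates inside the world frame + rendered input."""
    half = WORLD_PX / 2 - margin
    starts = rng.uniform(-half, half, size=(n, 2))
    targets = rng.uniform(-half, half, size=(n, 2))
    X = np.stack([render_trial(task, s, t, seed=rng)
                  for s, t in zip(starts, targets)])
    Y = np.stack([trial_output(task, s, t) for s, t in zip(starts, targets)])
    return X, Y, starts, targets


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    n_hidden: int = 100
    lr: float = 1e-3
    batch_size: int = 64
    n_steps: int = 2000
    early_stop_px: float = 4.0
    input_gain: float = 5.0   # compensates the sparse, low-intensity images


@dataclass
class RNN:
    """Vanilla tanh recurrent network with a linear 2-unit readout."""

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray
    Wo: np.ndarray
    bo: np.ndarray
    task: FrameTask | None = None
    train_log: list = field(default_factory=list)

    @classmethod
    def init(cls, n_in: int, n_hidden: int, rng: np.random.Generator,
             task: FrameTask | None = None, input_gain: float = 5.0) -> "RNN":
        q, _ = np.linalg.qr(rng.standard_normal((n_hidden, n_hidden)))
        return cls(
            Wx=input_gain * rng.standard_normal((n_in, n_hidden)) / np.sqrt(n_in),
            Wh=q,                       # orthogonal recurrent init
            b=np.zeros(n_hidden),
            Wo=rng.standard_normal((n_hidden, 2)) / np.sqrt(n_hidden),
            bo=np.zeros(2),
            task=task,
        )

    def hidden_states(self, X: np.ndarray) -> np.ndarray:
        """(T+1, batch, n_hidden) hidden trajectory; h[0] = 0."""
        T, B = X.shape[0], X.shape[1]
        H = np.zeros((T + 1, B, self.Wh.shape[0]))
        for t in range(T):
            H[t + 1] = np.tanh(X[t] @ self.Wx + H[t] @ self.Wh + self.b)
        return H

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Readout at the final frame.  X: (T, batch, n_in)."""
        return self.hidden_states(X)[-1] @ self.Wo + self.bo

    def _params(self):
        return [self.Wx, self.Wh, self.b, self.Wo, self.bo]

    def _grads(self, X, Ytrue):
        H = self.hidden_states(X)
        Y = H[-1] @ self.Wo + self.bo
        B = X.shape[1]
        dY = 2 * (Y - Ytrue) / (B * 2)
        gWo = H[-1].T @ dY
        gbo = dY.sum(0)
        dh = dY @ self.Wo.T
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        for t in range(X.shape[0] - 1, -1, -1):
            dpre = dh * (1 - H[t + 1] ** 2)
            gWx += X[t].T @ dpre
            gWh += H[t].T @ dpre
            gb += dpre.sum(0)
            dh = dpre @ self.Wh.T
        loss = float(np.mean((Y - Ytrue) ** 2))
        return loss, [gWx, gWh, gb, gWo, gbo]


def train_network(
    task: FrameTask | str, spec: NetworkSpec | None = None,
    seed: int | np.random.Generator = 0,
    n_test: int = 128,
) -> RNN:
    """Train one network on randomly generated trials; Adam on frame-11 MSE.

    Training stops early once the mean Euclidean readout error on held-out
    random trials falls below ``spec.early_stop_px``.  A network that never
    reaches it trains for the full budget and is flagged in ``train_log``.
    """
    if isinstance(task, str):
        task = FrameTask.from_name(task)
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(seed)
    Xte, Yte, _, _ = sample_trials(task, n_test, rng)
    Xte = Xte.transpose(1, 0, 2)

    net = RNN.init(Xte.shape[2], spec.n_hidden, rng, task=task,
                   input_gain=spec.input_gain)
    m = [np.zeros_like(p) for p in net._params()]
    v = [np.zeros_like(p) for p in net._params()]
    b1, b2, eps = 0.9, 0.999, 1e-8
    for step in range(1, spec.n_steps + 1):
        # fresh random trials every batch: effectively infinite training data
        Xb, Yb, _, _ = sample_trials(task, spec.batch_size, rng)
        loss, grads = net._grads(Xb.transpose(1, 0, 2), Yb)
        for p, g, mi, vi in zip(net._params(), grads, m, v):
            mi *= b1; mi += (1 - b1) * g
            vi *= b2; vi += (1 - b2) * g**2
            p -= spec.lr * (mi / (1 - b1**step)) \
                / (np.sqrt(vi / (1 - b2**step)) + eps)
        if step % 50 == 0 or step == spec.n_steps:
            err = float(np.mean(np.linalg.norm(net.forward(Xte) - Yte, axis=1)))
            net.train_log.append({"step": step, "loss": loss, "test_err_px": err})
            if err < spec.early_stop_px:
                return net
    final = net.train_log[-1]["test_err_px"] if net.train_log else np.inf
    if final > 3 * spec.early_stop_px:
        net.train_log.append({"step": -1, "diverged": True})
    return net


# ---------------------------------------------------------------------------
# test trajectories and hidden-unit analyses
# ---------------------------------------------------------------------------

def reference_trajectories_world(spacing_px: float = 12.0) -> pd.DataFrame:
    """The 24 short trajectories mapped into the 50x50 world frame.

    The port hexagon is inscribed with the given spacing (px) so that even
    the long trajectories' endpoints stay inside the frame.
    """
    from .geometry import build_port_wall, session_design

    wall = build_port_wall(spacing=25.0)   # dummy mm wall for the design
    design = session_design("reference", wall)
    scale = spacing_px / wall.spacing
    xy = wall.coordinates() * scale
    rows = [{
        "start_port": t.start_port, "target_port": t.target_port,
        "direction": t.direction,
        "start_x": xy[t.start_port, 0], "start_y": xy[t.start_port, 1],
        "target_x": xy[t.target_port, 0], "target_y": xy[t.target_port, 1],
    } for t in design.trajectories]
    return pd.DataFrame(rows)


def trajectory_hidden_activity(
    net: RNN, trajectories: pd.DataFrame | None = None,
    n_repeats: int = 8, seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hidden activity on the test trajectories.

    Returns ((n_frames, n_samples, n_hidden) array, sample table).  Each
    trajectory is rendered ``n_repeats`` times with fresh random distractors.
    """
    rng = np.random.default_rng(seed)
    traj = reference_trajectories_world() if trajectories is None else trajectories
    X, rows = [], []
    for _, tr in traj.iterrows():
        for rep in range(n_repeats):
            X.append(render_trial(net.task, (tr.start_x, tr.start_y),
                                  (tr.target_x, tr.target_y), seed=rng))
            rows.append({**tr.to_dict(), "repeat": rep})
    X = np.stack(X).transpose(1, 0, 2)
    H = net.hidden_states(X)[1:]         # (T, n_samples, n_hidden)
    return H, pd.DataFrame(rows)


def _cv_r2(Z: np.ndarray, Y: np.ndarray, k: int = 10, alpha: float = 1.0,
           rng=None) -> float:
    """k-fold CV R^2 of ridge-decoding Y (n, 2) from Z (n, p), pooled coords."""
    rng = rng or np.random.default_rng(0)
    n = len(Z)
    fold = rng.permutation(n) % k
    pred = np.empty_like(Y)
    for f in range(k):
        m = fold != f
        pred[~m] = Ridge(alpha=alpha).fit(Z[m], Y[m]).predict(Z[~m])
    sst = np.sum((Y - Y.mean(0)) ** 2)
    return float(1.0 - np.sum((Y - pred) ** 2) / sst)


def decode_hidden(
    nets: list[RNN], n_test: int = 256, seed: int = 0,
) -> pd.DataFrame:
    """Per-frame CV R^2 of linearly decoding start, vector and target
    position from hidden activity, for each network replicate.

    Test trials use start/target coordinates drawn at random inside the
    world frame (continuous, not the discrete task trajectories), so the
    decoder must exploit a genuine linear code rather than a
    condition-lookup over a small set of conditions.
    Returns tidy rows (task, replicate, frame, variable, cv_r2).
    """
    rows = []
    for rep, net in enumerate(nets):
        rng = np.random.default_rng(seed + rep)
        X, _, starts, tgts = sample_trials(net.task, n_test, rng)
        H = net.hidden_states(X.transpose(1, 0, 2))[1:]
        targets = {
            "start": starts,
            "vector": tgts - starts,
            "target": tgts,
        }
        for f in range(H.shape[0]):
            for var, Y in targets.items():
                rows.append({"task": net.task.name, "replicate": rep,
                             "frame": f + 1, "variable": var,
                             "cv_r2": _cv_r2(H[f], Y, rng=rng)})
    return pd.DataFrame(rows)


def detect_gain_field_units(
    net: RNN, n_repeats: int = 8, seed: int = 0, n_restarts: int = 3,
    k_folds: int = 5, max_units: int | None = None,
) -> pd.DataFrame:
    """Score each hidden unit for gain-field-like start x direction mixing.

    Frame-11 activity of each unit is fit with the additive and the
    gain-field encoding forms (Gaussian noise / least squares, angular
    Gaussian over direction relative to the unit's preferred direction,
    linear plane over start coordinates).  Positive ``gain_score``
    (CV R^2 gain-field minus CV R^2 additive) marks multiplicative mixing.
    """
    from scipy.optimize import minimize

    from .encoding import SIGMA_BOUNDS, _rate_and_jac

    rng = np.random.default_rng(seed)
    H, tab = trajectory_hidden_activity(net, n_repeats=n_repeats, seed=rng)
    act = H[-1]                                  # (n_samples, n_hidden)
    x = tab.start_x.to_numpy()
    y = tab.start_y.to_numpy()
    dirs = tab.direction.to_numpy()

    def sse(p, kind, theta_s, x_s, y_s, vals):
        f, J = _rate_and_jac(kind, p, theta_s, x_s, y_s)
        r = f - vals
        return float(r @ r), 2 * (J.T @ r)

    def fit_cv(kind, theta, vals):
        a = float(np.abs(vals).max()) + 0.1
        if kind == "additive":
            bounds = [(-2 * a, 2 * a), (-1, 1), (-1, 1), (-500, 500),
                      SIGMA_BOUNDS]
        else:
            bounds = [(-2 * a, 2 * a), (-20, 20), (-20, 20), SIGMA_BOUNDS]

        def optimize(m, p0):
            return minimize(sse, p0,
                            args=(kind, theta[m], x[m], y[m], vals[m]),
                            jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 150})

        everything = np.ones(len(vals), dtype=bool)
        best = None
        for r_i in range(n_restarts):
            p0 = np.array([np.clip(vals.mean(), *bounds[0])]
                          + [rng.uniform(lo / 10, hi / 10)
                             for lo, hi in bounds[1:-1]] + [60.0])
            res = optimize(everything, p0)
            if best is None or res.fun < best.fun:
                best = res
        fold = rng.permutation(len(vals)) % k_folds
        pred = np.empty_like(vals)
        for f_id in range(k_folds):
            m = fold != f_id
            r = optimize(m, best.x)
            pred[~m], _ = _rate_and_jac(kind, r.x, theta[~m], x[~m], y[~m])
        sst = np.sum((vals - vals.mean()) ** 2)
        return float(1 - np.sum((vals - pred) ** 2) / sst) if sst > 0 else 0.0

    rows = []
    n_units = act.shape[1] if max_units is None else min(max_units,
                                                         act.shape[1])
    for u in range(n_units):
        vals = act[:, u]
        # preferred direction of the unit: activity-weighted vector sum
        means = {d: vals[dirs == d].mean() for d in np.unique(dirs)}
        shift = min(means.values())
        vec = sum((m - shift) * np.array([np.cos(np.deg2rad(d)),
                                          np.sin(np.deg2rad(d))])
                  for d, m in means.items())
        pref = np.rad2deg(np.arctan2(vec[1], vec[0])) if np.linalg.norm(vec) > 1e-9 else 0.0
        theta = _wrap_deg(dirs - pref)
        r2_add = fit_cv("additive", theta, vals)
        r2_gf = fit_cv("gain_field", theta, vals)
        rows.append({"unit": u, "cv_r2_additive": r2_add,
                     "cv_r2_gain_field": r2_gf,
                     "gain_score": r2_gf - r2_add})
    return pd.DataFrame(rows)
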