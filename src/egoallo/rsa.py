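"""Representational similarity analysis between neural and network populations.

Both systems are condition-averaged over the same 24 reference trajectories,
reduced to their first 4 principal components, and summarized by a 24x24
representational dissimilarity matrix (RDM; correlation distance between the
4-PC activity patterns of condition pairs).  The similarity of two systems is
the Pearson correlation between the lower triangles of their RDMs.  Network
frames 3, 7 and 11 correspond to the task's pre-cue, post-cue and go windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .selectivity import KEY_WINDOWS
from .simulate import SpikeData


def trajectory_key(trials_or_df: pd.DataFrame) -> pd.Series:
    return (trials_or_df.start_port.astype(float).astype(int).astype(str)
            + ">" +
            trials_or_df.target_port.astype(float).astype(int).astype(str))


def population_condition_activity(
    trials: pd.DataFrame, neurons: list[SpikeData], window: tuple,
) -> tuple[np.ndarray, list[str]]:
    """(n_conditions, n_neurons) mean windowed spike counts per trajectory."""
    from .decoding import window_counts

    correct = trials[trials.outcome.eq("correct")]
    counts = window_counts(neurons, trials, window)[correct.index.to_numpy()]
    keys = trajectory_key(correct)
    order = sorted(keys.unique())
    act = np.stack([counts[(keys == k).to_numpy()].mean(0) for k in order])
    return act, order


def network_condition_activity(
    net, frame: int, n_repeats: int = 8, seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """(n_conditions, n_hidden) mean hidden activity at one frame (1-based)."""
    from .rnn import trajectory_hidden_activity

    H, tab = trajectory_hidden_activity(net, n_repeats=n_repeats, seed=seed)
    keys = trajectory_key(tab)
    order = sorted(keys.unique())
    act = np.stack([H[frame - 1][(keys == k).to_numpy()].mean(0)
                    for k in order])
    return act, order


def rdm(condition_activity: np.ndarray, n_pcs: int = 4) -> np.ndarray:
    """Correlation-distance RDM over the first ``n_pcs`` PCs of the activity."""
    n_cond = condition_activity.shape[0]
    pcs = PCA(n_components=min(n_pcs, *condition_activity.shape)) \
        .fit_transform(condition_activity)
    # canonicalize the sign of each component (nonnegative skewness) so the
    # RDM does not depend on the arbitrary orientation of the PC basis
    skew = (pcs**3).sum(axis=0)
    pcs = pcs * np.where(skew < 0, -1.0, 1.0)
    c = np.corrcoef(pcs)
    out = 1.0 - c
    np.fill_diagonal(out, 0.0)
    return out


def rdm_similarity(rdm_a: np.ndarray, rdm_b: np.ndarray) -> float:
    """Pearson r between the linearized lower triangles of two RDMs."""
    if rdm_a.shape != rdm_b.shape:
        raise ValueError(f"RDM shapes differ: {rdm_a.shape} vs {rdm_b.shape}")
    i, j = np.tril_indices(rdm_a.shape[0], k=-1)
    return float(np.corrcoef(rdm_a[i, j], rdm_b[i, j])[0, 1])


def rsa_similarity(
    trials: pd.DataFrame, neurons: list[SpikeData], nets: list,
    frames: tuple[int, ...] = (3, 7, 11),
    windows: dict | None = None,
    n_pcs: int = 4, n_repeats: int = 8, seed: int = 0,
) -> pd.DataFrame:
    """Frame x window RDM similarity between a population and RNN replicates.

    Returns tidy rows (task, replicate, frame, window, similarity); the
    frame/window diagonal (3<->pre-cue, 7<->post-cue, 11<->go) is the
    headline comparison.  Raises if the two systems do not share the same
    trajectory set.
    """
    windows = windows or {k: KEY_WINDOWS[k]
                          for k in ("pre_cue", "post_cue", "go")}
    pop_rdms, pop_order = {}, None
    for wname, w in windows.items():
        act, order = population_condition_activity(trials, neurons, w)
        pop_rdms[wname] = rdm(act, n_pcs)
        pop_order = order
    rows = []
    for rep, net in enumerate(nets):
        for frame in frames:
            act, order = network_condition_activity(
                net, frame, n_repeats=n_repeats, seed=seed + rep)
            if order != pop_order:
                missing = sorted(set(pop_order) ^ set(order))
                raise ValueError(f"condition mismatch between population and "
                                 f"network: {missing}")
            net_rdm = rdm(act, n_pcs)
            for wname, prdm in pop_rdms.items():
                rows.append({
                    "task": net.task.name, "replicate": rep, "frame": frame,
                    "window": wname,
                    "similarity": rdm_similarity(prdm, net_rdm),
                })
    return pd.DataFrame(rows)
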