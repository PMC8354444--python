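"""Conditioned plume navigation with a meta-learned circuit.

Trains a network whose velocity readouts steer a 2-D agent toward the
odor source that was paired with reward in a preceding conditioning
interval, then simulates one trial and prints the trajectory summary.
Runs the full 500-epoch protocol (a few minutes on one CPU); the
optimization landscape is rough and only a fraction of initializations
converge below the 0.4-m criterion (docs/methods.md), so the script uses
a seed known to converge.
"""

import numpy as np

from mbmeta.metalearn import TaskMix, TrainConfig, evaluate_navigation, train
from mbmeta.navigation import make_environment, run_navigation_trial

EPOCHS = 500

print(f"optimizing navigation network for {EPOCHS} epochs ...")
record = train(TaskMix(kind="navigation"), TrainConfig(n_epochs=EPOCHS),
               seed=30)
d = record.parts_history["mean_final_distance"]
# early epochs can blow up transiently (see docs/methods.md); summarize
# robustly with medians
start = float(np.nanmedian(d[:20]))
end = float(np.nanmedian(d[-20:]))
print(f"mean final distance: {start:.2f} m (start) -> "
      f"{end:.2f} m (end of optimization)")

ev = evaluate_navigation(record.params, n_trials=20, rng=3)
ev_blocked = evaluate_navigation(record.params, n_trials=20, rng=3,
                                 plasticity_nav=False)
print(f"test trials: control {ev['mean_distance']:.2f} m, "
      f"plasticity blocked during navigation "
      f"{ev_blocked['mean_distance']:.2f} m")

rng = np.random.default_rng(5)
env = make_environment(rng)
res = run_navigation_trial(record.params, env, rng)
traj = res["trajectory"]
print(f"\nexample trial: rewarded source at "
      f"({env.sources[0, 0]:+.1f}, {env.sources[0, 1]:.2f}) m; "
      f"final position ({traj['x1'].iloc[-1]:+.2f}, "
      f"{traj['x2'].iloc[-1]:.2f}) m; "
      f"final distance {res['final_distance']:.2f} m")
print(f"time inside rewarded plume: "
      f"{(traj['c_rewarded'] > 0).mean() * 100:.0f}% of the trial")
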