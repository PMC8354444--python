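"""Meta-learn a mushroom-body circuit and test it on first-order
conditioning.

Optimizes the output circuitry on the extinction + second-order mixture
(with random CS/US omissions), then freezes the parameters and evaluates
on fresh first-order trials where only the dopamine-gated plasticity
operates.  The run here is deliberately small (a few hundred epochs, a
couple of minutes on one CPU); error rates near zero need a few thousand
epochs — see docs/methods.md.
"""

import numpy as np

from mbmeta.metalearn import (TaskMix, TrainConfig, evaluate_error_rate,
                              train, unroll)
from mbmeta.tasks import make_conditioning_trial, ConditioningOptions

EPOCHS = 600

print(f"optimizing recurrent network for {EPOCHS} epochs "
      "(extinction + second-order mixture) ...")
record = train(TaskMix(kind="conditioning"), TrainConfig(n_epochs=EPOCHS),
               seed=0)
print(f"loss: {record.loss_history[:50].mean():.4f} (first 50 epochs) -> "
      f"{record.loss_history[-50:].mean():.4f} (last 50)")

res = evaluate_error_rate(record.params, "first_order", n_trials=50, rng=1)
print(f"\nfirst-order conditioning, 50 fresh test trials, threshold 0.2:")
print(f"  error rate = {res['error_rate']:.2f}  "
      f"(mean peak |readout - target| = {res['max_deviation'].mean():.2f})")

# one example trial in detail
trial = make_conditioning_trial("first_order", np.random.default_rng(7),
                                ConditioningOptions())
out = unroll(record.params, trial)
sign = trial.meta["us_sign"]
test = out.t[np.array([any(a <= t < b for a, b in trial.test_windows)
                       for t in out.t])]
sel = slice(int(test[0] / 0.5), int(test[-1] / 0.5) + 1)
print(f"\nexample trial (US sign {sign:+.0f}): readout during test CS = "
      + ", ".join(f"{v:+.2f}" for v in out.readout[sel, 0]))
print("After a single CS/US pairing the frozen circuit reports the learned "
      "valence at the next CS presentation, using only its plasticity rule.")
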