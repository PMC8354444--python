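"""The dopamine-gated plasticity rule's timing dependence.

Sweeps the lag between an isolated Kenyon-cell pulse and a dopamine pulse
and prints the integrated change in the latent synaptic weight w.  The
curve is biphasic: KC-before-DAN pairings (positive lag) depress the
synapse, DAN-before-KC pairings potentiate it, and the effect vanishes for
lags much longer than the eligibility-trace time constants.
"""

import numpy as np

from mbmeta import PlasticityConfig, pairing_curve

cfg = PlasticityConfig()  # 1-s eligibility traces, tau_W = 5 s
lags = np.arange(-10.0, 10.5, 0.5)
dw = pairing_curve(cfg, lags, pulse_amp=1.0, pulse_dur=2.0, dt=0.01)

print(" lag (s)   delta_w")
for lag, d in zip(lags, dw):
    bar = "#" * int(round(40 * abs(d) / np.abs(dw).max()))
    print(f"{lag:+6.1f}   {d:+.4f}  {bar}")

i_dep, i_pot = np.argmin(dw), np.argmax(dw)
print(f"\npeak depression  {dw[i_dep]:+.4f} at lag {lags[i_dep]:+.1f} s "
      "(KC first)")
print(f"peak potentiation {dw[i_pot]:+.4f} at lag {lags[i_pot]:+.1f} s "
      "(DAN first)")
print("Positive lags weaken the synapse (learning by depression); the "
      "window spans a few seconds, set by the trace time constants.")
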