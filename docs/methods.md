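# Methods

## The circuit model

The mushroom-body output circuitry is a rectified-linear rate network of
N = 100 neurons: 20 output neurons (MBONs), 20 dopamine neurons (DANs) and
60 feedback neurons (FBNs), integrated by explicit forward Euler,

    tau dr_i/dt = -r_i + [ sum_j W_recur[i,j] r_j + b_i + I_i(t) ]_+

with membrane time constant tau = 1 s and step dt = 0.5 s.  Rectification
applies inside the bracket only; the leak is linear.  MBONs receive Kenyon
cell (KC) input through the plastic weights W_KC->MBON (200 KCs), FBNs
receive external input (reinforcement, state pulses, wind) through W_ext,
and DANs receive no direct input: everything reaching them is relayed by
the recurrent circuitry.  The DAN->MBON block of W_recur is structurally
zero — dopamine gates plasticity rather than driving MBON firing — and no
other sign or sparsity constraint is imposed.  Behavior is read out
linearly: valence (optionally plus novelty) from MBON rates, and in the
state task a 3-way softmax decode of DAN rates.

At trial start, rates are reset to r0 (0 for MBONs, 0.1 for DANs/FBNs);
within multi-interval trials the same rate reset is applied at every
interval boundary so associations cannot be carried by persistent
activity.  Plastic weights and eligibility traces are never reset
mid-trial.

## Plasticity rule

Each KC->MBON synapse carries a latent plastic variable w_ij:

    dw_ij/dt = rbar_DAN_i r_KC_j - rbar_KC_j r_DAN_i (+ beta_i rbar_DAN_i)

where rbar are first-order low-pass filters (eligibility traces) of the
pre- and post-gating rates, and r_DAN_i is the dopamine rate assigned to
MBON i's compartment by the compartment map (identity by default; block
maps with fewer compartments average the DANs of a block with weight
1/block-size, which reduces to the identity at 20 compartments).  The rule
depresses synapses when the KC leads the DAN and potentiates them in the
reverse order; the optional nonnegative beta term potentiates synapses on
dopamine activity alone and is only enabled (and meta-learned,
initialized at 0.01) in continual-learning configurations.  w is clipped
to [0, w_max] with w_max = 0.05 after each Euler update; the effective
weight relaxes toward w with tau_W = 5 s, modelling the induction
timescale of LTD/LTP, and is therefore bounded by construction.  All
weights start at w_max.

The eligibility-trace time constants are not fixed by the source
experiments; we use tau = 1 s for both KC and DAN traces, which puts the
biphasic pairing window on the observed seconds-long scale.  Both
constants are configuration-exposed, and the pairing-curve utility
measures the resulting window directly.

Within one simulation step the order is: rate update -> plasticity update
(using the *pre-update* traces in the product terms, i.e. strictly causal
filters, and the post-step DAN rates) -> trace update.  The batched
training engine and the step-by-step reference simulator implement this
order identically, and a test asserts their exact agreement.

## Tasks (the synthetic-data layer)

All inputs are generated; there is no external data.  Odors are random
binary KC patterns with exactly 10% of cells active.  CS and US pulses
last 2 s; US valence is encoded on two external channels ((1,0) positive,
(0,1) negative, amplitude 1 except 0.1 in navigation conditioning).
Conditioning trials consist of 30-s intervals with presentation onsets
uniform in [5, 15] s and the US starting at CS offset (gap configurable,
default 0).

* first order: pairing interval, then a test interval with target +/-1
  during the test CS presentation (the target during the very first,
  pre-pairing presentation is 0).
* extinction: pairing, unreinforced CS+ (target still +/-1), test with
  target +/-0.5 — "partial" extinction; the residual fraction is a free
  constant of the task definition, exposed in the options.
* second order: CS1+US, then CS2 immediately followed by CS1 (CS1 target
  +/-1), then CS2 test with full transferred target.
* optimization mixture: extinction and second-order trials with equal
  probability; with probability 1/2 a trial is modified by an omission —
  either the US (all targets 0) or the middle-interval presentation
  (extinction then collapses to first-order conditioning) — which
  prevents overgeneralization to unreinforced stimuli.
* continual learning: a single 200-s interval; two CS+ and two CS- odors,
  presentation counts Poisson(2), every CS+ immediately reinforced with a
  random-sign US; the target of a CS+ presentation is the sign of its
  most recent previous pairing.  Stimulus windows never overlap (overlaps
  would make the pairing targets ill-defined): presentation blocks are
  placed by drawing sorted uniform points in the schedule's free space,
  i.e. uniformly among non-overlapping arrangements.
* internal state: a single 300-s trial; three states, transitions
  announced by 2-s pulses on dedicated channels, inter-transition gaps
  10 s * (1 + Exp(1)); the state target is the one-hot current state at
  every step.  Training trials embed a CS/US pairing plus re-presentation
  (and an unreinforced odor) so conditioning is learned concurrently;
  probe trials instead place a CS 8 s before the second transition with a
  later 5-s re-presentation, for the response-imprinting analysis.
* non-plastic comparison: a fixed odor bank (2-20 odors); CS+ pairing at
  exactly 5 s and a probe at 15 s which is the same odor with
  probability 1/2; KC->MBON weights are ordinary trained parameters
  (Gaussian init, variance 1/(2 n_KC)) and the plasticity rule is off.
* navigation: a 20-s conditioning interval (CS+ at 2 s, reward US of
  amplitude 0.1 at its offset) followed by 200 s of closed-loop movement.
  Two odor sources sit at x1 = +/-1 m, x2 ~ U[0, 2] m (>= 0.5 m apart),
  each with a Gaussian plume of half-height 0.25 m extending toward the
  origin, concentration 1/(1 + 0.5 dx1) exp(-dx2^2 / (0.1 dx1)); KC drive
  is the odor pattern scaled by local concentration, and wind is sensed
  as rectified egocentric projections (anterior/posterior/left/right) of
  the wind vector of the currently strongest plume (zero outside both
  plumes).  Forward velocity is Softplus(W_u r + b_u), angular velocity a linear
  readout; both read the feedback neurons only (they stand for locomotor
  pathways downstream of the output circuitry, and routing the sharp
  MBON/DAN odor transients straight into the velocities also destabilizes
  steering).  The unicycle is integrated at the circuit dt, heading
  before position.  Initial heading is uniform on
  [pi/2 (1-gamma), pi/2 (1+gamma)] with gamma annealed 0 -> 0.5 over
  optimization.  Because late exploding epochs can erase an already
  converged solution, the returned network is the best checkpoint (lowest
  batch-mean final distance over the second half of optimization); the
  0.4-m convergence criterion is then applied to fresh full-spread test
  trials.

What the generators deliberately do not emulate: naturalistic odor
statistics or projection-neuron->KC encoding, turbulent or intermittent
plumes, arena boundaries, spiking dynamics, or compartment-specific
learning-rule shapes beyond beta.  Passing tests therefore show that the
*circuit and learning mechanism* behave as specified under the stated
protocol, not that the model generalizes to richer sensory environments.

## Meta-learning

Parameters theta = {W_recur, b, W_ext, W_readout (+ W_state, velocity
readouts, beta where applicable)} are optimized by RMSprop (learning rate
0.001, batch B = 30 trials per epoch, batch loss the arithmetic mean of
trial losses).  RMSprop's remaining constants are not specified by the
task; we use the canonical smoothing 0.99 and epsilon 1e-8.  The
conditioning loss is the per-timestep mean squared readout error plus a
penalty lambda/T sum [r_DAN - 0.1]_+^2 with lambda = 0.1 (kept for the
continual task, dropped for the state task); the navigation loss is the
squared final distance to the rewarded source, with the conditioning
phase unsupervised.  Gradients are propagated through the full unrolled
dynamics — including the plasticity rule, the eligibility traces and (in
navigation) the agent kinematics and plume sensing — by a hand-written
reverse-mode sweep (no autodiff framework is used).  Nondifferentiable
points are handled by subgradients: rectifier 0 at the kink, weight clip
blocks gradient outside the open interval (0, w_max), and the
discrete "which plume's wind is sensed" choice is treated as locally
constant.  A test verifies analytic gradients against central finite
differences (float64) to better than 1% on both a conditioning trial and
the closed-loop navigation unroll.

Initialization: W_recur entries are zero-mean Gaussians with variance
1/(2 N_X) keyed to the presynaptic type X; W_readout variance 1/N_MBON;
W_ext variance 1; biases 0.1, including the velocity-readout biases
(initial forward speed softplus(0.1) ~ 0.74 m/s; the resulting large
early position errors supply the gradient signal that bootstraps
steering — slow-start initializations were found to stall in the
stand-still local optimum).  Velocity readout weights (whose scale the
protocol does not pin down) are Gaussian with variance 1/N; W_state rows
Gaussian with variance 1/N_DAN.

Continual learning carries KC->MBON weights across trials: the weights
starting trial l are (1-x) w0 + x w_{l-1}(T), with x rising linearly from
0 to 1 over the first half of optimization (the full-scale schedule is
2500 of 5000 epochs; at reduced epoch counts we keep the one-half
fraction).  Each batch lane is a persistent chain, and the gradient is
truncated at trial boundaries (carried weights enter as data).  Both the
latent w and the effective weight are carried.

The "no recurrence" ablation keeps only the feedforward FBN->MBON and
FBN->DAN blocks of W_recur.  Removing the matrix entirely would also
sever the only input pathway to the DANs (external input enters through
FBNs), making even first-order conditioning impossible, which is not what
the ablation is meant to probe; the feedforward mask removes every
recurrent loop while leaving reinforcement able to reach the dopamine
population.

After optimization, parameters are frozen; test-phase behavior changes
only through the plasticity rule.  Networks for the navigation task that
fail the 0.4-m mean-final-distance convergence criterion are discarded
(fresh seeds are drawn), mirroring the protocol's stated selection.

## Numerical choices

* Training runs in float32 with numba-compiled kernels; evaluation,
  analyses and gradient checks run in float64.  The forward kernel is
  asserted (in float64) to match the pure-numpy reference simulator.
* Navigation optimization runs in float64 and clips gradients to a global
  norm of 10 (configuration-exposed; no clipping for the open-loop
  tasks).  The 400-step reset-free closed loop makes the unrolled
  Jacobian products occasionally explode for marginally unstable
  recurrent-weight settings; unclipped, a single such epoch floods
  RMSprop's second-moment memory and silences learning for hundreds of
  epochs.  Epochs whose unroll leaves the representable range entirely
  contribute no update; a long run of them marks the seed as diverged
  (discarded under the convergence-selection protocol).
* Trials within a batch share interval structure, so the unroll is
  batched over B; a reusable buffer pool avoids re-faulting the ~90 MB
  history arrays every epoch.
* Trial streams, initialization and evaluation draws derive from one seed
  sequence, so ablations sharing a seed share trial streams.
* Degenerate cases: softmax is computed with max subtraction;
  zero-variance response vectors yield flagged NaN correlations.
* The plume is defined to start 1 cm downwind of its source (the exact
  on-axis source point is assigned concentration 1).  The concentration
  formula's spatial gradient is singular at the tip (it scales like
  dx2^2/dx1^2), which otherwise injects unbounded terms into the
  navigation gradient; 1 cm is below the agent's per-step movement
  (u dt ~ 1 cm at walking speed), so the cutoff is behaviorally
  invisible.  Optimization runs whose loss or gradient still becomes
  non-finite are flagged as diverged and that seed is discarded, per the
  stated convergence-selection protocol.

## Problem sizes used by the shipped runs

Full-scale optimization in the source protocol runs 2000 epochs
(first-order only), 5000 (mixture, continual) or 500 (state, navigation).
The acceptance script and test suite run the conditioning mixture and
navigation at their full scales (5000 and 500 epochs, one realization per
network class; the mixture's first-order error rate on 50 fresh test
trials reaches 0.00 there, while 4000 epochs is not reliable across
initialization seeds).  The remaining protocols run at desk scale —
state 150 epochs, continual 300, non-plastic sweeps 400, novelty 1000 —
with test sets of 15-50 trials; their loss curves are still slowly
improving at cutoff, so residual readout error is larger than at full
scale and only qualitative signatures are asserted there.

## Known limitations

* The eligibility-trace constants, extinction residual, conditioning US
  amplitude and target magnitude are task-definition constants, not
  fitted quantities; conclusions that depend on their precise values
  should sweep them.
* Cross-trial gradient truncation in continual learning means the
  optimizer does not see how weight carryover shapes later trials, only
  the within-trial consequences.
* The model is rate-based with a 0.5-s step: phenomena faster than ~1 s
  (spike-timing effects, fast sniff-locked plume encounters) are outside
  its resolution.
* Hierarchical-clustering linkage (average) and PCA centering (per
  neuron, no variance scaling) are display conventions; alternatives are
  exposed as arguments.
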