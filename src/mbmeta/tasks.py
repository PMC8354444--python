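"""Trial generators for the conditioning-style paradigms.

A :class:`Trial` is an ordered list of intervals, each carrying stimulus
events (CS odor presentations, US reinforcement pulses, internal-state
pulses) plus the target traces the readout should produce.  Trials are
rendered onto the simulation grid by :func:`render_trial`, yielding the
Kenyon-cell drive, the external-input channels, the target time series and
the rate-reset flags consumed by the unroll.

Conventions (shared by every paradigm):

* odors are sparse binary KC patterns with exactly ``round(0.1 * n_kc)``
  active cells;
* CS and US pulses last 2 s; within a 30-s interval, presentation onsets
  are drawn uniformly between 5 s and 15 s;
* the US follows the CS immediately at its offset (configurable gap);
* external-input channel 0 carries positive-valence US, channel 1 negative
  valence; state-pulse channels (state task) or wind channels (navigation)
  follow;
* firing rates are reset at the beginning of each interval, which prevents
  the network from using persistent activity to store associations;
* target valence is +/-1 (times ``valence_scale``) during test-window CS
  presentations and 0 elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusEvent",
    "Interval",
    "Trial",
    "RenderedTrial",
    "ConditioningOptions",
    "encode_odor",
    "make_conditioning_trial",
    "make_training_trial",
    "make_continual_sequence",
    "make_state_trial",
    "make_nonplastic_env_trial",
    "render_trial",
    "render_batch",
]

CONDITIONING_PARADIGMS = ("first_order", "cs_minus", "extinction",
                          "second_order", "reversal")


@dataclass
class StimulusEvent:
    kind: str                      # "CS" | "US" | "state_pulse"
    onset: float                   # s, relative to interval start
    duration: float = 2.0
    odor_id: int | None = None     # CS only
    valence: float | None = None   # US only, +/-1
    state_id: int | None = None    # state_pulse only
    amplitude: float = 1.0
    target_valence: float = 0.0    # valence target active during a CS window
    novelty: float = 0.0           # novelty target active during a CS window


@dataclass
class Interval:
    duration: float = 30.0
    reset: bool = True
    events: list[StimulusEvent] = field(default_factory=list)


@dataclass
class Trial:
    """A scheduled sequence of intervals with targets and odor patterns."""

    intervals: list[Interval]
    kc_patterns: dict[int, np.ndarray]
    d_ext: int = 2
    test_windows: list[tuple[float, float]] = field(default_factory=list)
    state_spans: list[tuple[float, int]] | None = None
    paradigm: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return sum(iv.duration for iv in self.intervals)

    def absolute_events(self):
        """Yield (absolute_onset, event) pairs in schedule order."""
        t0 = 0.0
        for iv in self.intervals:
            for ev in iv.events:
                if not 0.0 <= ev.onset and ev.onset + ev.duration <= iv.duration:
                    raise ValueError("event does not fit within its interval")
                yield t0 + ev.onset, ev
            t0 += iv.duration

    # -- JSON round trip for exact replay ------------------------------------

    def to_json(self) -> str:
        def ev_dict(ev):
            return {k: v for k, v in ev.__dict__.items() if v is not None}
        doc = {
            "paradigm": self.paradigm,
            "d_ext": self.d_ext,
            "test_windows": self.test_windows,
            "state_spans": self.state_spans,
            "meta": self.meta,
            "intervals": [{"duration": iv.duration, "reset": iv.reset,
                           "events": [ev_dict(e) for e in iv.events]}
                          for iv in self.intervals],
            "kc_patterns": {str(k): np.flatnonzero(v).tolist()
                            for k, v in self.kc_patterns.items()},
            "n_kc": {k: int(v.size) for k, v in self.kc_patterns.items()},
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Trial":
        doc = json.loads(text)
        patterns = {}
        for key, active in doc["kc_patterns"].items():
            n = doc["n_kc"][key]
            vec = np.zeros(n)
            vec[active] = 1.0
            patterns[int(key)] = vec
        intervals = [
            Interval(duration=iv["duration"], reset=iv["reset"],
                     events=[StimulusEvent(**e) for e in iv["events"]])
            for iv in doc["intervals"]
        ]
        spans = doc["state_spans"]
        return cls(intervals=intervals, kc_patterns=patterns,
                   d_ext=doc["d_ext"],
                   test_windows=[tuple(w) for w in doc["test_windows"]],
                   state_spans=[tuple(s) for s in spans] if spans else None,
                   paradigm=doc["paradigm"], meta=doc["meta"])


@dataclass
class ConditioningOptions:
    """Task constants shared across paradigms (defaults are the study
    conditions; see the methods note)."""

    n_kc: int = 200
    sparsity: float = 0.1
    interval_duration: float = 30.0
    cs_duration: float = 2.0
    us_duration: float = 2.0
    cs_us_gap: float = 0.0
    onset_range: tuple[float, float] = (5.0, 15.0)
    us_amplitude: float = 1.0
    valence_scale: float = 1.0
    extinction_residual: float = 0.5
    omission_prob: float = 0.5
    # continual learning
    continual_duration: float = 200.0
    n_cs_plus: int = 2
    n_cs_minus: int = 2
    mean_presentations: float = 2.0
    # state task
    state_duration: float = 300.0
    n_states: int = 3
    state_gap_base: float = 10.0
    state_pulse_duration: float = 2.0
    with_conditioning: bool = True
    probe_retest_delay: float = 30.0
    probe_retest_duration: float = 5.0


def encode_odor(n_kc: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Sparse binary KC code: exactly ``round(sparsity * n_kc)`` cells set to
    1, support uniformly random."""
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    k = int(round(sparsity * n_kc))
    if k < 1:
        raise ValueError("sparsity * n_kc must be at least 1")
    pattern = np.zeros(n_kc)
    pattern[rng.choice(n_kc, size=k, replace=False)] = 1.0
    return pattern


def _mark_novelty(trial: Trial) -> None:
    """Set the novelty target to 1 during the first presentation of each odor."""
    seen: set[int] = set()
    for _, ev in sorted(trial.absolute_events(), key=lambda p: p[0]):
        if ev.kind == "CS":
            if ev.odor_id not in seen:
                ev.novelty = 1.0
                seen.add(ev.odor_id)


def _cs(opts, onset, odor, target=0.0):
    return StimulusEvent("CS", onset, opts.cs_duration, odor_id=odor,
                         target_valence=target)


def _us(opts, cs_onset, sign):
    onset = cs_onset + opts.cs_duration + opts.cs_us_gap
    return StimulusEvent("US", onset, opts.us_duration, valence=sign,
                         amplitude=opts.us_amplitude)


def make_conditioning_trial(paradigm: str, rng: np.random.Generator,
                            options: ConditioningOptions | None = None,
                            omission: str | None = None) -> Trial:
    """Build a trial of one of the classical-conditioning paradigms.

    ``omission`` produces the target-consistent variants used during
    optimization: ``"us"`` removes the reinforcement (all valence targets
    become 0) and ``"middle"`` removes the middle-interval presentation
    (extinction collapses to first-order conditioning; second-order loses
    the CS1-CS2 pairing so the CS2 target becomes 0).
    """
    opts = options or ConditioningOptions()
    if paradigm not in CONDITIONING_PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if omission not in (None, "us", "middle"):
        raise ValueError(f"unknown omission {omission!r}")

    def onset():
        return rng.uniform(*opts.onset_range)

    sign = float(rng.choice([-1.0, 1.0]))
    target = sign * opts.valence_scale
    patterns = {0: encode_odor(opts.n_kc, opts.sparsity, rng)}
    iv = lambda events: Interval(opts.interval_duration, True, events)
    meta = {"us_sign": sign, "omission": omission}

    if paradigm == "first_order":
        on1, on2 = onset(), onset()
        intervals = [iv([_cs(opts, on1, 0), _us(opts, on1, sign)]),
                     iv([_cs(opts, on2, 0, target)])]
        if omission == "us":
            intervals[0].events = [_cs(opts, on1, 0)]
            intervals[1].events[0].target_valence = 0.0

    elif paradigm == "cs_minus":
        intervals = [iv([_cs(opts, onset(), 0)]), iv([_cs(opts, onset(), 0)])]

    elif paradigm == "extinction":
        on1, on2, on3 = onset(), onset(), onset()
        residual = sign * opts.valence_scale * opts.extinction_residual
        intervals = [iv([_cs(opts, on1, 0), _us(opts, on1, sign)]),
                     iv([_cs(opts, on2, 0, target)]),
                     iv([_cs(opts, on3, 0, residual)])]
        if omission == "us":
            intervals[0].events = [_cs(opts, on1, 0)]
            for k in (1, 2):
                intervals[k].events[0].target_valence = 0.0
        elif omission == "middle":
            intervals[1].events = []
            intervals[2].events[0].target_valence = target

    elif paradigm == "second_order":
        patterns[1] = encode_odor(opts.n_kc, opts.sparsity, rng)
        on1, on2, on3 = onset(), onset(), onset()
        cs1_paired = _cs(opts, on2 + opts.cs_duration + opts.cs_us_gap, 0, target)
        intervals = [iv([_cs(opts, on1, 0), _us(opts, on1, sign)]),
                     iv([_cs(opts, on2, 1), cs1_paired]),
                     iv([_cs(opts, on3, 1, target)])]
        if omission == "us":
            intervals[0].events = [_cs(opts, on1, 0)]
            intervals[1].events[1].target_valence = 0.0
            intervals[2].events[0].target_valence = 0.0
        elif omission == "middle":
            intervals[1].events = [_cs(opts, on2, 1)]
            intervals[2].events[0].target_valence = 0.0

    else:  # reversal (evaluation-only; S-figure protocol)
        patterns[1] = encode_odor(opts.n_kc, opts.sparsity, rng)
        early = lambda: rng.uniform(5.0, 10.0)
        late = lambda: rng.uniform(18.0, 23.0)
        on1 = early()
        on2r = early()
        intervals = [iv([_cs(opts, on1, 0), _us(opts, on1, sign),
                         _cs(opts, late(), 1)]),
                     iv([_cs(opts, on2r, 1), _us(opts, on2r, sign),
                         _cs(opts, late(), 0, target)]),
                     iv([_cs(opts, early(), 0,
                             target * opts.extinction_residual),
                         _cs(opts, late(), 1, target)])]
        meta["cs1_odor"], meta["cs2_odor"] = 0, 1

    trial = Trial(intervals=intervals, kc_patterns=patterns, d_ext=2,
                  paradigm=paradigm, meta=meta)
    _mark_novelty(trial)
    # score over the final CS presentation of the trial (both final-interval
    # CS for reversal)
    t0 = sum(ivl.duration for ivl in intervals[:-1])
    windows = [(t0 + ev.onset, t0 + ev.onset + ev.duration)
               for ev in intervals[-1].events if ev.kind == "CS"]
    trial.test_windows = windows
    if paradigm == "reversal":
        trial.meta["cs1_window"], trial.meta["cs2_window"] = windows
    return trial


def make_training_trial(rng: np.random.Generator,
                        options: ConditioningOptions | None = None,
                        paradigms: tuple[str, ...] = ("extinction",
                                                      "second_order")) -> Trial:
    """Draw one trial from the optimization mixture: equal probability over
    the paradigm families, with probability ``omission_prob`` of a random
    CS/US omission (targets updated accordingly)."""
    opts = options or ConditioningOptions()
    paradigm = str(rng.choice(list(paradigms)))
    omission = None
    if rng.random() < opts.omission_prob:
        omission = str(rng.choice(["us", "middle"]))
        if paradigm in ("first_order", "cs_minus"):
            omission = "us" if paradigm == "first_order" else None
    return make_conditioning_trial(paradigm, rng, opts, omission=omission)


def make_continual_sequence(rng: np.random.Generator,
                            options: ConditioningOptions | None = None) -> Trial:
    """One 200-s continual-learning interval: two CS+ and two CS- odors,
    presentation counts Poisson(mean 2) each; every CS+ presentation is
    immediately reinforced with a random-sign US which defines the target of
    the *next* presentation of that odor (0 before the first pairing)."""
    opts = options or ConditioningOptions()
    n_odors = opts.n_cs_plus + opts.n_cs_minus
    patterns = {k: encode_odor(opts.n_kc, opts.sparsity, rng)
                for k in range(n_odors)}
    counts = rng.poisson(opts.mean_presentations, size=n_odors)
    block = opts.cs_duration + opts.cs_us_gap + opts.us_duration

    # (odor, is_plus, block_length) for every presentation
    entries = []
    for odor in range(opts.n_cs_plus):
        entries += [(odor, True, block)] * counts[odor]
    for odor in range(opts.n_cs_plus, n_odors):
        entries += [(odor, False, opts.cs_duration)] * counts[odor]

    # uniform non-overlapping placement: permute the blocks, drop their
    # total length from the interval, draw sorted uniform points in the
    # free space and re-insert the blocks (overlapping schedules would
    # make the pairing targets ill-defined)
    order_perm = rng.permutation(len(entries))
    total_len = sum(ln for _, _, ln in entries)
    free = opts.continual_duration - total_len
    if free <= 0:
        raise ValueError("stimulus load exceeds the interval duration")
    points = np.sort(rng.uniform(0.0, free, size=len(entries)))
    onsets = [0.0] * len(entries)
    acc = 0.0
    for point, idx in zip(points, order_perm):
        onsets[idx] = point + acc
        acc += entries[idx][2]

    events: list[StimulusEvent] = []
    order = np.argsort(onsets)
    last_sign: dict[int, float] = {}
    test_windows = []
    for idx in order:
        odor, is_plus, _ = entries[idx]
        on = onsets[idx]
        target = last_sign.get(odor, 0.0) * opts.valence_scale if is_plus else 0.0
        events.append(_cs(opts, on, odor, target))
        test_windows.append((on, on + opts.cs_duration))
        if is_plus:
            sign = float(rng.choice([-1.0, 1.0]))
            events.append(_us(opts, on, sign))
            last_sign[odor] = sign

    trial = Trial(intervals=[Interval(opts.continual_duration, True, events)],
                  kc_patterns=patterns, d_ext=2, paradigm="continual",
                  test_windows=test_windows,
                  meta={"counts": counts.tolist()})
    _mark_novelty(trial)
    return trial


def make_state_trial(rng: np.random.Generator,
                     options: ConditioningOptions | None = None,
                     probe: bool = False) -> Trial:
    """300-s internal-state trial: the network is driven through a random
    sequence of three discrete states, each transition announced by a 2-s
    pulse on the channel of the *next* state.  Inter-transition gaps follow
    10 s * (1 + Exp(1)).  With ``with_conditioning`` a CS/US pairing and a
    later rewarded re-presentation are embedded so valence must be tracked
    concurrently.  With ``probe`` a CS is placed 8 s before the second
    transition and re-presented for 5 s later (stimulus-state imprinting
    protocol); embedded conditioning is disabled.
    """
    opts = options or ConditioningOptions()
    dur = opts.state_duration
    state = int(rng.integers(opts.n_states))
    spans = [(0.0, state)]
    events: list[StimulusEvent] = []
    t = 0.0
    transitions = []
    while True:
        t = t + opts.state_gap_base * (1.0 + rng.exponential(1.0))
        if t + opts.state_pulse_duration >= dur:
            break
        nxt = int(rng.choice([s for s in range(opts.n_states) if s != state]))
        events.append(StimulusEvent("state_pulse", t, opts.state_pulse_duration,
                                    state_id=nxt))
        spans.append((t, nxt))
        transitions.append((t, nxt))
        state = nxt

    patterns: dict[int, np.ndarray] = {}
    test_windows: list[tuple[float, float]] = []
    meta: dict = {"transitions": transitions}

    if probe:
        if len(transitions) < 2:
            raise ValueError("probe trial requires at least two transitions")
        t2, s2 = transitions[1]
        patterns[0] = encode_odor(opts.n_kc, opts.sparsity, rng)
        events.append(_cs(opts, t2 - 8.0, 0))
        retest_on = min(t2 + opts.probe_retest_delay,
                        dur - opts.probe_retest_duration)
        events.append(StimulusEvent("CS", retest_on, opts.probe_retest_duration,
                                    odor_id=0))
        meta["probe_state"] = s2
        meta["retest_window"] = (retest_on, retest_on + opts.probe_retest_duration)
    elif opts.with_conditioning:
        sign = float(rng.choice([-1.0, 1.0]))
        patterns[0] = encode_odor(opts.n_kc, opts.sparsity, rng)
        patterns[1] = encode_odor(opts.n_kc, opts.sparsity, rng)
        pair_on = rng.uniform(20.0, 0.35 * dur)
        retest_on = rng.uniform(0.5 * dur, dur - 20.0)
        events += [_cs(opts, pair_on, 0), _us(opts, pair_on, sign),
                   _cs(opts, retest_on, 0, sign * opts.valence_scale),
                   _cs(opts, rng.uniform(20.0, 0.35 * dur), 1),
                   _cs(opts, rng.uniform(0.5 * dur, dur - 20.0), 1)]
        test_windows.append((retest_on, retest_on + opts.cs_duration))
        meta["us_sign"] = sign

    trial = Trial(intervals=[Interval(dur, True, events)],
                  kc_patterns=patterns, d_ext=2 + opts.n_states,
                  paradigm="state_probe" if probe else "state",
                  test_windows=test_windows, state_spans=spans, meta=meta)
    _mark_novelty(trial)
    return trial


def make_nonplastic_env_trial(bank: list[np.ndarray], rng: np.random.Generator,
                              options: ConditioningOptions | None = None) -> Trial:
    """Fixed-odor-bank trial for the non-plastic comparison: CS+ pairing at
    5 s, probe at 15 s which is the same CS+ with probability 1/2 and a
    different bank odor otherwise; target valence is nonzero only when the
    probe is the CS+."""
    if len(bank) < 2:
        raise ValueError("odor bank needs at least 2 odors")
    opts = options or ConditioningOptions()
    sign = float(rng.choice([-1.0, 1.0]))
    cs_idx = int(rng.integers(len(bank)))
    same = bool(rng.random() < 0.5)
    if same:
        probe_idx = cs_idx
    else:
        probe_idx = int(rng.choice([k for k in range(len(bank)) if k != cs_idx]))
    target = sign * opts.valence_scale if same else 0.0
    events = [_cs(opts, 5.0, cs_idx), _us(opts, 5.0, sign),
              _cs(opts, 15.0, probe_idx, target)]
    patterns = {cs_idx: bank[cs_idx], probe_idx: bank[probe_idx]}
    trial = Trial(intervals=[Interval(opts.interval_duration, True, events)],
                  kc_patterns=patterns, d_ext=2, paradigm="nonplastic_env",
                  test_windows=[(15.0, 15.0 + opts.cs_duration)],
                  meta={"us_sign": sign, "probe_is_cs": same,
                        "cs_idx": cs_idx, "probe_idx": probe_idx})
    _mark_novelty(trial)
    return trial


# -- rendering ---------------------------------------------------------------

@dataclass
class RenderedTrial:
    """A trial sampled onto the integration grid."""

    t: np.ndarray            # (T,) times of each step
    kc: np.ndarray           # (T, n_kc)
    ext: np.ndarray          # (T, d_ext)
    target: np.ndarray       # (T, d_readout) valence (+ novelty)
    target_state: np.ndarray | None   # (T, n_states) one-hot, state task
    resets: np.ndarray       # (T,) bool, rate reset at step start
    test_mask: np.ndarray    # (T,) bool, steps scored by the error metric

    @property
    def n_steps(self) -> int:
        return self.t.size


def _render_into(trial: Trial, n_kc: int, dt: float, include_novelty: bool,
                 t, kc, ext, target, target_state, resets, test_mask):
    """Fill (pre-zeroed) trace arrays for one trial.  Separated out so
    batched rendering can write directly into reusable (T, B, .) buffers."""
    t0 = 0.0
    for iv in trial.intervals:
        idx = int(round(t0 / dt))
        if iv.reset and idx < t.size:
            resets[idx] = True
        t0 += iv.duration

    for onset, ev in trial.absolute_events():
        sel = (t >= onset) & (t < onset + ev.duration)
        if ev.kind == "CS":
            pattern = trial.kc_patterns[ev.odor_id]
            if pattern.size != n_kc:
                raise ValueError("odor pattern size does not match n_kc")
            kc[sel] += ev.amplitude * pattern
            target[sel, 0] += ev.target_valence
            if include_novelty:
                target[sel, 1] += ev.novelty
        elif ev.kind == "US":
            ext[sel, 0 if ev.valence > 0 else 1] += ev.amplitude
        elif ev.kind == "state_pulse":
            ext[sel, 2 + ev.state_id] += ev.amplitude
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    for w0, w1 in trial.test_windows:
        test_mask |= (t >= w0) & (t < w1)

    if trial.state_spans is not None:
        for k, (start, state) in enumerate(trial.state_spans):
            end = (trial.state_spans[k + 1][0]
                   if k + 1 < len(trial.state_spans) else trial.duration)
            sel = (t >= start) & (t < end)
            target_state[sel, state] = 1.0


def render_trial(trial: Trial, n_kc: int, dt: float = 0.5,
                 include_novelty: bool = False,
                 n_states: int = 3) -> RenderedTrial:
    """Deterministically render a trial to input and target traces.

    A pulse with onset ``s`` and duration ``d`` is active at step ``n`` iff
    ``s <= n*dt < s + d``; the readout produced after integrating step ``n``
    is compared against the target at step ``n``.
    """
    T = int(round(trial.duration / dt))
    t = np.arange(T) * dt
    kc = np.zeros((T, n_kc))
    ext = np.zeros((T, trial.d_ext))
    target = np.zeros((T, 2 if include_novelty else 1))
    target_state = (np.zeros((T, n_states))
                    if trial.state_spans is not None else None)
    resets = np.zeros(T, dtype=bool)
    test_mask = np.zeros(T, dtype=bool)
    _render_into(trial, n_kc, dt, include_novelty, t, kc, ext, target,
                 target_state, resets, test_mask)
    return RenderedTrial(t=t, kc=kc, ext=ext, target=target,
                         target_state=target_state, resets=resets,
                         test_mask=test_mask)


def render_batch(trials: list[Trial], n_kc: int, dt: float = 0.5,
                 include_novelty: bool = False, n_states: int = 3,
                 ws=None, dtype=float):
    """Render trials of identical structure into (T, B, ...) arrays.

    ``ws`` may be a buffer pool with an ``arr(key, shape, dtype)`` method
    (e.g. :class:`mbmeta.metalearn.engine.Workspace`); training loops pass
    one so per-epoch rendering reuses storage and writes float32 directly.
    """
    T = int(round(trials[0].duration / dt))
    B = len(trials)
    d_ext = trials[0].d_ext
    with_state = trials[0].state_spans is not None
    alloc = ws.arr if ws is not None else (lambda k, s, d: np.zeros(s, d))
    t = np.arange(T) * dt
    kc = alloc("rb_kc", (T, B, n_kc), dtype)
    ext = alloc("rb_ext", (T, B, d_ext), dtype)
    target = alloc("rb_target", (T, B, 2 if include_novelty else 1), dtype)
    target_state = alloc("rb_tstate", (T, B, n_states), dtype) \
        if with_state else None
    test_mask = alloc("rb_tmask", (T, B), bool)
    for a in (kc, ext, target, test_mask) + \
            ((target_state,) if with_state else ()):
        a[...] = 0
    resets = np.zeros(T, dtype=bool)
    scratch_resets = np.zeros(T, dtype=bool)
    for b, tr in enumerate(trials):
        if int(round(tr.duration / dt)) != T or tr.d_ext != d_ext or \
                (tr.state_spans is not None) != with_state:
            raise ValueError("trials in a batch must have the same duration")
        scratch_resets[:] = False
        _render_into(tr, n_kc, dt, include_novelty, t, kc[:, b], ext[:, b],
                     target[:, b],
                     target_state[:, b] if with_state else None,
                     scratch_resets, test_mask[:, b])
        if b == 0:
            resets[:] = scratch_resets
        elif not np.array_equal(scratch_resets, resets):
            raise ValueError("trials in a batch must share interval structure")
    return kc, ext, target, target_state, resets, test_mask


def export_rendered_csv(rendered: RenderedTrial, path: str | Path) -> None:
    """Write rendered input/target traces to CSV (one row per step)."""
    import pandas as pd

    cols = {"t": rendered.t,
            "n_active_kc": rendered.kc.sum(axis=1)}
    for j in range(rendered.ext.shape[1]):
        cols[f"ext_{j}"] = rendered.ext[:, j]
    for j in range(rendered.target.shape[1]):
        cols[f"target_{j}"] = rendered.target[:, j]
    cols["reset"] = rendered.resets.astype(int)
    cols["test_window"] = rendered.test_mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
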