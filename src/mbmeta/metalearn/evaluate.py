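"""Test-phase evaluation: frozen parameters, plasticity-only learning.

The headline behavioral metric is an error rate: a test trial counts as an
error when the reported valence deviates from the target by more than a
threshold anywhere in the scored window (the final CS presentation).  The
threshold is 0.2 for conditioning paradigms and 0.5 for the harder
continual-learning task.
"""

from __future__ import annotations

import numpy as np

from .. import navigation as nav
from ..params import CircuitParameters
from ..tasks import (ConditioningOptions, make_conditioning_trial,
                     make_continual_sequence, make_nonplastic_env_trial,
                     render_batch, render_trial)
from .engine import forward_batch, nav_forward_batch

__all__ = ["evaluate_error_rate", "evaluate_continual", "reversal_preference",
           "response_difference", "evaluate_navigation"]

DEFAULT_THRESHOLDS = {"continual": 0.5}


def _window_errors(readout, target, test_mask, threshold):
    dev = np.abs(readout - target[..., 0])
    dev = np.where(test_mask, dev, 0.0)
    return dev.max(axis=0) > threshold


def evaluate_error_rate(params: CircuitParameters, paradigm: str = "first_order",
                        n_trials: int = 50, threshold: float | None = None,
                        rng: np.random.Generator | int = 0,
                        options: ConditioningOptions | None = None,
                        plasticity_on: bool = True, pcfg=None,
                        W0: np.ndarray | None = None) -> dict:
    """Error rate over fresh test trials of a conditioning paradigm.

    Plastic weights start from baseline on every trial; only the inner
    (plasticity) learning operates.  ``W0`` substitutes trained KC->MBON
    weights for non-plastic networks.  Returns a dict with the rate, the
    per-trial error flags and the per-trial peak deviation.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if paradigm == "continual":
        return evaluate_continual(params, n_trials=n_trials,
                                  threshold=threshold or 0.5, rng=rng,
                                  options=options, pcfg=pcfg)
    threshold = DEFAULT_THRESHOLDS.get(paradigm, 0.2) if threshold is None \
        else threshold
    opts = options or ConditioningOptions(n_kc=params.n_kc)
    if n_trials == 0:
        return {"error_rate": float("nan"), "errors": np.zeros(0, dtype=bool),
                "max_deviation": np.zeros(0), "threshold": threshold}
    trials = [make_conditioning_trial(paradigm, rng, opts)
              for _ in range(n_trials)]
    kc, ext, target, _, resets, tmask = render_batch(
        trials, params.n_kc, params.dt,
        include_novelty=params.d_readout == 2)
    if W0 is not None:
        W0 = np.broadcast_to(W0, (n_trials,) + W0.shape[-2:])
    rec = forward_batch(params, kc, ext, resets, plasticity_on=plasticity_on,
                        pcfg=pcfg, W0=W0, w0=W0, dtype=np.float64)
    v = rec.readout[:, :, 0]
    dev = np.where(tmask, np.abs(v - target[:, :, 0]), 0.0)
    errors = dev.max(axis=0) > threshold
    return {"error_rate": float(errors.mean()), "errors": errors,
            "max_deviation": dev.max(axis=0), "threshold": threshold,
            "record": rec, "trials": trials}


def evaluate_continual(params: CircuitParameters, n_trials: int = 20,
                       warmup: int = 5, threshold: float = 0.5,
                       rng: np.random.Generator | int = 0,
                       options: ConditioningOptions | None = None,
                       pcfg=None) -> dict:
    """Sequential continual-learning evaluation with full weight carryover.

    Runs ``warmup + n_trials`` 200-s trials on one persistent chain
    (weights carried across trials), scoring the last ``n_trials``.  Also
    returns the final KC->MBON weights for the weight-distribution
    analysis.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opts = options or ConditioningOptions(n_kc=params.n_kc)
    w0 = W0 = None
    errors = []
    devs = []
    for k in range(warmup + n_trials):
        trial = make_continual_sequence(rng, opts)
        rt = render_trial(trial, params.n_kc, params.dt)
        rec = forward_batch(params, rt.kc[:, None], rt.ext[:, None],
                            rt.resets, plasticity_on=True, pcfg=pcfg,
                            w0=w0, W0=W0, dtype=np.float64)
        w0 = rec.w[-1]
        W0 = rec.W_kc_mbon[-1]
        if k >= warmup:
            v = rec.readout[:, 0, 0]
            dev = np.where(rt.test_mask, np.abs(v - rt.target[:, 0]), 0.0)
            errors.append(dev.max() > threshold)
            devs.append(dev.max())
    return {"error_rate": float(np.mean(errors)),
            "errors": np.asarray(errors), "max_deviation": np.asarray(devs),
            "threshold": threshold, "final_W": W0[0], "final_w": w0[0]}


def reversal_preference(params: CircuitParameters, n_trials: int = 20,
                        rng: np.random.Generator | int = 0,
                        options: ConditioningOptions | None = None,
                        pcfg=None) -> dict:
    """Reversal-learning generalization metric.

    After CS1->US pairing then reversal (CS2->US, CS1 unreinforced), the
    test-phase preference is the US-sign-aligned difference in mean
    reported valence between CS2 and CS1; positive values mean the
    reversed contingency was learned.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opts = options or ConditioningOptions(n_kc=params.n_kc)
    trials = [make_conditioning_trial("reversal", rng, opts)
              for _ in range(n_trials)]
    kc, ext, target, _, resets, _ = render_batch(
        trials, params.n_kc, params.dt,
        include_novelty=params.d_readout == 2)
    rec = forward_batch(params, kc, ext, resets, plasticity_on=True,
                        pcfg=pcfg, dtype=np.float64)
    t = np.arange(kc.shape[0]) * params.dt
    prefs, cs1_aligned, cs2_aligned = [], [], []
    for b, trial in enumerate(trials):
        v = rec.readout[:, b, 0]
        sign = trial.meta["us_sign"]
        w1 = trial.meta["cs1_window"]
        w2 = trial.meta["cs2_window"]
        v1 = v[(t >= w1[0]) & (t < w1[1])].mean()
        v2 = v[(t >= w2[0]) & (t < w2[1])].mean()
        prefs.append(sign * (v2 - v1))
        cs1_aligned.append(sign * v1)
        cs2_aligned.append(sign * v2)
    prefs = np.asarray(prefs)
    return {"preference": float(prefs.mean()), "per_trial": prefs,
            "cs1_aligned": float(np.mean(cs1_aligned)),
            "cs2_aligned": float(np.mean(cs2_aligned))}


def response_difference(params: CircuitParameters, bank, n_trials: int = 50,
                        rng: np.random.Generator | int = 0,
                        options: ConditioningOptions | None = None,
                        plasticity_on: bool = True,
                        W0: np.ndarray | None = None, pcfg=None) -> dict:
    """CS+ versus neutral-CS response difference in the fixed-odor-bank
    protocol (overgeneralization probe).

    For each trial the probe response is the mean reported valence during
    the probe window, aligned by the US sign.  The returned difference is
    mean(CS+ probes) - mean(neutral probes): ~1 for a network that answers
    only to the trained odor, ~0 for one that generalizes to the whole
    bank.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opts = options or ConditioningOptions(n_kc=params.n_kc)
    trials = [make_nonplastic_env_trial(bank, rng, opts)
              for _ in range(n_trials)]
    kc, ext, target, _, resets, tmask = render_batch(
        trials, params.n_kc, params.dt,
        include_novelty=params.d_readout == 2)
    if W0 is not None:
        W0 = np.broadcast_to(W0, (n_trials,) + W0.shape[-2:])
    rec = forward_batch(params, kc, ext, resets, plasticity_on=plasticity_on,
                        pcfg=pcfg, W0=W0, w0=W0, dtype=np.float64)
    v = rec.readout[:, :, 0]
    same = np.array([tr.meta["probe_is_cs"] for tr in trials])
    signs = np.array([tr.meta["us_sign"] for tr in trials])
    counts = tmask.sum(axis=0)
    probe_resp = (v * tmask).sum(axis=0) / np.maximum(counts, 1)
    aligned = signs * probe_resp
    if not (same.any() and (~same).any()):
        raise ValueError("need both probe types; increase n_trials")
    diff = float(aligned[same].mean() - aligned[~same].mean())
    return {"difference": diff, "aligned_response": aligned, "same": same}


def evaluate_navigation(params: CircuitParameters, n_trials: int = 50,
                        rng: np.random.Generator | int = 0,
                        plasticity_cond: bool = True,
                        plasticity_nav: bool = True, gamma: float = 0.5,
                        options: nav.NavOptions | None = None,
                        pcfg=None, return_record: bool = False,
                        ws=None) -> dict:
    """Mean final distance to the rewarded source over fresh navigation
    trials (the convergence criterion compares this to 0.4 m).

    The simulation record (rate/weight/trajectory histories, ~GB at 50
    trials) is returned only on request.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opts = options or nav.NavOptions()
    src, pat, theta0 = nav.sample_trial_batch(
        rng, n_trials, n_kc=params.n_kc, gamma=gamma, options=opts)
    kc_cond, ext_cond = nav.render_conditioning_phase(pat, opts, params.dt)
    Tn = int(round(opts.nav_duration / params.dt))
    rec = nav_forward_batch(params, kc_cond, ext_cond, Tn, src, theta0,
                            pat=pat, plasticity_cond=plasticity_cond,
                            plasticity_nav=plasticity_nav, pcfg=pcfg,
                            half_height=opts.half_height, dtype=np.float64,
                            ws=ws)
    dist = np.linalg.norm(rec.extras["x"][-1] - src[:, 0, :], axis=1)
    out = {"mean_distance": float(dist.mean()), "distances": dist}
    if return_record:
        out["record"] = rec
    return out
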