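"""Differentiable unroll: batched forward simulation and BPTT gradients.

This module wraps the numba kernels with a numpy interface.  The forward
pass reproduces, step for step, the reference operations in
:mod:`mbmeta.circuit` and :mod:`mbmeta.plasticity` (a property checked in
the tests); the backward pass returns gradients of the task losses with
respect to every meta-learned parameter.

``dtype`` selects the working precision: float32 for optimization runs,
float64 for gradient checks and reference comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..circuit import CircuitState
from ..params import CircuitParameters
from ..plasticity import PlasticityConfig
from . import _kernels as _k
from .losses import LossConfig

__all__ = ["ForwardRecord", "UnrollResult", "Workspace", "forward_batch",
           "loss_and_grads", "unroll", "nav_forward_batch",
           "nav_loss_and_grads"]


class Workspace:
    """Reusable buffer pool for repeated unrolls of identical shape.

    History arrays of a (T=180, B=30) unroll run to hundreds of megabytes;
    re-allocating (and first-touch faulting) them every epoch costs more
    than the arithmetic.  Training loops keep one workspace and pass it to
    :func:`loss_and_grads`.
    """

    def __init__(self) -> None:
        self._pool: dict = {}

    def arr(self, key: str, shape: tuple, dtype, zero: bool = False):
        full = (key, shape, np.dtype(dtype).str)
        buf = self._pool.get(full)
        if buf is None:
            buf = np.zeros(shape, dtype=dtype)
            self._pool[full] = buf
        elif zero:
            buf[...] = 0
        return buf

    def cast(self, key: str, array, dtype):
        if array.dtype == np.dtype(dtype) and array.flags["C_CONTIGUOUS"]:
            return array
        buf = self.arr(key, array.shape, dtype)
        buf[...] = array
        return buf


def _scalars(params: CircuitParameters, pcfg: PlasticityConfig, dtype):
    cast = np.dtype(dtype).type
    alpha = params.dt / params.tau
    rho = params.dt / pcfg.tau_w
    kap = params.dt / pcfg.tau_elig_kc
    dl = params.dt / pcfg.tau_elig_dan
    return tuple(cast(v) for v in (
        alpha, 1.0 - alpha, rho, 1.0 - rho, kap, 1.0 - kap, dl, 1.0 - dl,
        params.dt, pcfg.w_max))


def _pack(params: CircuitParameters, dtype):
    cast = lambda a: np.ascontiguousarray(a, dtype=dtype)
    G = params.gating_matrix()
    use_G = not (G.shape[0] == G.shape[1]
                 and np.array_equal(G, np.eye(G.shape[0])))
    return {
        "Wr": cast(params.W_recur),
        "WrT": cast(params.W_recur.T),
        "bvec": cast(params.b),
        "WextT": cast(params.W_ext.T),
        "r0": cast(params.rate_init()),
        "G": cast(G),
        "use_G": use_G,
        "beta_m": cast(params.beta_per_mbon()),
    }


@dataclass
class ForwardRecord:
    """Histories of a batched unroll (leading axis: step, 0 = initial)."""

    r: np.ndarray              # (T+1, B, N)
    w: np.ndarray              # (T+1, B, M, K)
    W_kc_mbon: np.ndarray      # (T+1, B, M, K)
    trace_kc: np.ndarray       # (T+1, B, K)
    trace_dan: np.ndarray      # (T+1, B, D)
    relu_mask: np.ndarray      # (T, B, N)
    readout: np.ndarray | None = None       # (T, B, d_readout)
    state_probs: np.ndarray | None = None   # (T, B, 3)
    extras: dict = field(default_factory=dict)

    def final_states(self, params: CircuitParameters) -> list[CircuitState]:
        B = self.r.shape[1]
        return [CircuitState(self.r[-1, b].astype(float),
                             self.w[-1, b].astype(float),
                             self.W_kc_mbon[-1, b].astype(float),
                             self.trace_kc[-1, b].astype(float),
                             self.trace_dan[-1, b].astype(float))
                for b in range(B)]


def forward_batch(params: CircuitParameters, kc: np.ndarray, ext: np.ndarray,
                  resets: np.ndarray, *, plasticity_on: bool = True,
                  pcfg: PlasticityConfig | None = None,
                  w0: np.ndarray | None = None, W0: np.ndarray | None = None,
                  dtype=np.float64, ws: Workspace | None = None,
                  store_W: bool = False) -> ForwardRecord:
    """Simulate a batch of rendered trials.

    ``kc`` (T, B, n_kc), ``ext`` (T, B, d_ext), ``resets`` (T,).  ``w0`` /
    ``W0`` override the plastic-weight initial condition (continual
    learning carryover, or the trained weights of a non-plastic network).
    With ``store_W`` the record carries the full effective-weight history;
    otherwise only the final value (the record's ``W_kc_mbon`` then has a
    single leading entry, so ``[-1]`` is the final state either way).
    """
    pcfg = pcfg or PlasticityConfig(w_max=params.w_max, dt=params.dt)
    ws = ws or Workspace()
    pk = _pack(params, dtype)
    sc = _scalars(params, pcfg, dtype)
    T, B, K = kc.shape
    N, M, D = params.n_total, params.n_mbon, params.n_dan

    r_h = ws.arr("r_h", (T + 1, B, N), dtype)
    r_h[0] = pk["r0"]
    w_run = ws.arr("w_run", (B, M, K), dtype)
    w_run[...] = params.w_max if w0 is None else w0
    clip_h = ws.arr("clip_h", (T, B, M, K), np.uint8)
    W_run = ws.arr("W_run", (B, M, K), dtype)
    W_run[...] = w_run if W0 is None else W0
    if store_W:
        W_h = ws.arr("W_h", (T + 1, B, M, K), dtype)
        W_h[0] = W_run
    else:
        W_h = W_run[None]
    p_h = ws.arr("p_h", (T + 1, B, K), dtype)
    p_h[0] = 0.0
    q_h = ws.arr("q_h", (T + 1, B, D), dtype)
    q_h[0] = 0.0
    mask = ws.arr("mask", (T, B, N), np.uint8)

    _k.forward_window(pk["WrT"], pk["bvec"], pk["WextT"], pk["r0"],
                      pk["G"], pk["use_G"], pk["beta_m"],
                      ws.cast("kc", kc, dtype),
                      ws.cast("ext", ext, dtype),
                      ws.cast("resets", resets, np.uint8),
                      *sc, plasticity_on,
                      r_h, w_run, clip_h, W_run, W_h, store_W, p_h, q_h,
                      mask)

    rec = ForwardRecord(r=r_h, w=w_run[None],
                        W_kc_mbon=W_h if store_W else W_run[None],
                        trace_kc=p_h, trace_dan=q_h, relu_mask=mask)
    rec.extras["clip_h"] = clip_h
    rec.readout = r_h[1:, :, :M] @ params.W_readout.T.astype(dtype)
    if params.W_state is not None:
        logits = r_h[1:, :, M:M + D] @ params.W_state.T.astype(dtype)
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        rec.state_probs = ez / ez.sum(axis=-1, keepdims=True)
    return rec


def _loss_terms(params: CircuitParameters, rec: ForwardRecord,
                target: np.ndarray, target_state: np.ndarray | None,
                cfg: LossConfig):
    """Loss pieces and the adjoint dL/dr_{t+1} (readout + DAN penalty +
    state terms), plus readout-weight gradients."""
    T, B = target.shape[:2]
    M, D = params.n_mbon, params.n_dan
    scale = 1.0 / (T * B)
    r_mbon = rec.r[1:, :, :M]
    r_dan = rec.r[1:, :, M:M + D]
    gout_r = np.zeros((T, B, params.n_total))

    resid = rec.readout.astype(float) - target
    loss_read = float((resid ** 2).sum() * scale)
    gout_r[:, :, :M] = 2.0 * scale * np.einsum(
        "tbd,dm->tbm", resid, params.W_readout)
    gW_readout = 2.0 * scale * np.einsum("tbd,tbm->dm", resid,
                                         r_mbon.astype(float))

    parts = {"readout": loss_read}
    grads_extra = {"W_readout": gW_readout}

    if cfg.include_dan_penalty and cfg.lambda_dan > 0:
        pen = np.maximum(r_dan.astype(float) - cfg.dan_baseline, 0.0)
        parts["dan_penalty"] = float(cfg.lambda_dan * (pen ** 2).sum() * scale)
        gout_r[:, :, M:M + D] += 2.0 * cfg.lambda_dan * scale * pen

    if target_state is not None:
        if rec.state_probs is None:
            raise ValueError("state loss requires params.W_state")
        s = rec.state_probs.astype(float)
        resid_s = s - target_state
        parts["state"] = float((resid_s ** 2).sum() * scale)
        ds = 2.0 * scale * resid_s
        glog = s * (ds - (ds * s).sum(axis=-1, keepdims=True))
        grads_extra["W_state"] = np.einsum("tbc,tbd->cd", glog,
                                           r_dan.astype(float))
        gout_r[:, :, M:M + D] += glog @ params.W_state

    return parts, gout_r, grads_extra


def loss_and_grads(params: CircuitParameters, kc, ext, resets, target,
                   target_state=None, *, loss_cfg: LossConfig | None = None,
                   plasticity_on: bool = True,
                   pcfg: PlasticityConfig | None = None,
                   w0=None, W0=None, nonplastic_train: bool = False,
                   dtype=np.float32, ws: Workspace | None = None):
    """Loss and parameter gradients for a batch of rendered trials.

    Returns ``(loss, parts, grads, record)``.  ``grads`` holds entries for
    W_recur, b, W_ext, W_readout and, when present in the parameters,
    W_state and beta; with ``nonplastic_train`` it additionally holds the
    gradient with respect to the (fixed) KC->MBON weight matrix.
    """
    loss_cfg = loss_cfg or LossConfig()
    pcfg = pcfg or PlasticityConfig(w_max=params.w_max, dt=params.dt)
    ws = ws or Workspace()
    rec = forward_batch(params, kc, ext, resets, plasticity_on=plasticity_on,
                        pcfg=pcfg, w0=w0, W0=W0, dtype=dtype, ws=ws)
    parts, gout_r, grads_extra = _loss_terms(params, rec, target,
                                             target_state, loss_cfg)

    pk = _pack(params, dtype)
    sc = _scalars(params, pcfg, dtype)
    T, B, K = kc.shape
    N, M, D = params.n_total, params.n_mbon, params.n_dan
    F = params.n_fbn
    gr = ws.arr("gr", (B, N), dtype, zero=True)
    gw = ws.arr("gw", (B, M, K), dtype, zero=True)
    gW = ws.arr("gW", (B, M, K), dtype, zero=True)
    gp = ws.arr("gp", (B, K), dtype, zero=True)
    gq = ws.arr("gq", (B, D), dtype, zero=True)
    gWr = ws.arr("gWr", (N, N), dtype, zero=True)
    gb = ws.arr("gb", (N,), dtype, zero=True)
    gWext = ws.arr("gWext", (F, params.d_ext), dtype, zero=True)
    gbeta_m = ws.arr("gbeta_m", (M,), dtype, zero=True)

    _k.backward_window(pk["Wr"], pk["WrT"], pk["bvec"], pk["WextT"],
                       pk["r0"], pk["G"], pk["use_G"], pk["beta_m"],
                       ws.cast("kc", kc, dtype),
                       ws.cast("ext", ext, dtype),
                       ws.cast("resets", resets, np.uint8),
                       *sc, plasticity_on,
                       rec.r, rec.extras["clip_h"], rec.W_kc_mbon,
                       rec.trace_kc, rec.trace_dan, rec.relu_mask,
                       ws.cast("gout_r", gout_r, dtype),
                       gr, gw, gW, gp, gq, gWr, gb, gWext, gbeta_m)

    grads = {"W_recur": gWr.astype(float), "b": gb.astype(float),
             "W_ext": gWext.astype(float)}
    grads.update(grads_extra)
    if params.beta is not None:
        grads["beta"] = np.bincount(params.mbon_compartment,
                                    weights=gbeta_m.astype(float),
                                    minlength=params.n_compartments)
    if nonplastic_train:
        grads["W_kc_mbon"] = gW.astype(float).sum(axis=0)
    loss = float(sum(parts.values()))
    return loss, parts, grads, rec


# ---------------------------------------------------------------------------
# single-trial unroll (the library-facing simulation op)
# ---------------------------------------------------------------------------

@dataclass
class UnrollResult:
    """Single-trial simulation output."""

    t: np.ndarray               # (T,)
    rates: np.ndarray           # (T+1, N); row 0 is the initial state
    readout: np.ndarray         # (T, d_readout)
    state_probs: np.ndarray | None
    final_state: CircuitState
    record: ForwardRecord


def unroll(params: CircuitParameters, trial, *, plasticity_on: bool = True,
           pcfg: PlasticityConfig | None = None,
           include_novelty: bool | None = None,
           state: CircuitState | None = None,
           dtype=np.float64) -> UnrollResult:
    """Simulate one :class:`~mbmeta.tasks.Trial` through the plastic circuit.

    Interleaves the rate step, the plasticity step and the trace update at
    every timestep and applies the interval rate-resets.  ``state`` sets the
    initial plastic weights/traces (continual learning); rates always start
    from r0.
    """
    from ..tasks import render_trial

    if include_novelty is None:
        include_novelty = params.d_readout == 2
    rt = render_trial(trial, params.n_kc, params.dt,
                      include_novelty=include_novelty)
    kc = rt.kc[:, None, :]
    ext = rt.ext[:, None, :]
    w0 = W0 = None
    if state is not None:
        w0 = state.w[None]
        W0 = state.W_kc_mbon[None]
    rec = forward_batch(params, kc, ext, rt.resets,
                        plasticity_on=plasticity_on, pcfg=pcfg,
                        w0=w0, W0=W0, dtype=dtype)
    if not np.all(np.isfinite(rec.r)):
        raise FloatingPointError("non-finite firing rates during unroll")
    return UnrollResult(
        t=rt.t, rates=rec.r[:, 0], readout=rec.readout[:, 0],
        state_probs=None if rec.state_probs is None else rec.state_probs[:, 0],
        final_state=rec.final_states(params)[0], record=rec)


# ---------------------------------------------------------------------------
# navigation
# ---------------------------------------------------------------------------

def _nav_alloc(params, Tc, Tn, B, dtype, ws: Workspace):
    N, M, D, K = params.n_total, params.n_mbon, params.n_dan, params.n_kc
    T = Tc + Tn
    return {
        "r": ws.arr("nav_r", (T + 1, B, N), dtype),
        "w_run": ws.arr("nav_wrun", (B, M, K), dtype),
        "clip": ws.arr("nav_clip", (T, B, M, K), np.uint8),
        "W": ws.arr("nav_W", (T + 1, B, M, K), dtype),
        "p": ws.arr("nav_p", (T + 1, B, K), dtype),
        "q": ws.arr("nav_q", (T + 1, B, D), dtype),
        "mask": ws.arr("nav_mask", (T, B, N), np.uint8),
    }


def nav_forward_batch(params: CircuitParameters, kc_cond, ext_cond, Tn, src,
                      theta0, *, pat, plasticity_cond=True,
                      plasticity_nav=True, pcfg=None, half_height=0.25,
                      dtype=np.float64, ws: Workspace | None = None):
    """Conditioning phase followed by the closed-loop navigation phase.

    ``kc_cond``/``ext_cond`` (Tc, B, ·) drive the conditioning interval
    (6 external channels: US+, US-, four wind channels held at 0).  ``src``
    (B, 2, 2) holds the two odor-source positions (index 0 = rewarded),
    ``pat`` (B, 2, K) the corresponding KC patterns and ``theta0`` (B,) the
    initial headings.  Rates are reset at the start of both phases.
    """
    pcfg = pcfg or PlasticityConfig(w_max=params.w_max, dt=params.dt)
    ws = ws or Workspace()
    pk = _pack(params, dtype)
    sc = _scalars(params, pcfg, dtype)
    Tc, B, K = kc_cond.shape
    N, M, D = params.n_total, params.n_mbon, params.n_dan
    buf = _nav_alloc(params, Tc, Tn, B, dtype, ws)
    r_h, w_run, clip_h, W_h, p_h, q_h, mask = (
        buf["r"], buf["w_run"], buf["clip"], buf["W"], buf["p"], buf["q"],
        buf["mask"])
    r_h[:] = 0.0
    p_h[:] = 0.0
    q_h[:] = 0.0
    r_h[0] = pk["r0"]
    w_run[...] = params.w_max
    W_h[0] = params.w_max

    resets_cond = np.zeros(Tc, dtype=np.uint8)
    resets_cond[0] = 1
    W_run = np.empty((B, M, params.n_kc), dtype=dtype)
    W_run[...] = W_h[0]
    _k.forward_window(pk["WrT"], pk["bvec"], pk["WextT"], pk["r0"],
                      pk["G"], pk["use_G"], pk["beta_m"],
                      np.ascontiguousarray(kc_cond, dtype=dtype),
                      np.ascontiguousarray(ext_cond, dtype=dtype),
                      resets_cond, *sc, plasticity_cond,
                      r_h[:Tc + 1], w_run, clip_h[:Tc], W_run,
                      W_h[:Tc + 1], True, p_h[:Tc + 1], q_h[:Tc + 1],
                      mask[:Tc])

    cast = np.dtype(dtype).type
    x_h = ws.arr("nav_x", (Tn + 1, B, 2), dtype, zero=True)
    th_h = ws.arr("nav_th", (Tn + 1, B), dtype, zero=True)
    u_h = ws.arr("nav_u", (Tn, B), dtype, zero=True)
    om_h = ws.arr("nav_om", (Tn, B), dtype, zero=True)
    c_h = ws.arr("nav_c", (Tn, B, 2), dtype, zero=True)
    act_h = ws.arr("nav_act", (Tn, B), np.int8, zero=True)
    zu_h = ws.arr("nav_zu", (Tn, B), dtype, zero=True)
    kc_buf = ws.arr("nav_kcbuf", (Tn, B, K), dtype, zero=True)
    ext_buf = ws.arr("nav_extbuf", (Tn, B, 6), dtype, zero=True)
    resets_nav = np.zeros(Tn, dtype=np.uint8)
    resets_nav[0] = 1
    wdir = -np.sign(src[:, :, 0]).astype(dtype)
    src_c = np.ascontiguousarray(src, dtype=dtype)
    pat_c = np.ascontiguousarray(pat, dtype=dtype)

    _k.forward_nav(pk["WrT"], pk["bvec"], pk["WextT"], pk["r0"],
                   pk["G"], pk["use_G"], pk["beta_m"],
                   *sc, plasticity_nav,
                   src_c, wdir, pat_c, cast(half_height),
                   np.ascontiguousarray(params.W_u, dtype=dtype), cast(params.b_u),
                   np.ascontiguousarray(params.W_omega, dtype=dtype),
                   cast(params.b_omega),
                   np.ascontiguousarray(theta0, dtype=dtype), resets_nav,
                   r_h[Tc:], w_run, clip_h[Tc:], W_h[Tc:], p_h[Tc:],
                   q_h[Tc:], mask[Tc:],
                   x_h, th_h, u_h, om_h, c_h, act_h, zu_h, kc_buf, ext_buf)

    rec = ForwardRecord(r=r_h, w=w_run[None], W_kc_mbon=W_h, trace_kc=p_h,
                        trace_dan=q_h, relu_mask=mask)
    rec.extras["clip_h"] = clip_h
    rec.extras.update({"x": x_h, "theta": th_h, "u": u_h, "omega": om_h,
                       "c": c_h, "active": act_h, "zu": zu_h,
                       "kc_nav": kc_buf, "ext_nav": ext_buf, "Tc": Tc,
                       "wdir": wdir, "src": src_c, "pat": pat_c,
                       "half_height": half_height})
    return rec


def nav_loss_and_grads(params: CircuitParameters, kc_cond, ext_cond, Tn, src,
                       theta0, *, pat, plasticity_cond=True,
                       plasticity_nav=True, pcfg=None, half_height=0.25,
                       dtype=np.float32, ws: Workspace | None = None):
    """Squared final distance to the rewarded source, averaged over the
    batch, and its gradients with respect to all circuit and velocity
    parameters."""
    pcfg = pcfg or PlasticityConfig(w_max=params.w_max, dt=params.dt)
    ws = ws or Workspace()
    rec = nav_forward_batch(params, kc_cond, ext_cond, Tn, src, theta0,
                            pat=pat, plasticity_cond=plasticity_cond,
                            plasticity_nav=plasticity_nav, pcfg=pcfg,
                            half_height=half_height, dtype=dtype, ws=ws)
    ex = rec.extras
    x_h, th_h = ex["x"], ex["theta"]
    if not np.all(np.isfinite(x_h)):
        raise FloatingPointError("non-finite agent position during navigation")
    Tc = ex["Tc"]
    B = x_h.shape[1]
    err = x_h[-1].astype(float) - src[:, 0, :]
    loss = float((err ** 2).sum() / B)
    final_dist = np.linalg.norm(err, axis=1)

    pk = _pack(params, dtype)
    sc = _scalars(params, pcfg, dtype)
    N, M, D, K = params.n_total, params.n_mbon, params.n_dan, params.n_kc
    F = params.n_fbn
    cast = np.dtype(dtype).type
    gx = np.ascontiguousarray(2.0 / B * err, dtype=dtype)
    gr = np.zeros((B, N), dtype=dtype)
    gw = np.zeros((B, M, K), dtype=dtype)
    gW = np.zeros((B, M, K), dtype=dtype)
    gp = np.zeros((B, K), dtype=dtype)
    gq = np.zeros((B, D), dtype=dtype)
    gWr = np.zeros((N, N), dtype=dtype)
    gb = np.zeros(N, dtype=dtype)
    gWext = np.zeros((F, 6), dtype=dtype)
    gbeta_m = np.zeros(M, dtype=dtype)
    gWu = np.zeros(N, dtype=dtype)
    gWw = np.zeros(N, dtype=dtype)
    gbu = np.zeros(1, dtype=dtype)
    gbw = np.zeros(1, dtype=dtype)
    resets_nav = np.zeros(Tn, dtype=np.uint8)
    resets_nav[0] = 1

    _k.backward_nav(pk["Wr"], pk["WrT"], pk["bvec"], pk["WextT"], pk["r0"],
                    pk["G"], pk["use_G"], pk["beta_m"],
                    *sc, plasticity_nav,
                    ex["src"], ex["wdir"], ex["pat"], cast(half_height),
                    np.ascontiguousarray(params.W_u, dtype=dtype),
                    np.ascontiguousarray(params.W_omega, dtype=dtype),
                    resets_nav,
                    rec.r[Tc:], rec.extras["clip_h"][Tc:], rec.W_kc_mbon[Tc:],
                    rec.trace_kc[Tc:], rec.trace_dan[Tc:], rec.relu_mask[Tc:],
                    ex["x"], ex["theta"], ex["u"], ex["omega"], ex["c"],
                    ex["active"], ex["zu"], ex["kc_nav"], ex["ext_nav"],
                    gx, gr, gw, gW, gp, gq,
                    gWr, gb, gWext, gbeta_m, gWu, gbu, gWw, gbw)

    Tc_steps = kc_cond.shape[0]
    resets_cond = np.zeros(Tc_steps, dtype=np.uint8)
    resets_cond[0] = 1
    gout_r = np.zeros((Tc_steps, B, N), dtype=dtype)
    _k.backward_window(pk["Wr"], pk["WrT"], pk["bvec"], pk["WextT"],
                       pk["r0"], pk["G"], pk["use_G"], pk["beta_m"],
                       np.ascontiguousarray(kc_cond, dtype=dtype),
                       np.ascontiguousarray(ext_cond, dtype=dtype),
                       resets_cond, *sc, plasticity_cond,
                       rec.r[:Tc + 1], rec.extras["clip_h"][:Tc],
                       rec.W_kc_mbon[:Tc + 1],
                       rec.trace_kc[:Tc + 1], rec.trace_dan[:Tc + 1],
                       rec.relu_mask[:Tc],
                       gout_r, gr, gw, gW, gp, gq, gWr, gb, gWext, gbeta_m)

    grads = {"W_recur": gWr.astype(float), "b": gb.astype(float),
             "W_ext": gWext.astype(float),
             "W_u": gWu.astype(float), "b_u": float(gbu[0]),
             "W_omega": gWw.astype(float), "b_omega": float(gbw[0])}
    if params.beta is not None:
        grads["beta"] = np.bincount(params.mbon_compartment,
                                    weights=gbeta_m.astype(float),
                                    minlength=params.n_compartments)
    return loss, grads, rec, final_dist
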