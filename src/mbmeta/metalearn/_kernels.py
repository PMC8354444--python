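"""Numba kernels for the differentiable unroll (forward and adjoint).

The meta-learning outer loop needs gradients of task losses with respect to
the circuit parameters, propagated through the full unrolled dynamics
(rate updates, plasticity rule, eligibility traces and — for navigation —
the agent kinematics and plume sensing).  These kernels implement
backpropagation through time by hand: the forward pass stores the
trajectory, the backward pass walks it in reverse accumulating
vector-Jacobian products.  Correctness is checked against central finite
differences in the test suite.

Shape conventions: T timesteps, B batch, N circuit neurons
(M MBONs | D DANs | F FBNs in that order), K Kenyon cells, E external
channels.  ``W_recur`` is passed both plain (``Wr``, used in the adjoint)
and transposed (``WrT``, used in the forward matmul); ``WextT`` is the
(E, F) transpose of ``W_ext``.  All scalar rates (``alpha = dt/tau`` etc.)
are passed pre-cast to the array dtype together with their complements so
float32 and float64 compile to clean single-precision/double kernels.

Per-step operation order (mirrored exactly by the reference simulator in
:mod:`mbmeta.circuit` / :mod:`mbmeta.plasticity`):

1. rate reset (interval boundary), 2. Euler rate step, 3. plasticity using
pre-update traces and the post-step DAN rates, 4. trace update,
5. readouts/losses.
"""

import numpy as np
from numba import njit

__all__ = ["forward_window", "backward_window", "forward_nav", "backward_nav"]

# Downwind displacement below which concentration is treated as zero.
# The plume-tip gradient scales like dx2^2/dx1^2 and is singular at the
# source; cutting the plume 1 cm downwind (below the ~1 cm/step movement
# resolution) bounds it without affecting behavior.
_EPS_D1 = 1e-2


@njit(cache=True, fastmath=True)
def _rate_forward(rt, kc_t, ext_t, WrT, bvec, WextT, W_t, alpha, om_alpha,
                  r_out, mask_out, M, D):
    """One Euler step of the rate dynamics. rt is the post-reset rate."""
    B, N = rt.shape
    K = kc_t.shape[1]
    E = WextT.shape[0]
    nMD = M + D
    a = np.dot(rt, WrT)
    for b in range(B):
        for i in range(N):
            ai = a[b, i] + bvec[i]
            if i < M:
                acc = ai * 0
                for j in range(K):
                    acc += W_t[b, i, j] * kc_t[b, j]
                ai += acc
            elif i >= nMD:
                f = i - nMD
                acc = ai * 0
                for e in range(E):
                    acc += WextT[e, f] * ext_t[b, e]
                ai += acc
            if ai > 0.0:
                mask_out[b, i] = 1
                r_out[b, i] = om_alpha * rt[b, i] + alpha * ai
            else:
                mask_out[b, i] = 0
                r_out[b, i] = om_alpha * rt[b, i]


@njit(cache=True, fastmath=True)
def _plast_forward(r_new, kc_t, w_run, W_t, W_out, p_t, q_t, G, use_G,
                   beta_m, dtv, wmax, rho, om_rho, clip_t, M, D):
    """Plasticity update in place on the running latent weights; records
    which synapses took an unclipped update (the only fact the adjoint
    needs about w)."""
    B = r_new.shape[0]
    K = kc_t.shape[1]
    for b in range(B):
        for i in range(M):
            if use_G:
                de = r_new[b, M] * 0
                qe = de
                for d in range(D):
                    de += G[i, d] * r_new[b, M + d]
                    qe += G[i, d] * q_t[b, d]
            else:
                de = r_new[b, M + i]
                qe = q_t[b, i]
            bq = beta_m[i] * qe
            for j in range(K):
                dw = qe * kc_t[b, j] - p_t[b, j] * de + bq
                u = w_run[b, i, j] + dtv * dw
                if 0.0 < u < wmax:
                    clip_t[b, i, j] = 1
                else:
                    clip_t[b, i, j] = 0
                    u = 0.0 if u <= 0.0 else (u if u < wmax else wmax)
                w_run[b, i, j] = u
                W_out[b, i, j] = om_rho * W_t[b, i, j] + rho * u


@njit(cache=True, fastmath=True)
def _plast_forward_io(r_new, kc_t, w_run, W_run, p_t, q_t, G, use_G,
                      beta_m, dtv, wmax, rho, om_rho, clip_t, M, D):
    """In-place variant of :func:`_plast_forward` (single effective-weight
    buffer; passing one array twice would defeat alias analysis and drop
    the loop to scalar code)."""
    B = r_new.shape[0]
    K = kc_t.shape[1]
    for b in range(B):
        for i in range(M):
            if use_G:
                de = r_new[b, M] * 0
                qe = de
                for d in range(D):
                    de += G[i, d] * r_new[b, M + d]
                    qe += G[i, d] * q_t[b, d]
            else:
                de = r_new[b, M + i]
                qe = q_t[b, i]
            bq = beta_m[i] * qe
            for j in range(K):
                dw = qe * kc_t[b, j] - p_t[b, j] * de + bq
                u = w_run[b, i, j] + dtv * dw
                if 0.0 < u < wmax:
                    clip_t[b, i, j] = 1
                else:
                    clip_t[b, i, j] = 0
                    u = 0.0 if u <= 0.0 else (u if u < wmax else wmax)
                w_run[b, i, j] = u
                W_run[b, i, j] = om_rho * W_run[b, i, j] + rho * u


@njit(cache=True, fastmath=True)
def _trace_forward(r_new, kc_t, p_t, q_t, kap, om_kap, del_, om_del,
                   p_out, q_out, M, D):
    B, K = kc_t.shape
    for b in range(B):
        for j in range(K):
            p_out[b, j] = om_kap * p_t[b, j] + kap * kc_t[b, j]
        for d in range(D):
            q_out[b, d] = om_del * q_t[b, d] + del_ * r_new[b, M + d]


@njit(cache=True, fastmath=True)
def forward_window(WrT, bvec, WextT, r0, G, use_G, beta_m,
                   kc, ext, resets,
                   alpha, om_alpha, rho, om_rho, kap, om_kap, del_, om_del,
                   dtv, wmax, plastic,
                   r_h, w_run, clip_h, W_run, W_h, store_W, p_h, q_h,
                   relu_mask):
    """Unroll T steps.  History arrays carry the initial state at index 0
    and are filled in place for indices 1..T.  ``w_run``/``W_run`` hold
    the current plastic weights (updated in place); ``clip_h`` records
    per step which latent-weight updates were unclipped (all the adjoint
    needs).  The full effective-weight history is stored in ``W_h`` only
    when ``store_W`` (the conditioning adjoint never reads it; the
    navigation adjoint needs it for the KC-input gradient)."""
    T, B, K = kc.shape
    N = bvec.shape[0]
    M, D = G.shape
    rt = np.empty((B, N), dtype=r_h.dtype)
    for t in range(T):
        if resets[t]:
            for b in range(B):
                for i in range(N):
                    rt[b, i] = r0[i]
        else:
            for b in range(B):
                for i in range(N):
                    rt[b, i] = r_h[t, b, i]
        _rate_forward(rt, kc[t], ext[t], WrT, bvec, WextT, W_run,
                      alpha, om_alpha, r_h[t + 1], relu_mask[t], M, D)
        if plastic:
            _plast_forward_io(r_h[t + 1], kc[t], w_run, W_run,
                              p_h[t], q_h[t], G, use_G, beta_m, dtv, wmax,
                              rho, om_rho, clip_h[t], M, D)
        if store_W:
            for b in range(B):
                for i in range(M):
                    for j in range(K):
                        W_h[t + 1, b, i, j] = W_run[b, i, j]
        _trace_forward(r_h[t + 1], kc[t], p_h[t], q_h[t],
                       kap, om_kap, del_, om_del, p_h[t + 1], q_h[t + 1], M, D)


@njit(cache=True, fastmath=True)
def _step_backward(t, kc_t, ext_t, Wr, WrT, bvec, WextT, r0, G, use_G, beta_m,
                   alpha, om_alpha, rho, om_rho, kap, om_kap, del_, om_del,
                   dtv, wmax, plastic, reset_t,
                   r_h, clip_h, W_h, p_h, q_h, relu_mask,
                   gr, gw, gW, gp, gq,
                   gWr, gb, gWext, gbeta_m,
                   need_gkc, gkc_t, need_gext, gext_t):
    """Adjoint of one unrolled step.  On entry the g* arrays hold the
    adjoints of the post-step state (r_{t+1}, w_{t+1}, ...); on exit they
    hold the adjoints of the pre-step state.  Parameter gradients
    accumulate into gWr/gb/gWext/gbeta_m."""
    B, N = gr.shape
    M, D = G.shape
    K = kc_t.shape[1]
    E = WextT.shape[0]
    nMD = M + D

    # traces backward (they were updated last in the forward order)
    for b in range(B):
        for d in range(D):
            gr[b, M + d] += del_ * gq[b, d]
            gq[b, d] = om_del * gq[b, d]
        for j in range(K):
            if need_gkc:
                gkc_t[b, j] += kap * gp[b, j]
            gp[b, j] = om_kap * gp[b, j]

    # plasticity + effective-weight relaxation backward
    if plastic:
        for b in range(B):
            for i in range(M):
                if use_G:
                    de = r_h[t + 1, b, M] * 0
                    qe = de
                    for d in range(D):
                        de += G[i, d] * r_h[t + 1, b, M + d]
                        qe += G[i, d] * q_h[t, b, d]
                else:
                    de = r_h[t + 1, b, M + i]
                    qe = q_h[t, b, i]
                acc_kc = de * 0
                acc_gde = acc_kc
                sum_gdw = acc_kc
                for j in range(K):
                    gWij = gW[b, i, j]
                    gwij = gw[b, i, j] + rho * gWij
                    gW[b, i, j] = om_rho * gWij
                    gu = gwij if clip_h[t, b, i, j] else 0.0
                    gw[b, i, j] = gu
                    gdw = dtv * gu
                    sum_gdw += gdw
                    acc_kc += gdw * kc_t[b, j]
                    gp[b, j] -= gdw * de
                    acc_gde -= gdw * p_h[t, b, j]
                    if need_gkc:
                        gkc_t[b, j] += gdw * qe
                acc_gqe = acc_kc + beta_m[i] * sum_gdw
                gbeta_m[i] += qe * sum_gdw
                if use_G:
                    for d in range(D):
                        gq[b, d] += G[i, d] * acc_gqe
                        gr[b, M + d] += G[i, d] * acc_gde
                else:
                    gq[b, i] += acc_gqe
                    gr[b, M + i] += acc_gde

    # rate step backward
    ga = np.empty((B, N), dtype=gr.dtype)
    for b in range(B):
        for i in range(N):
            if relu_mask[t, b, i]:
                ga[b, i] = alpha * gr[b, i]
            else:
                ga[b, i] = 0.0

    rt = np.empty((B, N), dtype=gr.dtype)
    if reset_t:
        for b in range(B):
            for i in range(N):
                rt[b, i] = r0[i]
    else:
        for b in range(B):
            for i in range(N):
                rt[b, i] = r_h[t, b, i]

    gaT = np.empty((N, B), dtype=gr.dtype)
    for b in range(B):
        for i in range(N):
            gaT[i, b] = ga[b, i]
    gWr += np.dot(gaT, rt)
    for b in range(B):
        for i in range(N):
            gb[i] += ga[b, i]
        for f in range(N - nMD):
            gaf = ga[b, nMD + f]
            if gaf != 0.0:
                for e in range(E):
                    gWext[f, e] += gaf * ext_t[b, e]
        if need_gext:
            for e in range(E):
                acc = ga[b, 0] * 0
                for f in range(N - nMD):
                    acc += ga[b, nMD + f] * WextT[e, f]
                gext_t[b, e] = acc
        for i in range(M):
            gai = ga[b, i]
            if gai != 0.0:
                if need_gkc:
                    for j in range(K):
                        gW[b, i, j] += gai * kc_t[b, j]
                        gkc_t[b, j] += gai * W_h[t, b, i, j]
                else:
                    for j in range(K):
                        gW[b, i, j] += gai * kc_t[b, j]

    grec = np.dot(ga, Wr)
    if reset_t:
        for b in range(B):
            for i in range(N):
                gr[b, i] = 0.0
    else:
        for b in range(B):
            for i in range(N):
                gr[b, i] = om_alpha * gr[b, i] + grec[b, i]


@njit(cache=True, fastmath=True)
def backward_window(Wr, WrT, bvec, WextT, r0, G, use_G, beta_m,
                    kc, ext, resets,
                    alpha, om_alpha, rho, om_rho, kap, om_kap, del_, om_del,
                    dtv, wmax, plastic,
                    r_h, clip_h, W_h, p_h, q_h, relu_mask,
                    gout_r,
                    gr, gw, gW, gp, gq,
                    gWr, gb, gWext, gbeta_m):
    """Adjoint sweep over a whole window.  ``gout_r[t]`` is the loss adjoint
    with respect to r_{t+1}; gr/gw/gW/gp/gq enter holding terminal adjoints
    (zeros, or the adjoints handed back by a later window) and exit holding
    the adjoints of the window's initial state."""
    T, B, K = kc.shape
    N = bvec.shape[0]
    dummy_kc = np.zeros((1, 1), dtype=gr.dtype)
    dummy_ext = np.zeros((1, 1), dtype=gr.dtype)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for i in range(N):
                gr[b, i] += gout_r[t, b, i]
        _step_backward(t, kc[t], ext[t], Wr, WrT, bvec, WextT, r0, G, use_G,
                       beta_m, alpha, om_alpha, rho, om_rho, kap, om_kap,
                       del_, om_del, dtv, wmax, plastic, resets[t],
                       r_h, clip_h, W_h, p_h, q_h, relu_mask,
                       gr, gw, gW, gp, gq, gWr, gb, gWext, gbeta_m,
                       False, dummy_kc, False, dummy_ext)


# ---------------------------------------------------------------------------
# navigation: closed-loop unroll with agent kinematics and plume sensing
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _plume_c(x0, x1, sx0, sx1, wd, half_height):
    """Gaussian plume concentration at a point; wd is the unit wind
    x1-component (pointing from the source toward the origin)."""
    d1 = wd * (x0 - sx0)
    d2 = x1 - sx1
    if d1 > _EPS_D1 and (d2 if d2 >= 0.0 else -d2) <= half_height:
        return (1.0 / (1.0 + 0.5 * d1)) * np.exp(-d2 * d2 / (0.1 * d1))
    return 0.0


@njit(cache=True, fastmath=True)
def _softplus(z):
    if z > 30.0:
        return z
    return np.log1p(np.exp(z))


@njit(cache=True, fastmath=True)
def forward_nav(WrT, bvec, WextT, r0, G, use_G, beta_m,
                alpha, om_alpha, rho, om_rho, kap, om_kap, del_, om_del,
                dtv, wmax, plastic,
                src, wdir, pat, half_height,
                Wu, bu, Ww, bw, th0, resets,
                r_h, w_run, clip_h, W_h, p_h, q_h, relu_mask,
                x_h, th_h, u_h, om_h, c_h, act_h, zu_h, kc_buf, ext_buf):
    """Closed-loop navigation phase.  The circuit state histories continue
    from the conditioning phase (index 0 holds its final state); the agent
    starts at the origin with heading th0.  kc_buf/ext_buf (T,B,·) record
    the sensory inputs for reuse in the adjoint."""
    Tn = u_h.shape[0]
    B, N = r_h.shape[1], r_h.shape[2]
    M, D = G.shape
    K = pat.shape[2]
    rt = np.empty((B, N), dtype=r_h.dtype)
    for b in range(B):
        x_h[0, b, 0] = 0.0
        x_h[0, b, 1] = 0.0
        th_h[0, b] = th0[b]
    for t in range(Tn):
        # sensory input from current position/heading
        for b in range(B):
            c0 = _plume_c(x_h[t, b, 0], x_h[t, b, 1], src[b, 0, 0],
                          src[b, 0, 1], wdir[b, 0], half_height)
            c1 = _plume_c(x_h[t, b, 0], x_h[t, b, 1], src[b, 1, 0],
                          src[b, 1, 1], wdir[b, 1], half_height)
            c_h[t, b, 0] = c0
            c_h[t, b, 1] = c1
            if c0 <= 0.0 and c1 <= 0.0:
                act_h[t, b] = -1
            elif c0 >= c1:
                act_h[t, b] = 0
            else:
                act_h[t, b] = 1
            for j in range(K):
                kc_buf[t, b, j] = pat[b, 0, j] * c0 + pat[b, 1, j] * c1
            for e in range(6):
                ext_buf[t, b, e] = 0.0
            a = act_h[t, b]
            if a >= 0:
                wd = wdir[b, a]
                cth = np.cos(th_h[t, b])
                sth = np.sin(th_h[t, b])
                f0 = wd * cth          # anterior
                f1 = -wd * cth         # posterior
                f2 = -wd * sth         # left
                f3 = wd * sth          # right
                ext_buf[t, b, 2] = f0 if f0 > 0.0 else 0.0
                ext_buf[t, b, 3] = f1 if f1 > 0.0 else 0.0
                ext_buf[t, b, 4] = f2 if f2 > 0.0 else 0.0
                ext_buf[t, b, 5] = f3 if f3 > 0.0 else 0.0
        # circuit dynamics
        if resets[t]:
            for b in range(B):
                for i in range(N):
                    rt[b, i] = r0[i]
        else:
            for b in range(B):
                for i in range(N):
                    rt[b, i] = r_h[t, b, i]
        _rate_forward(rt, kc_buf[t], ext_buf[t], WrT, bvec, WextT, W_h[t],
                      alpha, om_alpha, r_h[t + 1], relu_mask[t], M, D)
        if plastic:
            _plast_forward(r_h[t + 1], kc_buf[t], w_run, W_h[t], W_h[t + 1],
                           p_h[t], q_h[t], G, use_G, beta_m, dtv, wmax,
                           rho, om_rho, clip_h[t], M, D)
        else:
            for b in range(B):
                for i in range(M):
                    for j in range(K):
                        W_h[t + 1, b, i, j] = W_h[t, b, i, j]
        _trace_forward(r_h[t + 1], kc_buf[t], p_h[t], q_h[t],
                       kap, om_kap, del_, om_del, p_h[t + 1], q_h[t + 1], M, D)
        # velocity readouts and kinematics (heading first, then position)
        for b in range(B):
            zu = bu
            om = bw
            for i in range(N):
                zu += Wu[i] * r_h[t + 1, b, i]
                om += Ww[i] * r_h[t + 1, b, i]
            zu_h[t, b] = zu
            u = _softplus(zu)
            u_h[t, b] = u
            om_h[t, b] = om
            th_h[t + 1, b] = th_h[t, b] + dtv * om
            x_h[t + 1, b, 0] = x_h[t, b, 0] + dtv * u * np.cos(th_h[t + 1, b])
            x_h[t + 1, b, 1] = x_h[t, b, 1] + dtv * u * np.sin(th_h[t + 1, b])


@njit(cache=True, fastmath=True)
def backward_nav(Wr, WrT, bvec, WextT, r0, G, use_G, beta_m,
                 alpha, om_alpha, rho, om_rho, kap, om_kap, del_, om_del,
                 dtv, wmax, plastic,
                 src, wdir, pat, half_height,
                 Wu, Ww, resets,
                 r_h, clip_h, W_h, p_h, q_h, relu_mask,
                 x_h, th_h, u_h, om_h, c_h, act_h, zu_h, kc_buf, ext_buf,
                 gx, gr, gw, gW, gp, gq,
                 gWr, gb, gWext, gbeta_m, gWu, gbu_a, gWw, gbw_a):
    """Adjoint of the navigation phase.  ``gx`` enters as dL/dx(T) and the
    sweep propagates through kinematics, velocity readouts, circuit
    dynamics, plume concentration and wind sensing back to the circuit
    state at the start of navigation (left in gr/gw/gW/gp/gq)."""
    Tn = u_h.shape[0]
    B, N = gr.shape
    M, D = G.shape
    K = pat.shape[2]
    gth = np.zeros(B, dtype=gr.dtype)
    gkc_t = np.empty((B, K), dtype=gr.dtype)
    gext_t = np.empty((B, 6), dtype=gr.dtype)
    for t in range(Tn - 1, -1, -1):
        # kinematics + velocity readouts backward
        for b in range(B):
            cth1 = np.cos(th_h[t + 1, b])
            sth1 = np.sin(th_h[t + 1, b])
            gu = dtv * (cth1 * gx[b, 0] + sth1 * gx[b, 1])
            gth1 = gth[b] + dtv * u_h[t, b] * (-sth1 * gx[b, 0]
                                               + cth1 * gx[b, 1])
            gom = dtv * gth1
            gth[b] = gth1  # part of the theta_t adjoint; wind term added below
            z = zu_h[t, b]
            if z > 30.0:
                sig = 1.0
            else:
                sig = 1.0 / (1.0 + np.exp(-z))
            a1 = gu * sig
            for i in range(N):
                gr[b, i] += a1 * Wu[i] + gom * Ww[i]
                gWu[i] += a1 * r_h[t + 1, b, i]
                gWw[i] += gom * r_h[t + 1, b, i]
            gbu_a[0] += a1
            gbw_a[0] += gom
        # circuit dynamics backward (also yields input adjoints)
        for b in range(B):
            for j in range(K):
                gkc_t[b, j] = 0.0
        _step_backward(t, kc_buf[t], ext_buf[t], Wr, WrT, bvec, WextT, r0,
                       G, use_G, beta_m, alpha, om_alpha, rho, om_rho,
                       kap, om_kap, del_, om_del, dtv, wmax, plastic,
                       resets[t],
                       r_h, clip_h, W_h, p_h, q_h, relu_mask,
                       gr, gw, gW, gp, gq, gWr, gb, gWext, gbeta_m,
                       True, gkc_t, True, gext_t)
        # wind features -> heading
        for b in range(B):
            a = act_h[t, b]
            if a >= 0:
                wd = wdir[b, a]
                cth = np.cos(th_h[t, b])
                sth = np.sin(th_h[t, b])
                if wd * cth > 0.0:
                    gth[b] += gext_t[b, 2] * (-wd * sth)
                if -wd * cth > 0.0:
                    gth[b] += gext_t[b, 3] * (wd * sth)
                if -wd * sth > 0.0:
                    gth[b] += gext_t[b, 4] * (-wd * cth)
                if wd * sth > 0.0:
                    gth[b] += gext_t[b, 5] * (wd * cth)
        # KC drive -> concentration -> position
        for b in range(B):
            for s in range(2):
                c = c_h[t, b, s]
                if c > 0.0:
                    gc = 0.0
                    for j in range(K):
                        gc += gkc_t[b, j] * pat[b, s, j]
                    if gc != 0.0:
                        d1 = wdir[b, s] * (x_h[t, b, 0] - src[b, s, 0])
                        d2 = x_h[t, b, 1] - src[b, s, 1]
                        dcd1 = c * (-0.5 / (1.0 + 0.5 * d1)
                                    + d2 * d2 / (0.1 * d1 * d1))
                        dcd2 = c * (-2.0 * d2 / (0.1 * d1))
                        gx[b, 0] += gc * dcd1 * wdir[b, s]
                        gx[b, 1] += gc * dcd2
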