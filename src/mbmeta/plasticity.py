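"""Dopamine-gated, timing-dependent plasticity of KC->MBON synapses.

The latent plastic variable w_ij of the synapse from KC j onto MBON i obeys

    dw_ij/dt = rbar_DAN_i * r_KC_j  -  rbar_KC_j * r_DAN_i  (+ beta_i * rbar_DAN_i)

where rbar are eligibility traces (first-order low-pass filters of the
rates) and r_DAN_i is the dopamine rate gating compartment i (the
compartment-map average of DAN rates; identity by default).  Pairings in
which the KC fires before the DAN depress the synapse; the reverse order
potentiates it, giving the biphasic timing curve.  The optional beta term
is the non-specific potentiation used for continual learning: dopamine
activity alone, without KC activity, potentiates the synapse.

The effective weight W_KC->MBON relaxes toward w with time constant tau_W,
modelling the induction timescale of LTD/LTP:

    tau_W * dW_ij/dt = -W_ij + w_ij

Within a simulation step the product terms use the traces from the
*previous* step (strictly causal low-pass filters); traces are advanced
afterwards by :func:`update_traces`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .circuit import CircuitState
from .params import CircuitParameters

__all__ = ["PlasticityConfig", "update_traces", "plasticity_step", "pairing_curve"]


@dataclass
class PlasticityConfig:
    """Time constants and bounds of the plasticity rule.

    The eligibility-trace time constants set the width of the pairing
    window (the experimental curve spans several seconds); tau_w sets how
    fast effective weights track the latent plastic variable.
    """

    tau_elig_kc: float = 1.0    # s
    tau_elig_dan: float = 1.0   # s
    tau_w: float = 5.0          # s
    w_max: float = 0.05
    clip: bool = True
    dt: float = 0.5             # s, integration step

    def __post_init__(self) -> None:
        if min(self.tau_elig_kc, self.tau_elig_dan, self.tau_w) <= 0:
            raise ValueError("time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


def update_traces(config: PlasticityConfig, state: CircuitState,
                  kc_rates: np.ndarray, dan_rates: np.ndarray) -> CircuitState:
    """Advance the eligibility traces by one Euler step of the low-pass
    filter ``trace += dt/tau * (rate - trace)``."""
    kc_rates = np.asarray(kc_rates, dtype=float)
    dan_rates = np.asarray(dan_rates, dtype=float)
    if np.any(kc_rates < 0) or np.any(dan_rates < 0):
        raise ValueError("rates must be nonnegative")
    out = state.copy()
    out.trace_kc = state.trace_kc + (config.dt / config.tau_elig_kc) * (
        kc_rates - state.trace_kc)
    out.trace_dan = state.trace_dan + (config.dt / config.tau_elig_dan) * (
        dan_rates - state.trace_dan)
    return out


def plasticity_step(config: PlasticityConfig, params: CircuitParameters,
                    state: CircuitState, kc_rates: np.ndarray,
                    dan_rates: np.ndarray) -> CircuitState:
    """One Euler step of the plasticity rule and the effective-weight
    relaxation.

    Uses the traces currently stored in ``state`` (i.e. pre-update values)
    in the product terms; call :func:`update_traces` afterwards.  With
    ``config.clip`` the latent weights are confined to ``[0, w_max]``; the
    effective weights then stay bounded by construction.
    """
    kc_rates = np.asarray(kc_rates, dtype=float)
    dan_rates = np.asarray(dan_rates, dtype=float)
    gating = params.gating_matrix()
    dan_eff = dan_rates @ gating.T           # (..., n_mbon)
    dan_tr_eff = state.trace_dan @ gating.T  # (..., n_mbon)
    beta_m = params.beta_per_mbon()

    dw = (dan_tr_eff[..., :, None] * kc_rates[..., None, :]
          - state.trace_kc[..., None, :] * dan_eff[..., :, None]
          + beta_m[:, None] * dan_tr_eff[..., :, None])
    w_new = state.w + config.dt * dw
    if config.clip:
        w_new = np.clip(w_new, 0.0, config.w_max)
    W_new = state.W_kc_mbon + (config.dt / config.tau_w) * (w_new - state.W_kc_mbon)

    out = state.copy()
    out.w = w_new
    out.W_kc_mbon = W_new
    return out


def pairing_curve(config: PlasticityConfig, delta_t_grid: np.ndarray,
                  pulse_amp: float = 1.0, pulse_dur: float = 2.0,
                  dt: float | None = None) -> np.ndarray:
    """Total change in the latent weight w for an isolated KC/DAN pulse pair
    as a function of the pairing lag.

    ``delta_t > 0`` means the KC pulse precedes the DAN pulse (forward
    pairing, depression); ``delta_t < 0`` the reverse (potentiation).  Each
    lag is simulated from a fresh state with beta = 0 and clipping disabled
    so the raw rule is measured.

    Returns an array of integrated ``delta_w`` values, one per lag.
    """
    delta_t_grid = np.asarray(delta_t_grid, dtype=float)
    sim_dt = config.dt if dt is None else dt
    cfg = replace(config, clip=False, dt=sim_dt)
    tiny = CircuitParameters(n_mbon=1, n_dan=1, n_fbn=1, n_kc=1)
    tail = 6.0 * max(cfg.tau_elig_kc, cfg.tau_elig_dan)

    out = np.empty_like(delta_t_grid)
    for idx, lag in enumerate(delta_t_grid):
        kc_on = max(0.0, -lag)
        dan_on = max(0.0, lag)
        t_end = max(kc_on, dan_on) + pulse_dur + tail
        n_steps = int(np.ceil(t_end / sim_dt))
        state = CircuitState(
            r=np.zeros(3), w=np.zeros((1, 1)), W_kc_mbon=np.zeros((1, 1)),
            trace_kc=np.zeros(1), trace_dan=np.zeros(1))
        for n in range(n_steps):
            t = n * sim_dt
            kc = np.array([pulse_amp if kc_on <= t < kc_on + pulse_dur else 0.0])
            dan = np.array([pulse_amp if dan_on <= t < dan_on + pulse_dur else 0.0])
            state = plasticity_step(cfg, tiny, state, kc, dan)
            state = update_traces(cfg, state, kc, dan)
        out[idx] = state.w[0, 0]
    return out
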