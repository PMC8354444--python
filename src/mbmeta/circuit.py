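"""Rate dynamics of the mushroom-body output circuitry.

The circuit is a rectified-linear rate network integrated by explicit
forward Euler:

    tau * dr_i/dt = -r_i + [ sum_j W_recur[i,j] r_j + b_i + I_i ]_+

Input routing: MBONs receive Kenyon-cell input through the (plastic)
KC->MBON weights, feedback neurons receive external input through W_ext,
and dopamine neurons receive no direct input — everything reaching them is
relayed by the recurrent circuitry.

All operations accept states with arbitrary leading batch dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .params import CircuitParameters

__all__ = [
    "CircuitState",
    "initial_state",
    "reset_rates",
    "step",
    "readout",
    "state_readout",
]


@dataclass
class CircuitState:
    """Instantaneous state of the circuit.

    ``w`` is the latent plastic variable of the learning rule;
    ``W_kc_mbon`` is the effective synaptic weight that relaxes toward
    ``w`` with time constant tau_W.  ``trace_kc`` / ``trace_dan`` are the
    low-pass eligibility traces of presynaptic KC rates and compartment
    dopamine rates.
    """

    r: np.ndarray            # (..., N) firing rates, >= 0
    w: np.ndarray            # (..., n_mbon, n_kc) latent plastic variable
    W_kc_mbon: np.ndarray    # (..., n_mbon, n_kc) effective weights
    trace_kc: np.ndarray     # (..., n_kc)
    trace_dan: np.ndarray    # (..., n_dan)

    def copy(self) -> "CircuitState":
        return CircuitState(self.r.copy(), self.w.copy(), self.W_kc_mbon.copy(),
                            self.trace_kc.copy(), self.trace_dan.copy())


def initial_state(params: CircuitParameters,
                  batch_shape: tuple[int, ...] = ()) -> CircuitState:
    """Fresh state: MBON rates 0, DAN/FBN rates 0.1, all plastic weights at
    their maximum value w_max, traces 0."""
    params.validate()
    r = np.broadcast_to(params.rate_init(),
                        batch_shape + (params.n_total,)).copy()
    wshape = batch_shape + (params.n_mbon, params.n_kc)
    return CircuitState(
        r=r,
        w=np.full(wshape, params.w_max),
        W_kc_mbon=np.full(wshape, params.w_max),
        trace_kc=np.zeros(batch_shape + (params.n_kc,)),
        trace_dan=np.zeros(batch_shape + (params.n_dan,)),
    )


def reset_rates(params: CircuitParameters, state: CircuitState) -> CircuitState:
    """Reset firing rates to r0 (interval boundary) without touching the
    plastic variables or eligibility traces."""
    out = state.copy()
    out.r[...] = params.rate_init()
    return out


def step(params: CircuitParameters, state: CircuitState,
         kc_rates: np.ndarray, ext_input: np.ndarray) -> CircuitState:
    """One forward-Euler step of the rate dynamics.

    Does not update plastic variables or traces (see :mod:`mbmeta.plasticity`).

    Parameters
    ----------
    kc_rates : (..., n_kc) nonnegative Kenyon-cell rates at this step.
    ext_input : (..., d_ext) external input (US, state pulses, wind).
    """
    kc_rates = np.asarray(kc_rates, dtype=float)
    ext_input = np.asarray(ext_input, dtype=float)
    if kc_rates.shape[-1] != params.n_kc:
        raise ValueError(f"kc_rates last axis must be {params.n_kc}")
    if ext_input.shape[-1] != params.d_ext:
        raise ValueError(f"ext_input last axis must be {params.d_ext}")
    if np.any(kc_rates < 0):
        raise ValueError("kc_rates must be nonnegative")

    r = state.r
    drive = np.zeros(np.broadcast_shapes(r.shape[:-1], kc_rates.shape[:-1],
                                         ext_input.shape[:-1]) + (params.n_total,))
    drive[..., params.mbon_slice] = np.einsum(
        "...mk,...k->...m", state.W_kc_mbon, kc_rates)
    drive[..., params.fbn_slice] = ext_input @ params.W_ext.T
    pre = r @ params.W_recur.T + params.b + drive
    alpha = params.dt / params.tau
    out = state.copy()
    out.r = (1.0 - alpha) * r + alpha * np.maximum(pre, 0.0)
    return out


def readout(params: CircuitParameters, state: CircuitState) -> np.ndarray:
    """Linear readout of MBON rates: valence (and optionally novelty)."""
    return state.r[..., params.mbon_slice] @ params.W_readout.T


def state_readout(params: CircuitParameters, state: CircuitState) -> np.ndarray:
    """Softmax readout of DAN rates: decoded internal-state probabilities."""
    if params.W_state is None:
        raise ValueError("params.W_state is not set")
    logits = state.r[..., params.dan_slice] @ params.W_state.T
    return softmax(logits, axis=-1)
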