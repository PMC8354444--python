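"""Parameter initialization for the optimization phase.

Recurrent weights are zero-mean Gaussians whose variance is keyed to the
*presynaptic* neuron type, ``Var = 1/(2 N_X)`` for X in {MBON, DAN, FBN};
readout weights have variance ``1/N_MBON``; external-input weights variance
1; all biases start at 0.1.  The DAN->MBON block is zeroed (structural),
and a recurrence-ablation mask may remove further blocks.  The
non-specific-potentiation rates beta, when present, start at 0.01 and are
kept nonnegative by the optimizer.
"""

from __future__ import annotations

import numpy as np

from ..params import CircuitParameters, recurrence_mask

__all__ = ["initialize_parameters", "velocity_readout_mask"]


def velocity_readout_mask(params: CircuitParameters) -> np.ndarray:
    """Boolean mask of neurons feeding the velocity readouts (FBNs only)."""
    mask = np.zeros(params.n_total, dtype=bool)
    mask[params.fbn_slice] = True
    return mask


def _fbn_readout(rng, n_mbon, n_dan, n_fbn):
    n = n_mbon + n_dan + n_fbn
    w = np.zeros(n)
    w[n_mbon + n_dan:] = rng.normal(0.0, np.sqrt(1.0 / n_fbn), size=n_fbn)
    return w


def initialize_parameters(rng: np.random.Generator, *,
                          n_mbon: int = 20, n_dan: int = 20, n_fbn: int = 60,
                          n_kc: int = 200, d_ext: int = 2, d_readout: int = 1,
                          with_state: bool = False, with_velocity: bool = False,
                          with_beta: bool = False, n_compartments: int | None = None,
                          tau: float = 1.0, dt: float = 0.5,
                          w_max: float = 0.05,
                          recurrence: str = "full",
                          velocity_bias: float = 0.1) -> CircuitParameters:
    """Draw a fresh parameter set.

    ``recurrence`` selects the ablation mask ("full", "feedforward" or
    "zero").  ``n_compartments`` < n_mbon builds a coarser block
    compartment map (the compartment-count sweep); the default pairs DAN k
    with MBON k.  Velocity-readout biases follow the same 0.1
    initialization as the neuron biases, giving an initial forward speed
    softplus(0.1) ~ 0.74 m/s whose large early position errors carry the
    gradient signal that bootstraps steering.
    """
    n = n_mbon + n_dan + n_fbn
    std = np.empty(n)
    std[:n_mbon] = np.sqrt(1.0 / (2 * n_mbon))
    std[n_mbon:n_mbon + n_dan] = np.sqrt(1.0 / (2 * n_dan))
    std[n_mbon + n_dan:] = np.sqrt(1.0 / (2 * n_fbn))
    W_recur = rng.normal(0.0, 1.0, size=(n, n)) * std[None, :]

    comp = None
    if n_compartments is not None:
        if n_mbon % n_compartments or n_dan % n_compartments:
            raise ValueError("n_compartments must divide n_mbon and n_dan")
        comp = np.repeat(np.arange(n_compartments), n_mbon // n_compartments)

    params = CircuitParameters(
        n_mbon=n_mbon, n_dan=n_dan, n_fbn=n_fbn, n_kc=n_kc,
        W_recur=W_recur,
        b=np.full(n, 0.1),
        W_ext=rng.normal(0.0, 1.0, size=(n_fbn, d_ext)),
        W_readout=rng.normal(0.0, np.sqrt(1.0 / n_mbon),
                             size=(d_readout, n_mbon)),
        W_state=(rng.normal(0.0, np.sqrt(1.0 / n_dan), size=(3, n_dan))
                 if with_state else None),
        # velocity readouts live on the feedback neurons (locomotor
        # pathways downstream of the output circuitry), not on MBONs/DANs
        W_u=_fbn_readout(rng, n_mbon, n_dan, n_fbn) if with_velocity else None,
        b_u=velocity_bias if with_velocity else 0.0,
        W_omega=_fbn_readout(rng, n_mbon, n_dan, n_fbn) if with_velocity else None,
        b_omega=velocity_bias if with_velocity else 0.0,
        beta=None,
        tau=tau, dt=dt, w_max=w_max,
        mbon_compartment=comp, dan_compartment=comp.copy() if comp is not None else None,
    )
    if with_beta:
        params.beta = np.full(params.n_compartments, 0.01)
    params.W_recur *= recurrence_mask(params, recurrence)
    params.validate()
    return params
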