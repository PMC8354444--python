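"""Circuit parameters: architecture constants and all meta-learned weights.

Neuron ordering convention used throughout the package: indices
``[0, n_mbon)`` are MBONs, ``[n_mbon, n_mbon + n_dan)`` are DANs and the
remainder are feedback neurons (FBNs).  ``W_recur[i, j]`` is the weight of
the connection from neuron ``j`` onto neuron ``i``; the DAN->MBON block is
structurally zero because dopamine acts on KC->MBON synapses, not on MBON
firing directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = [
    "CircuitParameters",
    "dan_mbon_mask",
    "recurrence_mask",
    "save_parameters",
    "load_parameters",
]

_FORMAT_VERSION = 1

#: names of the optional array-valued parameter fields
_OPTIONAL_ARRAYS = ("W_state", "W_u", "W_omega", "beta")


@dataclass
class CircuitParameters:
    """All meta-learned quantities plus fixed architecture constants.

    Parameters with ``None`` defaults are task-dependent readouts that only
    exist when the corresponding task requires them (state decoding,
    navigation velocities, non-specific potentiation).
    """

    n_mbon: int = 20
    n_dan: int = 20
    n_fbn: int = 60
    n_kc: int = 200

    W_recur: np.ndarray | None = None      # (N, N)
    b: np.ndarray | None = None            # (N,)
    W_ext: np.ndarray | None = None        # (n_fbn, d_ext)
    W_readout: np.ndarray | None = None    # (d_readout, n_mbon)
    W_state: np.ndarray | None = None      # (3, n_dan)
    W_u: np.ndarray | None = None          # (N,) forward-velocity weights
    b_u: float = 0.0
    W_omega: np.ndarray | None = None      # (N,) angular-velocity weights
    b_omega: float = 0.0
    beta: np.ndarray | None = None         # (n_compartments,) >= 0

    tau: float = 1.0          # membrane time constant, s
    dt: float = 0.5           # integration step, s
    w_max: float = 0.05       # maximum plastic weight

    # compartment assignment of MBONs and DANs (identity pairing by default)
    mbon_compartment: np.ndarray | None = None   # (n_mbon,) int
    dan_compartment: np.ndarray | None = None    # (n_dan,) int

    def __post_init__(self) -> None:
        if self.mbon_compartment is None:
            self.mbon_compartment = np.arange(self.n_mbon)
        if self.dan_compartment is None:
            self.dan_compartment = np.arange(self.n_dan)
        self.mbon_compartment = np.asarray(self.mbon_compartment, dtype=int)
        self.dan_compartment = np.asarray(self.dan_compartment, dtype=int)
        if self.W_recur is None:
            self.W_recur = np.zeros((self.n_total, self.n_total))
        if self.b is None:
            self.b = np.zeros(self.n_total)
        if self.W_ext is None:
            self.W_ext = np.zeros((self.n_fbn, 2))
        if self.W_readout is None:
            self.W_readout = np.zeros((1, self.n_mbon))
        for name in ("W_recur", "b", "W_ext", "W_readout"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in _OPTIONAL_ARRAYS:
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.asarray(val, dtype=float))

    # -- derived architecture ------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.n_mbon + self.n_dan + self.n_fbn

    @property
    def mbon_slice(self) -> slice:
        return slice(0, self.n_mbon)

    @property
    def dan_slice(self) -> slice:
        return slice(self.n_mbon, self.n_mbon + self.n_dan)

    @property
    def fbn_slice(self) -> slice:
        return slice(self.n_mbon + self.n_dan, self.n_total)

    @property
    def d_ext(self) -> int:
        return self.W_ext.shape[1]

    @property
    def d_readout(self) -> int:
        return self.W_readout.shape[0]

    @property
    def n_compartments(self) -> int:
        return int(self.mbon_compartment.max()) + 1

    def rate_init(self) -> np.ndarray:
        """Reset rates r0: 0 for MBONs, 0.1 for DANs and FBNs."""
        r0 = np.full(self.n_total, 0.1)
        r0[self.mbon_slice] = 0.0
        return r0

    def gating_matrix(self) -> np.ndarray:
        """DAN -> MBON plasticity gating matrix G, shape (n_mbon, n_dan).

        ``(G @ r_dan)[i]`` is the dopamine drive gating plasticity of the
        synapses onto MBON ``i``.  With the default one-DAN-per-compartment
        map G is the identity; for coarser compartment maps each MBON reads
        the average of the DANs in its compartment (block structure with
        within-block weight 1/block-size).
        """
        g = (self.mbon_compartment[:, None] == self.dan_compartment[None, :])
        g = g.astype(float)
        counts = g.sum(axis=1, keepdims=True)
        if np.any(counts == 0):
            raise ValueError("every MBON compartment needs at least one DAN")
        return g / counts

    def beta_per_mbon(self) -> np.ndarray:
        """Per-MBON non-specific potentiation rate (0 when beta is unset)."""
        if self.beta is None:
            return np.zeros(self.n_mbon)
        return np.asarray(self.beta, dtype=float)[self.mbon_compartment]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        n = self.n_total
        if self.W_recur.shape != (n, n):
            raise ValueError(f"W_recur must be {(n, n)}, got {self.W_recur.shape}")
        if self.b.shape != (n,):
            raise ValueError(f"b must be ({n},), got {self.b.shape}")
        if self.W_ext.shape[0] != self.n_fbn:
            raise ValueError("W_ext rows must equal n_fbn (FBNs are the sole "
                             "entry point for external input)")
        if self.W_readout.shape[1] != self.n_mbon:
            raise ValueError("W_readout must read from MBON rates only")
        block = self.W_recur[self.mbon_slice, self.dan_slice]
        if np.any(block != 0.0):
            raise ValueError("DAN->MBON block of W_recur must be exactly zero")
        if self.beta is not None and np.any(self.beta < 0):
            raise ValueError("beta entries must be >= 0")
        if self.dt > self.tau:
            raise ValueError("dt must not exceed tau (forward-Euler stability)")
        if self.W_state is not None and self.W_state.shape != (3, self.n_dan):
            raise ValueError("W_state must be (3, n_dan)")
        for name in ("W_u", "W_omega"):
            v = getattr(self, name)
            if v is not None and v.shape != (n,):
                raise ValueError(f"{name} must be ({n},)")
        if self.mbon_compartment.shape != (self.n_mbon,):
            raise ValueError("mbon_compartment must assign every MBON")
        if self.dan_compartment.shape != (self.n_dan,):
            raise ValueError("dan_compartment must assign every DAN")

    def copy(self) -> "CircuitParameters":
        kwargs = {}
        for f in fields(self):
            v = getattr(self, f.name)
            kwargs[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return CircuitParameters(**kwargs)


def dan_mbon_mask(params: CircuitParameters) -> np.ndarray:
    """Boolean mask of W_recur entries that are structurally allowed
    (everything except the DAN->MBON block)."""
    mask = np.ones((params.n_total, params.n_total), dtype=bool)
    mask[params.mbon_slice, params.dan_slice] = False
    return mask


def recurrence_mask(params: CircuitParameters, mode: str = "full") -> np.ndarray:
    """Mask of permitted W_recur entries for a recurrence ablation mode.

    ``"full"``
        everything except the structural DAN->MBON zero block.
    ``"feedforward"``
        only FBN->MBON and FBN->DAN connections survive, so external input
        still reaches DANs (and MBONs) but no recurrent loop exists.  This is
        the "no recurrence" ablation: every pathway that could feed a
        neuron's output back to itself is removed.
    ``"zero"``
        no recurrent-matrix connections at all.
    """
    if mode == "full":
        return dan_mbon_mask(params)
    mask = np.zeros((params.n_total, params.n_total), dtype=bool)
    if mode == "feedforward":
        mask[params.mbon_slice, params.fbn_slice] = True
        mask[params.dan_slice, params.fbn_slice] = True
        return mask
    if mode == "zero":
        return mask
    raise ValueError(f"unknown recurrence mode {mode!r}")


# -- serialization -----------------------------------------------------------

def save_parameters(params: CircuitParameters, path: str | Path) -> None:
    """Write parameters to ``<path>.npz`` plus a JSON sidecar of scalars.

    The archive stores named arrays; the sidecar records format version,
    architecture counts and scalar constants so a saved model is
    self-describing.
    """
    path = Path(path)
    arrays = {"W_recur": params.W_recur, "b": params.b,
              "W_ext": params.W_ext, "W_readout": params.W_readout,
              "mbon_compartment": params.mbon_compartment,
              "dan_compartment": params.dan_compartment}
    for name in _OPTIONAL_ARRAYS:
        v = getattr(params, name)
        if v is not None:
            arrays[name] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    scalars = {
        "format_version": _FORMAT_VERSION,
        "n_mbon": params.n_mbon, "n_dan": params.n_dan,
        "n_fbn": params.n_fbn, "n_kc": params.n_kc,
        "tau": params.tau, "dt": params.dt, "w_max": params.w_max,
        "b_u": params.b_u, "b_omega": params.b_omega,
    }
    path.with_suffix(".json").write_text(json.dumps(scalars, indent=2))


def load_parameters(path: str | Path) -> CircuitParameters:
    path = Path(path)
    scalars = json.loads(path.with_suffix(".json").read_text())
    if scalars.pop("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported parameter-archive format version")
    with np.load(path.with_suffix(".npz")) as arc:
        arrays = {k: arc[k] for k in arc.files}
    params = CircuitParameters(**scalars, **arrays)
    params.validate()
    return params
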