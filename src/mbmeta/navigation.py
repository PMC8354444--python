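"""2-D plume environment and agent kinematics for conditioned navigation.

Two odor sources sit at horizontal positions x1 = +/-1 m with vertical
positions drawn uniformly on [0, 2] m (spacing >= 0.5 m).  Each source
emits a Gaussian plume carried by a unit wind vector parallel to the x1
axis, oriented so the plume extends from the source toward the origin.
For a point downwind of a source by dx1 > 0 and off-axis by dx2, inside
the 0.5-m-high plume band,

    c(dx1, dx2) = 1 / (1 + 0.5 dx1) * exp(-dx2^2 / (0.1 dx1)),

i.e. the plume widens and dilutes with distance.  The agent is a unicycle:
heading follows the angular-velocity readout and position integrates the
forward-velocity readout along the heading.  Wind is sensed egocentrically
as the rectified projections of the wind vector onto the agent's anterior,
posterior, left and right unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NavOptions",
    "NavEnvironment",
    "AgentState",
    "make_environment",
    "concentration",
    "wind_input",
    "step_agent",
    "run_navigation_trial",
    "sample_trial_batch",
    "render_conditioning_phase",
]


@dataclass
class NavOptions:
    """Task constants of the navigation protocol."""

    cond_duration: float = 20.0    # s, conditioning interval
    nav_duration: float = 200.0    # s, navigation interval
    cs_onset: float = 2.0          # s, CS+ onset within conditioning
    stim_duration: float = 2.0     # s, CS and US pulse length
    us_amplitude: float = 0.1      # conditioning US strength
    half_height: float = 0.25      # m, plume half-height
    min_spacing: float = 0.5       # m, minimum |x2| spacing of the sources


@dataclass
class NavEnvironment:
    """Two odor sources (index 0 rewarded) with their plumes and KC codes."""

    sources: np.ndarray            # (2, 2) positions [x1, x2] in m
    patterns: np.ndarray           # (2, n_kc) binary odor codes
    rewarded: int = 0
    half_height: float = 0.25

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.sources.shape != (2, 2):
            raise ValueError("exactly two sources expected")
        if self.rewarded != 0:
            raise ValueError("convention: the rewarded source is index 0")

    @property
    def wind_dirs(self) -> np.ndarray:
        """Unit wind x1-components, pointing from each source to the origin."""
        return -np.sign(self.sources[:, 0])


@dataclass
class AgentState:
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))  # m
    heading: float = np.pi / 2      # rad, wrapped to (-pi, pi]
    u: float = 0.0                  # m/s forward velocity
    omega: float = 0.0              # rad/s angular velocity

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = float((self.heading + np.pi) % (2 * np.pi) - np.pi)
        if self.heading == -np.pi:
            self.heading = np.pi


def make_environment(rng: np.random.Generator, n_kc: int = 200,
                     sparsity: float = 0.1,
                     options: NavOptions | None = None) -> NavEnvironment:
    """Sample source positions (x1 = +/-1 m, x2 ~ U[0, 2] m with minimum
    spacing) and fresh KC codes for the rewarded and neutral odors."""
    from .tasks import encode_odor

    opts = options or NavOptions()
    x1 = rng.choice([-1.0, 1.0], size=2)
    while True:
        x2 = rng.uniform(0.0, 2.0, size=2)
        if abs(x2[0] - x2[1]) >= opts.min_spacing:
            break
    patterns = np.stack([encode_odor(n_kc, sparsity, rng) for _ in range(2)])
    return NavEnvironment(sources=np.stack([x1, x2], axis=1),
                          patterns=patterns, half_height=opts.half_height)


def concentration(env: NavEnvironment, position: np.ndarray) -> np.ndarray:
    """Per-odor plume concentration at a position (2-vector result).

    Zero outside the plume band or upwind of the source; the on-axis limit
    at the source itself is 1.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    out = np.zeros(2)
    for s in range(2):
        wd = env.wind_dirs[s]
        d1 = wd * (position[0] - env.sources[s, 0])
        d2 = position[1] - env.sources[s, 1]
        if abs(d2) > env.half_height:
            continue
        # the plume starts 1 cm downwind: the formula's gradient is
        # singular at the source tip (see methods note)
        if d1 > 1e-2:
            out[s] = np.exp(-d2 ** 2 / (0.1 * d1)) / (1.0 + 0.5 * d1)
        elif 0.0 <= d1 <= 1e-2 and d2 == 0.0:
            out[s] = 1.0
    return out


def wind_input(env: NavEnvironment, agent: AgentState) -> np.ndarray:
    """Egocentric wind features: rectified projections of the active wind
    vector onto (anterior, posterior, left, right) unit vectors.

    The wind of the plume with the highest local concentration is sensed;
    when the agent is in neither plume the features are zero.  At most two
    of the four entries are nonzero.
    """
    c = concentration(env, agent.position)
    if np.all(c <= 0.0):
        return np.zeros(4)
    wd = env.wind_dirs[int(np.argmax(c))]
    cth, sth = np.cos(agent.heading), np.sin(agent.heading)
    proj = np.array([wd * cth, -wd * cth, -wd * sth, wd * sth])
    return np.maximum(proj, 0.0)


def step_agent(agent: AgentState, u: float, omega: float,
               dt: float) -> AgentState:
    """Euler update of the unicycle: heading first, then position along the
    new heading."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    heading = agent.heading + dt * omega
    pos = agent.position + dt * u * np.array([np.cos(heading),
                                              np.sin(heading)])
    return AgentState(position=pos, heading=heading, u=float(u),
                      omega=float(omega))


def sample_trial_batch(rng: np.random.Generator, batch: int, *,
                       n_kc: int = 200, sparsity: float = 0.1,
                       gamma: float = 0.5,
                       options: NavOptions | None = None):
    """Batched environments + initial headings for training/evaluation.

    Returns ``src`` (B, 2, 2), ``pat`` (B, 2, n_kc) and ``theta0`` (B,)
    with headings uniform on [pi/2 (1 - gamma), pi/2 (1 + gamma)].
    """
    envs = [make_environment(rng, n_kc, sparsity, options)
            for _ in range(batch)]
    src = np.stack([e.sources for e in envs])
    pat = np.stack([e.patterns for e in envs])
    theta0 = np.pi / 2 * (1.0 + gamma * rng.uniform(-1.0, 1.0, size=batch))
    return src, pat, theta0


def render_conditioning_phase(pat: np.ndarray, options: NavOptions,
                              dt: float):
    """Input traces of the pre-navigation conditioning interval: the
    rewarded odor's KC pattern followed by a positive US of amplitude 0.1
    at CS offset.  Returns ``kc`` (Tc, B, n_kc) and ``ext`` (Tc, B, 6)."""
    opts = options
    Tc = int(round(opts.cond_duration / dt))
    B, _, K = pat.shape
    t = np.arange(Tc) * dt
    kc = np.zeros((Tc, B, K))
    ext = np.zeros((Tc, B, 6))
    cs_sel = (t >= opts.cs_onset) & (t < opts.cs_onset + opts.stim_duration)
    us_on = opts.cs_onset + opts.stim_duration
    us_sel = (t >= us_on) & (t < us_on + opts.stim_duration)
    kc[cs_sel] = pat[:, 0, :][None]
    ext[us_sel, :, 0] = opts.us_amplitude
    return kc, ext


def run_navigation_trial(params, env: NavEnvironment,
                         rng: np.random.Generator, *,
                         plasticity_cond: bool = True,
                         plasticity_nav: bool = True,
                         gamma: float = 0.5,
                         options: NavOptions | None = None,
                         pcfg=None):
    """Simulate one full navigation trial with trained (or fresh) parameters.

    Conditioning phase (CS+/US pairing, US amplitude 0.1), then 200 s of
    closed-loop navigation driven by plume concentration and wind input.
    Plasticity can be blocked per phase.  Returns a dict with the
    trajectory (positions, heading, velocities, concentrations), the final
    distance to the rewarded source, and the circuit-rate history.
    """
    import pandas as pd

    from .metalearn.engine import nav_forward_batch

    opts = options or NavOptions()
    if params.W_u is None or params.W_omega is None:
        raise ValueError("parameters lack velocity readouts")
    theta0 = np.array([np.pi / 2 * (1.0 + gamma * rng.uniform(-1.0, 1.0))])
    kc_cond, ext_cond = render_conditioning_phase(env.patterns[None], opts,
                                                  params.dt)
    Tn = int(round(opts.nav_duration / params.dt))
    rec = nav_forward_batch(params, kc_cond, ext_cond, Tn,
                            env.sources[None], theta0, pat=env.patterns[None],
                            plasticity_cond=plasticity_cond,
                            plasticity_nav=plasticity_nav, pcfg=pcfg,
                            half_height=env.half_height, dtype=np.float64)
    ex = rec.extras
    if not np.all(np.isfinite(ex["x"])):
        raise FloatingPointError("non-finite agent dynamics")
    x = ex["x"][:, 0, :]
    final_distance = float(np.linalg.norm(x[-1] - env.sources[0]))
    n = ex["u"].shape[0]
    trajectory = pd.DataFrame({
        "t": np.arange(n) * params.dt,
        "x1": x[1:, 0], "x2": x[1:, 1],
        "theta": ex["theta"][1:, 0],
        "u": ex["u"][:, 0], "omega": ex["omega"][:, 0],
        "c_rewarded": ex["c"][:, 0, 0], "c_neutral": ex["c"][:, 0, 1],
    })
    return {"trajectory": trajectory, "final_distance": final_distance,
            "record": rec, "theta0": float(theta0[0])}
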