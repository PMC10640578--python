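"""Coupled two-node renewal systems and their consistency theory.

A two-node system couples three binary renewal processes — nodes x, y
and the link z between them — under the constraint that z is active
exactly when both x and y are active.  Each unit must individually
follow a prescribed waiting-time law (F, G, H).  At every step the four
joint probabilities for the next (x, y) states are computed from the
three hazards; the targets are *consistent* when these probabilities
stay in [0, 1] on every reachable trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import IETDistribution
from .errors import InconsistencyError, ParameterError

__all__ = [
    "Trajectory",
    "TwoNodeSystem",
    "JointStepProbabilities",
    "ConsistencyVerdict",
    "conditional_activation_probability",
    "joint_step_probabilities",
    "step_two_node",
    "check_consistency",
    "enumerate_trajectory_law",
    "first_gap_laws",
]

#: magnitude below which a negative joint probability is treated as
#: floating-point noise and clipped to zero
CLIP_TOL = 1e-12


class Trajectory:
    """Binary activity history of one unit, active at time 0."""

    __slots__ = ("states", "last_activation")

    def __init__(self, states=(1,)):
        states = [int(s) for s in states]
        if not states or states[0] != 1:
            raise ParameterError("trajectory must start active at time 0")
        if any(s not in (0, 1) for s in states):
            raise ParameterError("trajectory states must be 0/1")
        self.states = states
        self.last_activation = max(k for k, s in enumerate(states) if s == 1)

    def append(self, state: int) -> None:
        state = int(state)
        self.states.append(state)
        if state:
            self.last_activation = len(self.states) - 1

    @property
    def current_time(self) -> int:
        return len(self.states) - 1

    @property
    def next_gap(self) -> int:
        """Waiting time at the upcoming step: (n + 1) - last activation."""
        return len(self.states) - self.last_activation

    def __len__(self):
        return len(self.states)

    def __getitem__(self, t):
        return self.states[t]

    def __eq__(self, other):
        return isinstance(other, Trajectory) and self.states == other.states

    def __repr__(self):
        return f"Trajectory({self.states})"


@dataclass
class TwoNodeSystem:
    F: IETDistribution
    G: IETDistribution
    H: IETDistribution
    traj_x: Trajectory = field(default_factory=Trajectory)
    traj_y: Trajectory = field(default_factory=Trajectory)
    traj_z: Trajectory = field(default_factory=Trajectory)

    def __post_init__(self):
        if not (len(self.traj_x) == len(self.traj_y) == len(self.traj_z)):
            raise ParameterError("trajectories must share a common time")
        for t in range(len(self.traj_z)):
            if self.traj_z[t] != self.traj_x[t] * self.traj_y[t]:
                raise ParameterError("link state must equal the node product")


@dataclass(frozen=True)
class JointStepProbabilities:
    """Joint law of the next (x, y) states: both / x only / y only / neither."""

    p1: float
    p2: float
    p3: float
    p4: float

    def as_tuple(self):
        return (self.p1, self.p2, self.p3, self.p4)


def conditional_activation_probability(traj: Trajectory,
                                       dist: IETDistribution) -> float:
    """Probability the unit is active at the next step given its history.

    Equals the hazard of the target law at the unit's current waiting
    time — the defining property of the renewal dynamics.
    """
    return dist.hazard(traj.next_gap)


def joint_step_probabilities(system: TwoNodeSystem) -> JointStepProbabilities:
    hx = conditional_activation_probability(system.traj_x, system.F)
    hy = conditional_activation_probability(system.traj_y, system.G)
    hz = conditional_activation_probability(system.traj_z, system.H)
    raw = (hz, hx - hz, hy - hz, 1.0 + hz - hx - hy)
    labels = ("p1", "p2", "p3", "p4")
    clipped = []
    for name, p in zip(labels, raw):
        if p < -CLIP_TOL:
            raise InconsistencyError(
                f"{name} = {p:.6g} < 0: targets are inconsistent at "
                f"time {system.traj_x.current_time + 1}",
                time=system.traj_x.current_time + 1,
                probabilities=raw,
                trajectories=(tuple(system.traj_x.states),
                              tuple(system.traj_y.states)),
            )
        clipped.append(min(max(p, 0.0), 1.0))
    return JointStepProbabilities(*clipped)


def step_two_node(system: TwoNodeSystem,
                  rng: np.random.Generator) -> TwoNodeSystem:
    """Advance the coupled system by one time step (x first, then y)."""
    probs = joint_step_probabilities(system)
    hx = conditional_activation_probability(system.traj_x, system.F)
    x = int(rng.random() < hx)
    if x:
        q = probs.p1 / hx  # hx > 0 whenever x was sampled active
    else:
        q = probs.p3 / (1.0 - hx)  # hx < 1 whenever x was sampled inactive
    y = int(rng.random() < min(q, 1.0))
    system.traj_x.append(x)
    system.traj_y.append(y)
    system.traj_z.append(x * y)
    return system


# ---------------------------------------------------------------------------
# exact enumeration of the coupled chain
# ---------------------------------------------------------------------------

def _hazards(F, G, H, gx, gy, gz):
    return F.hazard(gx), G.hazard(gy), H.hazard(gz)


def _step_probs(hx, hy, hz):
    return (hz, hx - hz, hy - hz, 1.0 + hz - hx - hy)


def enumerate_trajectory_law(F: IETDistribution, G: IETDistribution,
                             H: IETDistribution, horizon: int,
                             order: str = "xy") -> dict:
    """Exact joint law of the (x, y) trajectories up to ``horizon``.

    Returns ``{(wx, wy): probability}`` over all trajectory pairs with
    positive probability, computed by multiplying the sequential
    sampling-rule probabilities step by step.  ``order="yx"`` swaps
    which node is sampled first (the law must not depend on it).
    Exponential in ``horizon``; intended for horizons <= ~10.
    """
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    if order not in ("xy", "yx"):
        raise ParameterError("order must be 'xy' or 'yx'")
    law = {}

    def joint_outcomes(hx, hy, hz):
        """Four (x, y)-outcome probabilities via the sequential rule."""
        p1, p2, p3, p4 = _step_probs(hx, hy, hz)
        for p in (p1, p2, p3, p4):
            if p < -CLIP_TOL:
                raise InconsistencyError(
                    f"negative joint probability {p:.6g} during enumeration",
                    probabilities=(p1, p2, p3, p4))
        if order == "xy":
            # sample x with hx, then y conditionally
            q_act = p1 / hx if hx > 0 else 0.0
            q_ina = p3 / (1.0 - hx) if hx < 1 else 0.0
            return ((1, 1, hx * q_act), (1, 0, hx * (1.0 - q_act)),
                    (0, 1, (1.0 - hx) * q_ina),
                    (0, 0, (1.0 - hx) * (1.0 - q_ina)))
        # sample y with hy, then x conditionally
        q_act = p1 / hy if hy > 0 else 0.0
        q_ina = p2 / (1.0 - hy) if hy < 1 else 0.0
        return ((1, 1, hy * q_act), (0, 1, hy * (1.0 - q_act)),
                (1, 0, (1.0 - hy) * q_ina),
                (0, 0, (1.0 - hy) * (1.0 - q_ina)))

    def recurse(wx, wy, gx, gy, gz, prob):
        if len(wx) == horizon + 1:
            key = (tuple(wx), tuple(wy))
            law[key] = law.get(key, 0.0) + prob
            return
        hx, hy, hz = _hazards(F, G, H, gx, gy, gz)
        for sx, sy, p in joint_outcomes(hx, hy, hz):
            if p <= 0.0:
                continue
            recurse(wx + [sx], wy + [sy],
                    1 if sx else gx + 1,
                    1 if sy else gy + 1,
                    1 if sx and sy else gz + 1,
                    prob * p)

    recurse([1], [1], 1, 1, 1, 1.0)
    return law


def first_gap_laws(F: IETDistribution, G: IETDistribution,
                   H: IETDistribution, horizon: int):
    """Exact law of each unit's first waiting time, by chain enumeration.

    Evolves the exact distribution over the gap state (gx, gy, gz) of
    the coupled chain and accumulates, for every unit, the probability
    that its first post-0 activation completes a gap of each length
    g = 1..horizon.  Under consistent targets these must equal the
    target pmfs restricted to {1..horizon}.  Polynomial in ``horizon``.
    """
    fx = np.zeros(horizon + 1)
    fy = np.zeros(horizon + 1)
    fz = np.zeros(horizon + 1)
    # state: (gx, gy, gz, x_virgin, y_virgin, z_virgin) -> probability,
    # where *_virgin means the unit has not activated since time 0
    states = {(1, 1, 1, True, True, True): 1.0}
    for t in range(1, horizon + 1):
        nxt = {}
        for (gx, gy, gz, vx, vy, vz), prob in states.items():
            hx, hy, hz = _hazards(F, G, H, gx, gy, gz)
            p1, p2, p3, p4 = _step_probs(hx, hy, hz)
            for p, (sx, sy) in zip((p1, p2, p3, p4),
                                   ((1, 1), (1, 0), (0, 1), (0, 0))):
                if p <= 0.0:
                    if p < -CLIP_TOL:
                        raise InconsistencyError(
                            f"negative joint probability {p:.6g} at "
                            f"time {t}", time=t,
                            probabilities=(p1, p2, p3, p4))
                    continue
                w = prob * p
                if sx and vx:
                    fx[t] += w
                if sy and vy:
                    fy[t] += w
                if sx and sy and vz:
                    fz[t] += w
                key = (1 if sx else gx + 1,
                       1 if sy else gy + 1,
                       1 if sx and sy else gz + 1,
                       vx and not sx, vy and not sy,
                       vz and not (sx and sy))
                nxt[key] = nxt.get(key, 0.0) + w
        states = nxt
    return fx[1:], fy[1:], fz[1:]


# ---------------------------------------------------------------------------
# consistency checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyVerdict:
    consistent: bool
    mode: str
    marginal: bool = False
    witness: tuple | None = None
    detail: str = ""

    def __bool__(self):
        return self.consistent


def check_consistency(F: IETDistribution, G: IETDistribution,
                      H: IETDistribution, mode: str = "enumerate",
                      horizon: int = 12) -> ConsistencyVerdict:
    """Decide whether targets (F, G, H) admit a valid joint construction.

    Modes
    -----
    ``enumerate``
        Exhaustively checks that all four joint probabilities lie in
        [0, 1] over every reachable gap state up to ``horizon``; on
        failure returns the violating (x, y) trajectory pair as witness.
    ``bursty_analytic``
        Power-law targets with a common node exponent: evaluates the
        three closed-form conditions (node exponent >= link exponent;
        h_F(1) + h_G(2) < 1; h_F(1) + h_G(1) < 1 + h_H(1)) using exact
        hazards.  Boundary cases within 1e-9 are reported as marginal.
    ``poisson_analytic``
        Discrete-exponential targets: consistent iff the node-minus-link
        rate difference lies in [0, ln 2].
    """
    if mode == "enumerate":
        return _check_enumerate(F, G, H, horizon)
    if mode == "bursty_analytic":
        if not (F.kind == G.kind == H.kind == "power_law"):
            raise ParameterError("bursty_analytic requires power_law targets")
        if F.exponent != G.exponent:
            # asymmetric node targets: no printed closed form; fall back
            return _check_enumerate(F, G, H, horizon)
        c1 = F.exponent - H.exponent                      # >= 0
        c2 = 1.0 - (F.hazard(1) + G.hazard(2))            # > 0
        c3 = 1.0 + H.hazard(1) - (F.hazard(1) + G.hazard(1))  # > 0
        margins = (c1, c2, c3)
        ok = c1 >= 0 and c2 > 0 and c3 > 0
        marginal = min(abs(m) for m in margins) < 1e-9
        return ConsistencyVerdict(
            consistent=bool(ok), mode=mode, marginal=marginal,
            detail=f"margins (exponent gap, gap-2, gap-1): {margins}")
    if mode == "poisson_analytic":
        if not (F.kind == G.kind == H.kind == "discrete_exponential"):
            raise ParameterError(
                "poisson_analytic requires discrete_exponential targets")
        if F.exponent != G.exponent:
            return _check_enumerate(F, G, H, horizon)
        diff = F.exponent - H.exponent
        ok = 0.0 <= diff <= math.log(2.0)
        marginal = min(abs(diff), abs(diff - math.log(2.0))) < 1e-9
        return ConsistencyVerdict(
            consistent=bool(ok), mode=mode, marginal=marginal,
            detail=f"node - link rate difference = {diff:.6g}, "
                   f"admissible range [0, ln 2]")
    raise ParameterError(f"unknown mode {mode!r}")


def _check_enumerate(F, G, H, horizon) -> ConsistencyVerdict:
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    # reachable gap states with a representative trajectory pair each
    states = {(1, 1, 1): ((1,), (1,))}
    for t in range(1, horizon + 1):
        nxt = {}
        for (gx, gy, gz), (wx, wy) in states.items():
            hx, hy, hz = _hazards(F, G, H, gx, gy, gz)
            probs = _step_probs(hx, hy, hz)
            for i, (p, (sx, sy)) in enumerate(zip(
                    probs, ((1, 1), (1, 0), (0, 1), (0, 0)))):
                if p < -CLIP_TOL or p > 1.0 + CLIP_TOL:
                    return ConsistencyVerdict(
                        consistent=False, mode="enumerate",
                        witness=(wx, wy),
                        detail=f"p{i + 1} = {p:.6g} outside [0, 1] at time "
                               f"{t} on trajectories x={wx}, y={wy}")
                if p <= CLIP_TOL:
                    continue
                key = (1 if sx else gx + 1,
                       1 if sy else gy + 1,
                       1 if sx and sy else gz + 1)
                if key not in nxt:
                    nxt[key] = (wx + (sx,), wy + (sy,))
        states = nxt
    return ConsistencyVerdict(consistent=True, mode="enumerate",
                              detail=f"all joint probabilities valid up to "
                                     f"horizon {horizon}")
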