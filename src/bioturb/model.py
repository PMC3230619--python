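"""Stochastic 2D lattice model of sediment bioturbation.

The sediment column is a grid of ``d`` layers (layer 0 at the
sediment–water interface, depth increasing downward), each with a fixed
capacity of ``w`` particles. Particles are either tracers (luminophores)
or non-marked sediment grains. One model time step has two phases:

1. **Active displacement** — each tracer particle in the reworked depth
   range is displaced with probability ``activity``; a displaced particle
   draws a direction (down with probability ``downwards``) and an integer
   magnitude from a configurable distribution with mean ``distance``, and
   lands at the clamped target layer (wall boundaries: particles stop at
   the interface or at the bottom layer rather than leaving the grid).
2. **Passive rebalancing** — active movement leaves layers over or under
   their capacity; surpluses are pushed layer by layer towards deficits
   (bottom-up first, then top-down if the surface overflows). The particles
   pushed out of a layer are drawn sequentially without replacement with
   tracer weight ``tracerdif`` against weight 1 for non-marked grains.

Both phases conserve the tracer and total particle inventories exactly;
after a full step every layer is exactly at capacity again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._sampling import draw_tracer_moves
from .errors import ConfigurationError, ConsistencyError
from .profiles import ProfileSeries

__all__ = [
    "ModelParams",
    "SimConfig",
    "LatticeState",
    "DisplacementLedger",
    "MAGNITUDE_DISTRIBUTIONS",
    "magnitude_second_moment",
    "init_lattice",
    "draw_active_displacements",
    "apply_ledger",
    "passive_rebalance",
    "step",
    "simulate",
]


# --------------------------------------------------------------------------
# displacement-magnitude distributions
#
# The framework treats the per-displacement step length as a pluggable
# integer distribution parameterised by its mean. "poisson" is the default;
# "fixed" rounds the mean stochastically (floor(m) plus a Bernoulli on the
# fractional part); "geometric" is a heavier-tailed alternative (support
# starting at 0). A draw of 0 leaves the particle in place.

def _poisson_magnitude(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    return rng.poisson(mean, size)


def _fixed_magnitude(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    base = math.floor(mean)
    frac = mean - base
    out = np.full(size, base, dtype=np.int64)
    if frac > 0:
        out += rng.random(size) < frac
    return out


def _geometric_magnitude(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    # support {0, 1, 2, ...} with mean (1-p)/p = mean
    p = 1.0 / (1.0 + mean)
    return rng.geometric(p, size) - 1


MAGNITUDE_DISTRIBUTIONS: dict[str, Callable[[np.random.Generator, float, int], np.ndarray]] = {
    "poisson": _poisson_magnitude,
    "fixed": _fixed_magnitude,
    "geometric": _geometric_magnitude,
}


def magnitude_second_moment(name: str, mean: float) -> float:
    """E[m^2] of the named magnitude distribution with the given mean.

    Needed by the diffusion-limit analysis: a symmetric walk with step
    magnitude m spreads depth variance at rate E[m^2] per displacement.
    """
    if name == "poisson":
        return mean + mean * mean
    if name == "fixed":
        base = math.floor(mean)
        frac = mean - base
        return (1 - frac) * base * base + frac * (base + 1) ** 2
    if name == "geometric":
        p = 1.0 / (1.0 + mean)
        var = (1.0 - p) / (p * p)
        return var + mean * mean
    raise ConfigurationError(f"unknown magnitude distribution {name!r}")


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ModelParams:
    """The five behavioural parameters of the bioturbation model.

    Parameters
    ----------
    activity : float
        Probability per tracer particle per time step of being actively
        displaced, in [0, 1]. The expected rest period of a particle is
        (1 - activity) x one time step.
    distance : float
        Mean displacement magnitude, in layers (> 0).
    downwards : float
        Probability that a displaced particle moves down rather than up,
        in [0, 1]; 0.5 gives symmetric mixing.
    range_frac : float
        Fraction of the total depth open to active reworking, in (0, 1];
        often simply called "range". Layers at or below
        round(range_frac * d) are never the origin of an active move.
    tracerdif : float
        Relative selection weight of a tracer particle versus a non-marked
        particle during passive relocation, in (0, 1]. Values below 1 make
        tracers lag behind the compensatory particle flow, which is what
        produces a subsurface tracer peak.
    """

    activity: float
    distance: float
    downwards: float = 0.5
    range_frac: float = 1.0
    tracerdif: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity <= 1.0:
            raise ConfigurationError(f"activity must be in [0, 1], got {self.activity}")
        if not self.distance > 0.0:
            raise ConfigurationError(f"distance must be > 0, got {self.distance}")
        if not 0.0 <= self.downwards <= 1.0:
            raise ConfigurationError(f"downwards must be in [0, 1], got {self.downwards}")
        if not 0.0 < self.range_frac <= 1.0:
            raise ConfigurationError(f"range_frac must be in (0, 1], got {self.range_frac}")
        if not 0.0 < self.tracerdif <= 1.0:
            raise ConfigurationError(f"tracerdif must be in (0, 1], got {self.tracerdif}")


@dataclass(frozen=True)
class SimConfig:
    """Lattice geometry, physical scales and time stepping.

    ``d`` layers of capacity ``w`` particles; the uppermost ``d_lum``
    layers start filled with tracer. ``layer_height_mm`` and ``dt_min``
    carry the physical scales of one layer and one time step.
    """

    d: int
    w: int
    d_lum: int
    layer_height_mm: float = 0.073
    dt_min: float = 5.0
    n_steps: int = 24
    seed: int = 0
    magnitude_dist: str = "poisson"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ConfigurationError(f"d must be >= 1, got {self.d}")
        if self.w < 1:
            raise ConfigurationError(f"w must be >= 1, got {self.w}")
        if not 0 <= self.d_lum <= self.d:
            raise ConfigurationError(
                f"d_lum must be in [0, d={self.d}], got {self.d_lum}"
            )
        if self.n_steps < 0:
            raise ConfigurationError(f"n_steps must be >= 0, got {self.n_steps}")
        if not self.layer_height_mm > 0:
            raise ConfigurationError(
                f"layer_height_mm must be > 0, got {self.layer_height_mm}"
            )
        if not self.dt_min > 0:
            raise ConfigurationError(f"dt_min must be > 0, got {self.dt_min}")
        if self.magnitude_dist not in MAGNITUDE_DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown magnitude_dist {self.magnitude_dist!r}; "
                f"choose one of {sorted(MAGNITUDE_DISTRIBUTIONS)}"
            )


@dataclass
class LatticeState:
    """Per-layer tracer and non-marked particle counts.

    Layer 0 is the sediment–water interface; indices increase downward.
    After any full model step every layer holds exactly ``capacity``
    particles in total.
    """

    tracer: np.ndarray
    nonmarked: np.ndarray
    capacity: int

    @property
    def d(self) -> int:
        return self.tracer.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.tracer + self.nonmarked

    @property
    def total_tracer(self) -> int:
        return int(self.tracer.sum())

    def copy(self) -> "LatticeState":
        return LatticeState(self.tracer.copy(), self.nonmarked.copy(), self.capacity)


@dataclass
class DisplacementLedger:
    """Per-layer tracer removals and additions from one active phase.

    Total removals equal total additions: active displacement relocates
    tracer particles, it never creates or destroys them.
    """

    removals: np.ndarray
    additions: np.ndarray

    @property
    def n_moved(self) -> int:
        return int(self.removals.sum())


# --------------------------------------------------------------------------
# operations


def init_lattice(config: SimConfig) -> LatticeState:
    """Initial lattice: the uppermost ``d_lum`` layers are pure tracer.

    This mirrors the experimental deposition of a luminophore layer on the
    sediment surface; every layer starts exactly at capacity ``w``.
    """
    tracer = np.zeros(config.d, dtype=np.int64)
    tracer[: config.d_lum] = config.w
    nonmarked = np.full(config.d, config.w, dtype=np.int64)
    nonmarked[: config.d_lum] = 0
    return LatticeState(tracer, nonmarked, config.w)


def draw_active_displacements(
    state: LatticeState,
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> DisplacementLedger:
    """Draw one round of active tracer displacement.

    For every layer within the reworked range, Binomial(t_i, activity)
    tracers are displaced; each draws an independent direction
    (down with probability ``downwards``) and a magnitude from the
    configured distribution with mean ``distance``. Targets are clamped
    to [0, d-1] (wall boundaries).
    """
    d = state.d
    n_active = int(round(params.range_frac * d))
    removals = np.zeros(d, dtype=np.int64)
    additions = np.zeros(d, dtype=np.int64)
    if n_active == 0 or params.activity == 0.0:
        return DisplacementLedger(removals, additions)

    counts = state.tracer[:n_active]
    n_disp = rng.binomial(counts, params.activity)
    total = int(n_disp.sum())
    if total == 0:
        return DisplacementLedger(removals, additions)

    origins = np.repeat(np.arange(n_active), n_disp)
    magnitudes = MAGNITUDE_DISTRIBUTIONS[config.magnitude_dist](
        rng, params.distance, total
    )
    down = rng.random(total) < params.downwards
    signed = np.where(down, magnitudes, -magnitudes)
    targets = np.clip(origins + signed, 0, d - 1)

    removals[:n_active] = n_disp
    np.add.at(additions, targets, 1)
    return DisplacementLedger(removals, additions)


def apply_ledger(state: LatticeState, ledger: DisplacementLedger) -> LatticeState:
    """Apply an active-displacement ledger to the tracer column.

    Conserves total tracer; layer totals may now deviate from capacity
    until :func:`passive_rebalance` runs.
    """
    if np.any(ledger.removals > state.tracer):
        bad = int(np.argmax(ledger.removals > state.tracer))
        raise ConsistencyError(
            f"ledger removes {ledger.removals[bad]} tracer from layer {bad} "
            f"which holds only {state.tracer[bad]}"
        )
    tracer = state.tracer - ledger.removals + ledger.additions
    return LatticeState(tracer, state.nonmarked.copy(), state.capacity)


def passive_rebalance(
    state: LatticeState,
    tracerdif: float,
    rng: np.random.Generator,
) -> LatticeState:
    """Restore every layer to exact capacity by compensatory relocation.

    Bottom-up pass: from the deepest layer upward, any surplus over the
    capacity ``w`` is moved to the layer above; the moved particles are
    drawn sequentially without replacement with tracer weight
    ``tracerdif`` versus 1 for non-marked grains, from the full current
    pool of the layer (including particles just received from below).
    If the surface layer then overflows, a symmetric top-down pass pushes
    the surplus back into the deficits below. Tracer and non-marked
    inventories are conserved exactly.
    """
    w = state.capacity
    d = state.d
    t = state.tracer.copy()
    s = state.nonmarked.copy()
    if int(t.sum() + s.sum()) != d * w:
        raise ConsistencyError(
            f"total particle count {int(t.sum() + s.sum())} != d*w = {d * w} "
            "on entry to passive rebalancing"
        )

    # upward pass, deepest layer first
    for i in range(d - 1, 0, -1):
        k = int(t[i] + s[i]) - w
        if k > 0:
            x = draw_tracer_moves(int(t[i]), int(s[i]), k, tracerdif, rng)
            t[i] -= x
            s[i] -= k - x
            t[i - 1] += x
            s[i - 1] += k - x

    # top-down pass only if active upward movement overfilled the surface
    if int(t[0] + s[0]) > w:
        for i in range(d - 1):
            k = int(t[i] + s[i]) - w
            if k > 0:
                x = draw_tracer_moves(int(t[i]), int(s[i]), k, tracerdif, rng)
                t[i] -= x
                s[i] -= k - x
                t[i + 1] += x
                s[i + 1] += k - x

    return LatticeState(t, s, w)


def step(
    state: LatticeState,
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> LatticeState:
    """One full model time step: active displacement, then rebalancing."""
    ledger = draw_active_displacements(state, params, config, rng)
    displaced = apply_ledger(state, ledger)
    return passive_rebalance(displaced, params.tracerdif, rng)


def simulate(
    params: ModelParams,
    config: SimConfig,
    initial: LatticeState | None = None,
) -> ProfileSeries:
    """Run the model and return the depth x time tracer-count matrix.

    Column 0 is the initial profile; column k the profile after k steps.
    Identical (params, config) — including ``config.seed`` — give
    bit-identical output. ``initial`` overrides the standard surface-slab
    initial condition (it must be a capacity-balanced state on the same
    grid), e.g. for a dilute mid-column tracer release.
    """
    rng = np.random.default_rng(config.seed)
    if initial is None:
        state = init_lattice(config)
    else:
        if initial.d != config.d or initial.capacity != config.w:
            raise ConfigurationError(
                f"initial state ({initial.d} layers, capacity {initial.capacity}) "
                f"does not match config (d={config.d}, w={config.w})"
            )
        state = initial.copy()
    counts = np.empty((config.d, config.n_steps + 1), dtype=np.int64)
    counts[:, 0] = state.tracer
    for k in range(config.n_steps):
        state = step(state, params, config, rng)
        counts[:, k + 1] = state.tracer
    return ProfileSeries(
        counts=counts,
        dt_min=config.dt_min,
        layer_height_mm=config.layer_height_mm,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, seed=seed)
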