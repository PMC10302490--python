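"""Particle swarm optimization with fuzzy self-tuning control coefficients.

The swarm searches a box-bounded parameter space; the first particle can
be seeded with prior knowledge (AA-mapped equilibrium values plus force
constant priors) while the rest start uniformly at random.  Two update
modes are provided:

``fst``
    Fuzzy self-tuning PSO: each particle carries its own inertia,
    cognitive and social coefficients plus velocity clamps, adapted every
    iteration by a zero-order Sugeno fuzzy system whose inputs are the
    particle's normalized fitness change and its normalized distance from
    the global best.  The rule base in this module is a reconstruction of
    the published self-tuning scheme (triangular/trapezoidal memberships,
    weighted-average defuzzification); the exact breakpoints are this
    package's documented choices.
``plain``
    Constriction-style PSO with fixed coefficients (omega = 0.72,
    c1 = c2 = 1.49), kept as a transparent fallback and for cross-checks.

Positions are reflected back into bounds, global/personal bests update
under strict improvement only, and the run terminates after a configured
number of stale iterations without improvement of the global best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Particle",
    "SwarmState",
    "OptimizerConfig",
    "default_swarm_size",
    "initialize_swarm",
    "step",
    "optimize",
]


def default_swarm_size(dim: int) -> int:
    """Population heuristic floor(10 + 2*sqrt(dim)) of the self-tuning PSO."""
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    return int(math.floor(10.0 + 2.0 * math.sqrt(dim)))


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_loss: float = np.inf
    prev_loss: float = np.inf
    # per-particle control coefficients (FST mode adapts these)
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    vmax_frac: float = 0.2     # max |velocity| as a fraction of the range
    vmin_frac: float = 0.0     # min |velocity| once moving


@dataclass
class SwarmState:
    particles: list[Particle]
    bounds: np.ndarray                  # (dim, 2)
    global_best_position: np.ndarray
    global_best_loss: float = np.inf
    worst_loss_seen: float = -np.inf
    iteration: int = 0
    stale_iterations: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    mode: str = "fst"

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]


@dataclass
class OptimizerConfig:
    swarm_size: int | None = None
    max_iterations: int = 500
    stale_limit: int = 10
    mode: str = "fst"          # "fst" | "plain"
    seed: int = 0


def initialize_swarm(
    bounds: np.ndarray,
    seed_vector: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    swarm_size: int | None = None,
    mode: str = "fst",
) -> SwarmState:
    """Uniform-random swarm within *bounds*; particle 0 is the seed vector.

    A seed outside the bounds is clamped with a warning.  Velocities start
    at zero.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be (dim, 2) with lo < hi")
    rng = rng if rng is not None else np.random.default_rng()
    dim = bounds.shape[0]
    n = swarm_size if swarm_size is not None else default_swarm_size(dim)
    lo, hi = bounds[:, 0], bounds[:, 1]
    positions = rng.uniform(lo, hi, size=(n, dim))
    if seed_vector is not None:
        seed_vector = np.asarray(seed_vector, dtype=float)
        if seed_vector.shape != (dim,):
            raise ValueError("seed vector dimension mismatch")
        clipped = np.clip(seed_vector, lo, hi)
        if not np.array_equal(clipped, seed_vector):
            import warnings

            warnings.warn("seed vector outside bounds; clamped", stacklevel=2)
        positions[0] = clipped
    particles = [
        Particle(
            position=positions[i].copy(),
            velocity=np.zeros(dim),
            best_position=positions[i].copy(),
        )
        for i in range(n)
    ]
    return SwarmState(
        particles=particles,
        bounds=bounds,
        global_best_position=positions[0].copy(),
        rng=rng,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# fuzzy rule base (zero-order Sugeno, weighted-average defuzzification)

def _tri(x: float, a: float, b: float, c: float) -> float:
    if x <= a or x >= c:
        return 0.0
    return (x - a) / (b - a) if x <= b else (c - x) / (c - b)


def _trap(x: float, a: float, b: float, c: float, d: float) -> float:
    if x <= a or x >= d:
        return 0.0
    if b <= x <= c:
        return 1.0
    return (x - a) / (b - a) if x < b else (d - x) / (d - c)


# input memberships: phi = normalized fitness change in [-1, 1]
# (negative = improved), delta = normalized distance from global best in [0, 1]
def _phi_memberships(phi: float) -> dict[str, float]:
    return {
        "better": _trap(phi, -1.001, -1.0, -0.5, 0.0),
        "same": _tri(phi, -0.5, 0.0, 0.5),
        "worse": _trap(phi, 0.0, 0.5, 1.0, 1.001),
    }


def _delta_memberships(delta: float) -> dict[str, float]:
    return {
        "same": _trap(delta, -0.001, 0.0, 0.05, 0.25),
        "near": _tri(delta, 0.05, 0.25, 0.6),
        "far": _trap(delta, 0.25, 0.6, 1.0, 1.001),
    }


# output singletons
_INERTIA = {"low": 0.3, "medium": 0.5, "high": 1.0}
_SOCIAL = {"low": 1.0, "medium": 2.0, "high": 3.0}
_COGNITIVE = {"low": 0.1, "medium": 1.5, "high": 3.0}
_VMAX = {"low": 0.1, "medium": 0.15, "high": 0.2}
_VMIN = {"low": 0.0, "medium": 0.001, "high": 0.01}

# rules: (input variable, input set) -> output level per output variable.
# A particle that just improved slows down and refines the region it is in
# (low inertia, small steps); one that worsened keeps momentum to leave the
# region; particles far from the global best get a stronger social pull and
# larger steps, particles on top of it search finely.
_RULES = [
    ("phi", "better", {"inertia": "low", "social": "medium", "cognitive": "medium",
                       "vmax": "low", "vmin": "low"}),
    ("phi", "same", {"inertia": "medium", "social": "medium", "cognitive": "medium",
                     "vmax": "medium", "vmin": "low"}),
    ("phi", "worse", {"inertia": "high", "social": "medium", "cognitive": "low",
                      "vmax": "high", "vmin": "medium"}),
    ("delta", "same", {"inertia": "low", "social": "medium", "cognitive": "medium",
                       "vmax": "low", "vmin": "low"}),
    ("delta", "near", {"inertia": "medium", "social": "medium", "cognitive": "medium",
                       "vmax": "medium", "vmin": "low"}),
    ("delta", "far", {"inertia": "high", "social": "high", "cognitive": "low",
                      "vmax": "high", "vmin": "medium"}),
]

_OUTPUT_TABLES = {
    "inertia": _INERTIA,
    "social": _SOCIAL,
    "cognitive": _COGNITIVE,
    "vmax": _VMAX,
    "vmin": _VMIN,
}


def _fuzzy_update(particle: Particle, phi: float, delta: float) -> None:
    mu = {"phi": _phi_memberships(phi), "delta": _delta_memberships(delta)}
    outputs = {name: 0.0 for name in _OUTPUT_TABLES}
    weight_sum = {name: 0.0 for name in _OUTPUT_TABLES}
    for var, level, consequents in _RULES:
        w = mu[var][level]
        if w == 0.0:
            continue
        for out_name, out_level in consequents.items():
            outputs[out_name] += w * _OUTPUT_TABLES[out_name][out_level]
            weight_sum[out_name] += w
    if weight_sum["inertia"] > 0:
        particle.inertia = outputs["inertia"] / weight_sum["inertia"]
        particle.social = outputs["social"] / weight_sum["social"]
        particle.cognitive = outputs["cognitive"] / weight_sum["cognitive"]
        particle.vmax_frac = outputs["vmax"] / weight_sum["vmax"]
        particle.vmin_frac = outputs["vmin"] / weight_sum["vmin"]


# ---------------------------------------------------------------------------


def _reflect(position: np.ndarray, velocity: np.ndarray, bounds: np.ndarray):
    """Reflect positions at the box walls, flipping the velocity component."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    pos = position.copy()
    vel = velocity.copy()
    for _ in range(10):  # repeated reflection for large overshoots
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            break
        pos[below] = 2 * lo[below] - pos[below]
        pos[above] = 2 * hi[above] - pos[above]
        vel[below] *= -1
        vel[above] *= -1
    np.clip(pos, lo, hi, out=pos)
    return pos, vel, span


def step(state: SwarmState, losses) -> SwarmState:
    """One synchronous swarm iteration given the loss of every particle.

    Non-finite losses count as failed evaluations (+inf).  Bests update
    under strict improvement; the stale counter resets only when the
    global best strictly improves.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.shape != (len(state.particles),):
        raise ValueError("need exactly one loss per particle")
    losses = np.where(np.isfinite(losses), losses, np.inf)

    improved_global = False
    for p, f in zip(state.particles, losses):
        if f < p.best_loss:
            p.best_loss = float(f)
            p.best_position = p.position.copy()
        if f < state.global_best_loss:
            state.global_best_loss = float(f)
            state.global_best_position = p.position.copy()
            improved_global = True

    diag = float(np.linalg.norm(state.bounds[:, 1] - state.bounds[:, 0]))
    if np.isfinite(losses).any():
        state.worst_loss_seen = max(
            state.worst_loss_seen, float(losses[np.isfinite(losses)].max())
        )
    # normalize fitness changes by the worst-to-best spread seen over the
    # whole run: stable late in the search, when the per-iteration spread
    # shrinks to the noise level
    scale = max(abs(state.worst_loss_seen - state.global_best_loss), 1e-12)

    for p, f in zip(state.particles, losses):
        if state.mode == "fst":
            if np.isfinite(p.prev_loss) and np.isfinite(f):
                phi = float(np.clip((f - p.prev_loss) / scale, -1.0, 1.0))
            else:
                phi = 1.0 if not np.isfinite(f) else 0.0
            delta = float(
                np.linalg.norm(p.position - state.global_best_position) / max(diag, 1e-12)
            )
            _fuzzy_update(p, phi, min(delta, 1.0))
        p.prev_loss = float(f)

        r1 = state.rng.random(state.dim)
        r2 = state.rng.random(state.dim)
        vel = (
            p.inertia * p.velocity
            + p.cognitive * r1 * (p.best_position - p.position)
            + p.social * r2 * (state.global_best_position - p.position)
        )
        span = state.bounds[:, 1] - state.bounds[:, 0]
        if not np.any(np.abs(vel) > 0):
            # a particle sitting exactly on its own and the global best
            # (e.g. the seeded first particle) would freeze forever; give
            # it a small exploratory kick instead
            vel = 0.002 * span * state.rng.standard_normal(state.dim)
        vmax = p.vmax_frac * span
        vel = np.clip(vel, -vmax, vmax)
        if state.mode == "fst" and p.vmin_frac > 0:
            vmin = p.vmin_frac * span
            small = (np.abs(vel) < vmin) & (vel != 0)
            vel[small] = np.sign(vel[small]) * vmin[small]
        pos, vel, _ = _reflect(p.position + vel, vel, state.bounds)
        p.position = pos
        p.velocity = vel

    state.iteration += 1
    state.stale_iterations = 0 if improved_global else state.stale_iterations + 1
    return state


@dataclass
class OptimizeHistory:
    iterations: list[dict] = field(default_factory=list)

    def record(self, iteration: int, losses: np.ndarray, best_loss: float) -> None:
        finite = losses[np.isfinite(losses)]
        self.iterations.append(
            {
                "iteration": iteration,
                "best_loss": best_loss,
                "iteration_min": float(finite.min()) if finite.size else np.inf,
                "iteration_mean": float(finite.mean()) if finite.size else np.inf,
                "n_failed": int(np.sum(~np.isfinite(losses))),
                "losses": losses.tolist(),
            }
        )


def optimize(
    objective,
    bounds: np.ndarray,
    config: OptimizerConfig | None = None,
    seed_vector: np.ndarray | None = None,
    callback=None,
) -> tuple[np.ndarray, float, OptimizeHistory, str]:
    """Run the swarm until the stale-iteration limit or max iterations.

    *objective* maps a position vector to a scalar loss (non-finite for a
    failed evaluation).  Returns (best position, best loss, history,
    convergence reason).  With a fixed config seed and a deterministic
    objective, the run is bit-reproducible.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(
        np.asarray(bounds, dtype=float),
        seed_vector=seed_vector,
        rng=rng,
        swarm_size=config.swarm_size,
        mode=config.mode,
    )
    history = OptimizeHistory()
    reason = "max_iterations"
    for _ in range(config.max_iterations):
        losses = np.array([objective(p.position.copy()) for p in state.particles],
                          dtype=float)
        if not np.isfinite(losses).any() and state.iteration == 0:
            raise RuntimeError("objective failed for every particle at start")
        step(state, losses)
        history.record(state.iteration, losses, state.global_best_loss)
        if callback is not None:
            callback(state)
        if state.stale_iterations >= config.stale_limit:
            reason = "stale_iterations"
            break
    return state.global_best_position.copy(), state.global_best_loss, history, reason
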