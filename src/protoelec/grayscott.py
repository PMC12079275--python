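"""Gray-Scott reaction-diffusion simulator with capacitance-driven
parameter modulation.

Two concentration fields evolve on a square periodic grid by explicit
Euler finite differences (dt = 1 grid-time unit, unit grid spacing,
5-point Laplacian):

    A <- A + dt * (D_A lap(A) - A B^2 + F (1 - A))
    B <- B + dt * (D_B lap(B) + A B^2 - (k + F) B)

A is the substrate (fed at rate F), B the activator (removed at rate
k + F). The published parameter triples for the three cells are
exported as ``ACTIN_GS``, ``PROTEINOID_GS`` and ``MIXTURE_GS``; all
share k = 0.0600.

Capacitance logs from impedance spectroscopy modulate D_A, D_B and F
multiplicatively around their base values,

    p_t = p_base * (1 + beta * (C_t - mean(C)) / mean(C)),

with the kill rate held fixed; the capacitance series is linearly
resampled to the number of simulation steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InstabilityError, InvalidSpecError

__all__ = [
    "GrayScottParams",
    "GrayScottState",
    "ACTIN_GS",
    "PROTEINOID_GS",
    "MIXTURE_GS",
    "init_state",
    "laplacian",
    "step",
    "simulate",
    "modulate_params",
    "pattern_metrics",
]


@dataclass(frozen=True)
class GrayScottParams:
    """Diffusion coefficients, feed rate F and kill rate k."""

    d_a: float
    d_b: float
    feed: float
    kill: float

    def __post_init__(self) -> None:
        for name in ("d_a", "d_b", "feed", "kill"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if self.d_a > 0.25 or self.d_b > 0.25:
            raise InvalidSpecError(
                "diffusion coefficients above 0.25 are unstable at dt = 1 on a unit grid"
            )


ACTIN_GS = GrayScottParams(d_a=0.1592, d_b=0.0604, feed=0.0202, kill=0.0600)
PROTEINOID_GS = GrayScottParams(d_a=0.1548, d_b=0.0618, feed=0.0209, kill=0.0600)
MIXTURE_GS = GrayScottParams(d_a=0.1582, d_b=0.0606, feed=0.0203, kill=0.0600)


@dataclass
class GrayScottState:
    """Substrate field A and activator field B on a square grid."""

    field_a: np.ndarray
    field_b: np.ndarray
    step_count: int = 0

    def __post_init__(self) -> None:
        self.field_a = np.asarray(self.field_a, dtype=float)
        self.field_b = np.asarray(self.field_b, dtype=float)
        if self.field_a.shape != self.field_b.shape or self.field_a.ndim != 2:
            raise InvalidSpecError("fields must be 2-D arrays of equal shape")
        if self.field_a.shape[0] != self.field_a.shape[1]:
            raise InvalidSpecError("fields must be square")

    @property
    def grid_size(self) -> int:
        return self.field_a.shape[0]


def init_state(
    grid_size: int = 100,
    seed_region_half_width: int = 5,
    noise_amp: float = 0.0,
    seed: int | None = 0,
) -> GrayScottState:
    """Standard initial condition: A = 1 everywhere, B = 1 inside the
    central square of side 2*half_width + 1, 0 elsewhere; optional
    uniform noise of amplitude ``noise_amp`` on both fields (seeded)."""
    if grid_size < 3:
        raise InvalidSpecError("grid must be at least 3x3")
    side = 2 * seed_region_half_width + 1
    if seed_region_half_width < 0 or side > grid_size:
        raise InvalidSpecError(
            f"seed region of side {side} does not fit a {grid_size}x{grid_size} grid"
        )
    a = np.ones((grid_size, grid_size))
    b = np.zeros((grid_size, grid_size))
    c = grid_size // 2
    lo, hi = c - seed_region_half_width, c + seed_region_half_width + 1
    b[lo:hi, lo:hi] = 1.0
    if noise_amp > 0:
        rng = np.random.default_rng(seed)
        a += noise_amp * rng.uniform(-1.0, 1.0, a.shape)
        b += noise_amp * rng.uniform(-1.0, 1.0, b.shape)
        np.clip(b, 0.0, None, out=b)
    return GrayScottState(field_a=a, field_b=b, step_count=0)


def laplacian(field: np.ndarray) -> np.ndarray:
    """5-point finite-difference Laplacian with periodic boundaries."""
    return (
        np.roll(field, 1, axis=0)
        + np.roll(field, -1, axis=0)
        + np.roll(field, 1, axis=1)
        + np.roll(field, -1, axis=1)
        - 4.0 * field
    )


def step(state: GrayScottState, params: GrayScottParams, dt: float = 1.0) -> GrayScottState:
    """One explicit Euler update; raises on numerical blow-up."""
    a, b = state.field_a, state.field_b
    reaction = a * b * b
    a_new = a + dt * (params.d_a * laplacian(a) - reaction + params.feed * (1.0 - a))
    b_new = b + dt * (params.d_b * laplacian(b) + reaction - (params.kill + params.feed) * b)
    if not (np.all(np.isfinite(a_new)) and np.all(np.isfinite(b_new))):
        raise InstabilityError(
            f"non-finite fields at step {state.step_count + 1} with params {params}"
        )
    return GrayScottState(field_a=a_new, field_b=b_new, step_count=state.step_count + 1)


def simulate(
    params: GrayScottParams,
    n_steps: int = 5000,
    grid_size: int = 100,
    seed_region_half_width: int = 5,
    noise_amp: float = 0.0,
    seed: int | None = 0,
    dt: float = 1.0,
    schedule: list[GrayScottParams] | None = None,
    snapshot_every: int | None = None,
) -> GrayScottState | tuple[GrayScottState, list[GrayScottState]]:
    """Run ``n_steps`` updates from the standard initial condition.

    A per-step parameter ``schedule`` (e.g. from
    :func:`modulate_params`) overrides ``params``; with
    ``snapshot_every`` set, intermediate states are also returned.
    """
    if n_steps < 1:
        raise InvalidSpecError("n_steps must be at least 1")
    if schedule is not None and len(schedule) != n_steps:
        raise InvalidSpecError(f"schedule length {len(schedule)} != n_steps {n_steps}")
    state = init_state(grid_size, seed_region_half_width, noise_amp, seed)
    snapshots: list[GrayScottState] = []
    for i in range(n_steps):
        p = schedule[i] if schedule is not None else params
        state = step(state, p, dt)
        if snapshot_every and (i + 1) % snapshot_every == 0:
            snapshots.append(state)
    if snapshot_every:
        return state, snapshots
    return state


def modulate_params(
    base: GrayScottParams,
    capacitance: np.ndarray,
    beta: float = 0.5,
    n_steps: int | None = None,
) -> list[GrayScottParams]:
    """Per-step parameter schedule driven by a capacitance series.

    D_A, D_B and F scale as p_base * (1 + beta * (C_t - mean(C))/mean(C));
    the kill rate stays fixed. The capacitance series is linearly
    resampled to ``n_steps`` (default: its own length). Raises when the
    modulation would push any parameter negative or past the diffusion
    stability bound.
    """
    c = np.asarray(capacitance, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise InvalidSpecError("capacitance must be a nonempty 1-D series")
    if np.any(c <= 0):
        raise InvalidSpecError("capacitance values must be positive")
    if n_steps is None:
        n_steps = len(c)
    if len(c) != n_steps:
        xi = np.linspace(0.0, len(c) - 1.0, n_steps)
        c = np.interp(xi, np.arange(len(c)), c)
    if np.ptp(c) == 0.0:
        rel = np.zeros(n_steps)  # constant capacitance: exactly no modulation
    else:
        rel = beta * (c - c.mean()) / c.mean()
    schedule = []
    for r in rel:
        factor = 1.0 + r
        if factor <= 0:
            raise InvalidSpecError(f"beta={beta} drives parameters negative (factor {factor:.3g})")
        try:
            schedule.append(replace(base, d_a=base.d_a * factor, d_b=base.d_b * factor,
                                    feed=base.feed * factor))
        except InvalidSpecError as exc:
            raise InvalidSpecError(f"modulated parameters unstable: {exc}") from exc
    return schedule


def pattern_metrics(state: GrayScottState) -> tuple[float, int, float]:
    """(spatial sd of B, spot count, mean of B).

    Spots are 4-connected components of cells with B above
    mean(B) + sd(B).
    """
    b = state.field_b
    if not np.all(np.isfinite(b)):
        raise InstabilityError("pattern metrics need finite fields")
    sd = float(np.std(b))
    mean = float(np.mean(b))
    mask = b > mean + sd
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n_spots = ndimage.label(mask, structure=structure)
    return sd, int(n_spots), mean
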