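"""Steady-state Newton–Raphson solution and BDF2 transient integration.

The sixteen unknowns and residuals are documented in
:mod:`proxtubule.balance`. The Jacobian is always formed by finite
differences on the scaled unknowns; steady states are polished to near
machine accuracy, and transients use the three-point, second-order backward
difference scheme

    (3·X‌ⁿ − 4·Xⁿ⁻¹ + Xⁿ⁻²)/(2Δt) = Σ J(Xⁿ)

for the ten conserved quantities (compartment volumes and volume ×
concentration products), coupled at every step with the six algebraic
closures. The first step of a run (and of each time-step phase) is a single
backward-Euler step, after which the three-point stencil applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import balance
from .balance import (
    N_UNKNOWNS,
    assemble_residuals,
    conservation_rates,
    default_initial_state,
    state_to_vector,
    vector_to_state,
)
from .core_types import BathComposition, EpithelialState, ModelParameters
from .flux_laws import FluxSet, compute_fluxes

__all__ = [
    "SolverSettings",
    "TransientHistory",
    "SolverError",
    "newton_steady_state",
    "solve_steady_state",
    "finite_difference_jacobian",
    "bdf2_step",
    "run_transient",
]

logger = logging.getLogger("proxtubule.solver")


class SolverError(RuntimeError):
    """Newton divergence; carries the residual trace for diagnosis."""

    def __init__(self, message: str, residual_trace: list[float] | None = None):
        super().__init__(message)
        self.residual_trace = residual_trace or []


@dataclass(frozen=True)
class SolverSettings:
    """Newton and time-stepping controls.

    newtonTol : convergence bound on the max |scaled residual|
    maxIter   : Newton iteration cap
    fdStep    : finite-difference step on the scaled unknowns
    dt        : time step, s
    dtInit    : refined step used for the first ``tInit`` seconds of a
                transient, resolving fast forcings
    damping   : initial Newton step-length factor in (0, 1]
    """

    newtonTol: float = 1e-11
    maxIter: int = 60
    fdStep: float = 1e-7
    dt: float = 0.01
    dtInit: float = 1e-4
    tInit: float = 0.01
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.newtonTol <= 0 or self.dt <= 0 or self.dtInit <= 0:
            raise ValueError("newtonTol, dt and dtInit must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


@dataclass
class TransientHistory:
    """Uniform-in-phase record of a transient run."""

    times: list[float] = field(default_factory=list)
    states: list[EpithelialState] = field(default_factory=list)
    fluxes: list[FluxSet] = field(default_factory=list)

    def append(self, t: float, state: EpithelialState, fx: FluxSet) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        self.times.append(t)
        self.states.append(state)
        self.fluxes.append(fx)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> EpithelialState:
        return self.states[-1]

    @property
    def final_fluxes(self) -> FluxSet:
        return self.fluxes[-1]


# ---------------------------------------------------------------------------
# Jacobian


def finite_difference_jacobian(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    fd_step: float,
    r0: np.ndarray | None = None,
) -> np.ndarray:
    """Column-wise one-sided difference Jacobian with relative step
    ``fd_step`` on each (scaled) unknown."""
    x = np.asarray(x, dtype=float)
    if r0 is None:
        r0 = residual_fn(x)
    if not np.all(np.isfinite(r0)):
        raise FloatingPointError("residual not finite at the probing point")
    n = x.size
    jac = np.empty((r0.size, n))
    for j in range(n):
        h = fd_step * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        rp = residual_fn(xp)
        if not np.all(np.isfinite(rp)):
            # retreat to a one-sided step in the other direction
            xp[j] = x[j] - h
            rm = residual_fn(xp)
            if not np.all(np.isfinite(rm)):
                raise FloatingPointError(
                    f"residual not finite while probing unknown {j}"
                )
            jac[:, j] = (r0 - rm) / h
        else:
            jac[:, j] = (rp - r0) / h
    return jac


# ---------------------------------------------------------------------------
# Newton


def _admissible(x: np.ndarray) -> bool:
    """Concentrations (0:9) must stay non-negative and volumes (14:16)
    positive on the scaled vector. A concentration of exactly zero is
    admissible (impermeant-free cells, glucose-free baths)."""
    return bool(np.all(x[:9] >= 0.0) and np.all(x[14:16] > 0.0))


def _newton(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    settings: SolverSettings,
    context: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton iteration on the scaled unknowns; returns (x, residual)."""
    x = np.asarray(x0, dtype=float).copy()
    if not _admissible(x):
        raise SolverError(f"{context}: inadmissible initial guess")
    r = residual_fn(x)
    trace = [float(np.max(np.abs(r)))]
    jac: np.ndarray | None = None
    for iteration in range(settings.maxIter):
        norm = np.max(np.abs(r))
        if norm < settings.newtonTol:
            logger.info(
                "%s: converged in %d iterations, residual %.3e",
                context, iteration, norm,
            )
            return x, r
        jac = finite_difference_jacobian(residual_fn, x, settings.fdStep, r0=r)
        # SVD-truncated minimum-norm step: identical to the Newton step on a
        # well-conditioned Jacobian, and well-defined when a direction
        # decouples (e.g. the cell volume at vanishing impermeant content)
        step, *_ = np.linalg.lstsq(jac, -r, rcond=1e-10)
        if not np.all(np.isfinite(step)):
            raise SolverError(f"{context}: non-finite Newton step", trace)
        lam = settings.damping
        accepted = False
        for _ in range(40):
            x_new = x + lam * step
            # an overshoot into slightly negative concentration is projected
            # back onto the admissible boundary (e.g. vanishing impermeant
            # content); volumes must stay strictly positive
            tiny = np.abs(lam * step[:9]) + 1e-300
            mask = (x_new[:9] < 0.0) & (x_new[:9] > -tiny)
            if np.any(mask):
                x_new[:9] = np.where(mask, 0.0, x_new[:9])
            if _admissible(x_new):
                try:
                    r_new = residual_fn(x_new)
                except FloatingPointError:
                    r_new = None
                if r_new is not None and np.all(np.isfinite(r_new)):
                    new_norm = np.max(np.abs(r_new))
                    if new_norm < norm or lam < 1e-8:
                        x, r = x_new, r_new
                        accepted = True
                        break
            lam *= 0.5
        if not accepted:
            raise SolverError(
                f"{context}: step-halving failed at residual {norm:.3e}", trace
            )
        trace.append(float(np.max(np.abs(r))))
    norm = float(np.max(np.abs(r)))
    if norm < settings.newtonTol * 8:
        logger.warning("%s: accepted marginal residual %.3e", context, norm)
        return x, r
    raise SolverError(
        f"{context}: no convergence in {settings.maxIter} iterations "
        f"(residual {norm:.3e})",
        trace,
    )


def newton_steady_state(
    params: ModelParameters,
    baths: BathComposition,
    guess: EpithelialState,
    settings: SolverSettings | None = None,
    Iclamp: float = 0.0,
) -> EpithelialState:
    """Solve the full nonlinear steady state from an admissible guess."""
    settings = settings or SolverSettings()
    guess.validate()

    def residual(x: np.ndarray) -> np.ndarray:
        state = vector_to_state(x, baths)
        return assemble_residuals(state, params, baths, Iclamp).values

    x, _ = _newton(residual, state_to_vector(guess, baths), settings, "steady")
    return vector_to_state(x, baths)


def solve_steady_state(
    params: ModelParameters,
    baths: BathComposition | None = None,
    guess: EpithelialState | None = None,
    settings: SolverSettings | None = None,
) -> EpithelialState:
    """Steady state with a default guess and, on Newton failure, a short
    continuation ramp of the pump and SGLT1 activities from 30% upward."""
    baths = baths if baths is not None else params.baths
    settings = settings or SolverSettings()
    guesses = [guess] if guess is not None else []
    guesses.append(default_initial_state(params, baths))
    for g in guesses:
        try:
            return newton_steady_state(params, baths, g, settings)
        except SolverError:
            logger.info("steady: direct solve failed, trying next start")
    # continuation: ramp the activity of pump, SGLT1 and the carriers up
    try:
        state = default_initial_state(params, baths)
        for scale in (0.1, 0.25, 0.5, 0.75, 1.0):
            scaled = replace(
                params,
                pump=replace(params.pump, ppump=params.pump.ppump * scale),
                sglt1=replace(params.sglt1, pmax=params.sglt1.pmax * scale),
                carriers=replace(
                    params.carriers,
                    kAmNaK2Cl=params.carriers.kAmNaK2Cl * scale,
                    kSmNaK2Cl=params.carriers.kSmNaK2Cl * scale,
                ),
            )
            state = newton_steady_state(scaled, baths, state, settings)
        return state
    except SolverError:
        logger.info("steady: continuation failed, relaxing pseudo-transiently")
    return _relax_to_steady(params, baths, settings, guess)


def _relax_to_steady(
    params: ModelParameters,
    baths: BathComposition,
    settings: SolverSettings,
    guess: EpithelialState | None = None,
) -> EpithelialState:
    """Pseudo-transient continuation: implicit relaxation with a growing
    time step until Newton converges on the steady equations."""
    state = guess if guess is not None else default_initial_state(params, baths)
    # fail fast inside the relaxation steps: one Euler solve per dt trial
    step_settings = SolverSettings(
        newtonTol=max(settings.newtonTol, 1e-10),
        maxIter=30,
        fdStep=settings.fdStep,
        dt=settings.dt,
        dtInit=settings.dtInit,
        tInit=settings.tInit,
        damping=settings.damping,
    )
    dt = 1e-2
    for iteration in range(120):
        history = TransientHistory()
        history.append(0.0, state, compute_fluxes(state, params, baths))
        y_prev = _conserved(state)

        def residual(x: np.ndarray, y0=y_prev, h=dt) -> np.ndarray:
            return _transient_residual(x, params, baths, y0, None, h)

        try:
            x, _ = _newton(
                residual, state_to_vector(state, baths), step_settings,
                f"relax dt={dt:.2g}",
            )
            state = vector_to_state(x, baths)
            dt = min(dt * 1.7, 1e4)
        except SolverError:
            dt /= 8.0
            if dt < 1e-7:
                break
            continue
        if dt > 30.0:
            try:
                return newton_steady_state(params, baths, state, settings)
            except SolverError:
                pass
    raise SolverError("steady state not reached by pseudo-transient relaxation")


# ---------------------------------------------------------------------------
# transients


def _conserved(state: EpithelialState) -> np.ndarray:
    """The ten conserved quantities: volumes and volume·concentration
    products, matching the row order of
    :func:`proxtubule.balance.conservation_rates` (species first)."""
    return np.array([
        state.volC * state.cNaC,
        state.volC * state.cKC,
        state.volC * state.cClC,
        state.volC * state.cGlucC,
        state.volL * state.cNaL,
        state.volL * state.cKL,
        state.volL * state.cClL,
        state.volL * state.cGlucL,
        state.volC,
        state.volL,
    ])


_CONSERVED_SCALE = np.array([1e-3] * 4 + [3e-5] * 4 + [1e-5, 3e-7])


def _transient_residual(
    x: np.ndarray,
    params: ModelParameters,
    baths: BathComposition,
    y_prev: np.ndarray,
    y_prev2: np.ndarray | None,
    dt: float,
) -> np.ndarray:
    state = vector_to_state(x, baths)
    fluxes = compute_fluxes(state, params, baths)
    y = _conserved(state)
    if y_prev2 is None:  # backward-Euler startup
        dydt = (y - y_prev) / dt
    else:
        dydt = (3.0 * y - 4.0 * y_prev + y_prev2) / (2.0 * dt)
    rates = conservation_rates(fluxes)
    out = np.empty(N_UNKNOWNS)
    out[:10] = (dydt - rates) / (_CONSERVED_SCALE / max(dt, 1e-6))
    out[10:] = balance.algebraic_residuals(state, params, baths, fluxes)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite transient residual")
    return out


def bdf2_step(
    history: TransientHistory,
    params: ModelParameters,
    baths: BathComposition,
    settings: SolverSettings,
    dt: float | None = None,
) -> EpithelialState:
    """Advance one implicit step from the last one or two recorded levels.

    Uses the three-point BDF2 stencil when two prior levels exist, otherwise
    a single backward-Euler step. On Newton failure the step is retried with
    a halved dt (bounded), keeping the recorded level spacing consistent by
    sub-stepping."""
    if len(history) == 0:
        raise ValueError("history must contain at least the initial state")
    dt = dt if dt is not None else settings.dt
    y_prev = _conserved(history.states[-1])
    uniform = (
        len(history) >= 2
        and abs((history.times[-1] - history.times[-2]) - dt) < 1e-12 + 1e-9 * dt
    )
    y_prev2 = _conserved(history.states[-2]) if uniform else None

    def residual(x: np.ndarray) -> np.ndarray:
        return _transient_residual(x, params, baths, y_prev, y_prev2, dt)

    x0 = state_to_vector(history.states[-1], baths)
    for attempt in range(4):
        try:
            x, _ = _newton(residual, x0, settings, f"bdf2 t={history.times[-1]:.4g}")
            return vector_to_state(x, baths)
        except SolverError:
            if attempt == 3:
                raise
            # retry the same interval as two half steps of backward Euler
            half = dt / (2 ** (attempt + 1))
            y_mid = y_prev
            x_mid = x0
            n_sub = 2 ** (attempt + 1)
            try:
                for _ in range(n_sub):
                    def sub_res(x, y_from=y_mid):
                        return _transient_residual(
                            x, params, baths, y_from, None, half
                        )
                    x_mid, _ = _newton(sub_res, x_mid, settings, "bdf2-substep")
                    y_mid = _conserved(vector_to_state(x_mid, baths))
                return vector_to_state(x_mid, baths)
            except SolverError:
                continue
    raise SolverError("bdf2 step failed after dt reductions")  # pragma: no cover


def run_transient(
    params: ModelParameters,
    baths_of_t: Callable[[float], BathComposition],
    horizon: float,
    settings: SolverSettings | None = None,
    initial: EpithelialState | None = None,
    record_every: int = 1,
    phases: Sequence[tuple[float, float]] | None = None,
) -> TransientHistory:
    """Integrate the model under time-dependent baths.

    ``phases`` is a sequence of (dt, duration) pairs; by default a refined
    phase (settings.dtInit for settings.tInit) precedes the main phase at
    settings.dt. Each phase starts with one backward-Euler step. The
    initial state defaults to the steady state under ``baths_of_t(0)``.
    ``record_every`` thins the recorded history (the levels used by the
    stencil are kept internally regardless).
    """
    settings = settings or SolverSettings()
    if initial is None:
        initial = solve_steady_state(params, baths_of_t(0.0), settings=settings)
    if phases is None:
        t_fine = min(settings.tInit, horizon)
        phases = []
        if t_fine > 0 and settings.dtInit < settings.dt:
            phases.append((settings.dtInit, t_fine))
        phases.append((settings.dt, horizon - sum(p[1] for p in phases)))

    history = TransientHistory()
    fx0 = compute_fluxes(initial, params, params.baths if baths_of_t is None
                         else baths_of_t(0.0))
    history.append(0.0, initial, fx0)

    recorded = TransientHistory()
    recorded.append(0.0, initial, fx0)

    t = 0.0
    for dt, duration in phases:
        if duration <= 0:
            continue
        n_steps = max(1, int(round(duration / dt)))
        # restart the stencil at a phase boundary: drop the second level
        if len(history) > 1:
            history = TransientHistory()
            history.append(recorded.times[-1], recorded.states[-1],
                           recorded.fluxes[-1])
        for k in range(n_steps):
            t_new = t + dt
            baths_n = baths_of_t(t_new)
            state = bdf2_step(history, params, baths_n, settings, dt=dt)
            fx = compute_fluxes(state, params, baths_n)
            history.append(t_new, state, fx)
            if len(history.times) > 3:  # keep the stencil window small
                del history.times[0], history.states[0], history.fluxes[0]
            t = t_new
            if (k + 1) % record_every == 0 or k == n_steps - 1:
                recorded.append(t, state, fx)
    return recorded
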