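"""Explicit time integration with CFL control and steady-state detection.

The semi-discrete system is advanced with strong-stability-preserving
Runge–Kutta methods (SSP-RK3 by default).  The step size is the CFL-safe
minimum of an advection bound ``dx / max|v|``, a diffusion bound
``2 Ω dx² / max(r |e|²)`` and a local-rate bound ``1 / max(total outflow)``
(jump losses, transition rates, absorption), scaled by a safety factor.
There is no randomness anywhere: repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .grids import Grid, GridDensity
from .model import ACMEModel
from .operators import SemiDiscreteOperator, rhs_matrix

__all__ = ["SolverSettings", "Trajectory", "SteadyStateResult", "compute_dt", "integrate", "steady_state"]

log = logging.getLogger("acmekit")

_BIG = 1e300


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings.

    ``split_local_sinks`` treats transitions into absorbing states with the
    exact per-step factor ``exp(-g dt)`` instead of including them in the
    explicit right-hand side; useful for stiff absorption rates.
    """

    t_final: float = 1.0
    method: str = "rk3"  # rk3 | rk2 | euler
    cfl_safety: float = 0.4
    snapshot_times: tuple[float, ...] = ()
    steady_tol: float = 1e-8
    max_steps: int = 50_000_000
    limiter: str = "minmod"
    split_local_sinks: bool = False
    record_every: int = 1
    progress_every: int = 0  # steps between INFO log lines; 0 = silent

    def __post_init__(self):
        if not (0 < self.cfl_safety <= 1):
            raise ValueError("cfl_safety must be in (0, 1]")
        if self.method not in ("rk3", "rk2", "euler"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Trajectory:
    """Snapshots at requested times plus per-step observable records."""

    model: ACMEModel
    grid: Grid
    times: list[float]
    snapshots: list[GridDensity]
    records: dict[str, np.ndarray]  # 't', 'mass' (n, K), optional 'absorption' (n, n_abs)
    absorbing_labels: tuple[str, ...] = ()
    n_steps: int = 0

    def snapshot_at(self, t: float) -> GridDensity:
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        if abs(self.times[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise KeyError(f"no snapshot at t={t}; have {self.times}")
        return self.snapshots[i]


@dataclass
class SteadyStateResult:
    density: GridDensity
    converged: bool
    residual: float
    method: str
    t_elapsed: float = 0.0


def compute_dt(model: ACMEModel, p: GridDensity, t: float, settings: SolverSettings,
               op: SemiDiscreteOperator | None = None) -> float:
    """CFL-safe step, clipped to the remaining time."""
    op = op or SemiDiscreteOperator(model, p.grid, settings.limiter)
    return _compute_dt(op, t, settings, settings.t_final - t)


def _compute_dt(op: SemiDiscreteOperator, t: float, settings: SolverSettings,
                remaining: float, exclude_local: float = 0.0) -> float:
    speed, diffr, local = op.rate_bounds(t)
    local = max(local - exclude_local, 0.0)
    dx = op.grid.dx
    bounds = [dx / speed if speed > 0 else _BIG]
    if op.model.diffusion_enabled and diffr > 0:
        bounds.append(2.0 * op.model.omega * dx * dx / diffr)
    if local > 0:
        bounds.append(1.0 / local)
    dt = settings.cfl_safety * min(bounds)
    return min(dt, remaining) if remaining > 0 else remaining


def _step(op: SemiDiscreteOperator, u: np.ndarray, t: float, dt: float, method: str) -> np.ndarray:
    if method == "euler":
        return u + dt * op.rhs(u, t)
    if method == "rk2":  # SSP-RK2 (Heun)
        u1 = u + dt * op.rhs(u, t)
        return 0.5 * u + 0.5 * (u1 + dt * op.rhs(u1, t + dt))
    u1 = u + dt * op.rhs(u, t)
    u2 = 0.75 * u + 0.25 * (u1 + dt * op.rhs(u1, t + dt))
    return u / 3.0 + (2.0 / 3.0) * (u2 + dt * op.rhs(u2, t + 0.5 * dt))


class _SinkSplitter:
    """Exact exponential treatment of transitions into absorbing states.

    Only applicable to autonomous, non-negative sink rates; the removed mass
    is credited to the absorbing state in place.
    """

    def __init__(self, op: SemiDiscreteOperator):
        self.entries = []  # (from_idx, to_idx, g array)
        kept = []
        rate_max = 0.0
        for term in op.transition_terms:
            if term.to_absorbing and term.autonomous and np.all(term.g_full >= 0):
                self.entries.append((term.from_idx, term.to_idx, term.g_full))
                rate_max = max(rate_max, float(term.g_full.max()))
            else:
                kept.append(term)
        op.transition_terms = kept
        op._rate_bounds_cache = None
        self.rate_max = rate_max

    def apply(self, u: np.ndarray, dt: float) -> None:
        for fi, ti, g in self.entries:
            factor = np.exp(-g * dt)
            removed = u[fi] * (1.0 - factor)
            u[fi] *= factor
            u[ti] += removed

    def influx(self, u: np.ndarray) -> dict[int, float]:
        return {ti: float((g * u[fi]).sum()) for fi, ti, g in self.entries}


def integrate(model: ACMEModel, p0: GridDensity, settings: SolverSettings) -> Trajectory:
    """Advance the semi-discrete system to ``t_final``.

    Snapshots are taken exactly at the requested times by clipping the step
    size (no interpolation).  Per-record-step observables: time, per-state
    masses, and the instantaneous influx into each absorbing state.
    """
    op = SemiDiscreteOperator(model, p0.grid, settings.limiter)
    splitter = _SinkSplitter(op) if settings.split_local_sinks else None
    u = p0.values.copy()
    t = 0.0
    vol = p0.grid.cell_volume
    labels = p0.labels
    absorbing = [lbl for lbl, s in zip(labels, model.states) if s.is_absorbing]

    snap_times = sorted(set(float(s) for s in settings.snapshot_times) | {settings.t_final})
    snap_times = [s for s in snap_times if s >= 0.0]
    snapshots: list[GridDensity] = []
    times: list[float] = []
    rec_t, rec_mass, rec_abs = [], [], []

    def record():
        rec_t.append(t)
        rec_mass.append(u.reshape(len(labels), -1).sum(axis=1) * vol)
        if absorbing:
            flux = op.absorption_influx(u, t)
            if splitter is not None:
                for ti, val in splitter.influx(u).items():
                    flux[labels[ti]] = flux.get(labels[ti], 0.0) + val * vol
            rec_abs.append([flux.get(lbl, 0.0) for lbl in absorbing])

    if snap_times and snap_times[0] == 0.0:
        snapshots.append(GridDensity(p0.grid, labels, u.copy()))
        times.append(0.0)
        snap_times = snap_times[1:]
    record()

    steps = 0
    next_snap = snap_times.pop(0) if snap_times else None
    while t < settings.t_final - 1e-14 and steps < settings.max_steps:
        remaining = (next_snap if next_snap is not None else settings.t_final) - t
        dt = _compute_dt(op, t, settings, remaining,
                         exclude_local=splitter.rate_max if splitter else 0.0)
        if dt <= 0:
            break
        u = _step(op, u, t, dt, settings.method)
        if splitter is not None:
            splitter.apply(u, dt)
        t += dt
        steps += 1
        if steps % settings.record_every == 0:
            record()
        if settings.progress_every and steps % settings.progress_every == 0:
            masses = u.reshape(len(labels), -1).sum(axis=1) * vol
            log.info("step %d t=%.6g dt=%.3g masses=%s", steps, t, dt,
                     np.array2string(masses, precision=6))
        if steps % 200 == 0 and not np.all(np.isfinite(u)):
            bad = np.argwhere(~np.isfinite(u))[0]
            raise FloatingPointError(
                f"non-finite density at t={t:.6g}, state {labels[bad[0]]}, cell {tuple(bad[1:])}")
        if next_snap is not None and abs(t - next_snap) < 1e-12 * max(1.0, next_snap):
            snapshots.append(GridDensity(p0.grid, labels, u.copy()))
            times.append(next_snap)
            next_snap = snap_times.pop(0) if snap_times else None

    if not np.all(np.isfinite(u)):
        bad = np.argwhere(~np.isfinite(u))[0]
        raise FloatingPointError(
            f"non-finite density at t={t:.6g}, state {labels[bad[0]]}, cell {tuple(bad[1:])}")
    if steps % settings.record_every != 0:
        record()
    if not times or abs(times[-1] - t) > 1e-12 * max(1.0, t):
        snapshots.append(GridDensity(p0.grid, labels, u.copy()))
        times.append(t)

    records = {"t": np.asarray(rec_t), "mass": np.asarray(rec_mass)}
    if absorbing:
        records["absorption"] = np.asarray(rec_abs)
    return Trajectory(model=model, grid=p0.grid, times=times, snapshots=snapshots,
                      records=records, absorbing_labels=tuple(absorbing), n_steps=steps)


def steady_state(model: ACMEModel, p0: GridDensity, settings: SolverSettings | None = None,
                 method: str = "auto") -> SteadyStateResult:
    """Stationary density of the semi-discrete system.

    ``direct`` solves the null space of the assembled linear operator (the
    advection slopes are then unlimited central differences); ``integrate``
    marches in time until ``‖dp/dt‖₁/‖p‖₁ < steady_tol``; ``auto`` picks
    ``direct`` for autonomous models.  Non-convergence is flagged on the
    result, not raised.
    """
    settings = settings or SolverSettings(t_final=100.0)
    op = SemiDiscreteOperator(model, p0.grid, settings.limiter)
    autonomous = all(term.autonomous for term in
                     op.reaction_terms + op.jump_terms + op.transition_terms)
    if method == "auto":
        method = "direct" if autonomous else "integrate"

    if method == "direct":
        if not autonomous:
            raise ValueError("direct steady state requires an autonomous model")
        A = rhs_matrix(model, p0.grid)
        n = A.shape[0]
        M = A.tolil()
        M[0, :] = 1.0
        b = np.zeros(n)
        b[0] = 1.0
        v = spla.spsolve(M.tocsc(), b)
        total = v.sum() * p0.grid.cell_volume
        if not np.isfinite(total) or abs(total) < 1e-300:
            return SteadyStateResult(p0.copy(), False, np.inf, "direct")
        v = v / total
        resid = float(np.abs(A @ v).sum() / max(np.abs(v).sum(), 1e-300))
        dens = GridDensity(p0.grid, p0.labels, v.reshape((len(p0.labels),) + p0.grid.shape))
        return SteadyStateResult(dens, resid < max(settings.steady_tol, 1e-6), resid, "direct")

    u = p0.values.copy()
    t = 0.0
    steps = 0
    resid = np.inf
    while steps < settings.max_steps and t < settings.t_final:
        dt = _compute_dt(op, t, settings, settings.t_final - t)
        if dt <= 0:
            break
        u = _step(op, u, t, dt, settings.method)
        t += dt
        steps += 1
        if steps % 25 == 0 or t >= settings.t_final:
            r = op.rhs(u, t)
            resid = float(np.abs(r).sum() / max(np.abs(u).sum(), 1e-300))
            if resid < settings.steady_tol:
                break
    dens = GridDensity(p0.grid, p0.labels, u)
    return SteadyStateResult(dens, resid < settings.steady_tol, resid, "integrate", t_elapsed=t)
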