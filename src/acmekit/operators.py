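"""Semi-discrete spatial operators.

Every continuum reaction advects (and, at finite Ω, diffuses) density along a
single integer direction ``e``, so on a uniform grid each operator acts along
one-dimensional *rays* of cells at index offset ``e``.  Advection uses a
second-order Kurganov–Tadmor central flux with limited slopes and zero flux at
ray ends; diffusion is the conservative second difference of ``r*p``; jump
processes become per-ray kernel matrices; discrete-state transitions exchange
density cell-by-cell.  All pieces telescope, so probability-mode models
conserve total mass to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grids import Grid, GridDensity
from .model import ACMEModel, JumpProcess, Reaction, validate_model

__all__ = [
    "DirectionalStencil",
    "JumpOperatorMatrix",
    "SemiDiscreteOperator",
    "advection_rhs",
    "diffusion_rhs",
    "build_jump_operator",
    "transitions_rhs",
    "assemble_rhs",
    "rhs_matrix",
    "save_operator_coo",
]


# ---------------------------------------------------------------------------
# rays

@dataclass(frozen=True)
class DirectionalStencil:
    """Partition of the grid into rays aligned with an integer direction.

    ``groups`` holds, per distinct ray length L, a flat-index array of shape
    (n_rays, L); consecutive entries along axis 1 differ by ``e`` in index
    space.  Every cell belongs to exactly one ray.
    """

    direction: tuple[int, ...]
    shape: tuple[int, ...]
    groups: tuple[np.ndarray, ...]

    @property
    def norm(self) -> float:
        return math.sqrt(sum(c * c for c in self.direction))


def build_stencil(grid: Grid, e: Sequence[int]) -> DirectionalStencil:
    e = tuple(int(c) for c in e)
    shape = grid.shape
    if len(e) != len(shape) or not any(e):
        raise ValueError(f"direction {e} incompatible with grid shape {shape}")
    idx = np.indices(shape).reshape(len(shape), -1)
    steps = np.full(idx.shape[1], np.iinfo(np.int64).max, dtype=np.int64)
    pred_ok = np.ones(idx.shape[1], dtype=bool)
    for a, ea in enumerate(e):
        if ea > 0:
            steps = np.minimum(steps, (shape[a] - 1 - idx[a]) // ea)
            pred_ok &= idx[a] - ea >= 0
        elif ea < 0:
            steps = np.minimum(steps, idx[a] // (-ea))
            pred_ok &= idx[a] - ea <= shape[a] - 1
    starts = np.flatnonzero(~pred_ok)
    strides = np.ones(len(shape), dtype=np.int64)
    for a in range(len(shape) - 2, -1, -1):
        strides[a] = strides[a + 1] * shape[a + 1]
    flat_step = int(sum(ea * s for ea, s in zip(e, strides)))
    lengths = steps[starts] + 1
    groups = []
    for L in np.unique(lengths):
        st = starts[lengths == L]
        groups.append(st[:, None] + np.arange(L)[None, :] * flat_step)
    return DirectionalStencil(direction=e, shape=shape, groups=tuple(groups))


# ---------------------------------------------------------------------------
# limiters and the 1-D KT kernel

def _minmod(a, b):
    return np.where(a * b > 0, np.sign(a) * np.minimum(np.abs(a), np.abs(b)), 0.0)


def _vanleer(a, b):
    ab = a * b
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ab > 0, 2.0 * ab / np.where(a + b != 0, a + b, 1.0), 0.0)


def _slopes(P: np.ndarray, limiter: str) -> np.ndarray:
    s = np.zeros_like(P)
    if P.shape[1] >= 3:
        d = np.diff(P, axis=1)
        if limiter == "minmod":
            s[:, 1:-1] = _minmod(d[:, :-1], d[:, 1:])
        elif limiter == "vanleer":
            s[:, 1:-1] = _vanleer(d[:, :-1], d[:, 1:])
        elif limiter == "none":  # unlimited central slopes (linear scheme)
            s[:, 1:-1] = 0.5 * (P[:, 2:] - P[:, :-2])
        else:
            raise ValueError(f"unknown limiter {limiter!r}")
    return s


def _kt_tendency(P: np.ndarray, v: np.ndarray, dx: float, limiter: str) -> np.ndarray:
    """Second-order central-scheme tendency for stacked rays.

    P: (R, L) cell averages; v: (R, L-1) interface velocities; no-flux ends.
    """
    s = _slopes(P, limiter)
    pL = P[:, :-1] + 0.5 * s[:, :-1]
    pR = P[:, 1:] - 0.5 * s[:, 1:]
    F = 0.5 * (v * (pL + pR) - np.abs(v) * (pR - pL))
    T = np.zeros_like(P)
    T[:, :-1] -= F
    T[:, 1:] += F
    T /= dx
    return T


def kt_tendency_periodic(p: np.ndarray, v: np.ndarray, dx: float, limiter: str = "minmod") -> np.ndarray:
    """Periodic single-ray variant (test harness for smooth-advection accuracy).

    ``v`` holds the velocity at the right interface of each cell.
    """
    d = p - np.roll(p, 1)  # d[j] = p[j] - p[j-1]
    a, b = d, np.roll(d, -1)
    if limiter == "minmod":
        s = _minmod(a, b)
    elif limiter == "vanleer":
        s = _vanleer(a, b)
    else:
        s = 0.5 * (np.roll(p, -1) - np.roll(p, 1))
    pL = p + 0.5 * s
    pR = np.roll(p, -1) - 0.5 * np.roll(s, -1)
    F = 0.5 * (v * (pL + pR) - np.abs(v) * (pR - pL))
    return -(F - np.roll(F, 1)) / dx


def _diffusion_tendency(W: np.ndarray) -> np.ndarray:
    """Conservative second difference along stacked rays, zero-flux ends.

    Returns the unscaled ``d2``; caller multiplies by 1/(2*omega*dx^2).
    """
    G = np.diff(W, axis=1)
    T = np.zeros_like(W)
    T[:, :-1] += G
    T[:, 1:] -= G
    return T


# ---------------------------------------------------------------------------
# jump operators

@dataclass
class JumpOperatorMatrix:
    """Per-ray kernel matrices for a jump process.

    ``mats[g]`` is either a shared (L, L) matrix for all rays of group ``g`` or
    a per-ray (R, L, L) stack; entry [m, s] is the fraction of an event at ray
    position s that lands in position m.  Probability mode: columns sum to 1
    after boundary-truncation renormalisation.  Fragmentation mode: columns
    conserve the source coordinate (first moment) exactly and sum to ~2.
    """

    stencil: DirectionalStencil
    mats: list[np.ndarray]
    shared: list[bool]
    mode: str

    def gain(self, fp_groups: list[np.ndarray]) -> list[np.ndarray]:
        out = []
        for W, is_shared, FP in zip(self.mats, self.shared, fp_groups):
            if is_shared:
                out.append(FP @ W.T)
            else:
                out.append(np.einsum("rms,rs->rm", W, FP))
        return out


def _axis_of(e: Sequence[int]) -> int | None:
    nz = [a for a, c in enumerate(e) if c]
    return nz[0] if len(nz) == 1 else None


def build_jump_operator(jump: JumpProcess, grid: Grid, stencil: DirectionalStencil | None = None,
                        t: float = 0.0) -> JumpOperatorMatrix:
    """Discretise the jump kernel into per-ray gain matrices.

    The kernel is integrated over destination-cell arc intervals (exactly when
    the kernel provides closed-form cell masses, by midpoint quadrature
    otherwise) and then normalised according to the multiplicity mode.
    """
    stencil = stencil or build_stencil(grid, jump.direction)
    e = stencil.direction
    h = grid.dx * stencil.norm
    axis = _axis_of(e)
    frag = jump.multiplicity_mode == "fragmentation"
    if frag and axis is None:
        raise ValueError("fragmentation kernels require an axis-aligned jump direction")

    kind = getattr(jump.kernel, "kind", "custom")
    if frag:
        source_dep = True
    elif kind == "exponential":
        source_dep = False
    else:
        source_dep = "x" in getattr(jump.kernel, "expr", "x")

    mats: list[np.ndarray] = []
    shared: list[bool] = []
    for idx in stencil.groups:
        R, L = idx.shape
        off = np.arange(L)[:, None] - np.arange(L)[None, :]  # m - s
        tri = off >= 0
        u_lo = np.where(tri, np.maximum(off * h - 0.5 * h, 0.0), 0.0)
        u_hi = np.where(tri, off * h + 0.5 * h, 0.0)
        if axis is not None:
            mi = np.unravel_index(idx, grid.shape)
            coord = (mi[axis] + 0.5) * grid.dx  # (R, L) coordinate along the jump axis
        else:
            coord = np.zeros((R, L))
        if not source_dep:
            W = np.where(tri, jump.kernel.cell_mass(u_lo, u_hi, 0.0, t), 0.0)
            if np.any(W < -1e-15):
                raise ValueError(f"jump kernel {jump.name!r} is negative on its support")
            W = _normalise_columns(W[None, ...], None, jump, grid, coord[None, 0] if R else None)[0]
            mats.append(W)
            shared.append(True)
        else:
            src = coord[:, None, :]  # (R, 1, L) source coordinate per column
            W = np.where(tri[None, ...], jump.kernel.cell_mass(u_lo[None, ...], u_hi[None, ...], src, t), 0.0)
            if np.any(W < 0):
                raise ValueError(f"jump kernel {jump.name!r} is negative on its support")
            dest = coord[:, :, None] if frag else None
            W = _normalise_columns(W, dest, jump, grid, coord)
            mats.append(W)
            shared.append(False)
    return JumpOperatorMatrix(stencil=stencil, mats=mats, shared=shared, mode=jump.multiplicity_mode)


def _normalise_columns(W: np.ndarray, dest_coord, jump: JumpProcess, grid: Grid, src_coord) -> np.ndarray:
    """Enforce the multiplicity-mode column invariants on a (R, L, L) stack."""
    if jump.multiplicity_mode == "probability":
        # Kernel mass that would land beyond the ray end is parked in the last
        # cell (it re-enters the bulk by drift, mimicking the recirculation of
        # the untruncated process); columns are then normalised to sum to one
        # exactly.
        col = W.sum(axis=1, keepdims=True)
        W = W.copy()
        W[:, -1, :] += np.clip(1.0 - col, 0.0, None)[:, 0, :]
        col = W.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(col > 1e-300, W / col, 0.0)
        return W
    # fragmentation: scale columns so the destination first moment equals the
    # source coordinate exactly (volume conservation); the number sum stays ~2.
    moment = (dest_coord * W).sum(axis=1, keepdims=True)
    src = src_coord[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(moment > 1e-300, src / moment, 0.0)
    return W * scale


# ---------------------------------------------------------------------------
# compiled operator

class _ReactionTerm:
    __slots__ = ("state_idx", "stencil", "rate", "v_groups", "c_groups", "autonomous", "name")


class _JumpTerm:
    __slots__ = ("state_idx", "op", "rate", "f_full", "f_groups", "autonomous", "name")


class _TransitionTerm:
    __slots__ = ("from_idx", "to_idx", "rate", "g_full", "autonomous", "to_absorbing")


class SemiDiscreteOperator:
    """Compiled right-hand side of the semi-discrete system for one model/grid.

    Rates of autonomous models are evaluated once at construction; the per-call
    cost is then a handful of vectorised array operations per term, linear in
    the density.
    """

    def __init__(self, model: ACMEModel, grid: Grid | None = None, limiter: str = "minmod"):
        errors = [d for d in validate_model(model) if d.severity == "error"]
        if errors:
            raise ValueError("model is not well-posed: " + "; ".join(map(str, errors)))
        self.model = model
        self.grid = grid or Grid.from_species(model.species)
        self.limiter = limiter
        self.labels = tuple(model.state_labels)
        self.K = len(self.labels)
        self.shape = self.grid.shape
        self.N = self.grid.n_cells
        self.dx = self.grid.dx
        self.coords = self.grid.coords()
        self.absorbing = np.array([s.is_absorbing for s in model.states], dtype=bool)
        self._stencils: dict[tuple[int, ...], DirectionalStencil] = {}
        self._iface_coords: dict[tuple[int, ...], list[tuple]] = {}

        self.reaction_terms: list[_ReactionTerm] = []
        self.jump_terms: list[_JumpTerm] = []
        self.transition_terms: list[_TransitionTerm] = []
        self._jump_ops: dict[int, JumpOperatorMatrix] = {}
        self._build_terms()
        self._rate_bounds_cache: tuple | None = None

    # -- construction -----------------------------------------------------

    def _stencil(self, e: tuple[int, ...]) -> DirectionalStencil:
        if e not in self._stencils:
            self._stencils[e] = build_stencil(self.grid, e)
        return self._stencils[e]

    def _interface_coords(self, e: tuple[int, ...]):
        """Coordinates of the interfaces between consecutive ray cells."""
        if e not in self._iface_coords:
            st = self._stencil(e)
            out = []
            for idx in st.groups:
                mi = np.unravel_index(idx[:, :-1], self.shape)
                out.append(tuple((mi[a] + 0.5) * self.dx + 0.5 * e[a] * self.dx
                                 for a in range(len(self.shape))))
            self._iface_coords[e] = out
        return self._iface_coords[e]

    def _gather(self, full: np.ndarray, st: DirectionalStencil) -> list[np.ndarray]:
        flat = full.reshape(-1)
        return [flat[idx] for idx in st.groups]

    def _build_terms(self) -> None:
        for rx in self.model.reactions:
            e = tuple(rx.displacement)
            st = self._stencil(e)
            for k, lbl in enumerate(self.labels):
                if self.absorbing[k]:
                    continue
                rf = rx.rate_for(lbl)
                if rf is None:
                    continue
                term = _ReactionTerm()
                term.state_idx, term.stencil, term.rate, term.name = k, st, rf, rx.name or f"e={e}"
                term.autonomous = not rf.time_dependent
                if term.autonomous:
                    term.v_groups = [self._check(rf(c, 0.0), term.name) for c in self._interface_coords(e)]
                    full = self._check(rf(self.coords, 0.0), term.name)
                    term.c_groups = self._gather(np.broadcast_to(full, self.shape), st) \
                        if self.model.diffusion_enabled else None
                else:
                    term.v_groups = term.c_groups = None
                self.reaction_terms.append(term)

        for j, jp in enumerate(self.model.jumps):
            e = tuple(jp.direction)
            st = self._stencil(e)
            if j not in self._jump_ops:
                self._jump_ops[j] = build_jump_operator(jp, self.grid, st)
            op = self._jump_ops[j]
            for k, lbl in enumerate(self.labels):
                if self.absorbing[k]:
                    continue
                rf = jp.rate_for(lbl)
                if rf is None:
                    continue
                term = _JumpTerm()
                term.state_idx, term.op, term.rate, term.name = k, op, rf, jp.name or f"jump{j}"
                term.autonomous = not rf.time_dependent
                if term.autonomous:
                    full = np.broadcast_to(self._check(rf(self.coords, 0.0), term.name), self.shape)
                    term.f_full = full
                    term.f_groups = self._gather(full, st)
                else:
                    term.f_full = term.f_groups = None
                self.jump_terms.append(term)

        for tr in self.model.transitions:
            fi = self.labels.index(tr.from_state)
            if self.absorbing[fi]:
                continue  # absorbing states have no outgoing terms
            term = _TransitionTerm()
            term.from_idx = fi
            term.to_idx = self.labels.index(tr.to_state)
            term.rate = tr.rate
            term.autonomous = not tr.rate.time_dependent
            term.to_absorbing = bool(self.absorbing[term.to_idx])
            term.g_full = np.broadcast_to(
                self._check(tr.rate(self.coords, 0.0), f"{tr.from_state}->{tr.to_state}"), self.shape
            ) if term.autonomous else None
            self.transition_terms.append(term)

    @staticmethod
    def _check(vals, name: str) -> np.ndarray:
        vals = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"rate for {name!r} evaluated to a non-finite value")
        return vals

    # -- evaluation --------------------------------------------------------

    def rhs(self, values: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Tendency dp/dt for stacked state arrays of shape (K, *grid.shape)."""
        out = np.zeros_like(values)
        flat_v = values.reshape(self.K, -1)
        flat_o = out.reshape(self.K, -1)

        for term in self.reaction_terms:
            st = term.stencil
            vgs = term.v_groups if term.autonomous else \
                [self._check(term.rate(c, t), term.name) for c in self._interface_coords(st.direction)]
            pf = flat_v[term.state_idx]
            of = flat_o[term.state_idx]
            for idx, v in zip(st.groups, vgs):
                of[idx] += _kt_tendency(pf[idx], v, self.dx, self.limiter)
            if self.model.diffusion_enabled:
                cgs = term.c_groups if term.autonomous else \
                    self._gather(np.broadcast_to(self._check(term.rate(self.coords, t), term.name),
                                                 self.shape), st)
                scale = 1.0 / (2.0 * self.model.omega * self.dx ** 2)
                for idx, C in zip(st.groups, cgs):
                    of[idx] += scale * _diffusion_tendency(C * pf[idx])

        for term in self.jump_terms:
            st = term.op.stencil
            if term.autonomous:
                f_full, f_groups = term.f_full, term.f_groups
            else:
                f_full = np.broadcast_to(self._check(term.rate(self.coords, t), term.name), self.shape)
                f_groups = self._gather(f_full, st)
            pf = flat_v[term.state_idx]
            of = flat_o[term.state_idx]
            fp_groups = [fg * pf[idx] for idx, fg in zip(st.groups, f_groups)]
            gains = term.op.gain(fp_groups)
            for idx, g in zip(st.groups, gains):
                of[idx] += g
            out[term.state_idx] -= f_full * values[term.state_idx]

        for term in self.transition_terms:
            g = term.g_full if term.autonomous else \
                np.broadcast_to(self._check(term.rate(self.coords, t), "transition"), self.shape)
            flow = g * values[term.from_idx]
            out[term.from_idx] -= flow
            out[term.to_idx] += flow
        return out

    def rhs_density(self, p: GridDensity, t: float = 0.0) -> GridDensity:
        return GridDensity(p.grid, p.labels, self.rhs(p.values, t))

    def absorption_influx(self, values: np.ndarray, t: float = 0.0) -> dict[str, float]:
        """Instantaneous probability flux into each absorbing state."""
        out: dict[str, float] = {lbl: 0.0 for lbl, a in zip(self.labels, self.absorbing) if a}
        vol = self.grid.cell_volume
        for term in self.transition_terms:
            if term.to_absorbing:
                g = term.g_full if term.autonomous else term.rate(self.coords, t)
                out[self.labels[term.to_idx]] += float((g * values[term.from_idx]).sum() * vol)
        return out

    def rate_bounds(self, t: float = 0.0) -> tuple[float, float, float]:
        """(max total advection speed, max total diffusion rate, max local outflow rate)."""
        if self._rate_bounds_cache is not None and all(
            term.autonomous for term in self.reaction_terms + self.jump_terms + self.transition_terms
        ):
            return self._rate_bounds_cache
        speed = np.zeros((self.K,) + self.shape)
        diffr = np.zeros((self.K,) + self.shape)
        local = np.zeros((self.K,) + self.shape)
        for term in self.reaction_terms:
            r = np.abs(np.broadcast_to(
                term.rate(self.coords, t) if not term.autonomous else term.rate(self.coords, 0.0),
                self.shape))
            speed[term.state_idx] += r
            if self.model.diffusion_enabled:
                diffr[term.state_idx] += r * sum(c * c for c in term.stencil.direction)
        for term in self.jump_terms:
            f = np.broadcast_to(term.f_full if term.autonomous else term.rate(self.coords, t), self.shape)
            local[term.state_idx] += np.abs(f)
        for term in self.transition_terms:
            g = np.broadcast_to(term.g_full if term.autonomous else term.rate(self.coords, t), self.shape)
            local[term.from_idx] += np.abs(g)
        bounds = (float(speed.max()), float(diffr.max()), float(local.max()))
        self._rate_bounds_cache = bounds
        return bounds


# ---------------------------------------------------------------------------
# functional wrappers (single-term tendencies and full assembly)

def _compiled(model: ACMEModel, grid: Grid | None, limiter: str) -> SemiDiscreteOperator:
    cache = getattr(model, "_compiled_ops", None)
    if cache is None:
        cache = model._compiled_ops = {}
    key = (grid.shape if grid is not None else None,
           grid.dx if grid is not None else None, limiter)
    if key not in cache:
        cache[key] = SemiDiscreteOperator(model, grid, limiter)
    return cache[key]


def assemble_rhs(model: ACMEModel, p: GridDensity, t: float = 0.0, limiter: str = "minmod") -> GridDensity:
    """Full semi-discrete tendency: reactions + jumps + transitions."""
    op = _compiled(model, p.grid, limiter)
    return op.rhs_density(p, t)


def advection_rhs(p: GridDensity, reaction: Reaction, stencil: DirectionalStencil | None = None,
                  t: float = 0.0, limiter: str = "minmod") -> GridDensity:
    """Tendency of the drift term ``-e^T grad(r p)`` for one reaction."""
    grid = p.grid
    e = tuple(reaction.displacement)
    st = stencil or build_stencil(grid, e)
    out = GridDensity.zeros(grid, p.labels)
    for k, lbl in enumerate(p.labels):
        rf = reaction.rate_for(lbl)
        if rf is None:
            continue
        pf = p.values[k].reshape(-1)
        of = out.values[k].reshape(-1)
        for idx in st.groups:
            mi = np.unravel_index(idx[:, :-1], grid.shape)
            iface = tuple((mi[a] + 0.5) * grid.dx + 0.5 * e[a] * grid.dx for a in range(grid.d))
            v = np.asarray(rf(iface, t), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"rate of reaction {reaction.name!r} is non-finite")
            v = np.broadcast_to(v, idx[:, :-1].shape)
            of[idx] += _kt_tendency(pf[idx], v, grid.dx, limiter)
    return out


def diffusion_rhs(p: GridDensity, reaction: Reaction, omega: float,
                  stencil: DirectionalStencil | None = None, t: float = 0.0) -> GridDensity:
    """Tendency of the finite-size diffusion term ``(1/2Ω) e^T H(r p) e``."""
    grid = p.grid
    e = tuple(reaction.displacement)
    st = stencil or build_stencil(grid, e)
    out = GridDensity.zeros(grid, p.labels)
    coords = grid.coords()
    scale = 1.0 / (2.0 * omega * grid.dx ** 2)
    for k, lbl in enumerate(p.labels):
        rf = reaction.rate_for(lbl)
        if rf is None:
            continue
        r = np.broadcast_to(np.asarray(rf(coords, t), dtype=float), grid.shape).reshape(-1)
        pf = p.values[k].reshape(-1)
        of = out.values[k].reshape(-1)
        for idx in st.groups:
            of[idx] += scale * _diffusion_tendency(r[idx] * pf[idx])
    return out


def transitions_rhs(p: GridDensity, transitions, states=None, t: float = 0.0) -> GridDensity:
    """Pointwise discrete-state exchange; cell-by-cell mass neutral."""
    grid = p.grid
    out = GridDensity.zeros(grid, p.labels)
    coords = grid.coords()
    absorbing = {s.label for s in states or [] if s.is_absorbing}
    for tr in transitions:
        if tr.from_state in absorbing:
            continue
        g = np.broadcast_to(np.asarray(tr.rate(coords, t), dtype=float), grid.shape)
        flow = g * p.state(tr.from_state)
        out.values[p.index(tr.from_state)] -= flow
        out.values[p.index(tr.to_state)] += flow
    return out


# ---------------------------------------------------------------------------
# linear assembly (steady states, oracles, debugging export)

def rhs_matrix(model: ACMEModel, grid: Grid | None = None, t: float = 0.0) -> sp.csr_matrix:
    """Sparse matrix of the semi-discrete operator with *unlimited* central
    slopes (the linear variant of the advection scheme), ordered state-major.

    Used for direct steady-state solves and operator export; the limited
    scheme is nonlinear and cannot be represented as a matrix.
    """
    op = SemiDiscreteOperator(model, grid, limiter="none")
    n = op.K * op.N
    basis = np.zeros((op.K,) + op.shape)
    flat = basis.reshape(-1)
    cols = []
    for i in range(n):
        flat[i] = 1.0
        col = op.rhs(basis, t).reshape(-1)
        nz = np.flatnonzero(col)
        cols.append((nz, col[nz]))
        flat[i] = 0.0
    indptr = np.cumsum([0] + [len(nz) for nz, _ in cols])
    indices = np.concatenate([nz for nz, _ in cols]) if cols else np.array([], int)
    data = np.concatenate([v for _, v in cols]) if cols else np.array([])
    return sp.csc_matrix((data, indices, indptr), shape=(n, n)).tocsr()


def save_operator_coo(mat: sp.spmatrix, path) -> None:
    """Export a sparse operator as coordinate-format text (row, col, value)."""
    coo = mat.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(path, index=False)
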