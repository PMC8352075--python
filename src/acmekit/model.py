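"""Declarative model layer for augmented master-equation systems.

An :class:`ACMEModel` couples three kinds of dynamics on a family of densities
``p_k(x, t)`` indexed by discrete states ``k``:

* local continuum reactions — drift ``-e_i^T ∇[r_ik p_k]`` plus, at finite
  system size Ω, diffusion ``(1/2Ω) e_i^T H(r_ik p_k) e_i`` along the
  stoichiometric displacement ``e_i``;
* non-local jump processes — loss at rate ``f_jk`` balanced by a gain
  redistributed along ``e_j`` by a kernel (burst production, fragmentation);
* discrete-state transitions at rates ``g_kl(x, t)``, which may be *negative*
  when the model opts in, turning the target into a "phantom" state that
  carries population bookkeeping rather than probability.

The continuum coordinate is the scaled copy number ``x = X/Ω``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._expr import RateFunction, as_rate, hill_rate, rate_expression_compile

__all__ = [
    "ContinuumSpecies",
    "DiscreteState",
    "Reaction",
    "JumpProcess",
    "JumpKernel",
    "ExponentialKernel",
    "UniformFragmentationKernel",
    "CustomKernel",
    "DiscreteTransition",
    "ACMEModel",
    "Diagnostic",
    "validate_model",
    "hill_rate",
    "rate_expression_compile",
    "PRESETS",
]

#: Named parameter presets.  ``lin-doering`` is the self-regulated gene
#: expression benchmark set: Hill basal/max rates r0, r1, exponent n, mean
#: burst size B (molecules), protein decay gamma0, system size omega.
PRESETS: dict[str, dict[str, float]] = {
    "lin-doering": {"r0": 2.0, "r1": 10.0, "n": 4.0, "B": 40.0, "gamma0": 1.0, "omega": 200.0},
}


@dataclass(frozen=True)
class ContinuumSpecies:
    """A continuum species with truncated domain ``[0, domain_max]``."""

    name: str
    domain_max: float
    n_cells: int

    @property
    def dx(self) -> float:
        return self.domain_max / self.n_cells


@dataclass(frozen=True)
class DiscreteState:
    """A discrete model state.

    ``is_phantom`` marks states reached at negative rates (no probability
    interpretation); ``is_absorbing`` states receive transition gains but have
    no outgoing terms evaluated.
    """

    label: str
    is_phantom: bool = False
    is_absorbing: bool = False


RateSpec = RateFunction | Callable | str | float | Mapping[str, "RateFunction | Callable | str | float"]


def _normalise_rate_spec(rate: RateSpec, symbols: Sequence[str], parameters=None):
    """Return either a single RateFunction (all states) or dict label->RateFunction."""
    if isinstance(rate, Mapping):
        return {label: as_rate(r, symbols, parameters) for label, r in rate.items()}
    return as_rate(rate, symbols, parameters)


@dataclass(frozen=True)
class Reaction:
    """A local reaction advecting (and, with diffusion, spreading) density along ``displacement``."""

    displacement: tuple[int, ...]
    rate: RateFunction | dict[str, RateFunction]
    name: str = ""

    def rate_for(self, label: str) -> RateFunction | None:
        if isinstance(self.rate, dict):
            return self.rate.get(label)
        return self.rate


class JumpKernel:
    """Base class for jump-size kernels.

    A kernel is a density per unit arc length ``u >= 0`` along the jump
    direction, possibly conditioned on the source coordinate (fragmentation).
    Subclasses may provide exact cell integrals via :meth:`cell_mass`.
    """

    #: kind tag used by config round-tripping
    kind = "custom"

    def density(self, u, source, t=0.0):  # pragma: no cover - abstract
        raise NotImplementedError

    def cell_mass(self, u_lo, u_hi, source, t=0.0):
        """Kernel mass on ``[u_lo, u_hi]``; default midpoint quadrature."""
        u_lo = np.maximum(u_lo, 0.0)
        mid = 0.5 * (u_lo + u_hi)
        return self.density(mid, source, t) * np.maximum(u_hi - u_lo, 0.0)

    def support_max(self, source) -> float:
        """Upper end of the kernel support in arc length (inf if unbounded)."""
        return math.inf

    def params(self) -> dict:
        return {}


@dataclass(frozen=True)
class ExponentialKernel(JumpKernel):
    """Forward-exponential jump sizes with mean ``b`` (burst production)."""

    mean: float

    kind = "exponential"

    def density(self, u, source, t=0.0):
        u = np.asarray(u, dtype=float)
        return np.where(u >= 0, np.exp(-u / self.mean) / self.mean, 0.0)

    def cell_mass(self, u_lo, u_hi, source, t=0.0):
        u_lo = np.maximum(np.asarray(u_lo, dtype=float), 0.0)
        u_hi = np.maximum(np.asarray(u_hi, dtype=float), 0.0)
        return np.exp(-u_lo / self.mean) - np.exp(-u_hi / self.mean)

    def params(self) -> dict:
        return {"mean": self.mean}


@dataclass(frozen=True)
class UniformFragmentationKernel(JumpKernel):
    """Binary fragmentation with a uniform offspring-size distribution.

    For a source of size ``y`` the gain density over offspring sizes is
    ``2/y`` on ``(0, y)``: two fragments per event, uniformly placed, so the
    kernel integrates to two while conserving total volume.
    """

    kind = "uniform_fragmentation"

    def density(self, u, source, t=0.0):
        u = np.asarray(u, dtype=float)
        y = np.asarray(source, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where((u >= 0) & (u <= y) & (y > 0), 2.0 / y, 0.0)
        return d

    def cell_mass(self, u_lo, u_hi, source, t=0.0):
        y = np.asarray(source, dtype=float)
        lo = np.clip(u_lo, 0.0, y)
        hi = np.clip(u_hi, 0.0, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(y > 0, 2.0 * (hi - lo) / y, 0.0)

    def support_max(self, source) -> float:
        return float(source)


@dataclass(frozen=True)
class CustomKernel(JumpKernel):
    """Kernel given by a text expression in the jump size ``z`` (and optionally
    the source coordinate ``x`` and time ``t``)."""

    expr: str
    support: float = math.inf  # upper arc-length cut; inf = unbounded

    kind = "custom_expr"

    def __post_init__(self):
        object.__setattr__(self, "_fn", rate_expression_compile(self.expr, symbols=("z", "x")))

    def density(self, u, source, t=0.0):
        u = np.asarray(u, dtype=float)
        vals = self._fn((u, np.broadcast_to(np.asarray(source, float), u.shape)), t)
        return np.where((u >= 0) & (u <= self.support), vals, 0.0)

    def support_max(self, source) -> float:
        return self.support

    def params(self) -> dict:
        p = {"expr": self.expr}
        if np.isfinite(self.support):
            p["support"] = self.support
        return p


@dataclass(frozen=True)
class JumpProcess:
    """Non-local exchange of density along ``direction`` with a size kernel.

    ``multiplicity_mode`` is ``"probability"`` (kernel columns normalised to
    one: mass conserving, e.g. bursts) or ``"fragmentation"`` (kernel sums to
    two per event while conserving the first moment along the jump axis).
    """

    direction: tuple[int, ...]
    rate: RateFunction | dict[str, RateFunction]
    kernel: JumpKernel
    multiplicity_mode: str = "probability"
    name: str = ""

    def rate_for(self, label: str) -> RateFunction | None:
        if isinstance(self.rate, dict):
            return self.rate.get(label)
        return self.rate


@dataclass(frozen=True)
class DiscreteTransition:
    """Probability flux from ``from_state`` to ``to_state`` at rate ``g(x, t)``.

    The rate may be negative in signed-rate models (phantom-state bookkeeping).
    """

    from_state: str
    to_state: str
    rate: RateFunction


@dataclass
class ACMEModel:
    """Full declarative description of a hybrid discrete/continuum system."""

    species: list[ContinuumSpecies]
    states: list[DiscreteState]
    reactions: list[Reaction] = field(default_factory=list)
    jumps: list[JumpProcess] = field(default_factory=list)
    transitions: list[DiscreteTransition] = field(default_factory=list)
    omega: float | None = None
    diffusion_enabled: bool = False
    allow_signed_rates: bool = False
    parameters: dict[str, float] = field(default_factory=dict)
    name: str = ""

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def state_labels(self) -> list[str]:
        return [s.label for s in self.states]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def state(self, label: str) -> DiscreteState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def compile_rate(self, expr_or_rate, per_state: bool = False) -> RateFunction | dict:
        """Coerce an expression / callable / mapping into rate functions bound
        to this model's coordinate symbols and parameters."""
        return _normalise_rate_spec(expr_or_rate, self.symbols, self.parameters)


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity}[{self.code}]: {self.message}"


class ModelError(ValueError):
    """Raised by strict validation on structural errors."""


def _sample_coords(model: ACMEModel, n: int = 9):
    axes = [np.linspace(sp.dx / 2, sp.domain_max - sp.dx / 2, min(n, sp.n_cells)) for sp in model.species]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _rate_entries(rate) -> list[RateFunction]:
    if isinstance(rate, dict):
        return list(rate.values())
    return [rate]


def validate_model(model: ACMEModel, strict: bool = False) -> list[Diagnostic]:
    """Structural and plausibility checks; empty list means well-posed.

    Errors cover broken references and dimension mismatches; warnings cover
    negative rates without the signed-rate/phantom opt-ins, kernels that will
    be truncated at the domain boundary, and grids coarser than one molecule.
    Pure: repeated calls give identical diagnostics.
    """
    diags: list[Diagnostic] = []
    err = lambda code, msg: diags.append(Diagnostic("error", code, msg))
    warn = lambda code, msg: diags.append(Diagnostic("warning", code, msg))

    d = model.d
    if d == 0:
        err("no-species", "model declares no continuum species")
    dxs = {round(sp.dx, 15) for sp in model.species}
    if len(dxs) > 1:
        err("dx-mismatch", f"cell width must be shared across species, got {sorted(dxs)}")
    for sp in model.species:
        if sp.domain_max <= 0:
            err("domain", f"species {sp.name!r}: domain_max must be positive")
        if sp.n_cells < 4:
            err("n-cells", f"species {sp.name!r}: n_cells must be at least 4")

    labels = model.state_labels
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        err("dup-state", f"duplicate discrete state labels {sorted(dup)}")
    label_set = set(labels)

    if model.diffusion_enabled and not (model.omega and model.omega > 0):
        err("omega", "diffusion_enabled requires a positive system size omega")
    if model.omega and model.species:
        dx = model.species[0].dx
        if dx * model.omega < 1.0:
            warn("dx-omega", f"dx*omega = {dx * model.omega:.3g} < 1: cells are finer than one molecule")

    coords = _sample_coords(model) if d and not diags else None

    def check_sign(rate_like, where: str, allow_negative_ok: bool):
        if coords is None:
            return
        for rf in _rate_entries(rate_like):
            try:
                vals = np.asarray(rf(coords, 0.0), dtype=float)
            except Exception as exc:  # noqa: BLE001 - surfaced as diagnostic
                err("rate-eval", f"{where}: rate evaluation failed: {exc}")
                continue
            if not np.all(np.isfinite(vals)):
                err("rate-finite", f"{where}: rate is non-finite on the domain")
            elif np.any(vals < 0):
                if not model.allow_signed_rates:
                    err("rate-sign", f"{where}: negative rate without allow_signed_rates")
                elif not allow_negative_ok:
                    warn("rate-sign", f"{where}: negative rate outside a phantom-state transition")

    for i, rx in enumerate(model.reactions):
        where = f"reaction[{i}]{'(' + rx.name + ')' if rx.name else ''}"
        if len(rx.displacement) != d:
            err("dim", f"{where}: displacement has length {len(rx.displacement)}, expected {d}")
        elif not any(rx.displacement):
            err("zero-e", f"{where}: displacement must be non-zero")
        if isinstance(rx.rate, dict):
            for lbl in rx.rate:
                if lbl not in label_set:
                    err("state-ref", f"{where}: rate refers to undefined state {lbl!r}")
        check_sign(rx.rate, where, allow_negative_ok=False)

    for j, jp in enumerate(model.jumps):
        where = f"jump[{j}]{'(' + jp.name + ')' if jp.name else ''}"
        if len(jp.direction) != d:
            err("dim", f"{where}: direction has length {len(jp.direction)}, expected {d}")
        elif not any(jp.direction):
            err("zero-e", f"{where}: direction must be non-zero")
        if jp.multiplicity_mode not in ("probability", "fragmentation"):
            err("mode", f"{where}: unknown multiplicity_mode {jp.multiplicity_mode!r}")
        if isinstance(jp.rate, dict):
            for lbl in jp.rate:
                if lbl not in label_set:
                    err("state-ref", f"{where}: rate refers to undefined state {lbl!r}")
        check_sign(jp.rate, where, allow_negative_ok=False)
        if model.species and len(jp.direction) == d and any(jp.direction):
            # will the kernel be truncated at the boundary for typical sources?
            sup = jp.kernel.support_max(model.species[0].domain_max / 2)
            arc = math.sqrt(sum(c * c for c in jp.direction)) * model.species[0].domain_max
            if math.isinf(sup) or sup > arc / 2:
                if jp.multiplicity_mode == "probability":
                    warn("kernel-trunc", f"{where}: kernel support exceeds the domain; "
                         "truncated columns will be renormalised")

    for k, tr in enumerate(model.transitions):
        where = f"transition[{k}]({tr.from_state}->{tr.to_state})"
        if tr.from_state not in label_set:
            err("state-ref", f"{where}: undefined state {tr.from_state!r}")
        if tr.to_state not in label_set:
            err("state-ref", f"{where}: undefined state {tr.to_state!r}")
        if tr.from_state == tr.to_state:
            err("self-loop", f"{where}: from_state equals to_state")
        to_phantom = tr.to_state in label_set and model.state(tr.to_state).is_phantom
        check_sign(tr.rate, where, allow_negative_ok=to_phantom)

    if strict and any(g.severity == "error" for g in diags):
        raise ModelError("; ".join(str(g) for g in diags if g.severity == "error"))
    return diags
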