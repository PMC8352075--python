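"""Prebuilt models for the three benchmark applications.

* self-regulated gene expression, with the mRNA either kept as discrete
  states (finite mRNA turnover rate ``gamma``) or eliminated into exponential
  protein bursts (the fast-mRNA limit);
* the first-passage augmentation of the bursty model: an absorbing discrete
  state entered at rate ``alpha`` once the protein level crosses a critical
  boundary, giving the full switching-time distribution;
* phenotypic selection: a birth-death process with a growth field coupled via
  a phantom state entered at the *negative* of the growth rate;
* growth-fragmentation of a size-structured population.

Also provides the random-model generator used by the conservation and
linearity property suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid, GridDensity, project_density
from .integrate import Trajectory
from .model import (ACMEModel, ContinuumSpecies, DiscreteState, DiscreteTransition,
                    ExponentialKernel, JumpProcess, PRESETS, Reaction,
                    UniformFragmentationKernel)

__all__ = [
    "build_gene_expression_finite_gamma",
    "build_gene_expression_bursty",
    "augment_first_passage",
    "SwitchingTimeSummary",
    "switching_summary",
    "build_selection_model",
    "selection_initial_condition",
    "SelectionGrowthResult",
    "normalise_and_growth_rate",
    "build_fragmentation_model",
    "generate_random_model",
    "uniform_initial",
    "delta_initial",
]

_HILL_EXPR = "r0 + r1*x^n/(1+x^n)"


def _gene_params(params: dict | None) -> dict:
    p = dict(PRESETS["lin-doering"])
    p.update(params or {})
    p["b"] = p.get("b", p["B"] / p["omega"])
    return p


def build_gene_expression_finite_gamma(gamma: float, K: int = 30, params: dict | None = None,
                                       n_cells: int = 80, domain_max: float = 4.0) -> ACMEModel:
    """Protein on the continuum, mRNA count 0..K as discrete states.

    Per mRNA state k the protein drifts at ``k*gamma*b - gamma0*x`` (split
    into a production and a degradation reaction); transcription k -> k+1 at
    the Hill rate H(x) and mRNA decay k -> k-1 at ``gamma*k``.  Noiseless
    continuum limit: diffusion off.
    """
    if K < 1 or gamma <= 0:
        raise ValueError("need K >= 1 and gamma > 0")
    p = _gene_params(params)
    pars = {"r0": p["r0"], "r1": p["r1"], "n": p["n"], "gamma0": p["gamma0"],
            "gamma": gamma, "b": p["b"]}
    m = ACMEModel(
        species=[ContinuumSpecies("x", domain_max, n_cells)],
        states=[DiscreteState(f"m{k}") for k in range(K + 1)],
        omega=p["omega"],
        diffusion_enabled=False,
        parameters=pars,
        name=f"gene-finite-gamma-{gamma:g}",
    )
    production = {f"m{k}": f"{k}*gamma*b" for k in range(1, K + 1)}
    m.reactions = [
        Reaction((1,), m.compile_rate(production), name="translation"),
        Reaction((-1,), m.compile_rate("gamma0*x"), name="protein-decay"),
    ]
    m.transitions = [
        DiscreteTransition(f"m{k}", f"m{k + 1}", m.compile_rate(_HILL_EXPR))
        for k in range(K)
    ] + [
        DiscreteTransition(f"m{k}", f"m{k - 1}", m.compile_rate(f"gamma*{k}"))
        for k in range(1, K + 1)
    ]
    return m


def build_gene_expression_bursty(params: dict | None = None, n_cells: int = 80,
                                 domain_max: float = 4.0) -> ACMEModel:
    """Fast-mRNA limit: protein decay plus Hill-rate bursts of exponential
    mean size ``b = B/omega`` (probability-mode kernel, mass conserving)."""
    p = _gene_params(params)
    pars = {"r0": p["r0"], "r1": p["r1"], "n": p["n"], "gamma0": p["gamma0"], "b": p["b"]}
    m = ACMEModel(
        species=[ContinuumSpecies("x", domain_max, n_cells)],
        states=[DiscreteState("p0")],
        omega=p["omega"],
        diffusion_enabled=False,
        parameters=pars,
        name="gene-bursty",
    )
    m.reactions = [Reaction((-1,), m.compile_rate("gamma0*x"), name="protein-decay")]
    m.jumps = [JumpProcess((1,), m.compile_rate(_HILL_EXPR),
                           ExponentialKernel(mean=p["b"]), "probability", name="burst")]
    return m


def augment_first_passage(model: ACMEModel, x_c: float = 0.825, alpha: float = 1000.0,
                          start_side: str = "low") -> ACMEModel:
    """Add an absorbing state entered at rate ``alpha`` on the far side of ``x_c``.

    For a start in the low mode (``x < x_c``) absorption is active where
    ``x > x_c`` and vice versa; a cell counts as inside the absorption region
    iff its centre is.  The original dynamics are untouched.
    """
    if start_side not in ("low", "high"):
        raise ValueError("start_side must be 'low' or 'high'")
    out = ACMEModel(
        species=list(model.species),
        states=list(model.states) + [DiscreteState("absorbed", is_absorbing=True)],
        reactions=list(model.reactions),
        jumps=list(model.jumps),
        transitions=list(model.transitions),
        omega=model.omega,
        diffusion_enabled=model.diffusion_enabled,
        allow_signed_rates=model.allow_signed_rates,
        parameters=dict(model.parameters),
        name=(model.name + "+first-passage") if model.name else "first-passage",
    )
    if alpha > 0:
        cmp = ">" if start_side == "low" else "<"
        rate = out.compile_rate(f"{alpha!r}*indicator(x {cmp} {x_c!r})")
        for s in model.states:
            if not s.is_absorbing and not s.is_phantom:
                out.transitions.append(DiscreteTransition(s.label, "absorbed", rate))
    return out


@dataclass
class SwitchingTimeSummary:
    """First-passage density on the recorded time grid with summary stats.

    The density is the instantaneous absorption rate; the mean carries an
    exponential tail correction with rate ``lambda_tail`` fitted log-linearly
    over the last decade of the record.
    """

    times: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    mode: float
    median: float
    mean: float
    lambda_tail: float
    tail_r2: float
    absorbed_final: float
    tail_dominated: bool  # True when < 99% absorbed by the horizon

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "density": self.density, "cdf": self.cdf})


def switching_summary(trajectory: Trajectory) -> SwitchingTimeSummary:
    """Summarise the absorption record of a first-passage trajectory."""
    if "absorption" not in trajectory.records:
        raise ValueError("trajectory has no absorbing states")
    t = trajectory.records["t"]
    density = trajectory.records["absorption"].sum(axis=1)
    labels = list(trajectory.snapshots[0].labels)
    abs_idx = [labels.index(lbl) for lbl in trajectory.absorbing_labels]
    cdf = trajectory.records["mass"][:, abs_idx].sum(axis=1)

    i = int(np.argmax(density))
    if 0 < i < len(t) - 1:
        # quadratic through the peak triple to reduce grid bias
        x0, x1, x2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = density[i - 1], density[i], density[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        bq = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
        mode = float(-bq / (2 * a)) if a < 0 else float(x1)
    else:
        mode = float(t[i])

    total = cdf[-1]
    median = float(np.interp(0.5, cdf, t)) if total >= 0.5 else math.nan

    horizon = t[-1]
    win = (t >= horizon / 10.0) & (density > 0)
    if win.sum() >= 3:
        coef, res = np.polyfit(t[win], np.log(density[win]), 1, full=False), None
        fit = np.polyval(coef, t[win])
        ss_res = float(np.sum((np.log(density[win]) - fit) ** 2))
        ss_tot = float(np.sum((np.log(density[win]) - np.log(density[win]).mean()) ** 2))
        lam = float(-coef[0])
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        lam, r2 = math.nan, math.nan

    mean = float(np.trapezoid(t * density, t))
    remaining = max(1.0 - total, 0.0)
    if remaining > 0 and lam > 0:
        mean += remaining * (horizon + 1.0 / lam)
    return SwitchingTimeSummary(times=t, density=density, cdf=cdf, mode=mode, median=median,
                                mean=mean, lambda_tail=lam, tail_r2=r2,
                                absorbed_final=float(total), tail_dominated=bool(total < 0.99))


# ---------------------------------------------------------------------------
# phenotypic selection

def build_selection_model(Lam: float = 3.0, g: float = 0.5, omega: float = 1000.0,
                          n_cells: int = 143, domain_max: float = 1.0) -> ACMEModel:
    """Birth ``Lam x(1-x)``, death ``x``, finite-size diffusion, and growth
    ``G(x) = g x`` encoded as a transition into a phantom state at rate
    ``-G(x)`` (signed rates opt-in)."""
    if Lam <= 0 or omega <= 0:
        raise ValueError("Lam and omega must be positive")
    m = ACMEModel(
        species=[ContinuumSpecies("x", domain_max, n_cells)],
        states=[DiscreteState("pop"), DiscreteState("phantom", is_phantom=True)],
        omega=omega,
        diffusion_enabled=True,
        allow_signed_rates=True,
        parameters={"Lam": Lam, "g": g},
        name="selection",
    )
    m.reactions = [
        Reaction((1,), {"pop": m.compile_rate("Lam*x*(1-x)")}, name="birth"),
        Reaction((-1,), {"pop": m.compile_rate("x")}, name="death"),
    ]
    if g != 0:
        m.transitions = [DiscreteTransition("pop", "phantom", m.compile_rate("-(g*x)"))]
    return m


def selection_initial_condition(grid: Grid, centre: float = 0.1, width2: float = 1e-3) -> GridDensity:
    """Narrow Gaussian population, all mass in the physical state."""
    norm = math.sqrt(1.0 / (math.pi * width2))
    p = project_density(lambda x: norm * np.exp(-((x - centre) ** 2) / width2),
                        grid, labels=("pop", "phantom"))
    return p


@dataclass
class SelectionGrowthResult:
    normalized: list[GridDensity]  # physical-state profile p0/P0 at snapshot times
    snapshot_times: list[float]
    growth_rate: pd.DataFrame      # per-record t, d(log P0)/dt (centred differences)
    flux_rate: pd.DataFrame        # per-record t, int G p dx / P0 (instantaneous identity)


def normalise_and_growth_rate(trajectory: Trajectory, state: str = "pop") -> SelectionGrowthResult:
    """Normalised profiles and two growth-rate estimators for a selection run.

    The finite-difference estimator differentiates ``log P0`` on the record
    grid; the flux estimator evaluates the exact identity ``dP0/dt = int G p0``
    with ``G`` recovered from the phantom-state transition rate.
    """
    model = trajectory.model
    labels = list(trajectory.snapshots[0].labels)
    k0 = labels.index(state)
    phantoms = {s.label for s in model.states if s.is_phantom}
    g_transitions = [tr for tr in model.transitions if tr.to_state in phantoms and tr.from_state == state]
    if len(g_transitions) != 1:
        raise ValueError("expected exactly one phantom-state transition carrying the growth field")
    coords = trajectory.grid.coords()
    G = -np.asarray(g_transitions[0].rate(coords, 0.0), dtype=float)

    t = trajectory.records["t"]
    P0 = trajectory.records["mass"][:, k0]
    if np.any(P0 <= 0):
        raise ValueError("total physical-state mass P0 must stay positive")
    rate_fd = np.gradient(np.log(P0), t)

    vol = trajectory.grid.cell_volume
    normalized, flux_t, flux_v = [], [], []
    for ts, snap in zip(trajectory.times, trajectory.snapshots):
        mass = snap.mass(state)
        if mass <= 0:
            raise ValueError(f"P0 <= 0 at snapshot t={ts}")
        prof = snap.values[k0] / mass
        normalized.append(GridDensity(trajectory.grid, (state,), prof[None, ...]))
        flux_t.append(ts)
        flux_v.append(float((G * prof).sum() * vol))
    return SelectionGrowthResult(
        normalized=normalized,
        snapshot_times=list(trajectory.times),
        growth_rate=pd.DataFrame({"t": t, "rate": rate_fd}),
        flux_rate=pd.DataFrame({"t": flux_t, "rate": flux_v}),
    )


# ---------------------------------------------------------------------------
# growth-fragmentation

def build_fragmentation_model(a: float = 5.0, k: float = 3.0, with_growth_decay: bool = False,
                              n_cells: int | None = None, domain_max: float | None = None) -> ACMEModel:
    """Size-structured population fragmenting at rate ``a x^k`` with a uniform
    binary offspring kernel (gain integrates to two, volume conserved).

    With ``with_growth_decay`` the size also grows at rate ``x`` and the
    population decays at unit rate into an inert state; the fragmentation
    rate then carries the extra factor ``k`` (the time rescaling that maps
    the pure-fragmentation similarity solution onto this system multiplies
    the fragmentation constant by ``k``).  The growth-decay run starts from a
    broad profile, so it defaults to a wider domain.
    """
    if a <= 0 or k < 1:
        raise ValueError("need a > 0 and k >= 1")
    if domain_max is None:
        domain_max = 6.0 if with_growth_decay else 3.0
    if n_cells is None:
        n_cells = int(round(domain_max / 0.005))
    states = [DiscreteState("rho0")]
    if with_growth_decay:
        states.append(DiscreteState("inert", is_absorbing=True))
    m = ACMEModel(
        species=[ContinuumSpecies("x", domain_max, n_cells)],
        states=states,
        diffusion_enabled=False,
        parameters={"a": a, "k": k},
        name="fragmentation" + ("-growth-decay" if with_growth_decay else ""),
    )
    rate_expr = "k*a*x^k" if with_growth_decay else "a*x^k"
    m.jumps = [JumpProcess((-1,), {"rho0": m.compile_rate(rate_expr)},
                           UniformFragmentationKernel(), "fragmentation", name="divide")]
    if with_growth_decay:
        m.reactions = [Reaction((1,), {"rho0": m.compile_rate("x")}, name="growth")]
        m.transitions = [DiscreteTransition("rho0", "inert", m.compile_rate("1.0"))]
    return m


# ---------------------------------------------------------------------------
# initial conditions and the property-test fixture generator

def uniform_initial(model: ACMEModel, state: str | None = None) -> GridDensity:
    """Unit mass spread uniformly over the domain, in one state."""
    grid = Grid.from_species(model.species)
    p = GridDensity.zeros(grid, model.state_labels)
    k = p.index(state) if state else 0
    p.values[k] = 1.0 / np.prod(grid.domain_max)
    return p


def delta_initial(model: ACMEModel, x0: float, state: str | None = None) -> GridDensity:
    """Point mass realised as one full cell (the cell containing ``x0``)."""
    grid = Grid.from_species(model.species)
    if grid.d != 1:
        raise ValueError("delta_initial supports one continuum dimension")
    p = GridDensity.zeros(grid, model.state_labels)
    k = p.index(state) if state else 0
    i = min(int(x0 / grid.dx), grid.shape[0] - 1)
    p.values[k][i] = 1.0 / grid.dx
    return p


def generate_random_model(seed: int, max_states: int = 2, max_reactions: int = 3,
                          allow_jump: bool = True, allow_diffusion: bool = True) -> ACMEModel:
    """Reproducible well-posed random models for conservation/linearity fuzzing.

    Polynomial rates bounded on the unit domain, probability-mode exponential
    burst kernels, non-negative constant transitions; every generated model
    passes validation with no errors and conserves total mass.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(rng.integers(8, 25))
    n_states = int(rng.integers(1, max_states + 1))
    labels = [f"s{i}" for i in range(n_states)]
    diffusion = bool(allow_diffusion and rng.random() < 0.5)
    m = ACMEModel(
        species=[ContinuumSpecies("x", 1.0, n_cells)],
        states=[DiscreteState(lbl) for lbl in labels],
        omega=float(rng.uniform(50, 500)) if diffusion else None,
        diffusion_enabled=diffusion,
        name=f"random-{seed}",
    )

    def poly_expr():
        c = np.round(rng.uniform(0.0, 2.0, size=3), 3)
        return f"{c[0]} + {c[1]}*x + {c[2]}*x*x"

    for _ in range(int(rng.integers(1, max_reactions + 1))):
        e = int(rng.choice([-1, 1]))
        m.reactions.append(Reaction((e,), m.compile_rate(poly_expr())))
    if allow_jump and rng.random() < 0.7:
        kern = ExponentialKernel(mean=float(np.round(rng.uniform(0.05, 0.3), 3)))
        m.jumps.append(JumpProcess((1,), m.compile_rate(poly_expr()), kern, "probability"))
    if n_states == 2:
        m.transitions = [
            DiscreteTransition("s0", "s1", m.compile_rate(f"{np.round(rng.uniform(0, 2), 3)}")),
            DiscreteTransition("s1", "s0", m.compile_rate(f"{np.round(rng.uniform(0, 2), 3)}")),
        ]
    return m
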