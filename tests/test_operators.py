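import numpy as np
import pytest

import acmekit as ak
from acmekit import (ACMEModel, ContinuumSpecies, DiscreteState, DiscreteTransition,
                     ExponentialKernel, Grid, GridDensity, JumpProcess, Reaction,
                     UniformFragmentationKernel, advection_rhs, assemble_rhs,
                     build_jump_operator, build_stencil, diffusion_rhs, transitions_rhs)
from acmekit.operators import kt_tendency_periodic


# ---------------------------------------------------------------------------
# rays

@pytest.mark.parametrize("shape, e", [((12,), (1,)), ((12,), (-1,)),
                                      ((6, 8), (1, 1)), ((6, 8), (1, -2)), ((6, 8), (0, 1))])
def test_stencil_partitions_grid(shape, e):
    st = build_stencil(Grid(dx=0.1, shape=shape), e)
    seen = np.concatenate([g.ravel() for g in st.groups])
    assert sorted(seen) == list(range(int(np.prod(shape))))
    strides = [int(np.prod(shape[a + 1:])) for a in range(len(shape))]
    step = sum(c * s for c, s in zip(e, strides))
    for g in st.groups:
        assert np.all(np.diff(g, axis=1) == step)


# ---------------------------------------------------------------------------
# advection

def _single_state_model(n, exprs, domain=1.0):
    m = ACMEModel(species=[ContinuumSpecies("x", domain, n)], states=[DiscreteState("s")])
    m.reactions = [Reaction((e,), m.compile_rate(expr)) for e, expr in exprs]
    return m


def test_advection_zero_rate_zero_tendency():
    m = _single_state_model(16, [(1, "0*x")])
    p = GridDensity(Grid.from_species(m.species), ("s",), np.random.default_rng(0).random((1, 16)))
    out = advection_rhs(p, m.reactions[0])
    assert np.all(out.values == 0.0)


def _translate_error(n, v=1.0, t_final=0.25):
    """L1 error of a periodic Gaussian translation at constant speed."""
    dx = 1.0 / n
    x = (np.arange(n) + 0.5) * dx
    prof = lambda y: np.exp(-100.0 * (np.mod(y - 0.5 + 0.5, 1.0) - 0.5) ** 2)
    p = prof(x)
    t = 0.0
    dt = 0.2 * dx / v
    vif = np.full(n, v)
    while t < t_final - 1e-12:
        h = min(dt, t_final - t)
        k1 = kt_tendency_periodic(p, vif, dx)
        u1 = p + h * k1
        u2 = 0.75 * p + 0.25 * (u1 + h * kt_tendency_periodic(u1, vif, dx))
        p = p / 3.0 + (2.0 / 3.0) * (u2 + h * kt_tendency_periodic(u2, vif, dx))
        t += h
    return np.abs(p - prof(x - v * t_final)).sum() * dx


def test_advection_translation_second_order():
    e1, e2 = _translate_error(200), _translate_error(400)
    assert e1 / e2 >= 3.2  # nominal 2nd order with the minmod limiter


def test_advection_decay_first_moment_ode():
    # drift -x: the first moment obeys d<x>/dt = -<x>, so <x>(t) = <x>(0) e^-t
    n = 200
    m = _single_state_model(n, [(-1, "x")], domain=2.0)
    g = Grid.from_species(m.species)
    p = ak.project_density(lambda x: np.exp(-200 * (x - 0.8) ** 2), g, labels=("s",), normalize=True)
    traj = ak.integrate(m, p, ak.SolverSettings(t_final=0.5))
    m1 = ak.moments(traj.snapshots[-1], 1)["s"]
    m0 = ak.moments(p, 1)["s"]
    assert m1 == pytest.approx(m0 * np.exp(-0.5), rel=2e-3)


# ---------------------------------------------------------------------------
# diffusion

def test_diffusion_constant_field_zero():
    m = _single_state_model(16, [(1, "1.0")])
    m.omega, m.diffusion_enabled = 100.0, True
    g = Grid.from_species(m.species)
    p = GridDensity(g, ("s",), np.ones((1, 16)))
    out = diffusion_rhs(p, m.reactions[0], omega=100.0)
    assert np.allclose(out.values, 0.0, atol=1e-14)


def test_diffusion_variance_growth_rate():
    # two unit-rate reactions (e = +-1, lam = mu = 0.5) with no net drift:
    # D = (lam+mu)/(2 omega); an interior pulse gains variance at 2D per unit time
    omega = 50.0
    m = ACMEModel(species=[ContinuumSpecies("x", 1.0, 200)], states=[DiscreteState("s")],
                  omega=omega, diffusion_enabled=True)
    m.reactions = [Reaction((1,), m.compile_rate("0.5")), Reaction((-1,), m.compile_rate("0.5"))]
    g = Grid.from_species(m.species)
    p = ak.project_density(lambda x: np.exp(-((x - 0.5) ** 2) / 4e-4), g, labels=("s",), normalize=True)
    t_final = 0.2
    traj = ak.integrate(m, p, ak.SolverSettings(t_final=t_final))
    x = g.centers()

    def var(d):
        w = d.values[0] / d.values[0].sum()
        mu = (x * w).sum()
        return ((x - mu) ** 2 * w).sum()

    D = 1.0 / (2 * omega)
    assert var(traj.snapshots[-1]) - var(p) == pytest.approx(2 * D * t_final, rel=2e-2)


def test_diffusion_vanishes_with_system_size():
    m = _single_state_model(16, [(1, "x")])
    g = Grid.from_species(m.species)
    p = GridDensity(g, ("s",), np.random.default_rng(1).random((1, 16)))
    assert np.max(np.abs(diffusion_rhs(p, m.reactions[0], omega=1e9).values)) < 1e-6
    assert np.max(np.abs(diffusion_rhs(p, m.reactions[0], omega=1e12).values)) < 1e-9


# ---------------------------------------------------------------------------
# jump operators

def test_exponential_jump_columns_sum_to_one():
    g = Grid(dx=0.05, shape=(40,))
    m = _single_state_model(40, [], domain=2.0)
    jp = JumpProcess((1,), m.compile_rate("1.0"), ExponentialKernel(0.2), "probability")
    op = build_jump_operator(jp, g)
    W = op.mats[0]
    assert np.allclose(W.sum(axis=0), 1.0, atol=1e-13)


def test_fragmentation_kernel_brute_force_invariants():
    # 16-cell grid: per-column number sum ~2 and exact first-moment conservation
    n = 16
    g = Grid(dx=1.0 / n, shape=(n,))
    m = _single_state_model(n, [])
    jp = JumpProcess((-1,), m.compile_rate("x"), UniformFragmentationKernel(), "fragmentation")
    op = build_jump_operator(jp, g)
    W = op.mats[0][0]  # per-ray stack, single ray; ray order is descending x
    x_ray = g.centers()[::-1]
    for s in range(n):
        col = W[:, s]
        moment = float((x_ray * col).sum())
        assert moment == pytest.approx(x_ray[s], rel=1e-12)
        if s < n - 1:  # all but the smallest source produce ~2 fragments
            assert float(col.sum()) == pytest.approx(2.0, rel=0.1)


def test_zero_rate_jump_is_zero_operator():
    m = _single_state_model(20, [])
    m.jumps = [JumpProcess((1,), m.compile_rate("0*x"), ExponentialKernel(0.1), "probability")]
    g = Grid.from_species(m.species)
    p = GridDensity(g, ("s",), np.random.default_rng(2).random((1, 20)))
    out = assemble_rhs(m, p)
    assert np.allclose(out.values, 0.0)


def test_negative_kernel_rejected():
    from acmekit.model import CustomKernel
    m = _single_state_model(8, [])
    jp = JumpProcess((1,), m.compile_rate("1.0"), CustomKernel(expr="0.5 - z", support=2.0),
                     "probability")
    with pytest.raises(ValueError, match="negative"):
        build_jump_operator(jp, Grid.from_species(m.species))


# ---------------------------------------------------------------------------
# transitions

def _two_state(n=10):
    m = ACMEModel(species=[ContinuumSpecies("x", 1.0, n)],
                  states=[DiscreteState("a"), DiscreteState("b")])
    return m


def test_transitions_symmetric_relaxation_closed_form():
    m = _two_state()
    m.transitions = [DiscreteTransition("a", "b", m.compile_rate("1.0")),
                     DiscreteTransition("b", "a", m.compile_rate("1.0"))]
    p0 = ak.case_studies.uniform_initial(m, state="a")
    traj = ak.integrate(m, p0, ak.SolverSettings(t_final=1.0, cfl_safety=0.05))
    mass_a = traj.snapshots[-1].mass("a")
    assert mass_a == pytest.approx(0.5 + 0.5 * np.exp(-2.0), rel=2e-5)


def test_absorbing_state_receives_but_never_sends():
    m = _two_state()
    m.states[1] = DiscreteState("b", is_absorbing=True)
    m.transitions = [DiscreteTransition("a", "b", m.compile_rate("1.0")),
                     DiscreteTransition("b", "a", m.compile_rate("5.0"))]  # must be ignored
    p = ak.case_studies.uniform_initial(m, state="a")
    out = assemble_rhs(m, p)
    assert np.all(out.values[1] >= 0)
    assert out.mass("b") == pytest.approx(1.0, rel=1e-12)


def test_phantom_transition_sign_bookkeeping():
    m = _two_state()
    m.states[1] = DiscreteState("b", is_phantom=True)
    m.allow_signed_rates = True
    m.transitions = [DiscreteTransition("a", "b", m.compile_rate("-(0.5*x)"))]
    p = ak.case_studies.uniform_initial(m, state="a")
    out = transitions_rhs(p, m.transitions, m.states)
    assert np.all(out.values[0] >= 0)  # -g p0 = +G p0 grows the physical state
    assert np.all(out.values[1] <= 0)
    assert out.total_mass() == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# assembly

def test_empty_model_zero_tendency():
    m = _two_state()
    p = ak.case_studies.uniform_initial(m)
    assert np.all(assemble_rhs(m, p).values == 0.0)


def test_probability_mode_total_mass_tendency_zero():
    m = ak.case_studies.build_gene_expression_bursty(n_cells=32)
    p = ak.case_studies.uniform_initial(m)
    assert assemble_rhs(m, p).total_mass() == pytest.approx(0.0, abs=1e-12)


def test_selection_mass_growth_identity():
    # d(mass of p0)/dt must equal int G p0 dx with G = g x
    m = ak.case_studies.build_selection_model(n_cells=50)
    g = Grid.from_species(m.species)
    p = ak.case_studies.selection_initial_condition(g)
    out = assemble_rhs(m, p)
    x = g.centers()
    expected = (0.5 * x * p.values[0]).sum() * g.dx
    assert out.mass("pop") == pytest.approx(expected, rel=1e-10)


def test_assemble_rhs_linearity():
    # the unlimited central scheme is exactly linear; the limited variant is
    # nonlinear in the slopes but still homogeneous of degree one
    m = ak.case_studies.generate_random_model(11)
    g = Grid.from_species(m.species)
    rng = np.random.default_rng(4)
    p = GridDensity(g, tuple(m.state_labels), rng.random((len(m.states),) + g.shape))
    q = GridDensity(g, tuple(m.state_labels), rng.random((len(m.states),) + g.shape))
    lhs = assemble_rhs(m, p.scaled(1.7) + q.scaled(-0.3), limiter="none")
    rhs = assemble_rhs(m, p, limiter="none").scaled(1.7) + \
        assemble_rhs(m, q, limiter="none").scaled(-0.3)
    assert np.allclose(lhs.values, rhs.values, atol=1e-12)
    hom = assemble_rhs(m, p.scaled(-2.5))
    assert np.allclose(hom.values, assemble_rhs(m, p).scaled(-2.5).values, atol=1e-12)


# ---------------------------------------------------------------------------
# brute-force oracle on a 12-cell grid

def _minmod(a, b):
    if a * b <= 0:
        return 0.0
    return np.sign(a) * min(abs(a), abs(b))


def _oracle_rhs(model, p, grid):
    """Independent plain-loop reimplementation of the semi-discrete operator
    (1-D, unit displacements): limited central advection, conservative second
    difference, exact-integral exponential kernel with boundary pile-up,
    pointwise transitions."""
    n = grid.shape[0]
    dx = grid.dx
    x = grid.centers()
    labels = list(p.labels)
    out = np.zeros_like(p.values)
    absorbing = {s.label for s in model.states if s.is_absorbing}

    for rx in model.reactions:
        e = rx.displacement[0]
        for k, lbl in enumerate(labels):
            if lbl in absorbing:
                continue
            rf = rx.rate_for(lbl)
            if rf is None:
                continue
            ray = list(range(n)) if e > 0 else list(range(n - 1, -1, -1))
            P = [p.values[k][i] for i in ray]
            s = [0.0] * n
            for j in range(1, n - 1):
                s[j] = _minmod(P[j] - P[j - 1], P[j + 1] - P[j])
            F = [0.0] * (n - 1)
            for j in range(n - 1):
                xi = x[ray[j]] + e * dx / 2.0
                v = float(rf((np.array([xi]),), 0.0)[0])
                pl = P[j] + 0.5 * s[j]
                pr = P[j + 1] - 0.5 * s[j + 1]
                F[j] = 0.5 * (v * (pl + pr) - abs(v) * (pr - pl))
            for j in range(n):
                left = F[j - 1] if j > 0 else 0.0
                right = F[j] if j < n - 1 else 0.0
                out[k][ray[j]] += -(right - left) / dx
            if model.diffusion_enabled:
                w = [float(rf((np.array([x[ray[j]]]),), 0.0)[0]) * P[j] for j in range(n)]
                for j in range(n):
                    gr = (w[j + 1] - w[j]) if j < n - 1 else 0.0
                    gl = (w[j] - w[j - 1]) if j > 0 else 0.0
                    out[k][ray[j]] += (gr - gl) / (2.0 * model.omega * dx * dx)

    for jp in model.jumps:
        b = jp.kernel.mean
        W = np.zeros((n, n))
        for src in range(n):
            for m_ in range(src, n):
                lo = max((m_ - src) * dx - dx / 2.0, 0.0)
                hi = (m_ - src) * dx + dx / 2.0
                W[m_, src] = np.exp(-lo / b) - np.exp(-hi / b)
            W[n - 1, src] += max(1.0 - W[:, src].sum(), 0.0)
            W[:, src] /= W[:, src].sum()
        for k, lbl in enumerate(labels):
            if lbl in absorbing:
                continue
            rf = jp.rate_for(lbl)
            if rf is None:
                continue
            f = np.array([float(rf((np.array([xi]),), 0.0)[0]) for xi in x])
            out[k] += W @ (f * p.values[k]) - f * p.values[k]

    for tr in model.transitions:
        if tr.from_state in absorbing:
            continue
        gk = np.array([float(tr.rate((np.array([xi]),), 0.0)[0]) for xi in x])
        flow = gk * p.values[labels.index(tr.from_state)]
        out[labels.index(tr.from_state)] -= flow
        out[labels.index(tr.to_state)] += flow
    return out


def test_assemble_rhs_matches_loop_oracle_on_12_cells():
    m = ACMEModel(species=[ContinuumSpecies("x", 1.2, 12)],
                  states=[DiscreteState("a"), DiscreteState("b")],
                  omega=80.0, diffusion_enabled=True)
    m.reactions = [Reaction((1,), m.compile_rate("0.4 + 0.3*x")),
                   Reaction((-1,), m.compile_rate("1.1*x"))]
    m.jumps = [JumpProcess((1,), m.compile_rate("0.2 + x*x"), ExponentialKernel(0.15), "probability")]
    m.transitions = [DiscreteTransition("a", "b", m.compile_rate("0.7")),
                     DiscreteTransition("b", "a", m.compile_rate("0.2 + x"))]
    g = Grid.from_species(m.species)
    rng = np.random.default_rng(5)
    for _ in range(3):
        p = GridDensity(g, ("a", "b"), rng.random((2, 12)))
        got = assemble_rhs(m, p).values
        want = _oracle_rhs(m, p, g)
        assert np.allclose(got, want, atol=1e-13), np.abs(got - want).max()
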