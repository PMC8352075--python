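import numpy as np
import pytest
import scipy.sparse.linalg as spla
from scipy.integrate import quad

import acmekit as ak
from acmekit.analytic import (SwitchingTimeFormulaInputs, fit_gaussian_width,
                              fragmentation_growth_decay, fragmentation_limit_profile,
                              fragmentation_selfsimilar, mean_switching_times,
                              selection_asymptotics, stationary_bursty_density)


# ---------------------------------------------------------------------------
# stationary bursty density

def test_stationary_density_parameter_combinations():
    # with the benchmark preset the density is e^{-x/0.2} x^{1} (1+x^4)^{2.5}
    x = np.array([0.5, 1.0, 2.0])
    d = stationary_bursty_density(x, 2, 10, 4, 1, 0.2, domain_max=4.0)
    ref = np.exp(-x / 0.2) * x * (1 + x ** 4) ** 2.5
    ratio = d / ref
    assert np.allclose(ratio, ratio[0], rtol=1e-9)


def test_stationary_density_zero_at_origin_and_normalised():
    x = np.linspace(0, 4, 1601)
    d = stationary_bursty_density(x, 2, 10, 4, 1, 0.2, domain_max=4.0)
    assert d[0] == 0.0
    assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-5)


def test_stationary_density_bimodal_on_0_3():
    x = np.linspace(1e-3, 3.0, 3000)
    d = stationary_bursty_density(x, 2, 10, 4, 1, 0.2, domain_max=4.0)
    maxima = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))
    assert len(maxima) == 2


def test_stationary_density_rejects_nonpositive_r0():
    with pytest.raises(ValueError):
        stationary_bursty_density(np.array([1.0]), 0.0, 10, 4, 1, 0.2)


# ---------------------------------------------------------------------------
# mean switching times

@pytest.fixture(scope="module")
def st_inputs():
    return SwitchingTimeFormulaInputs(r0=2, r1=10, n=4, gamma0=1, b=0.2, x_c=0.825)


def test_high_to_low_zero_below_boundary(st_inputs):
    _, hl = mean_switching_times(st_inputs, 0.0)
    assert hl == 0.0
    _, hl = mean_switching_times(st_inputs, 0.5)
    assert hl == 0.0


def test_low_to_high_at_boundary_is_boundary_term_only(st_inputs):
    # the integral part vanishes at x = x_c, and nearby values differ by it
    lh_c, _ = mean_switching_times(st_inputs, st_inputs.x_c)
    lh_below, _ = mean_switching_times(st_inputs, st_inputs.x_c - 0.05)
    assert lh_below > lh_c > 0


def test_high_to_low_monotone_above_boundary(st_inputs):
    xs = np.linspace(0.85, 3.0, 40)
    _, hl = mean_switching_times(st_inputs, xs)
    assert np.all(np.diff(hl) > 0)


def test_switching_times_against_riemann_oracle(st_inputs):
    """Brute-force fixed-grid Riemann quadrature (1e5 points) of the same
    double integrals, written independently of the production path."""
    p = st_inputs
    xs = np.linspace(1e-9, 16.0, 100_001)
    dxs = xs[1] - xs[0]
    H = 2 + 10 * xs ** 4 / (1 + xs ** 4)
    dH = 10 * 4 * xs ** 3 / (1 + xs ** 4) ** 2
    logeM = 3.0 * np.log(xs) - np.log(H) + 2.5 * np.log1p(xs ** 4) - xs / 0.2
    eM = np.exp(logeM)
    phi = 1 / (0.2 * xs) + dH / (xs * H)
    V = -np.cumsum(phi * eM) * dxs
    V_inf = V[-1]
    ic = int(np.argmin(np.abs(xs - p.x_c)))
    eMi = np.exp(-logeM)
    T_hl_or = lambda x: np.sum((eMi * (V - V_inf))[ic: int(np.argmin(np.abs(xs - x)))]) * dxs
    boundary = (1 - p.x_c * V[ic] * eMi[ic]) / H[ic]
    T_lh_or = lambda x: boundary - np.sum((eMi * V)[int(np.argmin(np.abs(xs - x))): ic]) * dxs

    lh, _ = mean_switching_times(p, 0.5)
    _, hl = mean_switching_times(p, 1.5)
    assert lh == pytest.approx(T_lh_or(0.5), rel=2e-3)
    assert hl == pytest.approx(T_hl_or(1.5), rel=2e-3)


def test_switching_times_match_monte_carlo_frozen_values(st_inputs):
    """Frozen means from a 20k-path Monte Carlo of the burst process
    (decay at rate x between Hill-rate bursts of Exp(0.2) size):
    T_low->high(0.5125) = 3.458 +- 0.029, T_high->low(1.5125) = 18.18 +- 0.23.
    """
    lh, _ = mean_switching_times(st_inputs, 0.5125)
    _, hl = mean_switching_times(st_inputs, 1.5125)
    assert lh == pytest.approx(3.458, rel=0.02)
    assert hl == pytest.approx(18.18, rel=0.03)


def test_switching_times_deterministic(st_inputs):
    a = mean_switching_times(st_inputs, np.array([0.3, 1.2]))
    b = mean_switching_times(st_inputs, np.array([0.3, 1.2]))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# selection asymptotics

def test_selection_critical_point_and_growth_rate():
    asym = selection_asymptotics(lambda x: 0.5 * x, Lam=2.0, omega=1000.0)
    assert asym.x_c == pytest.approx(0.5)
    asym3 = selection_asymptotics(lambda x: 0.5 * x, Lam=3.0, omega=1000.0)
    assert asym3.r0 == pytest.approx(0.5 * (1 - 1 / 3))  # g (1 - 1/Lam)


def test_selection_limit_toward_unity():
    asym = selection_asymptotics(lambda x: 0.5 * x, Lam=1.0 + 1e-9, omega=100.0)
    assert asym.x_c == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        selection_asymptotics(lambda x: x, Lam=1.0, omega=100.0)


def test_selection_gaussian_width_matches_operator_eigenvector():
    # the dominant eigenvector of the assembled (linear) operator on a fine
    # grid is an independent discretisation-side oracle for the profile width
    n = 286
    m = ak.case_studies.build_selection_model(n_cells=n)
    grid = ak.Grid.from_species(m.species)
    A = ak.rhs_matrix(m, grid)[:n, :n]
    vals, vecs = spla.eigs(A, k=1, which="LR")
    v = np.abs(np.real(vecs[:, 0]))
    v /= v.sum() * grid.dx
    x = grid.centers()
    mu = (x * v).sum() * grid.dx
    sd = np.sqrt(((x - mu) ** 2 * v).sum() * grid.dx)
    asym = selection_asymptotics(lambda y: 0.5 * y, 3.0, 1000.0)
    assert np.real(vals[0]) == pytest.approx(asym.r0, rel=1e-3)
    assert sd == pytest.approx(np.sqrt(asym.sigma2), rel=0.02)
    assert asym.limiting_profile(x).sum() * grid.dx == pytest.approx(1.0, abs=1e-6)


def test_fit_gaussian_width_recovers_known_width():
    x = np.linspace(0, 1, 400)
    s = 0.03
    prof = np.exp(-((x - 0.4) ** 2) / (2 * s * s)) / np.sqrt(2 * np.pi) / s
    assert fit_gaussian_width(x, prof, 0.4) == pytest.approx(s, rel=1e-6)


# ---------------------------------------------------------------------------
# fragmentation closed forms

def _residual_pure(x, t, a, k):
    """Numerical residual of the self-similar solution in the pure
    fragmentation equation (loss a x^k, gain kernel 2 a y^{k-1})."""
    eps = 1e-6
    dt = (fragmentation_selfsimilar(x, t + eps, a, k) -
          fragmentation_selfsimilar(x, t - eps, a, k)) / (2 * eps)
    loss = a * x ** k * fragmentation_selfsimilar(x, t, a, k)
    gain, _ = quad(lambda y: 2 * a * y ** (k - 1) * float(fragmentation_selfsimilar(y, t, a, k)),
                   x, np.inf, limit=200)
    return dt + loss - gain


def test_selfsimilar_solution_satisfies_pde():
    for x in (0.2, 0.7, 1.4):
        for t in (0.5, 1.5):
            scale = float(fragmentation_selfsimilar(0.0, t, 5.0, 3.0))
            assert abs(_residual_pure(x, t, 5.0, 3.0)) < 1e-3 * max(scale, 1.0)


def test_selfsimilar_volume_invariant_k2():
    c = 1.3
    for t in (0.4, 1.0, 2.5):
        vol, _ = quad(lambda y: y * float(fragmentation_selfsimilar(y, t, 5.0, 2.0, c)), 0, np.inf)
        assert vol == pytest.approx(c / 2.0, rel=1e-8)


def test_selfsimilar_origin_density_diverges():
    vals = [float(fragmentation_selfsimilar(0.0, t, 5.0, 2.0)) for t in (1, 10, 100)]
    assert vals[0] < vals[1] < vals[2]


def _residual_growth_decay(x, t, a, k):
    """Residual in the growth (rate x) + unit decay + fragmentation equation
    with rate a k x^k and gain 2 a k y^{k-1}."""
    eps = 1e-6
    f = lambda xx, tt: fragmentation_growth_decay(np.asarray(xx, float), tt, a, k)
    dt = (f(x, t + eps) - f(x, t - eps)) / (2 * eps)
    dxv = (float((x + eps) * f(x + eps, t)) - float((x - eps) * f(x - eps, t))) / (2 * eps)
    loss = (a * k * x ** k + 1.0) * float(f(x, t))
    gain, _ = quad(lambda y: 2 * a * k * y ** (k - 1) * float(f(y, t)), x, np.inf, limit=200)
    return float(dt) + dxv + loss - gain


def test_growth_decay_solution_satisfies_pde():
    for x in (0.3, 0.8):
        for t in (0.3, 1.0):
            scale = float(fragmentation_growth_decay(0.0, t, 5.0, 2.0))
            assert abs(_residual_growth_decay(x, t, 5.0, 2.0)) < 1e-3 * max(scale, 1.0)


def test_growth_decay_limits_to_profile():
    x = np.linspace(0, 3, 50)
    late = fragmentation_growth_decay(x, 12.0, 5.0, 2.0)
    lim = fragmentation_limit_profile(x, 5.0, 2.0)
    assert np.allclose(late, lim, rtol=1e-4, atol=1e-12)


def test_limit_profile_efolding_scale():
    # a = 5, k = 2: the profile falls to 1/e of its origin value at x = 1/sqrt(5)
    x0 = 1.0 / np.sqrt(5.0)
    assert fragmentation_limit_profile(x0, 5.0, 2.0) == pytest.approx(
        fragmentation_limit_profile(0.0, 5.0, 2.0) / np.e)
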