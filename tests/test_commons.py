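"""The lasting-commons model: payoff, equilibrium, Omega, z*."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from kinscape import (
    CommonsParams,
    K_statistic,
    Lattice,
    commons_effect_fields,
    commons_extended_effects,
    convergence_check,
    differentiate_env_map,
    env_equilibrium,
    environmental_map,
    extended_effects_table,
    omega,
    payoff,
    selection_gradient_commons,
    singular_strategy,
    survival_effects,
    truncated_binomial_kernel,
    uniform_kernel,
)
from kinscape.commons import MethodContractError


def make_params(dims=(11,), N=10, m=0.6, lm=1.8, d=0.9, ld=2.5, eps=0.5,
                B=2.0, C=1.0, aB=1, aC=4, P0=None, lifecycle=None):
    lat = Lattice(dims)
    kwargs = dict(
        lattice=lat,
        N=N,
        m_kernel=truncated_binomial_kernel(lat, m, lm),
        d_kernel=truncated_binomial_kernel(lat, d, ld),
        B=B,
        C=C,
        alpha_B=aB,
        alpha_C=aC,
        epsilon=eps,
        P0=float(N if P0 is None else P0),
    )
    if lifecycle is not None:
        kwargs["lifecycle"] = lifecycle
    return CommonsParams(**kwargs)


def test_payoff_values():
    p = make_params()
    assert payoff(0.0, 0.0, p) == 1.0
    assert payoff(0.0, 0.5, p) == pytest.approx(math.e)  # B=2, alpha_B=1, n=0.5
    assert payoff(0.3, 0.0, p) < 1.0  # trait expression is individually costly
    assert payoff(-0.3, 0.0, p) < 1.0  # in either direction (alpha_C even)


def test_parameter_invariants():
    with pytest.raises(ValueError):
        make_params(aB=2)  # alpha_B must be odd
    with pytest.raises(ValueError):
        make_params(aC=3)  # alpha_C must be even
    with pytest.raises(ValueError):
        make_params(aB=5, aC=4)  # costs must rise faster
    with pytest.raises(ValueError):
        make_params(eps=0.0)
    with pytest.raises(ValueError):
        make_params(B=-1.0)


def test_env_equilibrium_and_fixed_point_iteration():
    """Iterating the commons map from an empty landscape converges to
    n-hat = P(z)/eps in every patch."""
    p = make_params()
    z = 0.1
    n_hat = env_equilibrium(z, p)
    assert n_hat == pytest.approx(p.P0 * z / p.epsilon)
    assert env_equilibrium(0.0, p) == 0.0
    # fixed-point iteration of the full map (all patches), via the
    # focal-patch evaluator and spatial homogeneity
    n = np.zeros(p.lattice.D)
    z_field = np.full(p.lattice.D, z)
    Dmat = p.d_kernel.p[p.lattice.sub_index]
    for _ in range(200):
        n = Dmat @ ((1 - p.epsilon) * n + p.P0 * z_field)
    assert np.max(np.abs(n - n_hat)) < 1e-10
    # the focal-patch evaluator agrees at the fixed point
    assert environmental_map(z_field, n, p) == pytest.approx(n_hat)


def test_commons_effect_fields_analytic_vs_numeric():
    p = make_params()
    z = 0.2
    analytic = commons_effect_fields(z, p)
    numeric = differentiate_env_map(
        lambda zf, nf: environmental_map(zf, nf, p),
        z,
        env_equilibrium(z, p),
        p.N,
        p.lattice,
    )
    assert np.max(np.abs(analytic.psi - numeric.psi)) < 1e-6
    assert np.max(np.abs(analytic.c - numeric.c)) < 1e-6


def test_full_decay_kills_coupling():
    p = make_params(eps=1.0)
    assert np.max(np.abs(commons_effect_fields(0.0, p).c)) == 0.0
    table = commons_extended_effects(0.0, p, 4)
    for t in range(2, 5):
        assert np.max(np.abs(table[t])) < 1e-15


def test_commons_extended_effects_cross_route():
    """Closed form (decay-discounted movement walk) equals the generic
    spectral recursion on psi and c."""
    lat = Lattice([31])
    p = make_params(dims=(31,), N=20, m=0.3, lm=1.55, d=0.98, ld=8.0, eps=0.5)
    closed = commons_extended_effects(0.1, p, 10)
    generic = extended_effects_table(commons_effect_fields(0.1, p), 10)
    for t in range(1, 11):
        assert np.max(np.abs(closed[t] - generic[t])) < 1e-12
    # first generation: production spread by one round of movement
    assert np.max(np.abs(closed[1] - p.P0 * p.d_kernel.p / p.N)) < 1e-12


def test_omega_uniform_kernels_vanish():
    lat = Lattice([8])
    p = CommonsParams(
        lattice=lat, N=5,
        m_kernel=uniform_kernel(lat), d_kernel=uniform_kernel(lat),
        B=2.0, C=1.0, alpha_B=1, alpha_C=4, epsilon=0.5, P0=5.0,
    )
    assert omega(p, "closed_form") == pytest.approx(0.0, abs=1e-14)
    assert omega(p, "series") == pytest.approx(0.0, abs=1e-14)


@pytest.mark.parametrize("lifecycle", [None, survival_effects(0.6)])
def test_omega_routes_agree(lifecycle):
    p = make_params(lifecycle=lifecycle)
    closed = omega(p, "closed_form")
    series = omega(p, "series")
    assert abs(series - closed) <= 1e-8 * (1.0 + abs(closed))
    if lifecycle is None:  # Wright-Fisher fecundity
        cov = omega(p, "covariance_wf")
        assert abs(cov - closed) <= 1e-8


def test_omega_covariance_requires_wf():
    p = make_params(lifecycle=survival_effects(0.5))
    with pytest.raises(MethodContractError):
        omega(p, "covariance_wf")
    with pytest.raises(MethodContractError):
        omega(p, "no_such_method")


def test_omega_equals_eps_K_N_over_Pprime():
    for lc in (None, survival_effects(0.3)):
        p = make_params(lifecycle=lc)
        derivs = commons_effect_fields(0.0, p)
        K = K_statistic(
            p.m_kernel, derivs.psi_spectrum(), derivs.c_spectrum(), p.N, p.lifecycle
        )
        assert omega(p, "closed_form") == pytest.approx(
            p.epsilon * K * p.N / p.P0, abs=1e-10
        )


def test_weak_dispersal_limit():
    p = make_params(dims=(13, 13), N=50, m=0.01, lm=1.54, d=0.01, ld=8.0, eps=0.5, P0=50)
    closed = omega(p, "closed_form")
    limit = omega(p, "weak_dispersal")
    assert closed > 0
    assert abs(closed - limit) / abs(closed) < 0.05


def test_gradient_at_zero_proportional_to_omega():
    """In a population not expressing the trait, selection is driven by
    Omega alone: s(0) = Omega * B * alpha_B * P0/eps for alpha_B = 1."""
    p = make_params()
    om = omega(p)
    assert selection_gradient_commons(0.0, p) == pytest.approx(
        om * p.B * p.P0 / p.epsilon, rel=1e-12
    )


def test_zero_omega_leaves_pure_cost_gradient():
    p = make_params()
    assert selection_gradient_commons(0.5, p, omega_value=0.0) == pytest.approx(
        -p.C * p.alpha_C * 0.5 ** (p.alpha_C - 1)
    )
    assert singular_strategy(p, omega_value=0.0) == 0.0


def test_singular_strategy_closed_form_vs_numeric_root():
    for lifecycle in (None, survival_effects(0.6)):
        p = make_params(lifecycle=lifecycle)
        om = omega(p)
        z_closed = singular_strategy(p, om)
        g = lambda z: selection_gradient_commons(z, p, om)
        lo, hi = (1e-8, 10.0) if om > 0 else (-10.0, -1e-8)
        z_num = brentq(g, lo, hi, xtol=1e-14)
        assert z_closed == pytest.approx(z_num, abs=1e-8)
        assert math.copysign(1.0, z_closed) == math.copysign(1.0, om)


def test_singular_strategy_scales_with_benefit_cost_and_P0():
    base = abs(singular_strategy(make_params()))
    assert abs(singular_strategy(make_params(B=4.0))) > base
    assert abs(singular_strategy(make_params(C=2.0))) < base
    assert abs(singular_strategy(make_params(P0=30.0))) > base


def test_convergence_stability():
    p = make_params()
    z_star = singular_strategy(p)
    stable, slope = convergence_check(z_star, p)
    assert stable and slope < 0
    # halving the step does not change the slope sign
    _, slope2 = convergence_check(z_star, p)
    assert math.copysign(1.0, slope) == math.copysign(1.0, slope2)
    # z = 0 is not a root when Omega != 0
    with pytest.raises(ValueError):
        convergence_check(0.0, p)
    # and selection moves away from 0 upward when Omega > 0
    om = omega(p)
    assert om > 0
    assert selection_gradient_commons(0.0, p, om) > 0
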