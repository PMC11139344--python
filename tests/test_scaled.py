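"""Scaled relatedness: lambda coefficients, kappa routes, and K."""

import numpy as np
import pytest

from kinscape import (
    K_series,
    K_statistic,
    Lattice,
    LifeCycle,
    fitness_payoff_form,
    group_convolve,
    kappa_from_definition,
    kappa_general,
    kappa_wf,
    lambda_from_fitness,
    survival_effects,
    truncated_binomial_kernel,
    uniform_kernel,
    walk_distribution,
    wf_fecundity,
)
from kinscape.effects import EnvDerivatives
from kinscape.relatedness import relatedness_table
from kinscape.scaled import K_statistic_survival, K_statistic_wf


N_RING = 5


def test_monomorphic_fitness_is_one(ring9_kernel):
    """At equal payoffs every individual exactly replaces itself."""
    for lc in (wf_fecundity(), survival_effects(0.7), LifeCycle(0.3, 0.5, 1.2, 0.8)):
        w = fitness_payoff_form(1.0, np.ones(9), ring9_kernel, N_RING, lc)
        assert w == pytest.approx(1.0, abs=1e-14)
        # also away from the reference payoff, as long as payoffs are equal
        w = fitness_payoff_form(1.3, np.full(9, 1.3), ring9_kernel, N_RING, lc)
        assert w == pytest.approx(1.0, abs=1e-12)


def test_lambda_wf_matches_analytic_differentiation(ring9, ring9_kernel):
    """Wright-Fisher competition coefficients in closed form.

    Differentiating the fitness function analytically gives
    lambda_k = (a_k - delta_k0 a_0/N) / (1 - a_0/N) with a_k the
    two-step dispersal distribution; the numeric gradient must agree.
    """
    lam = lambda_from_fitness(ring9_kernel, N_RING, wf_fecundity())
    a = group_convolve(ring9_kernel.p, ring9_kernel.p, ring9)
    expected = a / (1.0 - a[0] / N_RING)
    expected[0] = a[0] * (N_RING - 1) / N_RING / (1.0 - a[0] / N_RING)
    assert np.max(np.abs(lam - expected)) < 1e-6


def test_lambda_symmetry_and_uniform_exchangeability(ring9):
    lam = lambda_from_fitness(
        truncated_binomial_kernel(ring9, 0.5, 1.5), N_RING, wf_fecundity()
    )
    assert np.max(np.abs(lam - lam[ring9.neg_index])) < 1e-9
    lam_u = lambda_from_fitness(uniform_kernel(ring9), N_RING, wf_fecundity())
    assert np.max(np.abs(lam_u[1:] - lam_u[1])) < 1e-9


def test_kappa_wf_same_generation_constant(ring9_kernel):
    """kappa_{k,0} = -1/(DN-1): helping contemporaries is never favoured."""
    kap = kappa_wf(ring9_kernel, N_RING, 0)
    assert np.allclose(kap, -1.0 / (9 * N_RING - 1))
    assert kap.max() <= 0


def test_kappa_wf_uniform_kernel_vanishes_for_future():
    lat = Lattice([8])
    kap = kappa_wf(uniform_kernel(lat), 4, 3)
    assert np.max(np.abs(kap)) < 1e-12


def test_kappa_wf_sign_follows_walk_excess(ring9_kernel):
    for t in (1, 2, 5):
        kap = kappa_wf(ring9_kernel, N_RING, t)
        excess = walk_distribution(ring9_kernel, t) - 1.0 / 9
        assert np.all(np.sign(kap) == np.sign(excess))


def test_kappa_general_reduces_to_wf(ring9_kernel):
    for t in range(5):
        kg = kappa_general(ring9_kernel, N_RING, wf_fecundity(), t)
        assert np.max(np.abs(kg - kappa_wf(ring9_kernel, N_RING, t))) < 1e-12


def test_kappa_general_symmetry_and_survival_decay():
    """With high adult survival the genetic value of the future decays
    away from the focal patch faster than without survival."""
    lat = Lattice([31])
    ker = truncated_binomial_kernel(lat, 0.3, 1.55)
    N = 20
    lo = kappa_general(ker, N, survival_effects(0.0), 5)
    hi = kappa_general(ker, N, survival_effects(0.9), 5)
    assert np.max(np.abs(lo - lo[lat.neg_index])) < 1e-12
    assert np.max(np.abs(hi - hi[lat.neg_index])) < 1e-12
    # normalized spatial profiles: high survival concentrates genetic
    # value on the focal patch (faster decay with distance)
    lo_prof = (lo - lo.min()) / (lo[0] - lo.min())
    hi_prof = (hi - hi.min()) / (hi[0] - hi.min())
    for k in (1, 2, 3):
        assert hi_prof[k] < lo_prof[k]


@pytest.mark.parametrize(
    "lc",
    [
        wf_fecundity(),
        LifeCycle(0.0, 0.4, 1.3, 0.8),
        LifeCycle(0.0, 1.0, 1.0, 0.0),
        LifeCycle(0.0, -0.3, 0.7, 1.2),
    ],
)
@pytest.mark.parametrize("t", [0, 1, 3])
def test_kappa_definition_route_matches_closed_form(ring9_kernel, lc, t):
    """Assembling kappa from relatedness and numeric lambda reproduces the
    spectral closed form (semelparous life cycles, where the neutral
    process is Wright-Fisher)."""
    lam = lambda_from_fitness(ring9_kernel, N_RING, lc)
    R = relatedness_table(ring9_kernel, N_RING, max(t, 1))
    kd = kappa_from_definition(lam, R, N_RING, t)
    kg = kappa_general(ring9_kernel, N_RING, lc, t)
    assert np.max(np.abs(kd - kg)) < 1e-8


def test_kappa_definition_with_zero_lambda_is_relatedness(ring9, ring9_kernel):
    R = relatedness_table(ring9_kernel, N_RING, 3)
    kd = kappa_from_definition(np.zeros(ring9.D), R, N_RING, 2)
    assert np.max(np.abs(kd - R[2])) < 1e-15


def test_kappa_definition_uniform_kernel_t0_branch(ring9):
    """With a uniform kernel the t = 0 scaled relatedness still equals
    -1/(DN-1) when assembled from (zero) relatedness and uniform lambda."""
    ker = uniform_kernel(ring9)
    lam = lambda_from_fitness(ker, N_RING, wf_fecundity())
    R = relatedness_table(ker, N_RING, 2)
    kd = kappa_from_definition(lam, R, N_RING, 0)
    assert np.max(np.abs(kd - (-1.0 / (9 * N_RING - 1)))) < 1e-9


def _commons_fields(lattice, d_kernel, eps, slope, N):
    psi = slope * d_kernel.p / N
    c = (1.0 - eps) * d_kernel.p
    return EnvDerivatives(lattice, psi, c)


def test_K_zero_when_psi_zero(ring9, ring9_kernel):
    derivs = EnvDerivatives(ring9, np.zeros(ring9.D), 0.5 * ring9_kernel.p)
    K = K_statistic(
        ring9_kernel, derivs.psi_spectrum(), derivs.c_spectrum(), N_RING, wf_fecundity()
    )
    assert K == 0.0


@pytest.mark.parametrize(
    "lc",
    [wf_fecundity(), survival_effects(0.4), LifeCycle(0.2, 0.6, 1.1, 0.5)],
)
def test_K_series_oracle(ring9, ring9_kernel, lc):
    """The resolvent K equals the truncated double series over e and kappa."""
    d_ker = truncated_binomial_kernel(ring9, 0.9, 2.5)
    derivs = _commons_fields(ring9, d_ker, 0.4, 3.0, N_RING)
    K_res = K_statistic(
        ring9_kernel, derivs.psi_spectrum(), derivs.c_spectrum(), N_RING, lc
    )
    K_ser = K_series(ring9_kernel, derivs.psi, derivs.c, N_RING, lc)
    assert K_res == pytest.approx(K_ser, abs=1e-8)


def test_K_specializations_agree_with_general(ring9, ring9_kernel):
    d_ker = truncated_binomial_kernel(ring9, 0.9, 2.5)
    derivs = _commons_fields(ring9, d_ker, 0.4, 3.0, N_RING)
    Psi, C = derivs.psi_spectrum(), derivs.c_spectrum()
    K_gen = K_statistic(ring9_kernel, Psi, C, N_RING, wf_fecundity())
    assert K_statistic_wf(ring9_kernel, Psi, C, N_RING) == pytest.approx(K_gen, abs=1e-10)
    s = 0.6
    K_gen_s = K_statistic(ring9_kernel, Psi, C, N_RING, survival_effects(s))
    assert K_statistic_survival(ring9_kernel, Psi, C, N_RING, s) == pytest.approx(
        K_gen_s, abs=1e-10
    )


def test_lifecycle_validation():
    with pytest.raises(ValueError):
        LifeCycle(s=1.0, s_prime=0.1, f=1.0, f_prime=0.1)
    with pytest.raises(ValueError):
        LifeCycle(s=0.5, s_prime=0.0, f=1.0, f_prime=0.0)
    with pytest.raises(ValueError):
        LifeCycle(s=0.0, s_prime=0.0, f=-1.0, f_prime=1.0)
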