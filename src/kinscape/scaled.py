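"""Scaled relatedness: the genetic value of others in payoff units.

When fitness is mediated by a payoff function through a
survival/fecundity life cycle, the selection gradient weighs payoff
effects on the patch at displacement ``k``, ``t`` generations away, by a
*scaled* relatedness coefficient ``kappa_{k,t}``: plain relatedness
discounted by the kin competition that a payoff increase in that patch
induces.  Two computational routes are provided and must agree:

* the definition route, assembling ``kappa`` from relatedness ``R`` and
  the numerically differentiated fitness-interdependence coefficients
  ``lambda_k``; and
* the closed spectral form for the survival/fecundity life cycle, which
  only needs the dispersal characteristic function and the four scalars
  ``(s, s', f, f')`` of the life cycle at the resident payoff.

The module also computes the scalar ``K`` summarizing selection on
environmentally mediated interactions under local payoffs, both as a
frequency-domain resolvent sum and as the (truncated) double series
``sum_t sum_k e_{k,t} kappa_{k,t}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Kernel
from .lattice import group_convolve, inverse_transform
from .relatedness import RelatednessTable, _mixing_spectrum, walk_distribution

__all__ = [
    "LifeCycle",
    "wf_fecundity",
    "survival_effects",
    "fitness_payoff_form",
    "lambda_from_fitness",
    "kappa_wf",
    "kappa_general",
    "kappa_from_definition",
    "K_statistic",
    "K_series",
]


class DegenerateLifeCycleError(ArithmeticError):
    """Life-cycle parameters make a scaled-relatedness denominator vanish."""


class IllConditionedError(ArithmeticError):
    """Numerical differentiation of the fitness function is unreliable."""


class DivergentSeriesError(ArithmeticError):
    """A spectral radius condition fails and the series for K diverges."""


@dataclass(frozen=True)
class LifeCycle:
    """Survival and fecundity, and their payoff derivatives, at the resident.

    Attributes
    ----------
    s : baseline survival probability, in [0, 1).
    s_prime : derivative of survival with respect to payoff.
    f : baseline fecundity (> 0).
    f_prime : derivative of fecundity with respect to payoff.
    """

    s: float
    s_prime: float
    f: float
    f_prime: float

    def __post_init__(self):
        if not 0.0 <= self.s < 1.0:
            raise ValueError(f"baseline survival s={self.s} must be in [0, 1)")
        if self.f <= 0.0:
            raise ValueError(f"baseline fecundity f={self.f} must be positive")
        if self.s_prime == 0.0 and self.f_prime == 0.0:
            raise ValueError("payoff must affect survival or fecundity")

    @property
    def is_wf_fecundity(self) -> bool:
        return self.s == 0.0 and self.s_prime == 0.0


def wf_fecundity() -> LifeCycle:
    """Wright-Fisher process with payoff acting directly as fecundity."""
    return LifeCycle(s=0.0, s_prime=0.0, f=1.0, f_prime=1.0)


def survival_effects(s: float) -> LifeCycle:
    """Iteroparous life cycle where payoff affects only survival
    (birth-death updating) with baseline survival ``s``."""
    return LifeCycle(s=s, s_prime=1.0, f=1.0, f_prime=0.0)


# ---------------------------------------------------------------------------
# The survival/fecundity fitness function and its payoff derivatives
# ---------------------------------------------------------------------------

def fitness_payoff_form(
    pi_focal: float,
    pi_field: np.ndarray,
    kernel: Kernel,
    N: int,
    lc: LifeCycle,
) -> float:
    """Expected number of successful offspring of the focal individual.

    ``pi_field[k]`` is the average payoff of individuals in the patch at
    displacement ``k`` (at ``k = 0``, the average over the focal's patch
    neighbours, excluding the focal itself).  Survival and fecundity are
    the local linearizations ``s + s'(pi - 1)`` and ``f + f'(pi - 1)``
    around the resident payoff (normalized to 1), which is exact for the
    first-order selection analysis.  In a monomorphic resident population
    at equal payoffs the function returns exactly 1.
    """
    lattice = kernel.lattice
    pi_field = lattice.check_field(np.asarray(pi_field, dtype=float))
    s_of = lambda pi: lc.s + lc.s_prime * (pi - 1.0)
    f_of = lambda pi: lc.f + lc.f_prime * (pi - 1.0)

    s_focal = s_of(pi_focal)
    f_focal = f_of(pi_focal)
    sR = s_of(pi_field)
    fR = f_of(pi_field)
    # patch averages in the focal patch include the focal individual
    sR = sR.copy()
    fR = fR.copy()
    sR[0] = s_focal / N + (N - 1) * s_of(pi_field[0]) / N
    fR[0] = f_focal / N + (N - 1) * f_of(pi_field[0]) / N

    competition = group_convolve(fR, kernel.p, lattice)
    if np.any(np.abs(competition) < 1e-14):
        raise ZeroDivisionError("zero local competition for breeding spots")
    w = s_focal + float(np.sum(kernel.p * (1.0 - sR) * f_focal / competition))
    return w


def lambda_from_fitness(kernel: Kernel, N: int, lc: LifeCycle) -> np.ndarray:
    """Fitness-interdependence coefficients ``lambda_k`` by central differences.

    ``lambda_k = -(dw/dpi_k) / (dw/dpi_focal)`` at the resident point
    where every payoff equals 1 (and fitness equals 1).  When positive,
    ``lambda_k`` measures the strength of competition exerted on the
    focal individual by a payoff increase at displacement ``k``.  A
    Richardson step-halving check guards against ill conditioning.
    """
    lattice = kernel.lattice

    def gradient(step: float) -> np.ndarray:
        base = np.ones(lattice.D)
        dw = np.empty(lattice.D + 1)
        w_plus = fitness_payoff_form(1.0 + step, base, kernel, N, lc)
        w_minus = fitness_payoff_form(1.0 - step, base, kernel, N, lc)
        dw[0] = (w_plus - w_minus) / (2 * step)
        for k in range(lattice.D):
            pert = base.copy()
            pert[k] = 1.0 + step
            w_plus = fitness_payoff_form(1.0, pert, kernel, N, lc)
            pert[k] = 1.0 - step
            w_minus = fitness_payoff_form(1.0, pert, kernel, N, lc)
            dw[k + 1] = (w_plus - w_minus) / (2 * step)
        if abs(dw[0]) < 1e-10:
            raise IllConditionedError(
                "fitness is insensitive to the focal individual's own payoff"
            )
        return -dw[1:] / dw[0]

    step = 1e-5 * 2.0  # 1e-5 * (1 + |pi|) at pi = 1
    lam = gradient(step)
    lam_check = gradient(2 * step)
    if np.max(np.abs(lam - lam_check)) > 1e-6 * (1.0 + np.max(np.abs(lam))):
        raise IllConditionedError("lambda gradient fails the step-halving check")
    return lam


# ---------------------------------------------------------------------------
# Scaled relatedness
# ---------------------------------------------------------------------------

def kappa_wf(kernel: Kernel, N: int, t: int) -> np.ndarray:
    """Scaled relatedness under the Wright-Fisher process.

    ``kappa_{k,0} = -1/(DN - 1)`` for every ``k`` (helping contemporaries
    is never favoured), and for ``t >= 1``
    ``kappa_{k,t} = D (p_{k,t} - 1/D) / (DN - 1)`` where ``p_{k,t}`` is
    the neutral gene random walk.
    """
    if N < 1:
        raise ValueError(f"patch size N={N} must be >= 1")
    if t < 0:
        raise ValueError(f"temporal distance t={t} must be >= 0")
    lattice = kernel.lattice
    D = lattice.D
    if D * N < 2:
        raise ValueError("DN must be at least 2")
    if t == 0:
        return np.full(D, -1.0 / (D * N - 1))
    p = walk_distribution(kernel, t)
    return D * (p - 1.0 / D) / (D * N - 1)


def kappa_general(kernel: Kernel, N: int, lc: LifeCycle, t: int) -> np.ndarray:
    """Scaled relatedness for a general survival/fecundity life cycle.

    Closed spectral form in terms of the dispersal characteristic
    function ``M(h)`` and the life-cycle scalars; reduces to
    :func:`kappa_wf` when ``s = s' = 0`` and ``f' = 1``.
    """
    if t < 0:
        raise ValueError(f"temporal distance t={t} must be >= 0")
    lattice = kernel.lattice
    D = lattice.D
    M = _mixing_spectrum(kernel)
    s, sp, f, fp = lc.s, lc.s_prime, lc.f, lc.f_prime

    shared = 1.0 + s + (1.0 - s) * M
    F = -(1.0 - s) * (sp * f - 2.0 * fp * s) * M / shared
    g0 = (1.0 + s) * (sp * f + 2.0 * fp * (1.0 - s)) / 2.0
    L_F = inverse_transform(F.astype(complex), lattice)
    denom = N * (sp * f + fp * (1.0 - s)) + L_F[0] - g0 / D
    if abs(denom) < 1e-12:
        raise DegenerateLifeCycleError(
            "scaled-relatedness denominator vanishes for this life cycle"
        )
    if t == 0:
        return (L_F - g0 / D) / denom
    Mtilde = s + (1.0 - s) * M
    G_t = (
        (1.0 + s)
        * (sp * f + fp * (1.0 - s) * (1.0 + M))
        * Mtilde**t
        / shared
    )
    L_G = inverse_transform(G_t.astype(complex), lattice)
    return (L_G - g0 / D) / denom


def kappa_from_definition(
    lambda_field: np.ndarray,
    relatedness: RelatednessTable,
    N: int,
    t: int,
) -> np.ndarray:
    """Assemble scaled relatedness from its definition.

    Combines relatedness ``R_{k,t}`` with the competition coefficients
    ``lambda_k`` (three branches: same generation same patch, same
    generation other patch, and past generations).  Serves as the
    independent cross-check of :func:`kappa_general`.
    """
    lattice = relatedness.lattice
    lam = lattice.check_field(np.asarray(lambda_field, dtype=float))
    R0 = relatedness[0]
    denom = 1.0 - float(np.sum(lam * R0))
    if abs(denom) < 1e-12:
        raise DegenerateLifeCycleError("1 - sum_j lambda_j R_{j,0} vanishes")

    # R_shift[j, k] = R_{j-k}
    def shifted_sum(R: np.ndarray) -> np.ndarray:
        return np.einsum("j,jk->k", lam, R[lattice.sub_index])

    if t == 0:
        if N < 2:
            raise ValueError("the t = 0 branches require N >= 2")
        out = np.empty(lattice.D)
        full = shifted_sum(R0)  # sum_j lambda_j R_{j-k,0} including j = k
        # k = 0 branch
        out[0] = (
            R0[0]
            - lam[0] * (1.0 / (N - 1) + (N - 2) / (N - 1) * R0[0])
            - (float(np.sum(lam * R0)) - lam[0] * R0[0])
        ) / denom
        # k != 0 branch: subtract the j = k term (R_{0,0}) then the lambda_k part
        k_idx = np.arange(1, lattice.D)
        out[1:] = (
            R0[k_idx]
            - lam[k_idx] * (1.0 / N + (N - 1) / N * R0[0])
            - (full[k_idx] - lam[k_idx] * R0[0])
        ) / denom
        return out
    Rt = relatedness[t]
    return (Rt - shifted_sum(Rt)) / denom


# ---------------------------------------------------------------------------
# The K statistic
# ---------------------------------------------------------------------------

def _check_spectral(M: np.ndarray, C_neg: np.ndarray) -> None:
    prod = np.abs(C_neg[1:] * M[1:])
    if prod.size and prod.max() >= 1.0 - 1e-12:
        raise DivergentSeriesError(
            f"spectral radius |C(h)M(h)| = {prod.max():.6f} >= 1: the"
            " environmental feedback series diverges"
        )
    if np.any(np.abs(1.0 - C_neg[1:]) < 1e-12):
        raise DivergentSeriesError("1 - C(h) vanishes at a nonzero frequency")


def K_statistic(
    m_kernel: Kernel,
    psi_spectrum: np.ndarray,
    c_spectrum: np.ndarray,
    N: int,
    lc: LifeCycle,
) -> float:
    """Selection summary ``K`` for local payoffs, resolvent route.

    ``K = sum_t sum_k e_{k,t} kappa_{k,t}`` evaluated in the frequency
    domain, given the spectra of the one-generation environmental effect
    fields ``psi`` and ``c``.  Positive ``K`` means selection favours
    trait values that improve the environment for the future.
    """
    lattice = m_kernel.lattice
    D = lattice.D
    M = _mixing_spectrum(m_kernel)
    Psi = lattice.check_field(np.asarray(psi_spectrum, dtype=complex))
    C = lattice.check_field(np.asarray(c_spectrum, dtype=complex))
    neg = lattice.neg_index
    C_neg = C[neg]
    Psi_neg = Psi[neg]
    s, sp, f, fp = lc.s, lc.s_prime, lc.f, lc.f_prime
    shared = 1.0 + s + (1.0 - s) * M
    Mtilde = s + (1.0 - s) * M  # backward lineage-movement spectrum
    _check_spectral(Mtilde, C_neg)
    H = (D * N - 1) * (sp * f + fp * (1.0 - s)) - float(
        np.sum((1.0 - s) * (sp * f - 2.0 * fp * s) * M[1:] / shared[1:])
    )
    if abs(H) < 1e-14:
        raise DegenerateLifeCycleError("normalization H vanishes")
    num = (
        (1.0 + s)
        * (sp * f + fp * (1.0 - s) * (1.0 + M[1:]))
        * Mtilde[1:]
        * Psi_neg[1:]
    )
    den = shared[1:] * (1.0 - C_neg[1:] * Mtilde[1:])
    total = np.sum(num / den) / H
    if abs(total.imag) > 1e-9 * (1.0 + abs(total.real)):
        raise ArithmeticError(f"K has imaginary residue {total.imag:.3e}")
    return float(total.real)


def K_statistic_wf(
    m_kernel: Kernel, psi_spectrum: np.ndarray, c_spectrum: np.ndarray, N: int
) -> float:
    """``K`` specialized to Wright-Fisher fecundity effects (s = s' = 0)."""
    lattice = m_kernel.lattice
    M = _mixing_spectrum(m_kernel)
    neg = lattice.neg_index
    C_neg = np.asarray(c_spectrum, dtype=complex)[neg]
    Psi_neg = np.asarray(psi_spectrum, dtype=complex)[neg]
    _check_spectral(M, C_neg)
    total = np.sum(M[1:] * Psi_neg[1:] / (1.0 - C_neg[1:] * M[1:])) / (
        lattice.D * N - 1
    )
    return float(total.real)


def K_statistic_survival(
    m_kernel: Kernel,
    psi_spectrum: np.ndarray,
    c_spectrum: np.ndarray,
    N: int,
    s: float,
) -> float:
    """``K`` specialized to survival effects (f' = 0) with baseline ``s``."""
    lattice = m_kernel.lattice
    D = lattice.D
    M = _mixing_spectrum(m_kernel)
    neg = lattice.neg_index
    C_neg = np.asarray(c_spectrum, dtype=complex)[neg]
    Psi_neg = np.asarray(psi_spectrum, dtype=complex)[neg]
    _check_spectral(s + (1.0 - s) * M, C_neg)
    shared = 1.0 + s + (1.0 - s) * M[1:]
    Mtilde = s + (1.0 - s) * M[1:]
    H = (D * N - 1) - float(np.sum((1.0 - s) * M[1:] / shared))
    num = (1.0 + s) * Mtilde * Psi_neg[1:]
    den = shared * (1.0 - C_neg[1:] * Mtilde)
    total = np.sum(num / den) / H
    return float(total.real)


def K_series(
    m_kernel: Kernel,
    psi: np.ndarray,
    c: np.ndarray,
    N: int,
    lc: LifeCycle,
    tol: float = 1e-12,
    max_terms: int = 100_000,
) -> float:
    """Time-domain series ``sum_t sum_k e_{k,t} kappa_{k,t}`` for ``K``.

    Independent oracle for :func:`K_statistic`: extended effects are
    built by the spectral recursion and scaled relatedness by the closed
    form, with the sum truncated once a geometric tail bound (ratio
    ``max_h |C(h) M~(h)|``) falls below ``tol`` of the partial sum.
    """
    from .lattice import fourier_transform

    lattice = m_kernel.lattice
    M = _mixing_spectrum(m_kernel)
    Psi = fourier_transform(np.asarray(psi, float), lattice)
    C = fourier_transform(np.asarray(c, float), lattice)
    Mtilde = lc.s + (1.0 - lc.s) * M
    ratio = float(np.max(np.abs(C[1:] * Mtilde[1:]))) if lattice.D > 1 else 0.0
    if ratio >= 1.0:
        raise DivergentSeriesError("series ratio >= 1")

    total = 0.0
    E_t = Psi.copy()  # spectrum of e_{k,t} at t = 1
    t = 0
    while t < max_terms:
        t += 1
        if t > 1:
            E_t = E_t * C
        e_t = inverse_transform(E_t, lattice)
        kap = kappa_general(m_kernel, N, lc, t)
        term = float(np.sum(e_t * kap))
        total += term
        tail = abs(term) * ratio / (1.0 - ratio) if ratio > 0 else 0.0
        if t > 1 and tail <= tol * max(abs(total), 1e-300):
            break
    return total
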