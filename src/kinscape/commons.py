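"""The lasting-commons model: inter-temporal helping and harming.

Individuals pay an immediate payoff cost ``exp(-C z^alpha_C)`` to
produce (or destroy, for ``z < 0``) a durable environmental commons.
Each generation the commons is produced locally at rate ``P(z-bar)``,
moves between patches with kernel ``d_k``, and decays at rate
``epsilon``; the local commons level multiplies payoff through
``exp(B n^alpha_B)``.  With ``alpha_B`` odd and ``alpha_C`` even
(``alpha_C > alpha_B``) the model admits a single convergence-stable
singular trait value

    z* = [ (B/C) (alpha_B/alpha_C) (P0/epsilon)^alpha_B Omega ]^(1/(alpha_C - alpha_B)),

whose sign is the sign of ``Omega`` — the expected genetic value, in
payoff units, of the future individuals reached by a unit of commons
produced in the focal patch.  ``Omega > 0`` selects for a common good
(posthumous altruism), ``Omega < 0`` for a common bad (posthumous
spite).  ``Omega`` is computed by four mutually consistent routes
(resolvent closed form, kappa-weighted series, random-walk covariance
under Wright-Fisher fecundity, and a weak-dispersal limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .effects import EnvDerivatives, ExtendedEffectTable
from .kernels import Kernel, kernel_spectrum
from .lattice import Lattice
from .relatedness import _mixing_spectrum, walk_distribution
from .scaled import (
    DivergentSeriesError,
    LifeCycle,
    K_statistic,
    kappa_general,
    wf_fecundity,
)

__all__ = [
    "CommonsParams",
    "payoff",
    "log_payoff",
    "env_equilibrium",
    "commons_effect_fields",
    "commons_extended_effects",
    "omega",
    "selection_gradient_commons",
    "singular_strategy",
    "convergence_check",
]

OMEGA_METHODS = ("closed_form", "series", "covariance_wf", "weak_dispersal")


class MethodContractError(ValueError):
    """An Omega method was requested for an incompatible life cycle."""


@dataclass(frozen=True)
class CommonsParams:
    """Full parameterization of the lasting-commons model.

    ``production`` may override the linear production function
    ``P(z) = P0 * z``; it must satisfy ``P(0) = 0`` and ``P' > 0``.
    """

    lattice: Lattice
    N: int
    m_kernel: Kernel
    d_kernel: Kernel
    B: float
    C: float
    alpha_B: int
    alpha_C: int
    epsilon: float
    P0: float
    lifecycle: LifeCycle = dc_field(default_factory=wf_fecundity)
    production: Optional[Callable[[float], float]] = None
    production_slope: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.B <= 0 or self.C <= 0:
            raise ValueError("payoff coefficients B and C must be positive")
        if self.alpha_B < 1 or self.alpha_B % 2 != 1:
            raise ValueError(f"alpha_B={self.alpha_B} must be a positive odd integer")
        if self.alpha_C < 2 or self.alpha_C % 2 != 0:
            raise ValueError(f"alpha_C={self.alpha_C} must be a positive even integer")
        if self.alpha_C <= self.alpha_B:
            raise ValueError("costs must rise faster than benefits: alpha_C > alpha_B")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError(f"decay rate epsilon={self.epsilon} must be in (0, 1]")
        if self.P0 <= 0:
            raise ValueError(f"production slope P0={self.P0} must be positive")
        if self.N < 1:
            raise ValueError("patch size N must be >= 1")

    def P(self, z: float) -> float:
        if self.production is not None:
            return float(self.production(z))
        return self.P0 * z

    def P_prime(self, z: float) -> float:
        if self.production is not None:
            if self.production_slope is not None:
                return float(self.production_slope(z))
            h = 1e-6 * (1.0 + abs(z))
            return (self.production(z + h) - self.production(z - h)) / (2 * h)
        return self.P0


def log_payoff(z_self: float, n_local: float, p: CommonsParams) -> float:
    """``B n^alpha_B - C z^alpha_C``: log of the individual payoff."""
    return p.B * n_local**p.alpha_B - p.C * z_self**p.alpha_C


def payoff(z_self: float, n_local: float, p: CommonsParams) -> float:
    """Individual payoff ``exp(B n^alpha_B - C z^alpha_C)`` (> 0)."""
    return math.exp(log_payoff(z_self, n_local, p))


def env_equilibrium(z: float, p: CommonsParams) -> float:
    """Monomorphic commons equilibrium ``n-hat = P(z)/epsilon``."""
    return p.P(z) / p.epsilon


def environmental_map(z_field: np.ndarray, n_field: np.ndarray, p: CommonsParams) -> float:
    """Next-generation commons level of the focal patch.

    ``sum_k d_k ( (1 - eps) n_k + P(z-bar_k) )``: local production from
    patch-average traits, movement by the ``d`` kernel, decay at rate
    ``epsilon``.
    """
    produced = np.array([p.P(z) for z in np.asarray(z_field, float)])
    stock = (1.0 - p.epsilon) * np.asarray(n_field, float) + produced
    return float(np.sum(p.d_kernel.p * stock))


def commons_effect_fields(z: float, p: CommonsParams) -> EnvDerivatives:
    """Analytic one-generation effect fields of the commons map.

    ``psi_k = P'(z) d_k / N`` and ``c_k = (1 - epsilon) d_k``.
    """
    psi = p.P_prime(z) * p.d_kernel.p / p.N
    c = (1.0 - p.epsilon) * p.d_kernel.p
    return EnvDerivatives(p.lattice, psi, c)


def commons_extended_effects(z: float, p: CommonsParams, t_max: int) -> ExtendedEffectTable:
    """``e_{k,t} = (P'(z)/N) (1 - eps)^{t-1} q_{k,t}`` with ``q`` the
    commons random walk driven by the movement kernel."""
    if t_max < 1:
        raise ValueError(f"t_max={t_max} must be >= 1")
    entries = [np.zeros(p.lattice.D)]
    slope = p.P_prime(z) / p.N
    for t in range(1, t_max + 1):
        q = walk_distribution(p.d_kernel, t)
        entries.append(slope * (1.0 - p.epsilon) ** (t - 1) * q)
    return ExtendedEffectTable(p.lattice, tuple(entries))


# ---------------------------------------------------------------------------
# Omega
# ---------------------------------------------------------------------------

def _series_horizon(epsilon: float, tol: float = 1e-12, cap: int = 100_000) -> int:
    if epsilon >= 1.0:
        return 1
    T = 1 + int(math.ceil(math.log(tol) / math.log(1.0 - epsilon)))
    return min(max(T, 2), cap)


def omega(p: CommonsParams, method: str = "closed_form") -> float:
    """Expected genetic value ``Omega`` of a unit of commons, in payoff units.

    Methods
    -------
    closed_form
        Frequency-domain resolvent sum; under Wright-Fisher fecundity
        ``Omega = eps/(DN-1) sum_{h!=0} D(-h)M(h)/(1-(1-eps)D(-h)M(h))``,
        otherwise via ``Omega = eps K N / P'`` with the general ``K``.
    series
        Truncated time series ``sum_t sum_k eps (1-eps)^{t-1} kappa_{k,t} q_{k,t}``.
    covariance_wf
        Wright-Fisher fecundity only: decay-discounted covariance between
        the gene and commons random walks.
    weak_dispersal
        First-order expansion in the movement probabilities ``m`` and
        ``d``; positive whenever both are sufficiently small.
    """
    if method not in OMEGA_METHODS:
        raise MethodContractError(f"unknown Omega method {method!r}")
    lattice = p.lattice
    D = lattice.D
    M = _mixing_spectrum(p.m_kernel)
    Dspec = kernel_spectrum(p.d_kernel)
    neg = lattice.neg_index
    D_neg = Dspec[neg]
    lc = p.lifecycle

    if method == "closed_form":
        if lc.is_wf_fecundity:
            terms = D_neg[1:] * M[1:] / (1.0 - (1.0 - p.epsilon) * D_neg[1:] * M[1:])
            if np.any(np.abs(1.0 - (1.0 - p.epsilon) * D_neg[1:] * M[1:]) < 1e-12):
                raise DivergentSeriesError("resolvent denominator vanishes")
            return float(p.epsilon * np.sum(terms) / (D * p.N - 1))
        derivs = commons_effect_fields(0.0, p)
        K = K_statistic(
            p.m_kernel, derivs.psi_spectrum(), derivs.c_spectrum(), p.N, lc
        )
        return p.epsilon * K * p.N / p.P_prime(0.0)

    if method == "series":
        T = _series_horizon(p.epsilon)
        total = 0.0
        for t in range(1, T + 1):
            q = walk_distribution(p.d_kernel, t)
            kap = kappa_general(p.m_kernel, p.N, lc, t)
            total += p.epsilon * (1.0 - p.epsilon) ** (t - 1) * float(np.sum(kap * q))
        return total

    if method == "covariance_wf":
        if not lc.is_wf_fecundity:
            raise MethodContractError(
                "the covariance form of Omega holds only for Wright-Fisher"
                " fecundity effects"
            )
        T = _series_horizon(p.epsilon)
        total = 0.0
        for t in range(1, T + 1):
            pt = walk_distribution(p.m_kernel, t)
            qt = walk_distribution(p.d_kernel, t)
            cov = float(np.mean(pt * qt) - np.mean(pt) * np.mean(qt))
            total += (1.0 - p.epsilon) ** (t - 1) * cov
        return p.epsilon * D**2 * total / (D * p.N - 1)

    # weak_dispersal
    m = p.m_kernel.move_probability
    d = p.d_kernel.move_probability
    return float(
        (D - 1) / (D * p.N - 1) - (m + d) * D / (p.epsilon * (D * p.N - 1))
    )


def selection_gradient_commons(z: float, p: CommonsParams, omega_value: float | None = None) -> float:
    """Selection gradient of the commons model, up to a positive constant.

    ``-C alpha_C z^(alpha_C - 1) + Omega B alpha_B (P'(z)/eps) (P(z)/eps)^(alpha_B - 1)``.
    """
    if omega_value is None:
        omega_value = omega(p, "closed_form")
    cost = -p.C * p.alpha_C * z ** (p.alpha_C - 1)
    benefit = (
        omega_value
        * p.B
        * p.alpha_B
        * (p.P_prime(z) / p.epsilon)
        * (p.P(z) / p.epsilon) ** (p.alpha_B - 1)
    )
    return cost + benefit


def singular_strategy(p: CommonsParams, omega_value: float | None = None) -> float:
    """Convergence-stable singular trait value ``z*``.

    Closed form for linear production ``P(z) = P0 z``; the exponent
    ``1/(alpha_C - alpha_B)`` is taken as an odd real root when the
    argument is negative (spite), which requires ``alpha_C - alpha_B``
    odd; a numeric root of the gradient is used for non-linear
    production.
    """
    if omega_value is None:
        omega_value = omega(p, "closed_form")
    if p.production is not None:
        return _numeric_root(p, omega_value)
    arg = (
        (p.B / p.C)
        * (p.alpha_B / p.alpha_C)
        * (p.P0 / p.epsilon) ** p.alpha_B
        * omega_value
    )
    root_order = p.alpha_C - p.alpha_B
    if arg < 0 and root_order % 2 == 0:
        raise ValueError(
            "negative root argument with even alpha_C - alpha_B: no real"
            " singular strategy"
        )
    return math.copysign(abs(arg) ** (1.0 / root_order), arg)


def _numeric_root(p: CommonsParams, omega_value: float) -> float:
    g = lambda z: selection_gradient_commons(z, p, omega_value)
    if omega_value == 0.0:
        return 0.0
    lo, hi = (0.0, 1.0) if omega_value > 0 else (-1.0, 0.0)
    # expand the bracket until the gradient changes sign
    for _ in range(200):
        if g(lo) * g(hi) <= 0:
            break
        lo, hi = lo * 2 - (omega_value < 0), hi * 2 + (omega_value > 0)
    return brentq(g, lo, hi, xtol=1e-12)


def convergence_check(
    z_star: float,
    p: CommonsParams,
    omega_value: float | None = None,
    root_tol: float = 1e-6,
) -> tuple[bool, float]:
    """Convergence stability at ``z_star``: gradient slope by central
    differences; returns ``(slope < 0, slope)``."""
    if omega_value is None:
        omega_value = omega(p, "closed_form")
    g0 = selection_gradient_commons(z_star, p, omega_value)
    scale = max(abs(p.C * p.alpha_C * z_star ** (p.alpha_C - 1)), abs(omega_value), 1e-12)
    if abs(g0) > root_tol * (1.0 + scale):
        raise ValueError(f"z={z_star} is not a root of the gradient (s={g0:.3e})")
    h = 1e-5 * (1.0 + abs(z_star))
    slope = (
        selection_gradient_commons(z_star + h, p, omega_value)
        - selection_gradient_commons(z_star - h, p, omega_value)
    ) / (2 * h)
    return slope < 0, slope
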