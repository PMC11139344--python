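"""Dispersal and commons-movement kernels on the patch lattice.

A kernel assigns to every displacement ``k`` the probability that an
offspring (dispersal kernel ``m_k``) or a unit of the environmental
commons (movement kernel ``d_k``) ends up in a patch at distance ``k``
from where it originated.  Kernels are probability distributions on the
group of patches and are spatially symmetric, ``m_k = m_{-k}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .lattice import Lattice, fourier_transform

__all__ = [
    "Kernel",
    "uniform_kernel",
    "island_kernel",
    "truncated_binomial_kernel",
    "validate_kernel",
    "kernel_spectrum",
]

SUM_TOL = 1e-10
SYM_TOL = 1e-12
NEG_TOL = 1e-12


class KernelValidationError(ValueError):
    """Kernel field violates the simplex or symmetry invariants."""


class KernelParameterError(ValueError):
    """Kernel constructor parameters are out of range or infeasible."""


@dataclass(frozen=True)
class Kernel:
    """A symmetric probability distribution on the patch group."""

    lattice: Lattice
    p: np.ndarray

    @property
    def stay_probability(self) -> float:
        """Probability of remaining at displacement 0."""
        return float(self.p[0])

    @property
    def move_probability(self) -> float:
        """Probability of leaving the patch of origin."""
        return 1.0 - self.stay_probability

    def spectrum(self) -> np.ndarray:
        return kernel_spectrum(self)


def validate_kernel(field: np.ndarray, lattice: Lattice) -> Kernel:
    """Check the simplex and symmetry invariants and wrap the field.

    Tiny negative round-off (above ``-1e-12``) is clipped to zero and the
    field renormalized; genuine violations raise
    :class:`KernelValidationError` naming the broken invariant.
    """
    p = np.asarray(lattice.check_field(field), dtype=float).copy()
    if np.min(p) < -NEG_TOL:
        raise KernelValidationError(
            f"negative probability mass {np.min(p):.3e} at displacement "
            f"{lattice.coords_of(int(np.argmin(p)))}"
        )
    total = p.sum()
    if abs(total - 1.0) > SUM_TOL:
        raise KernelValidationError(f"probabilities sum to {total!r}, not 1")
    asym = np.max(np.abs(p - p[lattice.neg_index]))
    if asym > SYM_TOL:
        raise KernelValidationError(
            f"kernel is asymmetric: max |p_k - p_-k| = {asym:.3e}"
        )
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return Kernel(lattice, p)


def uniform_kernel(lattice: Lattice) -> Kernel:
    """Panmictic kernel ``m_k = 1/D`` for all ``k``."""
    return Kernel(lattice, np.full(lattice.D, 1.0 / lattice.D))


def island_kernel(lattice: Lattice, m: float) -> Kernel:
    """Island-model kernel: stay with probability ``1 - m``, otherwise any
    of the ``D - 1`` other patches uniformly."""
    if not 0.0 < m < 1.0:
        raise KernelParameterError(f"island migration rate m={m} not in (0, 1)")
    if lattice.D < 2:
        raise KernelParameterError("island kernel needs at least two patches")
    p = np.full(lattice.D, m / (lattice.D - 1))
    p[0] = 1.0 - m
    return Kernel(lattice, p)


def truncated_binomial_kernel(
    lattice: Lattice, move_prob: float, mean_distance: float
) -> Kernel:
    """Kernel with binomially distributed movement distance.

    With probability ``1 - move_prob`` no movement occurs.  Conditional on
    moving, the minimal-image Manhattan distance ``r`` follows a binomial
    distribution with index ``r_max`` (the largest Manhattan norm on the
    torus) truncated to ``1 <= r <= r_max``, whose success probability is
    solved numerically so the conditional mean distance equals
    ``mean_distance``.  Mass at distance ``r`` is divided equally among
    all displacement vectors of minimal-image Manhattan norm ``r``, which
    makes the kernel exactly symmetric.
    """
    if not 0.0 <= move_prob <= 1.0:
        raise KernelParameterError(f"move_prob={move_prob} not in [0, 1]")
    p = np.zeros(lattice.D)
    if move_prob == 0.0:
        p[0] = 1.0
        return Kernel(lattice, p)

    norms = lattice.manhattan
    r_max = int(norms.max())
    if r_max < 1:
        raise KernelParameterError("lattice has a single patch; cannot move")
    if not 1.0 < mean_distance < r_max:
        raise KernelParameterError(
            f"mean_distance={mean_distance} infeasible: must lie strictly "
            f"between 1 and the maximum Manhattan distance {r_max}"
        )
    prob = _solve_truncated_binomial(r_max, mean_distance)
    pmf = binom.pmf(np.arange(1, r_max + 1), r_max, prob)
    pmf /= pmf.sum()
    counts = np.bincount(norms, minlength=r_max + 1)
    p[0] = 1.0 - move_prob
    for r in range(1, r_max + 1):
        sel = norms == r
        p[sel] += move_prob * pmf[r - 1] / counts[r]
    return validate_kernel(p, lattice)


def _truncated_mean(n: int, prob: float) -> float:
    r = np.arange(1, n + 1)
    pmf = binom.pmf(r, n, prob)
    total = pmf.sum()
    if total == 0.0:
        return float(n)
    return float((r * pmf).sum() / total)


def _solve_truncated_binomial(r_max: int, target_mean: float) -> float:
    """Success probability of Binomial(r_max, p) | 1 <= r <= r_max with the
    requested conditional mean; the mean is monotone in p."""
    lo, hi = 1e-12, 1.0 - 1e-12
    f = lambda q: _truncated_mean(r_max, q) - target_mean
    if f(lo) > 0 or f(hi) < 0:
        raise KernelParameterError(
            f"mean distance {target_mean} unattainable with r_max={r_max}"
        )
    return brentq(f, lo, hi, xtol=1e-14)


def kernel_spectrum(kernel: Kernel) -> np.ndarray:
    """Characteristic function of the kernel (real, 1 at ``h = 0``).

    For a symmetric probability kernel the transform is real with
    ``|M(h)| <= 1`` everywhere and equality at the origin.
    """
    F = fourier_transform(kernel.p, kernel.lattice)
    return F.real
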