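"""Neutral gene-lineage random walks and Wright-Fisher relatedness.

Under neutrality a gene lineage performs a random walk on the patch
group with step distribution given by the dispersal kernel.  The
relatedness ``R_{k,t}`` between a focal individual and a random
individual in the patch at displacement ``k``, ``t`` generations apart,
measures the excess probability (relative to the population average) of
sharing an allele identical by descent.  For the Wright-Fisher life
cycle (no adult survival, semelparous reproduction) it admits the
closed spectral form

    R_{k,t} = (1/(D*N + M)) * sum_{h != 0} M(h)^t / (1 - M(h)^2) * conj(chi_k(h)),

with ``M = sum_{h != 0} M(h)^2 / (1 - M(h)^2)`` and ``M(h)`` the
characteristic function of the dispersal kernel.  Same-generation
relatedness is obtained by evaluating the formula at ``t = 2``
(``R_{k,0} = R_{k,2}`` holds for every ``k``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Kernel, kernel_spectrum
from .lattice import Lattice, inverse_transform

__all__ = ["RelatednessTable", "walk_distribution", "relatedness_wf"]

MIXING_TOL = 1e-12


class NonMixingKernelError(ValueError):
    """Some frequency has |M(h)| = 1 off the origin: parts of the lattice
    never mix and the relatedness series diverges."""


@dataclass(frozen=True)
class RelatednessTable:
    """Relatedness fields ``R_{k,t}`` for ``t = 0..t_max``.

    ``entries[t]`` is the spatial field at temporal distance ``t``.
    """

    lattice: Lattice
    entries: tuple[np.ndarray, ...]

    @property
    def t_max(self) -> int:
        return len(self.entries) - 1

    def __getitem__(self, t: int) -> np.ndarray:
        return self.entries[t]


def _mixing_spectrum(kernel: Kernel) -> np.ndarray:
    M = kernel_spectrum(kernel)
    if np.max(np.abs(M[1:])) >= 1.0 - MIXING_TOL:
        h = kernel.lattice.coords_of(int(np.argmax(np.abs(M[1:]))) + 1)
        raise NonMixingKernelError(
            f"|M(h)| = 1 at frequency {h}; dispersal kernel does not mix"
        )
    return M


def walk_distribution(kernel: Kernel, t: int) -> np.ndarray:
    """Distribution ``p_{k,t} = L_k(M^t)`` of a ``t``-step dispersal walk.

    Equals the ``t``-fold group convolution of the kernel with itself.
    """
    if t < 1:
        raise ValueError(f"walk length t={t} must be >= 1")
    lattice = kernel.lattice
    M = kernel_spectrum(kernel)
    p = inverse_transform((M.astype(complex)) ** t, lattice)
    # exact non-negativity up to round-off
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def relatedness_wf(kernel: Kernel, N: int, t: int) -> np.ndarray:
    """Wright-Fisher relatedness field ``R_{k,t}`` (closed spectral form).

    ``t = 0`` is served by evaluating the formula at ``t = 2``.  The mean
    of the returned field over patches is zero.
    """
    if N < 1:
        raise ValueError(f"patch size N={N} must be >= 1")
    if t < 0:
        raise ValueError(f"temporal distance t={t} must be >= 0")
    if t == 0:
        t = 2
    lattice = kernel.lattice
    M = _mixing_spectrum(kernel)
    D = lattice.D
    weights = np.zeros(D, dtype=complex)
    denom = 1.0 - M[1:] ** 2
    weights[1:] = M[1:] ** t / denom
    big_m = float(np.sum(M[1:] ** 2 / denom))
    spectrum = D * weights / (D * N + big_m)
    return inverse_transform(spectrum, lattice)


def relatedness_table(kernel: Kernel, N: int, t_max: int) -> RelatednessTable:
    """Relatedness fields for all ``t`` in ``0..t_max``."""
    entries = tuple(relatedness_wf(kernel, N, t) for t in range(t_max + 1))
    return RelatednessTable(kernel.lattice, entries)
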