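"""Extended phenotypic effects through environmental dynamics.

A focal individual's trait perturbs the environmental state variable of
every patch one generation ahead (the field ``psi_k``); thereafter the
perturbation propagates through the deterministic environmental map,
whose linearization around the spatially homogeneous equilibrium is the
field ``c_k`` (effect of one patch's environment on another's at
displacement ``k``).  The extended phenotypic effect

    e_{k,t} = L_k( Psi(h) C(h)^{t-1} )

is the marginal effect of the focal trait on the environment of the
patch at displacement ``k``, ``t`` generations in the future.  A
matrix-valued generalization covers several coupled environmental
variables (e.g. interacting resources in a metacommunity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lattice import Lattice, fourier_transform, inverse_transform

__all__ = [
    "EnvDerivatives",
    "ExtendedEffectTable",
    "differentiate_env_map",
    "extended_effects_table",
    "extended_effects_multi",
]

FIXED_POINT_TOL = 1e-8


class NotAFixedPointError(ValueError):
    """The supplied (trait, environment) pair is not an equilibrium of the map."""


@dataclass(frozen=True)
class EnvDerivatives:
    """One-generation environmental effect fields ``psi`` and ``c``."""

    lattice: Lattice
    psi: np.ndarray
    c: np.ndarray

    def psi_spectrum(self) -> np.ndarray:
        return fourier_transform(self.psi, self.lattice)

    def c_spectrum(self) -> np.ndarray:
        return fourier_transform(self.c, self.lattice)


@dataclass(frozen=True)
class ExtendedEffectTable:
    """Fields ``e_{k,t}`` for ``t = 1..t_max`` (``entries[t]``; index 0 unused)."""

    lattice: Lattice
    entries: tuple[np.ndarray, ...]

    @property
    def t_max(self) -> int:
        return len(self.entries) - 1

    def __getitem__(self, t: int) -> np.ndarray:
        if t < 1:
            raise IndexError("extended effects start at t = 1")
        return self.entries[t]


def differentiate_env_map(
    env_map: Callable[[np.ndarray, np.ndarray], float],
    z: float,
    n_hat: float,
    N: int,
    lattice: Lattice,
    step_scale: float = 1e-6,
) -> EnvDerivatives:
    """Central finite differences of the focal-patch environmental map.

    ``env_map(trait_field, env_field)`` must return the next-generation
    environmental state of the focal patch given the current fields of
    patch-average traits and environments.  The pair ``(z, n_hat)`` must
    be a spatially homogeneous fixed point of the map.  Returns
    ``psi_k`` (focal individual's one-generation effect, i.e. the trait
    derivative divided by patch size ``N``) and ``c_k`` (environment-
    on-environment effect).
    """
    D = lattice.D
    z_field = np.full(D, float(z))
    n_field = np.full(D, float(n_hat))
    resid = abs(env_map(z_field, n_field) - n_hat)
    if resid > FIXED_POINT_TOL * (1.0 + abs(n_hat)):
        raise NotAFixedPointError(
            f"|g(z, n_hat) - n_hat| = {resid:.3e} exceeds tolerance"
        )

    hz = step_scale * (1.0 + abs(z))
    hn = step_scale * (1.0 + abs(n_hat))
    psi = np.empty(D)
    c = np.empty(D)
    for k in range(D):
        zp = z_field.copy()
        zp[k] = z + hz
        zm = z_field.copy()
        zm[k] = z - hz
        psi[k] = (env_map(zp, n_field) - env_map(zm, n_field)) / (2 * hz) / N
        np_ = n_field.copy()
        np_[k] = n_hat + hn
        nm = n_field.copy()
        nm[k] = n_hat - hn
        c[k] = (env_map(z_field, np_) - env_map(z_field, nm)) / (2 * hn)
    return EnvDerivatives(lattice, psi, c)


def extended_effects_table(derivs: EnvDerivatives, t_max: int) -> ExtendedEffectTable:
    """Spectral computation of ``e_{k,t}`` for ``t = 1..t_max``."""
    if t_max < 1:
        raise ValueError(f"t_max={t_max} must be >= 1")
    lattice = derivs.lattice
    Psi = derivs.psi_spectrum()
    C = derivs.c_spectrum()
    entries: list[np.ndarray] = [np.zeros(lattice.D)]  # t = 0 placeholder
    E_t = Psi.copy()
    for t in range(1, t_max + 1):
        if t > 1:
            E_t = E_t * C
        entries.append(inverse_transform(E_t, lattice))
    return ExtendedEffectTable(lattice, tuple(entries))


def extended_effects_multi(
    psi_vec: Sequence[np.ndarray],
    c_matrix: Sequence[Sequence[np.ndarray]],
    t_max: int,
    lattice: Lattice,
) -> list[ExtendedEffectTable]:
    """Extended effects for ``n_e`` coupled environmental variables.

    ``psi_vec[i]`` is the focal effect field on variable ``i``;
    ``c_matrix[i][j]`` the field of one-generation effects of variable
    ``j`` on variable ``i`` at each displacement.  Per frequency the
    community matrix power ``C(h)^{t-1}`` is applied to the Psi vector
    (repeated multiplication; ``t_max`` is small), then inverse
    transformed per variable.
    """
    if t_max < 1:
        raise ValueError(f"t_max={t_max} must be >= 1")
    n_e = len(psi_vec)
    if n_e < 1 or any(len(row) != n_e for row in c_matrix) or len(c_matrix) != n_e:
        raise ValueError("c_matrix must be square with one row per psi field")
    D = lattice.D
    Psi = np.stack([fourier_transform(np.asarray(p, float), lattice) for p in psi_vec])
    C = np.empty((n_e, n_e, D), dtype=complex)
    for i in range(n_e):
        for j in range(n_e):
            C[i, j] = fourier_transform(np.asarray(c_matrix[i][j], float), lattice)
    # E[:, h] for t = 1 is Psi[:, h]; multiply by C(h) each extra step
    E = Psi.copy()
    per_var: list[list[np.ndarray]] = [[np.zeros(D)] for _ in range(n_e)]
    for t in range(1, t_max + 1):
        if t > 1:
            E = np.einsum("ijh,jh->ih", C, E)
        for i in range(n_e):
            per_var[i].append(inverse_transform(E[i], lattice))
    return [ExtendedEffectTable(lattice, tuple(rows)) for rows in per_var]
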