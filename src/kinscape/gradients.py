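"""Assembly of selection gradients from effect fields.

The gradients are returned up to a positive proportionality constant:
their zeros and signs — which determine singular strategies and the
direction of selection — are the meaningful outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effects import ExtendedEffectTable
from .lattice import Lattice
from .relatedness import RelatednessTable

__all__ = [
    "PayoffDerivatives",
    "se_fitness_form",
    "gradient_payoff_nonlocal",
    "gradient_payoff_local",
]


class NonLocalPayoffError(ValueError):
    """Payoff derivatives have support away from the focal patch where a
    local-payoff form was requested."""


@dataclass(frozen=True)
class PayoffDerivatives:
    """Marginal payoff effects at the resident equilibrium.

    ``d_self`` is the effect of the focal individual's own trait on its
    payoff; ``d_z[k]`` the effect of the average trait in the patch at
    displacement ``k``; ``d_n[k]`` the effect of the environmental state
    of the patch at displacement ``k``.
    """

    lattice: Lattice
    d_self: float
    d_z: np.ndarray
    d_n: np.ndarray

    def __post_init__(self):
        self.lattice.check_field(self.d_z)
        self.lattice.check_field(self.d_n)

    @property
    def is_local(self) -> bool:
        return not (
            np.any(self.d_z[1:] != 0.0) or np.any(self.d_n[1:] != 0.0)
        )


def se_fitness_form(
    effects: ExtendedEffectTable,
    dw_dn: np.ndarray,
    relatedness: RelatednessTable,
    N: int,
    t_max: int,
) -> float:
    """Inter-temporal selection, fitness form.

    ``sum_t sum_k sum_j e_{j-k,t} (dw/dn_j) N R_{k,t}``: the focal
    individual's effect on the environment everywhere, converted to
    fitness of the individuals living ``t`` generations later, weighted
    by their relatedness.  Truncated at ``t_max``.
    """
    if effects.t_max < t_max or relatedness.t_max < t_max:
        raise ValueError(
            f"need effects and relatedness up to t={t_max}; have "
            f"{effects.t_max} and {relatedness.t_max}"
        )
    lattice = effects.lattice
    w = lattice.check_field(np.asarray(dw_dn, dtype=float))
    sub = lattice.sub_index  # sub[j, k] = j - k
    total = 0.0
    for t in range(1, t_max + 1):
        e_shift = effects[t][sub]  # [j, k] -> e_{j-k,t}
        inner = w @ e_shift  # sum_j dw_dn[j] e_{j-k,t}
        total += float(np.sum(inner * N * relatedness[t]))
    return total


def gradient_payoff_nonlocal(
    pd: PayoffDerivatives,
    effects: ExtendedEffectTable,
    kappa: list[np.ndarray],
    N: int,
    t_max: int,
) -> float:
    """Selection gradient (payoff form) for possibly non-local payoffs.

    ``kappa[t]`` must hold the scaled-relatedness field for each
    ``t = 0..t_max``.  Intra-temporal terms use ``kappa[0]``; the
    inter-temporal part sums ``e_{k-j,t} (dpi/dn_j) N kappa_{k,t}``.
    """
    if len(kappa) < t_max + 1 or effects.t_max < t_max:
        raise ValueError("kappa and effects must cover t = 0..t_max")
    lattice = pd.lattice
    total = pd.d_self + float(np.sum(kappa[0] * pd.d_z))
    sub = lattice.sub_index
    for t in range(1, t_max + 1):
        e_shift = effects[t][sub]  # [k, j] -> e_{k-j,t}
        inner = e_shift @ pd.d_n  # sum_j e_{k-j,t} dpi_dn[j]
        total += float(np.sum(inner * N * kappa[t]))
    return total


def gradient_payoff_local(
    pd: PayoffDerivatives, K: float, N: int, kappa_00: float
) -> float:
    """Selection gradient for strictly local payoffs.

    ``dpi/dz_self + (dpi/dz_0) kappa_{0,0} + (dpi/dn_0) N K``.
    """
    if not pd.is_local:
        raise NonLocalPayoffError(
            "payoff derivatives must be supported at displacement 0 only"
        )
    return pd.d_self + pd.d_z[0] * kappa_00 + pd.d_n[0] * N * K
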