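"""Individual-based Wright-Fisher lattice simulation with commons dynamics.

Each patch carries exactly ``N`` adults.  One demographic time step:
individual payoffs from own trait and local commons; deterministic
commons update from parental patch-mean traits (production, movement,
decay); recruitment of ``N`` offspring per patch, each drawing a parent
with probability proportional to ``m_{k-j}`` times the parent's payoff
(fecundity = payoff: the Wright-Fisher fecundity life cycle); rare
Gaussian mutation of the inherited trait.  The long-run population mean
trait is compared against the analytically predicted singular value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .commons import CommonsParams, env_equilibrium

__all__ = ["SimConfig", "PopulationState", "init_population", "step_wf", "run",
           "estimate_equilibrium", "recruitment_weights"]


class DegenerateStateError(ArithmeticError):
    """All recruitment weights vanished (no finite fecundity anywhere)."""


@dataclass
class SimConfig:
    params: CommonsParams
    generations: int
    burn_in: int = 0
    mutation_prob: float = 1e-4
    mutation_sd: float = 1e-2
    seed: int = 0
    init_trait: float = 0.0
    init_env: Union[float, str] = "equilibrium"

    def __post_init__(self):
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.generations and not self.burn_in < self.generations:
            raise ValueError("burn_in must be smaller than generations")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be a probability")
        if self.mutation_sd <= 0:
            raise ValueError("mutation_sd must be positive")


@dataclass
class PopulationState:
    traits: np.ndarray  # (D, N) adult trait values
    env: np.ndarray  # (D,) commons level per patch
    generation: int
    rng: np.random.Generator


def init_population(cfg: SimConfig) -> PopulationState:
    """Monomorphic start at ``init_trait`` with the commons at its
    deterministic equilibrium (or at a supplied level)."""
    p = cfg.params
    D, N = p.lattice.D, p.N
    traits = np.full((D, N), float(cfg.init_trait))
    if isinstance(cfg.init_env, str):
        if cfg.init_env != "equilibrium":
            raise ValueError(f"unknown init_env {cfg.init_env!r}")
        n0 = env_equilibrium(cfg.init_trait, p)
    else:
        n0 = float(cfg.init_env)
    env = np.full(D, n0)
    return PopulationState(traits, env, 0, np.random.default_rng(cfg.seed))


def _circulant(kernel_p: np.ndarray, lattice) -> np.ndarray:
    """Matrix ``A[k, j] = kernel_{k-j}`` for patch-to-patch transport."""
    return kernel_p[lattice.sub_index]


def recruitment_weights(pi: np.ndarray, m_kernel_p: np.ndarray, lattice) -> np.ndarray:
    """Unnormalized parent-sampling weights, one row per destination patch.

    ``weights[k, j*N + i]`` is proportional to the probability that a
    given recruit of patch ``k`` descends from adult ``i`` of patch
    ``j``: dispersal probability ``m_{k-j}`` times that adult's
    fecundity (= payoff).  Row-normalizing yields the exact offspring
    distribution of the Wright-Fisher fecundity life cycle, so the
    expected number of offspring of an adult is ``N`` times the sum of
    its column probabilities — which equals the survival/fecundity
    fitness function evaluated at the realized payoffs.
    """
    D, N = pi.shape
    Mmat = _circulant(m_kernel_p, lattice)
    return (Mmat[:, :, None] * pi[None, :, :]).reshape(D, D * N)


def step_wf(state: PopulationState, cfg: SimConfig) -> PopulationState:
    """Advance one demographic time step in place and return the state."""
    p = cfg.params
    lattice = p.lattice
    D, N = lattice.D, p.N
    rng = state.rng

    # (1) individual payoffs from own trait and local commons
    log_pi = (
        p.B * state.env[:, None] ** p.alpha_B - p.C * state.traits**p.alpha_C
    )
    if not np.all(np.isfinite(log_pi)):
        raise DegenerateStateError("non-finite payoff encountered")
    pi = np.exp(log_pi - log_pi.max())  # global shift cancels in the weights

    # (2) commons update from parental patch means (deterministic)
    zbar = state.traits.mean(axis=1)
    produced = np.array([p.P(z) for z in zbar])
    Dmat = _circulant(p.d_kernel.p, lattice)
    new_env = Dmat @ ((1.0 - p.epsilon) * state.env + produced)

    # (3) recruitment: parent of each of the N slots in patch k is adult i
    #     of patch j with probability proportional to m_{k-j} * pi_{j,i}
    weights = recruitment_weights(pi, p.m_kernel.p, lattice)
    cum = np.cumsum(weights, axis=1)
    totals = cum[:, -1]
    if np.any(totals <= 0.0):
        raise DegenerateStateError("zero total fecundity reaching some patch")
    u = rng.random((D, N)) * totals[:, None]
    parents = np.empty((D, N), dtype=np.int64)
    for k in range(D):
        parents[k] = np.searchsorted(cum[k], u[k], side="right")
    new_traits = state.traits.reshape(-1)[parents]

    # (4) mutation
    mutate = rng.random((D, N)) < cfg.mutation_prob
    n_mut = int(mutate.sum())
    if n_mut:
        new_traits[mutate] += rng.normal(0.0, cfg.mutation_sd, n_mut)

    state.traits = new_traits
    state.env = new_env
    state.generation += 1
    return state


def run(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Simulate ``cfg.generations`` steps; per-generation summaries.

    Returns arrays ``generation``, ``mean_trait``, ``sd_trait`` and
    ``mean_env`` of length ``generations + 1`` (the initial census is
    row 0).  Deterministic given ``cfg.seed``.
    """
    state = init_population(cfg)
    T = cfg.generations
    gen = np.arange(T + 1)
    mean_trait = np.empty(T + 1)
    sd_trait = np.empty(T + 1)
    mean_env = np.empty(T + 1)

    def record(i: int) -> None:
        mean_trait[i] = state.traits.mean()
        sd_trait[i] = state.traits.std()
        mean_env[i] = state.env.mean()

    record(0)
    for i in range(1, T + 1):
        step_wf(state, cfg)
        record(i)
    return {
        "generation": gen,
        "mean_trait": mean_trait,
        "sd_trait": sd_trait,
        "mean_env": mean_env,
    }


def estimate_equilibrium(
    trajectory: dict[str, np.ndarray] | np.ndarray, burn_in: int
) -> tuple[float, float]:
    """Post-burn-in mean and standard deviation of the population-mean trait."""
    series = (
        trajectory["mean_trait"] if isinstance(trajectory, dict) else np.asarray(trajectory)
    )
    if not 0 <= burn_in < len(series):
        raise ValueError(f"burn_in={burn_in} leaves an empty window")
    window = series[burn_in:]
    return float(window.mean()), float(window.std())
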