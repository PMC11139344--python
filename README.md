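# kinscape

**Selection on environmentally mediated social traits under isolation by
distance** — exact Fourier machinery for relatedness and scaled relatedness on
lattice-structured populations, extended phenotypic effects of traits on
dynamic environmental variables, and a lasting-commons model in which
*posthumous spite* readily evolves, validated by an individual-based
Wright-Fisher simulator.

## The scientific problem

Many social interactions are indirect: organisms modify shared environmental
variables — a common-pool resource, a secreted compound, a pollutant — that
persist, move through space, and feed back on the survival and reproduction of
individuals living far away and long after the actor. In a population
subdivided into `D` patches of `N` adults arranged on a torus
(`G = Z_{D_1} x ... x Z_{D_d}`), with spatially homogeneous dispersal
(`m_k = m_{-k}`), who gains and who loses from such environmental legacies is
decided by the interplay of three quantities:

* **Relatedness** `R_{k,t}`: the excess probability, relative to a random
  individual, that someone in the patch at displacement `k`, `t` generations
  away, shares an allele identical by descent with a focal individual. For the
  Wright-Fisher life cycle it has the closed spectral form

      R_{k,t} = 1/(DN + M) * Σ_{h≠0} M(h)^t / (1 − M(h)²) · conj(χ_k(h)),

  where `M(h)` is the characteristic function of the dispersal kernel,
  `χ_k(h) = exp(2πi Σ_j k_j h_j / D_j)` and `M = Σ_{h≠0} M(h)²/(1 − M(h)²)`.

* **Scaled relatedness** `κ_{k,t}`: relatedness discounted by kin
  competition — the number of payoff units a focal individual would exchange
  with a random individual in patch `(k, t)` without changing a rare mutant's
  fate. Under Wright-Fisher reproduction `κ_{k,0} = −1/(DN−1)` (helping
  contemporaries is never favoured) and `κ_{k,t} = D(p_{k,t} − 1/D)/(DN−1)`,
  with `p_{k,t}` the neutral gene random walk.

* **Extended phenotypic effects** `e_{k,t}`: the marginal effect of the focal
  individual's trait on the environmental state of patch `k`, `t` generations
  ahead, computed spectrally as `e_{k,t} = L_k(Ψ(h) C(h)^{t−1})` from the
  one-generation effect fields `ψ` (trait on environment) and `c`
  (environment on environment).

For payoffs that depend only on the local patch, selection on the
environmental pathway is summarized by the scalar
`K = Σ_t Σ_k e_{k,t} κ_{k,t}`.

## The lasting-commons model

Individuals pay an immediate cost `exp(−C z^{α_C})` to produce a durable
commons at rate `P(z) = P_0 z`; the commons moves between patches with kernel
`d_k`, decays at rate `ε`, and multiplies payoff by `exp(B n^{α_B})`. The
direction of selection is set by

    Ω = Σ_t Σ_k ε(1−ε)^{t−1} κ_{k,t} q_{k,t}
      = ε/(DN−1) · Σ_{h≠0} D(−h)M(h) / (1 − (1−ε)D(−h)M(h)),

the expected genetic value, in payoff units, of the future individuals reached
by a unit of commons (`q_{k,t}` is the commons random walk, `D(h)` its
characteristic function). The convergence-stable trait value is

    z* = [ (B/C)(α_B/α_C)(P_0/ε)^{α_B} · Ω ]^{1/(α_C − α_B)},

positive (environmental altruism) when Ω > 0, negative (indiscriminate,
posthumous spite) when Ω < 0. Spite is favoured when gene lineages and the
commons they produce become spatially dissociated — high dispersal, fast
decay, or a commons that travels much farther than offspring do.

## Worked example

The posthumous-spite regime on a 13×13 torus with `N = 50`: offspring disperse
short range (`m = 0.3`, mean distance 1.54) while the commons moves far
(`d = 1`, mean distance 8) and decays at `ε = 0.5`; payoff parameters `B = 2`,
`α_B = 1`, `C = 1`, `α_C = 4`, production `P(z) = 50 z`:

```python
import yaml
from kinscape import make_fixtures
yaml.safe_dump(make_fixtures()["commons_13x13"], open("commons.yaml", "w"))
```

```text
$ kinscape zstar --config commons.yaml --out zstar.json
{"omega": -4.506126901644963e-05, "method": "closed_form",
 "z_star": -0.13109651320256707, "n_hat": -13.109651320256708,
 "stable": true, "slope": -0.20623554979806782}
```

Ω < 0: a unit of commons produced here is, on balance, experienced by
individuals *less* related than average to the producer's lineage, so
selection favours degrading the environment. The population converges to
`z* ≈ −0.131` — every individual pays a payoff cost to make the commons a
common bad — and the commons equilibrates at `n̂ = P(z*)/ε ≈ −13.1`. The
gradient slope at `z*` is negative, so the strategy is convergence stable.
The same number emerges from the covariance between the gene and commons
random walks:

```text
$ kinscape omega --config commons.yaml --method covariance_wf --out omega.json
omega = -4.5061269e-05 (covariance_wf)
```

The bundled `sim_7x7` configuration runs the individual-based Wright-Fisher
simulator (`kinscape simulate`) on a scaled-down lattice; its post-burn-in
mean trait reproduces the analytic `z*` to within the simulation's standard
deviation (see `tests/test_acceptance.py`).

Other entry points: `kinscape relatedness` and `kinscape kappa` write
`R_{k,t}` / `κ_{k,t}` tables as long CSV; `kinscape extended-effects` the
`e_{k,t}` fields; `kinscape gradient` evaluates the selection gradient at a
trait value. Every run writes a manifest (`*.manifest.json`) echoing the
resolved parameters, seed, and package version, from which any result file is
reproducible bit for bit.

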