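# Methods

## Model and assumptions

The population is subdivided into `D` patches of exactly `N` haploid adults,
arranged on a `d`-dimensional torus so that the set of patches carries the
abelian group structure `G = Z_{D_1} × … × Z_{D_d}`. The life cycle per
demographic time step is: (a) reproduction and (optionally) adult survival,
(b) offspring dispersal with a symmetric kernel `m_k = m_{−k}`, (c)
density-dependent regulation back to `N` adults per patch. All processes are
spatially homogeneous: effects between patches depend only on the
displacement between them, and are symmetric under `k → −k`. Each patch
carries one (or several, in the multi-variable generalization) environmental
state variable whose deterministic dynamics couple patches through a
transition map; in a monomorphic population this map is assumed to have a
unique, hyperbolically stable, spatially homogeneous equilibrium. Selection
is analysed to first order in trait variation (convergence stability of a
trait substitution sequence), which is why one-generation *linearizations* of
the environmental map (`ψ`, `c`) and of survival/fecundity around the
resident payoff are sufficient and exact for the quantities computed here.

Fourier analysis on `G` uses the population-genetics sign convention: the
forward transform applies the character `χ_k(h) = exp(+2πi Σ_j k_j h_j/D_j)`,
so the transform of a probability kernel is its characteristic function; the
inverse uses the conjugate. This is the reverse of the engineering
convention, and the optional FFT fast path maps onto `ifftn`/`fftn`
accordingly. Transforms default to the explicit `O(D²)` character-matrix
product — exact with respect to the definition and cheap at the lattice sizes
of interest (`D ≤ a few hundred`) — with the FFT path available and required
by the tests to agree to 1e−12.

## Relatedness and its scope

The closed spectral form for `R_{k,t}` implemented in `relatedness_wf` is
specific to the Wright-Fisher life cycle (no adult survival, semelparous
reproduction); requesting it as part of a life cycle with adult survival is
rejected rather than silently combined. Same-generation relatedness is served
by evaluating the formula at `t = 2`, which is an identity of this process.
Consequently, the definitional route to scaled relatedness
(`kappa_from_definition`, which combines `R` with numerically differentiated
competition coefficients `λ_k`) is cross-checked against the spectral closed
form (`kappa_general`) on semelparous life cycles — the Wright-Fisher case
and grids over `(s′, f, f′)` at `s = 0`, where the neutral genealogical
process is Wright-Fisher regardless of the payoff derivatives. For `s > 0`
the neutral lineage process itself changes (lineages move with the modified
spectrum `s + (1−s)M(h)`), so the general-life-cycle `κ` is provided only by
the spectral closed form, which is in turn validated against the independent
time-domain series for `K` (below).

## The K statistic and Ω

`K = Σ_{t≥1} Σ_k e_{k,t} κ_{k,t}` summarizes selection through the
environmental pathway for local payoffs. It is computed two ways that must
agree: a frequency-domain resolvent, derived by applying Parseval's identity
to the spectra of `e` and `κ` (the per-frequency time sum is the geometric
series `Σ_t C(h)^{t−1} M̃(h)^t = M̃/(1 − C M̃)` with
`M̃(h) = s + (1−s)M(h)`), and the truncated time-domain double series. At
`s = 0` the resolvent reduces to the familiar Wright-Fisher form
`K = (DN−1)^{-1} Σ_{h≠0} M(h)Ψ(−h)/(1 − C(−h)M(h))`. The series is truncated
when a geometric tail bound — ratio `max_{h≠0} |C(h)M̃(h)|`, applied to the
last computed term — falls below 1e−12 of the partial sum (hard cap 1e5
terms); frequencies with `|C M̃| ≥ 1` raise a divergent-series error instead
of returning a truncation artefact.

For the lasting-commons model, `Ω = εKN/P′(z)` is implemented by four routes:
the resolvent closed form; the `κ`-weighted series over the commons random
walk (truncated when `(1−ε)^{t−1} < 1e−12`); the covariance form (valid for
Wright-Fisher fecundity only, and refused otherwise); and a first-order
weak-dispersal expansion, `Ω ≈ (D−1)/(DN−1) − (m+d)D/(ε(DN−1))`, obtained by
expanding the resolvent to first order in the movement probabilities `m` and
`d`. The expansion is an asymptotic statement; the tests hold it to within 5%
of the closed form at `m = d = 0.01` and make no claim at larger movement
probabilities. Note that `Ω` is independent of the resident trait for any
production function, because `K` is proportional to `P′(z)` through `ψ`.

## Kernels

The movement-distance kernel used throughout draws the minimal-image
Manhattan distance `r` from a binomial distribution with index
`r_max = Σ_j ⌊D_j/2⌋` (the largest distance on the torus), truncated to
`1 ≤ r ≤ r_max`, with success probability solved by bisection so the
conditional mean equals the requested mean distance; mass at distance `r` is
divided equally among all displacement vectors of that norm, which makes
symmetry exact by construction (the norm is invariant under `k → −k`,
including the self-inverse displacements `D_j/2` on even lattices). Movement
probabilities span `[0, 1]`: a kernel with `move_prob = 1` (all mass leaves
the origin) is legitimate for the commons, whose dynamics never require
mixing; dispersal kernels used for relatedness must satisfy `|M(h)| < 1` off
the origin and are rejected otherwise. Validation tolerances: simplex sum to
1e−10, symmetry to 1e−12; negative mass below −1e−12 is an error, smaller
round-off is clipped and renormalized.

## Parameters

| Parameter | Meaning | Typical value and rationale |
|---|---|---|
| `D_1 × … × D_d` | lattice shape | 51-ring and 13×13 torus in the worked examples; large enough for distance structure, small enough for exact transforms |
| `N` | adults per patch (dimensionless) | 20–50; kin competition scales with `1/(DN−1)` |
| `m`, `λ̄_m` | offspring movement probability and mean distance | e.g. 0.3 / 1.54 (short-range dispersal) |
| `d`, `λ̄_d` | commons movement probability and mean distance | e.g. 1.0 / 8 (far-travelling commons) |
| `ε` | commons decay rate per generation, in (0, 1] | 0.5 in the examples; sets the memory `1/ε` of the environment |
| `B, α_B` | payoff benefit of the local commons (`α_B` odd) | 2, 1 |
| `C, α_C` | payoff cost of trait expression (`α_C` even, `> α_B`) | 1, 4; costs must steepen faster than benefits for an interior `z*` |
| `P_0` | production slope, commons units per trait unit | `N` (each individual contributes one unit per unit trait) |
| `s, s′, f, f′` | survival/fecundity and payoff derivatives at the resident | presets: Wright-Fisher fecundity `(0,0,1,1)`; survival effects `(s,1,1,0)` |

## The individual-based simulator

One step: individual payoffs `exp(B n^{α_B} − C z^{α_C})` from the parental
environment; deterministic commons update from parental *patch-mean* traits
(the environmental map is defined on patch averages, which is exact to the
first order at which the analytic predictions hold); recruitment of exactly
`N` offspring per patch, each drawing its parent with probability
proportional to `m_{k−j}` times the parent's payoff (fecundity = payoff — the
Wright-Fisher fecundity life cycle in expectation, verified exactly on a
two-patch configuration against the survival/fecundity fitness function);
then Gaussian mutation with probability 1e−4 and standard deviation 1e−2 per
offspring (the trait-substitution regime: mutational input is rare and
small). Payoff exponents are globally shifted before exponentiation, which
cancels in the sampling weights and guards against overflow. A single seeded
`numpy` generator drives all randomness; runs are reproducible bit for bit
from the seed recorded in the manifest.

What the simulator emulates — and what it does not: environmental dynamics
are deterministic given the trait field (no environmental noise), generations
do not overlap (no survival-effects simulator; the survival case is covered
analytically through the spectral `κ` and `Ω`), and mutation is a Gaussian
step on an unbounded trait. Agreement between simulation and the analytic
`z*` therefore demonstrates the correctness of the selection analysis under
exactly these assumptions, not robustness to demographic or environmental
stochasticity beyond the drift intrinsic to finite `N`.

The validation runs use a 7×7 lattice with `N = 20` and 4000 generations
(burn-in 1000), initialized at the predicted `z*` — the protocol of the
full-scale analysis at a size where a complete run takes seconds. The
recovery check is stochastic by nature: the post-burn-in mean trait is
required to lie within two standard deviations of the per-generation
population-mean series around the analytic prediction.

## Numerical choices

* Inverse transforms of symmetric spectra are cast to real after checking
  `max|Im| ≤ 1e−9 (1 + max|Re|)`; a larger residue raises.
* `λ_k` uses central differences with step `2e−5` at the resident payoff and
  a step-doubling consistency check to 1e−6; the environmental-map
  derivatives use step `1e−6 (1 + |scale|)` and verify the supplied
  equilibrium to 1e−8 before differentiating.
* The three-branch assembly of `κ` from its definition raises on a vanishing
  denominator `1 − Σ_j λ_j R_{j,0}` rather than regularizing; the conditions
  under which it can vanish are not characterized.
* `z*` takes the odd real root when `α_C − α_B` is odd and `Ω < 0` (spite);
  a negative argument with an even root order has no real singular strategy
  and raises. Non-linear production functions fall back to bracketed root
  finding on the gradient.
* Convergence stability is checked by a central-difference slope at `z*`
  (step `1e−5 (1 + |z*|)`) after confirming the gradient is numerically zero
  there.
* Matrix powers in the multi-variable extended effects use repeated
  multiplication per frequency rather than eigendecomposition, avoiding
  defective-matrix corner cases at negligible cost for small horizons.

## Known limitations

* Relatedness with adult survival has no closed form here; life cycles with
  `s > 0` are supported through scaled relatedness and `K`/`Ω` only.
* The weak-dispersal `Ω` is first-order in `(m, d)` and degrades as `m + d`
  approaches `ε`.
* Environmental dynamics must be deterministic with a stable homogeneous
  equilibrium; the only stability diagnostic applied is the spectral
  condition on `|C(h)|` products, per the scope of the linearized analysis.
* Anisotropic or asymmetric dispersal, non-product group structures, and
  joint evolution of several traits are out of scope.
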