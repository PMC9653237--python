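# Methods

## Model

A *compartment* is a cell stage with a shared fate law. Every cell in it,
independently of all others, undergoes exactly one of four events:

| event                | probability | effect |
|----------------------|-------------|--------|
| symmetric division   | `p_b`       | two daughters in the same compartment, generation +1 |
| death                | `p_d`       | cell removed |
| exit                 | `p_e`       | cell moves to the next compartment (or becomes a product cell after the last), same generation |
| asymmetric division  | `p_a`       | one daughter stays, one exits; both at generation +1 |

with `p_b + p_d + p_e + p_a = 1`. A chain is an ordered sequence of C
compartments; a single progenitor (generation 0) enters compartment 1, and
the *family size* R is the number of cells that ultimately exit compartment
C. Time plays no role: only the embedded sequence of events matters, so the
discrete fate draw and a continuous-time exponential-clock race with rates
(λ, μ, ν) and `(p_b, p_d, p_e) = (λ, μ, ν)/(λ+μ+ν)` give identical ultimate
counts. Inter-event times and time courses are deliberately out of scope.

**Subcriticality.** Construction rejects `2 p_b + p_a ≥ 1` (mean number of
daughters remaining in the compartment at least one). Under subcriticality
every family is finite with probability one and all quantities below are
finite.

## Exact quantities

*Single compartment.* The first-step argument gives the generating-function
fixed point `φ = p_d + p_e z + p_b φ² + p_a z φ`; the branch with φ(1)=1 is
taken in the cancellation-free form `φ = 2c/(b + √(b²−4 p_b c))` with
`b = 1−p_a z`, `c = p_d + p_e z`, which remains correct in the linear limit
p_b → 0. From it: amplification `N = (p_e+p_a)/(1−2p_b−p_a)`, extinction
without exit `q_0 = 2p_d/(1+Δ)` with `Δ = √(1−4 p_d p_b)`, and
`V = var(R) = φ″(1) + N − N²` with
`φ″(1) = (2p_b N² + 2p_a N)/(1−2p_b−p_a)`. For the three-fate case
(`p_a = 0`) the pmf has the Catalan closed form
`q_k = (p_b/Δ)^(k−1)(p_e/Δ)^k c_{k−1}`, generated in practice by the stable
ratio recursion `q_{k+1} = (2k−1)/(k+1) · 2p_b p_e/Δ² · q_k` in linear
space; entries below the double-precision underflow threshold flush to zero,
which only matters beyond any tail of interest. The tail obeys
`q_k ~ (p_e/(√π Δ)) γ_1^{k−1} k^{−3/2}` with `γ_1 = 4p_b p_e/Δ²`. This
asymptote is approached from above and is *not* a uniform bound at small k
(at k = 1 it is 1/√π of the true q_1); the package exposes it as
`tail_asymptote` and reserves the word "bound" for the clonality bound below.

*Chains.* Independence makes the product-count generating function the
nested composition `Φ_C(z) = φ_1(φ_2(…φ_C(z)))` — outermost is the first
compartment. Coefficients Q_k(C) are extracted order-by-order from the
composed fixed point `Φ = p_d(1) + p_e(1)Ψ + p_b(1)Φ² + p_a(1)ΨΦ`, where Ψ
is the sub-chain series: the k-th equation is linear in Q_k with pivot
`s = √(b²−4p_b c)` once lower orders are known. Applied innermost-first this
is O(C·K²) and reproduces the C = 1 closed form to machine precision; it is
additionally cross-validated against nested scalar evaluation of Φ_C on a
z-grid and against Monte Carlo. Overall `N = ∏ N_c`; `var(R)` follows the
backward compound-sum recursion `v ← n_c v + v_c m²`, `m ← n_c m`, and for
equal death-free stages grows like `N^(2+1/C)`. The chain tail constant is
`γ_C = (1 + (1−γ_1)/(γ_1 N/N_1))^{−1}` (first compartment three-fate), with
the large-N approximation `1 − (1−2p_d(1))/(4N_1N)` reported alongside.

*Clonality.* `k50` is the smallest K with `Σ_{k≤K} k q_k > N/2` — a strict
crossing, no interpolation. The analytic lower bound
`k50 > (π/16)·Δ²/(1−2p_d)²·(2N−1)²` is returned as the raw real number
(70.88 at N = 10, 7775.6 at N = 100). For chains the same crossing is applied
to Q_k(C) with the truncation doubling from 2048 until the partial sum
crosses (hard cap 2^18).

*Generations.* A cell keeps its generation across transitions; both
daughters of any division (symmetric or asymmetric) advance one generation,
so the exiting daughter of an asymmetric division carries n+1. With
`m = 2p_b + p_a` the expected number of exits at generation n per entering
cell is `y_n = p_e m^n + p_a m^{n−1}` (n ≥ 1; y_0 = p_e), giving
`D_c = (p_e m + p_a)/((1−m)(p_e+p_a))` — in the three-fate case the
geometric law `P(G=n) = (1−2p_b)(2p_b)^n`, `D_c = 2p_b/(1−2p_b)` and
`var = D_c(D_c+1)`. Per-compartment gains are independent, so the chain law
of G is their convolution, `D = Σ D_c` and `var(G) = Σ var_c`. The
generation-advancing convention for asymmetric division is fixed by the
requirement that a die-or-asymmetrically-divide stage have `D_c = 1/p_d`
(20/11 and 10/9 for the two thymus variants), which it reproduces exactly.

*Optimal design.* With death probabilities fixed and division probabilities
free, minimizing `D = Σ(α_c N_c − β_c)` (`α_c = 2/(1−2p_d(c))`,
`β_c = 1 + α_c/2`) under `∏ N_c = N*` gives the stationarity condition
`α_1N_1 = … = α_CN_C`, hence `N_c = N*^{1/C} α̃/α_c` (α̃ the geometric mean)
and `D_min = C(α̃N*^{1/C} − ᾱ/2 − 1)`; with uniform death this is
`2C/(1−2p_d)(N*^{1/C}−1+p_d)`, which tends to `2 ln N*` as C → ∞. Allocations
whose implied p_b leaves (0, 1/2) raise an infeasibility error. Optimization
under asymmetric division is intentionally not offered.

## Monte-Carlo simulator

The simulator is the package's independent oracle, not a fitting tool.

- `simulate_family` is event-driven: a work queue of (compartment,
  generation) cells, one fate draw per pop. LIFO and FIFO disciplines give
  the same law because fates are independent; a 10⁷-event safety cap guards
  against misuse with near-critical parameters.
- `simulate_summary(mode="discrete")` advances the whole ensemble
  compartment-by-compartment and generation-by-generation with vectorized
  multinomial draws — the same embedded law, orders of magnitude faster —
  processing families in batches of 20 000 from a single seeded stream.
  Output is reproducible for a fixed (seed, batch size).
- `mode="continuous"` runs the Gillespie picture per family (exponential
  clock races from the stored rates); it exists to confirm that ultimate
  counts are insensitive to waiting-time distributions and requires a chain
  built from rates.

What simulation does and does not show: agreement of empirical R- and
G-histograms with the exact pmfs (total-variation ≈ 10⁻² at 10⁵ families)
validates the closed forms under the model's own assumptions — independent
fates, homogeneous compartments, no feedback or competition. It says nothing
about real populations violating those assumptions (cell–cell interaction,
age structure, de-differentiation), which are out of scope.

## Numerical choices and tolerances

- Probability sums validated to 1e-9 on construction; published inputs are
  rounded to ~4 digits, and p_e may be left implicit (complement).
- The pmf truncation K is caller-chosen for single compartments; chain k50
  auto-doubles K; generation pmfs pick K from the geometric tail so the
  missed mass is below ~1e-12 per compartment.
- Exact ties in the continuous-clock race resolve death < divide < exit (a
  probability-zero event for continuous samplers).
- Statistical tests use 3–4 standard-error windows with error bars taken
  from analytic variances for i.i.d.-family statistics and from independent
  replicate batches for pooled generation means (cells within a family are
  correlated).
- Grid searches verifying optimizer optimality use 400 points per free
  dimension; they are test utilities, not API.
- Test problem sizes (10⁴–10⁵ families, K ≤ 10⁴) keep the full suite under
  ten seconds while leaving Monte-Carlo error well below the asserted
  windows.

## Known limitations

- The tail-constant γ_C requires a three-fate first compartment; the
  composed-pmf machinery itself supports p_a > 0 anywhere.
- The large-N expansion of γ_C for equal compartments is asymptotic: at
  moderate N (say N_c = 5) the residual against its leading term is of
  relative order N^{−1/C}, so series-truncation comparisons are only made in
  the genuinely asymptotic regime.
- Published multi-compartment k50 reference values in the source literature
  differ from the exact strict-crossing computation by up to ~0.5%
  (34 vs 33, 1005 vs 1010, 26 vs 25, 527 vs 528); this package's values are
  cross-validated by the nested generating function and by simulation, and
  the exact computation is reported.
- No time-course quantities, no age structure, no backward transitions, no
  cell–cell interaction.
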