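# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.

## Gamete and genotype frequency models

**Pairing configurations.** A `K`-ploid parent with allele dosage `ℓ` forms
`K/2` bivalent pairs during meiosis. A configuration `m = (m0, m1, m2)`
(pairs with 0, 1, 2 allele copies; `m1 + 2m2 = ℓ`) determines the gamete
dosage distribution `p_k = C(m1, k − m2)/2^{m1}`: double pairs always
transmit one copy, mixed pairs transmit a copy with probability 1/2. The
number of configurations is `b_{Kℓ} = K/2 − ⌈ℓ/2⌉ + 1` for `ℓ ≥ K/2` and
`⌊ℓ/2⌋ + 1` otherwise. Configurations are enumerated in descending `m1`
("most mixed first"); the order is arbitrary but frozen, because mixture
weights `γ` are indexed by it. A convenient consequence of this ordering is
that allele relabeling (`ℓ → K − ℓ`) maps the list elementwise onto the
reversed configurations, so `γ` needs no re-indexing under dosage reversal.

**Polysomic weights.** Uniform random matching of the `K` chromosome copies
gives configuration probabilities proportional to the number of perfect
matchings realizing each configuration,

```
w(m) ∝ C(ℓ, 2m2)(2m2−1)!! · C(K−ℓ, 2m0)(2m0−1)!! · m1! ,
```

normalized by `(K−1)!!`. These are computed in exact rational arithmetic
and the test suite checks them against a brute-force enumeration of all
perfect matchings for `K ≤ 8`. Mixing configuration distributions with
these weights reproduces the hypergeometric gamete distribution, the
classical polysomic result.

**Double reduction.** The multivalent model: with probability `α_i` a
gamete carries `i` doubled chromosomes (both chromatid copies of the same
chromosome) and `K/2 − 2i` singletons, all underlying chromosomes drawn
without replacement from the parent's `K`. The implied dosage distribution
is an exact sum of hypergeometric products (no Monte Carlo). At a simplex
locus this collapses to a two-parameter family
`(1/2 + β, 1/2 − 2β, β, 0, …)` with `β = (1/K) Σ i·α_i`; the suite verifies
the collapse to 1e-12 across 100 random `α` draws per ploidy.

**CES bounds.** Upper bounds on `α` come from a mechanistic
complete-equational-segregation model of meiosis: chromosomes form
reciprocal complete-exchange pairs, so each dyad carries one of its own
chromatid segments and one of its partner's; dyads assort uniformly at
division I; each dyad contributes one chromatid to the gamete. Writing `T`
for the number of complete exchange pairs at a pole (a matching-type
hypergeometric count), the gamete's double-reduction pair count is
binomial(`T`, 1/2), giving

```
α_i = Σ_t  C(K/2, t) C(K/2 − t, K/2 − 2t) 2^{K/2−2t} / C(K, K/2) · C(t, i) (1/2)^t .
```

For tetraploids this yields the classical maximum `α = 1/6`; values for all
supported ploidies are tabulated exactly (e.g. hexaploid 3/10, octoploid
(27/70, 3/140)) and cross-checked in the test suite against a brute-force
enumeration of all pole assignments and chromatid segregations. `β_max`
follows by the collapse formula (1/24, 1/20, 3/56, 1/18, 5/88 for
K = 4, 6, 8, 10, 12).

**Outliers.** Genotype frequencies are mixed with an outlier distribution
in proportion `π`, bounded by a user ceiling `π_max` (default 0.03). The
default outlier distribution is uniform over the `K+1` dosages; a point
mass at dosage 0 is available for suspected null alleles. A single
offspring-level `π` is used; parent-specific outlier rates are out of
scope.

## Likelihoods and fitting

Known genotypes give a multinomial likelihood (the multinomial coefficient
is retained so null and alternative log-likelihoods share a scale; it
cancels in the ratio). Uncertain genotypes give
`Σ_i log Σ_k g_ik q_k`, evaluated from per-row max-normalized likelihood
matrices for numerical stability. The unconstrained MLE is `x/n` (known)
or the fixed point of the standard mixture EM (uncertain; uniform
initialization, convergence when the log-likelihood gain drops below 1e-8,
cap 1000 iterations). The alternative likelihood is concave in `q`, so
initialization affects speed only; a multistart agreement test exercises
this.

Null fitting per family:

* **auto**: only `π` is free; profiled by bounded Brent-type scalar
  optimization on `[0, π_max]` with tolerance 1e-10, with the exact
  endpoints also evaluated and preferred on ties (so boundary estimates are
  exactly on the boundary for the degrees-of-freedom rule).
* **allo**: exhaustive enumeration of configuration pairs, `π` profiled per
  pair; ties broken by enumeration order.
* **seg / auto-dr**: free simplex-valued `γ` blocks (stick-breaking
  parameterization with logistic links, centered so the origin maps to the
  uniform vector), box-bounded `β`, `α`, `π` via scaled logistic links.
  A deterministic scrambled-Sobol multistart (32 points, fixed internal
  seed, plus the center) screens the unconstrained space; L-BFGS-B polishes
  the best three candidates. The attained log-likelihood is finally floored
  by the embedded allo and auto profile fits — both are boundary points of
  the segmental family — which enforces the nesting ladder
  `loglik(auto) ≤ loglik(seg)`, `loglik(allo) ≤ loglik(seg)` by
  construction rather than by optimizer luck. Correctness is defined by
  attained log-likelihood against dense grid-search oracles in the tests,
  not by the parameterization.

Unknown parental dosages: candidate `(ℓ1, ℓ2)` pairs are enumerated
(unordered when both are unknown — the likelihood is swap-symmetric; this
collapse halves the search), filtered, when genotypes are known and
outliers disallowed, to candidates whose attainable support covers the
observed dosages, then fitted; the best log-likelihood wins with
first-in-order tie-breaking. The chosen dosages are then treated as known
for the test.

## Degrees of freedom

`df = max(1, df_alt − df_null)`.

`df_alt` is the ploidy minus the number of dosages with estimated frequency
below 1e-6 under **both** the null and the alternative fit. The 1e-6 zero
threshold is a package choice (the rule itself gives none) and is exposed
as an argument. Note that when `π̂ > 0` the null frequencies are positive
everywhere, so the subtraction only engages when the outlier component is
off or estimated at zero — a deliberately conservative reading.

`df_null` combines two rules, taking the minimum: (i) only parameters
interior to their bounds count (interior = farther than 1e-6 from every
bound; for a simplex-valued `γ` the local dimension is the number of
entries above 1e-6 minus one); (ii) the numeric rank of the
central-difference Jacobian (step 1e-6 on the natural scale) of `θ → q` at
the MLE, restricted to interior directions, counting singular values at
least `σ_max/1000`. Simplex directions are taken along `e_i − e_ref` with
the reference the last positive entry, which keeps perturbations on the
simplex. The chi-squared reference is central; no boundary
mixture-of-chi-squared correction is applied beyond the interior counting
— the data-dependent df plays that role. The floor `df ≥ 1` covers
degenerate cases where the subtraction would reach zero; it keeps the test
defined and conservative.

`BIC = −2·loglik_0 + df_null·log n` uses the estimated null dimension only;
estimated parental dosages are not charged as parameters.

Outlier posteriors follow the standard two-component mixture formula
`π f0 / (π f0 + (1−π) f1)` with `f1` the individual's likelihood under the
fitted non-outlier frequencies and `f0` under the outlier distribution; for
counts data, individuals are reported in ascending dosage order.

## Simulation engine

Genotype counts are multinomial draws from the scenario's frequency vector.
Read counts are beta-binomial at fixed depth: the allele fraction `k/K` is
distorted by sequencing error `e` into `ξ = (k/K)(1−e) + (1−k/K)e`
(allele bias optionally via `ξ/(ξ + (1−ξ)h)`), and overdispersion `ρ`
enters through the usual `(ξ(1−ρ)/ρ, (1−ξ)(1−ρ)/ρ)` shape parameterization
(`ρ = 0` degenerates to binomial). Genotype likelihoods are the same
beta-binomial pmfs evaluated under each candidate genotype. Defaults are
`e = 0.01`, `ρ = 0.01`, no bias, matching the experiment designs. Infinite
depth means genotypes are observed directly (one-hot likelihoods / counts).

The null design crosses ploidies {4, 6, 8}, unordered parent dosage pairs
with per-parent options (one option at `ℓ ∈ {0, K}`; β at 0, half, and the
CES maximum at simplex dosages; mixtures (1,0), (0.5,0.5), (0,1) where two
configurations exist; seven fixed mixtures at the octoploid tetraplex
dosage), `n ∈ {20, 200}`, depth ∈ {10, ∞}, and `π ∈ {0, 0.015, 0.03}` —
7,920 scenarios, with dosage pairs unordered but option pairs fully
crossed (this is the convention that reproduces the count). The robustness
design crosses ploidy, `ℓ1 ∈ {0..K}`, `ℓ2 ∈ {2..K−2}` (full cross), `n`,
depth, and double-reduction rates at 0, half, and the full CES maximum
(vectors scaled componentwise), with no outliers — 852 scenarios. Power
alternatives are uniform Dirichlet draws on the genotype simplex ("easy")
or convolutions of uniform gamete-simplex draws ("hard", which preserves
the null's convolution structure).

What the generator does **not** emulate: locus-to-locus sharing of
individuals (each locus is simulated independently), linkage, allele-bias
variation, depth variation across individuals, and genotyping-model
misspecification (the analysis uses the same beta-binomial family that
generated the reads). Passing tests therefore demonstrate calibration and
power under a correctly specified read model; real-data robustness to read-
model misspecification is only probed indirectly through the outlier
component and the double-reduction robustness design.

## Test-suite problem sizes

The statistical acceptance checks run at the design's `n = 200` with 200
replications: a stratified sample of 54 null-grid scenarios (3 per ploidy ×
depth × outlier-proportion stratum, strided across parent-model
combinations) for type-I error, the octoploid nulliplex-by-hexaplex
scenario for the p-value Q–Q dominance check (99% DKW band), and 200
uniform-simplex alternatives at `K = 4` for power. These sizes keep the
whole suite within a few minutes on one CPU while leaving the binomial
acceptance bounds meaningful.

## Known limitations

* Odd ploidies, mixed-ploidy crosses, and multiallelic loci are out of
  scope; ploidies above 12 are rejected.
* Double reduction at non-simplex loci is not modeled under the segmental
  family (only the auto-dr family covers it); the outlier component
  absorbs moderate amounts, mirroring the robustness design's intent.
* The degrees-of-freedom heuristic is asymptotic in spirit; at `n = 20`
  mild anticonservatism can occur in some corners of the design.
* Genotype likelihoods are taken as given (or built from read depths with
  user-supplied error/overdispersion); the package does not re-estimate
  genotyping model parameters.
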