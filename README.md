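# polyseg

Likelihood-ratio tests for segregation distortion in F1 populations of
arbitrary even ploidy (2–12), accounting for partial preferential pairing,
double reduction at simplex loci, a bounded proportion of outlier
("invalid") genotypes, and genotype uncertainty via genotype likelihoods.

Segregation-distortion testing is a standard quality-control step for
experimental crosses used in linkage and QTL mapping. In polyploids the
naive chi-squared test against fixed Mendelian ratios is miscalibrated:
meiosis may be disomic, polysomic, or anywhere in between (segmental
allopolyploidy), multivalent formation can produce double reduction, a few
offspring can carry anomalous genotypes, and sequencing-based dosage calls
are uncertain. `polyseg` models all of these in the null hypothesis, so a
rejection means distortion rather than an artifact of the meiosis model or
of genotyping noise.

## The model

For a biallelic locus in a `K`-ploid F1 cross, offspring genotype (allele
dosage) frequencies are

```
q_k = (1 − π) · Σ_i p1_i · p2_{k−i}  +  π · u_k ,
```

the convolution of the parents' gamete dosage distributions mixed with an
outlier distribution `u` (uniform by default, or a point mass at dosage 0
for null alleles) in proportion `π ≤ π_max` (default 0.03).

Each parent's gamete distribution depends on how its `K` chromosome copies
pair. A pairing configuration `m = (m0, m1, m2)` counts bivalent pairs with
0/1/2 copies of the allele and yields `p_k = C(m1, k−m2) / 2^{m1}`. The
null families are:

* **auto** — polysomic: configurations mixed with the uniform
  random-matching weights (e.g. 2/3, 1/3 for an autotetraploid duplex,
  giving the classic 1:4:1 gamete ratio);
* **allo** — disomic: the single best configuration per parent;
* **seg** — segmental: free mixture weights `γ` per parent (the general
  model). At simplex loci (`ℓ ∈ {1, K−1}`), where only one configuration
  exists, double reduction is modeled instead through
  `p = (1/2 + β, 1/2 − 2β, β, 0, …)` with
  `β = (1/K) Σ_i i·α_i ∈ [0, β_max(K)]`;
* **auto-dr** — polysomic with free double-reduction rates `α`, bounded by
  their maxima under complete equational segregation (CES).

With known genotypes the dosage counts are multinomial in `q`; with
uncertain genotypes the likelihood is `Π_i Σ_k g_ik q_k` for per-individual
genotype likelihoods `g_ik` (from VCF `GL`/`PL` fields or read depths). The
unconstrained MLE is the empirical frequency vector (or its EM analogue
under genotype likelihoods); the null MLE is found by Brent profiling of
`π`, configuration enumeration, or bounded quasi-Newton optimization with a
deterministic Sobol multistart, depending on the family. The LRT statistic
is referred to a chi-squared distribution whose degrees of freedom adapt to
the data: boundary parameters are not counted, weak identifiability is
handled through the numeric rank of the Jacobian of `θ → q` at the MLE, and
dosages estimated empty under both hypotheses are subtracted from the
alternative's dimension.

The package also reports the BIC of each fitted null (for comparing meiosis
models across loci), per-individual outlier posteriors, and
Benjamini–Hochberg q-values across loci. A simulation engine reproduces the
null (7,920 scenarios), double-reduction robustness (852 scenarios), and
power experiment designs, including beta-binomial read-count simulation
(error 0.01, overdispersion 0.01) and genotype-likelihood construction.

## Worked example

Simulate a hexaploid simplex × duplex cross (200 offspring, read depth 10)
with two well-behaved loci and one distorted locus, then test:

```sh
polyseg test --in example.vcf --ploidy 6 --parents 1,2 --model seg --out results.tsv
```

```
locus       stat  df      p_value      q_value         bic       pi_hat  n_outliers
 snp1   0.194122   2 9.075008e-01 9.090239e-01  782.948438 1.843252e-07           0
 snp2   1.005085   4 9.090239e-01 9.090239e-01  796.685138 1.843252e-07           0
 snp3 264.870674   5 3.534623e-55 1.060387e-54 1208.525411 2.999982e-02          13
```

The two loci simulated under the null keep large p-values, estimate an
outlier proportion of essentially zero, and flag no individuals; the
distorted locus is rejected overwhelmingly, its outlier proportion is
driven to the 0.03 ceiling, and 13 individuals get outlier posteriors above
0.5. `--compare` additionally fits every family and prints the fraction of
loci where each has the lower BIC; `--parents` also accepts sample names,
in which case parental dosages are called from their own genotype data, or
can be omitted to maximize jointly over parental dosages.

Scenario tables and simulated genotype-likelihood VCFs for the built-in
experiment designs come from `polyseg simulate --grid
null|robustness|power --reps R --seed S --out dir/`.

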