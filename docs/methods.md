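# Methods

## The model

A two-sided P-value from a 1-df chi-square association statistic is
uniform on (0, 1) when the tested variant has no effect.  For a genuine
signal the statistic is noncentral chi-square, `X = (Z + √γ)²` with
`Z ~ N(0, 1)`, and the induced P-value density is the ratio of the
noncentral to the central density at the statistic value
`x = G₀⁻¹(1 − p)`:

    f(p | γ) = g_γ(x) / g₀(x) = exp(−γ/2) · cosh(√(γx)).

The closed form on the right is specific to 1 df and is what the package
evaluates (in log space, with `logcosh(t) = |t| + log1p(e^{−2|t|}) − log 2`,
so P-values down to 1e-300 and noncentralities in the thousands stay in
range).  The statistic inversion uses the normal-quantile route
`x = [Φ⁻¹(1 − p/2)]²`, identical to the chi-square quantile but accurate
through the far tail.  A P-value of exactly 0 is rejected rather than
clamped; callers that need a floor must clamp explicitly (the simulator
clamps at the smallest positive double, since `chi2.sf` can underflow for
extreme draws).

Under the logistic model the noncentrality decomposes as
`γ = N · D · q(1−q)` where `D = (ln OR)²`, `q` is the pooled allele
frequency, and `N = n₁n₂/(n₁+n₂)` is one half of the harmonic mean of
case and control allele counts.  Effect-size priors can therefore live on
three scales — directly on γ, on the standardized effect `E = D·q(1−q)`
(γ = N·E), or on `D` itself (γ = N·q(1−q)·D, record-specific) — and each
maps to a noncentrality-scale prior by a scalar multiplier, which for the
gamma family just rescales the scale parameter.

## Posterior conversion

With prior null probability Pr(H₀) and the marginal density for genuine
signals `f̄(p) = E_γ[f(p|γ)]`,

    Pr(H₀ | p) = [1 + (1 − Pr(H₀))/Pr(H₀) · f̄(p)]⁻¹,

and POFIG = 1 − Pr(H₀|p) is the probability the finding is genuine.
Posterior odds are accumulated in log space so values near 0 or 1 retain
relative precision; outputs below 1e-15 are reported as-is, never clamped
to zero.  The bin-mode variant replaces the sharp null by a near-zero
"null bin" (by convention odds ratios in [1, 1.001], representative
1.0005) and returns the full posterior over bins plus the posterior mean
effect Σ γᵢ Pr(Hᵢ|p); with a sufficiently narrow null bin it agrees with
the sharp-null posterior to well past two decimals.

FPRP, provided for comparison, is the tail-area analogue
`[1 + odds · F̄(α)/α]⁻¹` with `F̄(α) = E_γ[Pr(P ≤ α | γ)] ≤ 1`, which is
why FPRP can never exceed the prior while the density-based posterior
can.  The FDR estimate for a selected set of findings is the arithmetic
mean of their posterior null probabilities.

## Evaluating the marginal density

Three evaluations are implemented:

* **exact** — quadrature of `f(p|γ)` against the prior.  For a gamma
  prior with shape 1 (exponential, scale λ) the integral has the closed
  form `1/(λb) + c√π/(2λb^{3/2}) · e^{c²/(4b)} · erf(c/(2√b))` with
  `b = 1/2 + 1/λ`, `c = √x`; this is used whenever shape = 1 (including
  the vectorized per-record simulator path).  Other shapes use adaptive
  Gauss–Kronrod quadrature in `u = √γ` coordinates after subtracting the
  integrand's log maximum (located on a 1024-point grid), with the upper
  limit the larger of the prior's 1−1e-14 quantile and the point where
  the exponent has fallen 60 nats below its peak.  Convergence is
  enforced at 1e-6 relative reported error; failures raise a numerical
  error with diagnostics.  The quadrature, the closed form, and a
  Monte-Carlo average over prior draws are cross-checked in the tests.
* **mean** — the typical-effect-size plug-in `f(p | μ_γ)` with μ_γ the
  prior mean mapped to noncentrality.  For very small P-values this
  understates the density (the prior's right tail dominates there) and so
  overstates Pr(H₀|p): a conservative bias.  For the worked example's
  prior the crossover sits near p ≈ 1e-9; above it the plug-in slightly
  *overstates* the density.  The bias direction is therefore asserted in
  the tests only in the regime where it holds.
* **binned** — a weight-normalized mixture over tabulated effect sizes.
  `discretize` collapses a continuous prior into three bins whose middle
  bin is centered on the prior mean μ with width μ (edges μ/2 and 3μ/2);
  bin weights are prior masses and representative values conditional
  means within the bin (computed via the gamma first-moment identity
  `x·g(x; a, s) = μ·g(x; a+1, s)`), with interval midpoints available
  for sensitivity analysis.  For bin counts other than three — a case the
  three-bin construction does not determine — equal-probability quantile
  bins are used.  Externally published tables on the standardized scale
  `2Dq(1−q)` are converted by γ = value·N/2.

## Combining studies

The density product `∏ f̄ⱼ(pⱼ)` with the initial prior is identical to
sequential prior updating in any order (checked to 1e-12).  It ignores
effect direction.  The direction-aware route converts each two-sided p to
the signed one-sided score `Φ⁻¹(p/2)`, flips it when the study's sign
disagrees with the first study's, pools with weights wᵢ (√N of each study
by default) normalized by √(Σwᵢ²), and folds back through the far normal
tail (`p_t = 2·Φ̄(|pooled|)`, immune to `1 − Φ` cancellation).  The two
routes are *not* equivalent: the two-sided product discards
sign-concordance information (worth about a factor 2 on the Bayes factor
when two directions agree) and treats effects as independent across
studies, while the pooled-score route conditions on a shared effect.  On
data simulated under the model they agree closely in the typical range
(median relative deviation of Pr(H₀|·) under 10%) but can differ by an
order of magnitude on near-zero posteriors; the test suite asserts the
summary-level agreement.

## The simulation study

The generator reproduces the study conditions of the selection-effect
experiments: each of K tests is spurious with probability Pr(H₀)
(P-value uniform); otherwise `D ~ Gamma(1, (ln 1.1)²)` (mean odds ratio
1.1), `q ~ Uniform(0.05, 0.95)`, `γ = N·D·q(1−q)` with N = 200
(n₁ + n₂ = 800) for K up to 10⁴ and N = 1000 (n₁ + n₂ = 4000) for the
10⁶-test scans, and the P-value comes from `(Z + √γ)²`.  A sample allele
frequency is drawn binomially with n₁ + n₂ trials (the total allele
count; the choice of trial count is configurable).  Estimators see only
the P-value and the sample frequency — the truth label and γ are withheld
— and assume the generating prior and effect distribution known, at three
knowledge levels (exact integration, three bins + null bin, prior mean).

Selections are the single smallest P-value or the m smallest; retention
rules are Bonferroni (min p ≤ 0.05/K) and the Benjamini–Hochberg step-up
at 10% over all K tests with all m selected P-values required to be
significant.  The BH implementation is cross-checked against
statsmodels' `fdr_bh` and reproduces the reported retention rate of
roughly 1 in 18 experiments for the K = 10⁴, Pr(H₀) = 0.5 cell.  Note
that for K = 100, Pr(H₀) = 0.9 the BH retention rate under this design is
only ~4·10⁻⁴, so estimates conditioned on retention need large raw
replicate counts; the acceptance script uses 800,000 raw replicates for
that cell.

For K = 10⁶ scans the all-null minimum is drawn directly as
Beta(1, n_null) while the ~10³ genuine signals are simulated explicitly;
the shortcut is validated against brute force at K = 2000 within joint
Monte-Carlo error.

Replicates are generated in fixed chunks of 256 from
`SeedSequence(seed, spawn_key=(chunk,))` substreams: any single replicate
is reproducible in isolation by regenerating its chunk, results are
bit-identical for a given seed and configuration, and generation stays
vectorized.  Replicate counts in the tests and the acceptance script
(50,000 for the minP cells, 2,000–10,000 for the heavier grids) were
chosen to put three Monte-Carlo standard errors at or below about one
printed unit of the reference values.

The scan/replication experiment takes each scan's minP, regenerates the
same effect (same D and population frequency, fresh noise and a 4×
sample) in a replication study, and combines the two P-values by the
signed inverse-normal rule before converting at the pooled design
(N_scan + N_repl, pooled sample frequency).  Replication posteriors
conservatively reuse the scan's effect-size prior.

### What the generator does and does not emulate

The simulations generate independent tests with exactly the assumed prior
and effect-size distribution, so passing calibration checks demonstrate
the method's core property — immunity to selection when the prior is
correctly specified — and nothing about robustness to a *misspecified*
prior, to linkage-disequilibrium-correlated statistics, to confounding or
stratification artifacts in real P-values, or to effect heterogeneity
between studies.  Those caveats transfer directly to real-data use.

## The worked example

The Crohn's disease example ships as a packaged TSV of eleven SNPs
(scan, replication, and combined two-sided P-values from Barrett et
al.'s 2008 GWAS meta-analysis).  The reference analysis uses the prior
Pr(H₀) = 1 − 142/12877 (142 estimated susceptibility loci among 12,877
LD-defined genome segments) and an exponential noncentrality prior of
mean 17.25; the sensitivity grid varies the locus count (76/142/219) and
the prior shape (1 vs 0.634, the shape that halves the median at equal
scale).  Because the noncentrality prior is shared by all records,
posterior ranks coincide with P-value ranks here; a prior on D instead
would break that correspondence through the allele-frequency term.

## Numerical choices and limitations

* Degenerate priors (0 or 1) return the prior with a warning rather than
  an error — no data can move them.
* `sq_log_or`-scale priors require a per-record allele frequency and a
  design; records lacking them are rejected with guidance rather than
  silently falling back to another scale.
* Multiple-testing procedures are deliberately *not* applied to
  posteriors; Bonferroni/BH exist only as selection/retention rules
  inside the simulator.
* Only 1-df chi-square (and the equivalent two-sided normal) statistics
  are implemented; the P-value-distribution layer is the extension hook
  for other families.  Permutation/resampling P-values are out of scope —
  the method needs an explicit parametric alternative.
* Estimating the effect-size distribution or the susceptibility-locus
  count from data is out of scope; the package consumes such estimates.
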