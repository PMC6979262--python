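# Methods

This note documents the generative model, the estimators behind each
differential-expression (DE) test, the evaluation protocol, and the design
choices made where several defensible options existed. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The beta-Poisson count model

A single isoform's expression in one cell is modelled as

    X = λ₂ · K,   K ~ Poisson(λ₁ B),   B ~ Beta(α, β).

`B` is the transcriptional activity of the gene in that cell: promoter
bursting keeps it near 0 in many cells and near 1 in a few, which produces
the characteristic zero inflation and overdispersion of single-cell data
without a separate dropout component. `λ₁` sets the maximal transcription
rate, and `λ₂` is a lattice/scale factor (all draws are multiples of λ₂).
With `φ₁ = α/(α+β)` and `φ₂ = β/(α(α+β+1))`:

    E X   = μ = λ₁ λ₂ φ₁
    Var X = μ λ₂ + μ² φ₂  ≥  μ λ₂

The zero probability has the closed form
`P(X = 0) = E e^{-λ₁B} = ₁F₁(α; α+β; -λ₁)` (Kummer's confluent
hypergeometric), used by the fitter below.

### Parameter population priors

A simulated experiment draws per-isoform parameters independently from

| parameter | prior              | default rationale |
|-----------|--------------------|-------------------|
| α         | Gamma(shape 2, scale 1) | mostly O(1) shapes; ~26% below 1, giving strongly bimodal activities |
| β         | Gamma(shape 2, scale 2) | activities skewed toward 0 (mean φ₁ ≈ 0.35) |
| λ₁        | LogNormal(log-mean 3, log-sd 1.5) | right-skewed expression; median rate ≈ 20, heavy upper tail |
| λ₂        | fixed at 1         | scale enters through library sizes instead |

These priors keep the package self-contained while yielding the qualitative
features that matter for DE benchmarking: a right-skewed mean distribution,
a substantial zero fraction (≈ 19% of matrix entries at the defaults, checked
by test), and a realistic split into highly/lowly expressed strata. Users
with a real matrix can fit per-isoform models with `fit_bp4` and substitute
their own population. The priors are deliberately *not* tied to any specific
tissue; what passing tests show is therefore behaviour under a plausible
beta-Poisson world, not under any particular real data set.

### What the generator emulates, and what it does not

Emulated: per-isoform heterogeneity, bursting zeros, overdispersion,
per-cell library-size variation (uniform on 1–3 million by default, entering
multiplicatively through λ₂ so the expected cell total equals the drawn
library size), non-integer expression estimates, true DE as a λ₁ fold change
of `2^(±lfc)` with random sign (default: 5% of isoforms at |lfc| = 1), and
removal of all-zero rows after group concatenation.

Not emulated: batch effects, cell-cycle covariates, gene–gene correlation
(isoforms are independent given their parameters), UMI-specific noise,
multi-group designs, and transcript-length effects (hence CPM is used as the
TPM surrogate everywhere a threshold is applied). Conclusions about methods
that exploit gene–gene correlation do not transfer from these simulations.

### Fitting (`fit_bp4`)

Method of moments on (mean, variance, zero fraction), with λ₂ taken from the
value lattice when the data sit on one and 1 otherwise. Given the moment
identities, fixing the overdispersion component
`φ₂ = (s² − m)/m²` leaves a one-parameter family indexed by φ₁
(`α+β = (1−φ₁)/(φ₁φ₂) − 1`, `λ₁ = m/φ₁`); φ₁ is chosen so the model zero
probability matches the observed zero fraction. That map is monotone in φ₁,
so a bracketed root find (Brent) suffices, and the fitted parameters
reproduce the sample mean and variance exactly by construction. Degenerate
inputs (all-zero or constant vectors) are flagged, never silently fitted.
When a sample contains no zeros φ₁ is weakly identified; the fitter then
uses the deterministic fallback `φ₁ = 0.5/(1+φ₂)` and records a note.
Underdispersed samples get φ₂ floored at 10⁻⁶.

## The seven DE tests

All tests consume a `CountMatrix` with exactly two cell groups and emit one
record per isoform (statistic, effect on the log₂ scale where defined,
p-value, note). Shared degenerate rules: zero variance in both groups with
equal means → p = 1; isoforms a test cannot fit carry a missing p-value with
a note and are ranked last downstream. Count likelihoods round half-to-even
to integers, since upstream quantifiers produce fractional estimates.

1. **ttest** — Welch (unequal-variance) t on log₂(CPM+1). Welch rather than
   pooled: it is the safer default under the heteroscedasticity typical of
   single-cell groups, at negligible cost when variances are equal.
2. **wilcoxon** — two-sided Mann–Whitney on log₂(CPM+1); exact enumeration
   for small tie-free samples, tie-corrected normal approximation otherwise.
   Complete ties → p = 1.
3. **limmatrend** — per-isoform linear model on log₂(CPM+1); log residual
   variances are smoothed against average expression (lowess, span 0.4), the
   scatter of log-variances around the trend is matched to the theoretical
   scaled-F moments (`trigamma` inversion) to give a prior df d₀, and
   posterior variances `(d₀s₀² + ds²)/(d₀+d)` feed a moderated t on `d+d₀`
   df. When variances carry no scatter beyond sampling noise, d₀ = ∞ and the
   statistic reduces to an ordinary t with normal reference — checked by test.
4. **nbwald** — per-isoform negative-binomial regression, log link, log
   library-size offset. With a two-level group factor the IRLS normal
   equations decouple into scalar per-group updates, so the whole matrix is
   fitted vectorised. Dispersions are Pearson method-of-moments estimates
   (from the closed-form Poisson group fit) shrunk in log space toward a
   lowess mean-dispersion trend with 10 pseudo-observations; the group
   coefficient gets a Wald z. This is a *representative* NB test: it
   deliberately omits the quasi-likelihood F reference and the weighted
   conditional-likelihood shrinkage of the established bulk tools. A group
   with zero total counts leaves the log-link MLE unbounded; such isoforms
   get a missing p with a note.
5. **zinb** — per-isoform zero-inflated NB (mixing weight π, mean μ, size r)
   fitted by L-BFGS-B on (logit π, log μ, log r), to each group and to the
   pooled cells; the pooled solution seeds the group fits so the alternative
   likelihood can never fall below the null. LRT on 3 df — the literal
   free-parameter difference. Note the chi-square reference assumes interior
   MLEs: on data with no real zero inflation, π sits at its boundary and the
   test is conservative by construction. The calibration suite therefore
   checks it against a ZINB null.
6. **hurdle** — detection (value > 0) tested by a logistic-regression LRT
   (closed form for a binary covariate) plus a Gaussian LRT on log₂(CPM+1)
   among positive cells with shared variance; the statistics add, df = 2.
   A component with no information (all/no cells detected; fewer than one
   positive cell per group or three overall) contributes 0 with df reduced,
   which avoids spurious significance for fully detected genes. Isoforms
   with fewer than 2 positive cells overall are skipped.
7. **bp4** — beta-Poisson GLM on CPM: `E X = exp(b₀ + b₁·group)` with
   variance function `V(μ) = μλ₂ + μ²φ₂`. λ₂ is fixed per cell at the known
   counts-to-CPM factor (10⁶ / library size) rather than estimated — the CPM
   transform is known exactly, and this keeps the variance function on the
   right scale across cells. φ₂ is a pooled moment estimate per isoform.
   IRLS with group-decoupled updates; Wald z on b₁ with a Pearson
   (quasi-likelihood) scale factor, which also absorbs residual variance
   misspecification under the null.

Tests always run on the full isoform set; stratification is applied only at
evaluation time, because the trend-based tests (limmatrend, nbwald) borrow
strength across all genes.

An external tool can be attached by writing its p-values in the same
five-column tsv and feeding them to the evaluation layer; no adapter is
bundled or tested by default.

## Evaluation protocol

- **Splits** — per replicate, 2k cells per group are sampled without
  replacement; the first k per group form the training set, the next k the
  validation set. Train and validation are disjoint and group-balanced by
  construction.
- **Ranking** — by (p ascending, |statistic| descending, isoform id);
  missing p ranks last. The tie-break is arbitrary but deterministic, which
  RDR needs to be reproducible. Top-k sizes use `ceil`, so small strata
  always yield a non-empty top set.
- **Strata** — an isoform is *high* iff CPM > 1 in strictly more than 25% of
  cells ("more than" read literally as strict). Strata are computed on the
  training matrix and reused for the paired validation metrics, mimicking an
  analysis where stratification precedes validation.
- **FPR** — fraction of (non-missing) p below α in a stratum; missing p
  counts as not significant.
- **RDR / TrueRDR / ratio** — RDR is the fraction of the training top-k that
  reaches p < α in validation; TrueRDR additionally intersects with the true
  DE flags; the ratio TrueRDR/RDR is undefined (missing) when RDR = 0.
- **AUC** — on the training-ranked top-k restriction, isoforms are scored by
  −log₁₀(p) and the tie-corrected Mann–Whitney statistic against the truth
  flags gives the AUC. Ties contribute ½, so an uninformative scorer gets
  0.5. The top-k construction (training ranks, same result's scores) is one
  of several possible conventions and is fixed here by decision. Single-class
  restrictions yield a missing value with a log entry.
- **Null scenario** — for simulated data the null regenerates the data set
  with `de_fraction = 0` (a genuine global null); for user-supplied real
  matrices, `run_null_resampling` pools the cells ignoring labels and draws
  pseudo-groups.
- **Seeding** — the global seed expands through `numpy` `SeedSequence`
  children keyed by replicate and stage, so adding a method or metric leaves
  the simulator's draws untouched. Per-(method, replicate) failures are
  logged and never abort a sweep.
- **No multiplicity adjustment** — all metrics use raw p < α (default 0.05)
  by design; the benchmark measures calibration and reproducibility of the
  raw tests, not of any FDR pipeline.

## Numerical choices and problem sizes

- NB/BP4 IRLS: 25 iterations, step clipping at ±5, convergence at 1e-10;
  dispersion floors at 0 (NB) and 1e-8 (φ₂).
- ZINB optimizer bounds: logit π ∈ [−12, 7], log μ capped by the sample
  maximum, log r ∈ [log 1e−3, log 1e5]; moment-based starts.
- Trigamma inversion by Newton iteration (50 steps, relative tolerance
  1e-10).
- The bundled test suite runs simulations at 10,000 isoforms × 160 cells for
  the calibration/RDR checks (20 replicates) and smaller panels elsewhere;
  these sizes reproduce the standard study conditions while keeping the
  default test run in the tens of seconds.

## Known limitations

- Isoform independence makes Monte-Carlo standard errors across isoforms
  smaller than they would be on correlated real data; calibration bands that
  pass here can be wider in practice.
- The NB Wald test's missing-p rule for one-sided zero groups discards
  exactly the isoforms where a shrinkage-based bulk tool would report its
  most extreme effects; comparisons on the low stratum should keep that in
  mind.
- `fit_bp4` identifies φ₁ through the zero fraction; for samples with very
  few zeros the estimate is driven by a handful of observations, and for
  zero-free samples it falls back to a convention.
- The CLI accepts `--threads` for interface stability but the implementation
  is single-threaded; results are trivially independent of the value.
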