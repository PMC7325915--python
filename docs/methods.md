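# Methods

## Study design and estimand

The package targets 1:m matched ("full") case-control studies of a binary
outcome, with one case matched to 1–3 controls on age band (±5 years),
sex, recruiting center and enrolment period. For each biallelic SNP,
genotype is dichotomized under a dominant model — carrier of at least one
variant allele vs homozygous reference — and crossed with a binary drug
exposure into four cells. The estimand is the departure of the joint
exposure×genotype effect from additivity of the two separate excess odds
ratios, summarized by RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 and the synergy index
S = (OR₁₁ − 1)/((OR₁₀ − 1) + (OR₀₁ − 1)). A codominant (0/1/2) coding is
available as a configuration option.

Exposure is derived from dated intake events relative to a per-subject
index date (first symptoms for cases, interview date for controls): a
subject is exposed iff at least one event of the drug class falls in the
closed window [index − w, index], default w = 7 days. The endpoint
convention is not universal, so the window is closed and configurable;
events after the index date never count, since exposure must precede the
outcome.

## Estimation

The matched design is fit by the conditional logistic likelihood

logL(β) = Σ_s [ x_case·β − log Σ_{j∈s} exp(x_j·β) ],

i.e. conditioning on each stratum containing exactly one case. This is a
deliberate design choice over a multi-level random-effects binomial model:
because controls are matched within center and period is a stratum
attribute, conditioning on the matched set absorbs center and period
exactly, yields an explicit likelihood with closed-form score and Hessian,
and is directly testable against brute-force enumeration. Exact numeric
agreement with a random-effects fit of the same data is not expected and
not claimed. An unconditional logistic fit with fixed per-stratum
intercepts is provided as a cross-check mode only; with many small strata
it is biased away from the null (the Neyman–Scott problem), so tests
compare it on sign/ordering, never value.

Maximization is Newton–Raphson with step-halving on the exact Hessian.
Convergence: max |score| < 1e-8, or relative log-likelihood change below
1e-10; maximum 100 iterations (failure raises, carrying the trace). The
variance is the inverse negative Hessian at the optimum, symmetrized.
Coefficients beyond ±15 on the log-odds scale are reported as separated —
the MLE is effectively infinite — rather than returned silently. Strata
are padded to a common size and the likelihood evaluated with masked
log-sum-exp, so fits and bootstrap refits are vectorized over strata.

Crude 2×2 odds ratios use the Woolf log-scale interval; a single zero
cell triggers the Haldane–Anscombe +0.5 correction with a flag, and two
zero cells in a row/column leave the OR undefined.

## Covariate selection

Candidates are screened by bivariate matched models (outcome ~ candidate);
those with Wald p < 0.2 proceed. Backward elimination then repeatedly
considers dropping the remaining candidate with the largest Wald p,
accepting a drop only if (i) no exposure-term coefficient changes by more
than 10% — interpreted as relative change on the log-odds scale, with an
OR-scale alternative via config, since the convention is not fixed — and
(ii) BIC = −2 logL + k·log(n_strata) improves. The elimination log records
every considered drop. Wald tests are the default; the 10% threshold and
screening alpha are parameters.

## Interaction measures and intervals

Cell ORs are exp(β) of the three joint-category indicators. Within-stratum
re-referenced ORs (exposure within carriers, etc.) are computed either as
coefficient contrasts of the joint model (identity OR₁₁/OR₀₁, CI from the
contrast variance) or by refitting within each stratum subset; the
stratified refit is the default presentation because published tables of
this layout are typically produced that way, and both are reported.

The delta-method RERI variance uses gradient (−e^{β₁₀}, −e^{β₀₁}, e^{β₁₁})
against the 3×3 coefficient covariance; the S interval is computed on
ln S, and is undefined (flagged) when S ≤ 0. A negative denominator for S
is permitted but flagged as an interpretability warning. The independent
check is a stratum-level nonparametric bootstrap (strata resampled with
replacement, model refit warm-started at the full-data MLE, percentile
intervals, seeded); on a 1000-stratum cohort its endpoints agree with the
delta method within a few percent of the interval width. RERI is also
recomputed from the stored ORs and must match the coefficient-path value
to machine precision — display rounding (2 dp) is applied only at render
time.

Presentation follows the joint-classification recommendations for
reporting interaction: per-cell Ns, cell ORs against the common reference
(printed 1.00), within-stratum ORs, RERI and S with CIs. Any SNP with
fewer than 5 subjects (cases + controls) in one of the four cells is
segregated as "inconclusive"; the threshold is configurable. No
multiple-testing correction is applied across SNPs (configurable off by
design); multiplicative-scale product-term p-values live in the fit
output only.

## Hardy–Weinberg QC

HWE is assessed in controls. The default test is the 1-df Pearson
chi-square of observed genotype counts against (1−p̂)², 2p̂(1−p̂), p̂² at the
estimated allele frequency; monomorphic SNPs return χ² = 0, p = 1 with a
flag. An exact test enumerates the heterozygote count conditional on the
allele counts (P(h) ∝ 2^h / (n_AA! n_Aa! n_aa!)), summing configurations
no more probable than the observed one. SNPs with HWE p below a
configurable alpha (default 0.001) or call rate below 0.98 are flagged —
never auto-dropped, because the flagging direction conventions differ
across reports and dropping is an analyst's decision.

## Synthetic-data generator

The generator emulates the matched hospital-based design: a large source
population (default 150 × n_strata) with ages mixed 12.7% under 45, 36.2%
45–65, 51.1% over 65 within 18–90, 74.7% male, four centers, two
enrolment periods; genotypes drawn under HWE at the configured MAF
(default 0.3, giving carrier prevalence ≈ 0.51); exposure Bernoulli with
baseline odds set by the control prevalence (default 0.03, matching
low-dose-aspirin use in an elderly outpatient control series) multiplied
by each confounder's exposure OR; disease odds = small baseline (0.012) ×
cell multiplier (1, OR₁₀, OR₀₁, OR₁₁) × confounder outcome ORs, with
OR₁₁ = OR₁₀ + OR₀₁ − 1 + RERI_target inverted from the target RERI. Cases
are then sampled and greedily matched to unused disease-free controls
sharing the 5-year age band, sex, center and period. Because the baseline
odds are small, cell odds ratios ≈ risk ratios and the conditional model
recovers the configured ORs; non-collapsibility effects are below
Monte-Carlo error at the sizes tested. Exposed subjects receive an
aspirin event inside the window; 10% of unexposed subjects receive a
stale event outside it, so the window logic is exercised end to end.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (simulated independently), dose–response, measurement error in
recall, the real study's full covariate joint distribution, or
informative missingness. Passing recovery/calibration tests therefore
demonstrates correctness of the estimators under the declared model, not
robustness to those real-data features.

## Simulation sizes used in the test suite

Chosen as the package's own verification conditions: end-to-end recovery
uses 3000 strata with cell ORs (3.42, 0.85, 8.22) and a 3-SE tolerance;
null calibration uses 500 replicates of 300 strata with 20% exposure
prevalence — at the study-like 3% prevalence the exposed cells at this
stratum count are near-empty and no Wald-type interval is expected to be
calibrated, so the calibration check is run where the asymptotics it
tests are in force; delta-vs-bootstrap agreement uses 1000 strata and
2000 bootstrap replicates; HWE behaviour uses 100 seeds of 200-strata
cohorts (600 controls), large enough that the chi-square null
distribution is continuous to the 0.01 level being checked.

## Degenerate inputs and tie-breaks

Strata losing their case, all controls, or covariate completeness are
dropped per-analysis and logged (complete-case per SNP, so per-SNP Ns
vary and are reported). Stratum-constant columns contribute nothing to
the conditional likelihood; a singular Hessian falls back to a ridged
solve and pseudo-inverse covariance. In backward elimination, candidates
are tried in decreasing Wald-p order and the first acceptable drop is
taken. Bootstrap replicates that fail to converge or separate are skipped
(counted implicitly by the replicate totals).

## Known limitations

No random-effects GLMM solver and no Firth correction (separation is
reported, not corrected). The exact HWE enumeration is O(minor-allele
count) per SNP — fine for cohort-scale counts. The generator's greedy
matcher can fail on infeasible configurations (tiny population
multiplier); it raises with the remedy rather than silently returning
fewer strata. VCF ingestion reads biallelic GT fields only.
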