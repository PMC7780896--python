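# Methods

## The two-sample model and what the package estimates

All computation starts from per-SNP summary associations: gamma_hat_j with
standard error sigma_Xj from the exposure sample, alpha_hat_j with sigma_Yj
from the outcome sample, aligned to a common effect allele. The generative
model behind both the estimators' assumptions and the synthetic-data module
is

    gamma_hat_j = gamma_j + k_x psi_j + eps_Xj
    alpha_hat_j = alpha_j + k_y psi_j + beta (gamma_j + k_x psi_j) + eps_Yj

with independent mean-zero noise of variances sigma_Xj², sigma_Yj². beta is
the causal effect of interest; alpha_j is a direct ("horizontal pleiotropic")
effect; psi_j links SNP j to a confounder U with loadings k_x, k_y on
exposure and outcome. U is modeled per-SNP through psi_j, which is what the
displayed equations imply (no shared confounder realization across SNPs is
needed at the summary level).

## Harmonization and clumping

* Tab-delimited tables (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N; a
  `column_map` handles dialects). Alleles are uppercased; indels and
  multi-allelic rows are rejected with row-level reasons; se <= 0 rejects a
  row rather than the file.
* Clumping is greedy by ascending p-value under an externally supplied
  pairwise r² table (default r² < 0.001 within 10,000 kb). LD is an input,
  not computed from genotypes: the package is summary-statistic-only.
* Harmonization keeps or sign-flips the outcome beta for matching allele
  pairs. Palindromic (A/T, C/G) variants are oriented by allele-frequency
  agreement and dropped as "ambiguous palindrome" when either trait's MAF
  exceeds 0.42 — the field's de-facto cutoff; the frequency rule itself has
  no information left near 0.5. Palindromes without frequency, strand-flipped
  non-palindromes, and unmatched allele sets are dropped with explicit
  reasons rather than guessed at. Every input SNP ends up either harmonized
  or dropped-with-reason, so accounting is conserved.

## Diagnostics

* mean F = (1/J) Σ (gamma_hat_j/sigma_Xj)²; weak-instrument flag at <= 10.
* I²_GX = max(0, (Q_GX − (J−1))/Q_GX) from the weighted heterogeneity of
  gamma_hat; NOME flagged violated below 0.90 (equality satisfies).
* Cochran's Q about the IVW estimate with first-order weights
  w_j = gamma_hat_j²/sigma_Yj² (J−1 df); Rücker's Q′ as the weighted RSS of
  the Egger fit (J−2 df). First-order weights are the baseline of the
  literature this routing comes from; modified second-order weights are out
  of scope. Significance for all heterogeneity flags is 0.05.

## Estimators

All slope and intercept inference uses the two-sided normal reference, for
cross-method consistency. Standard errors are model-based (fixed-effect):
IVW SE = sqrt(1/Σw), Egger covariance (XᵀWX)⁻¹ with no dispersion factor.
This keeps the algebraic identity "Egger slope with intercept constrained to
zero = IVW slope" exact, which the tests assert. Heterogeneous settings are
routed to other methods by the selector rather than patched with
random-effects inflation.

* **Egger orientation**: every SNP is flipped so gamma_hat_j >= 0 before the
  fit (the intercept is only meaningful in that frame).
* **SIMEX**: lambda grid (0, 0.5, 1, 1.5, 2), 1,000 perturbation replicates
  per positive lambda, quadratic extrapolation of the per-lambda mean
  coefficients to lambda = −1. SEs extrapolate the per-lambda mean
  model-based SEs the same way (the "simple extrapolation" variant); this is
  approximate and documented as such, falling back to the naive SE if the
  extrapolated value is nonpositive. With sigma_X identically zero the
  estimator short-circuits to plain Egger, exactly.
* **Weighted median**: ratios sorted (ties broken by SNP id), normalized
  weights w'_j, mid-interval positions p_k = s_k − w'_k/2, linear
  interpolation of the percentile function at 1/2 with clamping at the ends.
  SE from 1,000 parametric bootstrap draws of (gamma_hat, alpha_hat); the
  bootstrap is seed-controlled. Note the folk rule "an instrument with >50%
  weight returns its own ratio" is exact only when that instrument's weight
  interval is centred on 1/2; elsewhere interpolation applies, as in the
  estimator's standard definition.
* **MR-PRESSO**: observed RSS uses leave-one-out IVW predictions (avoiding
  self-influence); the null distribution re-simulates both gamma_hat and
  alpha_hat and recomputes the leave-one-out statistic per simulated
  dataset. Global and per-SNP p-values use the add-one rule, so the floor is
  1/(n_sim+1) (default n_sim = 5,000). Outliers are flagged at p <
  0.05/J (Bonferroni); the corrected estimate is IVW on the remainder; the
  distortion test compares the observed raw-vs-corrected shift against
  shifts from dropping random same-size subsets. With no outliers the
  distortion step is skipped and no corrected estimate is emitted.

## Method selection

Flags: weak instruments (mean F <= 10), NOME violated (I²_GX < 0.90), and
significance of Q, Q′ and the PRESSO global (RSS) test. Heterogeneity means
any of the three tests fired. The rule set:

* no heterogeneity — strong instruments → IVW (a low I²_GX alone does not
  displace IVW, which is not dilution-prone); weak instruments → weighted
  median; weak instruments with NOME violated → Egger (SIMEX);
* heterogeneity with NOME violated → Egger (SIMEX);
* heterogeneity with NOME satisfied → pattern of (Q, Q′, RSS): all three →
  MR-PRESSO; Q alone or Q with Q′ → MR-Egger; Q′ or RSS patterns not
  implicating Q → IVW with strong instruments, MR-PRESSO with weak; Q with
  RSS → Egger and PRESSO jointly.

Patterns not exemplified in applied tables carry a "low-confidence" note in
the rationale. The design was genuinely open here: published checkmark
tables of this routing are partly garbled in circulation, so the rules were
reconstructed from the per-pair recommendations in the bundled 39-row
validation dataset (`mrkit.datasets.glycemic_assumption_checks`), where they
reproduce 36 of 39 rows; the three exceptions are rows the source itself
treats inconsistently (identical flag profiles routed differently
elsewhere in the same table). When the PRESSO global p is unavailable and
neither Q nor Q′ fired, RSS is assumed nonsignificant with a note; if either
fired, selection refuses rather than guesses. InSIDE is treated as
untestable and never flagged.

## Power

Two-sided asymptotic Wald power: Phi(ncp − z_{1−a/2}) + Phi(−ncp − z_{1−a/2})
with ncp = |b| sqrt(n R² v); v = cf(1−cf) for binary outcomes (case fraction
cf) and 1 for continuous ones. Both tails are retained so power(0) = alpha
exactly. An unadjusted binary variant (v = 1) is exposed for comparability
with calculators that assume a fixed standardized effect; the adjusted form
is the default. Validation is against a Monte-Carlo draw of the Wald
statistic, not against published figure read-offs.

## Synthetic data: what it emulates and what it does not

The generator draws |gamma_j| ~ Uniform(0.05, 0.3) (random sign by default),
noise scales uniform on configurable ranges (defaults sigma_X in
0.003–0.008, sigma_Y in 0.05–0.15 — strong instruments, mean F in the
hundreds, I²_GX ≈ 1), invents alleles and frequencies deterministically from
the seed (10% palindromic by default), and emits the exact equations above.
Direct effects hit a configurable fraction of SNPs with mean/SD and an
optional correlation with gamma (InSIDE violation). In sign-coherent
("directional") regimes gamma is oriented positive: a nonzero mean direct
effect is only meaningful relative to the exposure-raising allele, and under
random gamma signs it would cancel in the Wald ratios rather than bias them.
A truth sidecar retains every latent quantity so recovery tests never
re-derive them.

Scenario presets fix the regimes used throughout testing: `null`,
`valid_causal` (beta 0.2), `balanced_pleiotropy`, `directional_pleiotropy`
(mean 0.05), `inside_violated` (rho 0.7), `weak_instruments` (mean F ≈ 5),
`nome_violated` (positive-sign gamma in 0.1–0.3 with sigma_X ≈ 0.034–0.042,
giving I²_GX ≈ 0.7 while mean F ≈ 30, and beta 0.3 so dilution is visible;
sigma_Y 0.008–0.015 keeps the dilution bias large against sampling noise),
and `outlier_contaminated` (10% of 20 SNPs with ≈5 sigma_Y direct effects).

What the generator does not emulate: LD between instruments (r² is an
external input), allele-frequency-dependent effect sizes, sample overlap
between the two samples, binary-trait liability scaling, and population
stratification. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the stated model, not
robustness to those real-data features.

## The synthetic study design

`synthetic_study` instantiates the full design: exposures with 34, 7 and 11
instruments crossed with 6 cancer and 7 vascular outcomes (so the Bonferroni
thresholds are 0.05/6 and 0.05/7), replication sources for CAD and LDL
cholesterol, and true effects only for FPG → CAD (0.21) and HbA1c → LDL
(0.23). Each exposure's latents are drawn once; every outcome redraws
outcome-sample noise from the shared truth, so one outcome table covers all
three exposures' instruments, as in a real outcome GWAS.

## Numerical and procedural choices

* Greedy clumping ties broken by SNP id; harmonized sets preserve clumped
  (chromosome, position) order so reruns reproduce bit-identically.
* Stage seeds derive from the study seed via CRC32 of (seed, stage, names),
  keeping every derived seed below 2^31 and the whole pipeline deterministic.
* Degenerate inputs fail loudly: zero gamma (undefined ratio), J below a
  method's minimum, all-equal gamma after orientation (singular Egger
  design), missing in-window r², empty harmonized intersection.
* Pairs with fewer than two harmonizable SNPs are reported "not estimable"
  with reasons instead of raising; skipped methods keep their grid cell with
  a reason so the 195-cell accounting stays checkable.
* Simulation sizes in the test suite and acceptance script (e.g. 1,000 null
  replicates for IVW calibration, 500 for recovery, 200 for SIMEX/PRESSO
  behaviour, 100,000 Monte-Carlo draws for power) were chosen to make the
  Monte-Carlo error small against the tolerances being asserted while the
  whole suite stays fast; pipeline-level runs in tests reduce the inner
  simulation counts (PRESSO n_sim, SIMEX replicates, bootstrap draws) since
  only accounting, not precision, is at stake there.

## Known limitations

* No random-effects IVW, mode-based or multivariable estimators; no proxy
  SNP search; no remote data retrieval.
* SIMEX standard errors are extrapolation-based approximations, not the
  full asymptotic variance of the SIMEX estimator.
* The selector encodes one defensible reconstruction of common practice;
  mixed heterogeneity patterns outside the well-supported ones are
  explicitly low-confidence.
* Units are opaque labels carried from input (logOR vs mg/dL vs SD); no
  conversions are attempted.
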