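# Methods

This note documents the models, calibrations and numerical choices behind
`rtcit`: a simulation and analysis pipeline for the Go/No-go variant of the
reaction-time Concealed Information Test (RT-CIT).

## The paradigm

The RT-CIT probes recognition memory: an examinee classifies serially
presented items as *familiar* or *unfamiliar*. Probes (the examinee's own
first and last name) must be denied — classified "unfamiliar" like the
eight matched irrelevant names — while two learned target cities require
the "familiar" response, forcing attention to item identity. The Go/No-go
variant adds two no-go animals for which any press is a commission error,
indexing response-inhibition capacity. The default session uses the
multiple-probes protocol: all 14 items intermixed, 6 presentations each per
block, 4 blocks (336 trials), 1500 ms stimulus duration, 800 ms response
deadline, ISI drawn uniformly from {250, 500, 750} ms, and no item on two
consecutive trials.

The per-participant **RT-CIT effect** is the mean probe RT minus the mean
irrelevant RT over retained go trials; **dCIT** divides this difference by
the SD of that participant's retained irrelevant RTs.

## Trial-schedule generation

Each block is a uniform random permutation of six copies of every item.
Adjacent repeats (the block boundary treated as contiguous, since the
session runs continuously) are removed by re-drawing a random swap partner
for the offending position, with bounded retries and a full-reshuffle
fallback. At the default density (14 items, 6 repetitions) a handful of
repairs per block suffices; the residual deviation from uniformity over
constraint-satisfying sequences is negligible for every quantity this
package computes.

## Reaction-time model

Go-trial RTs are **ex-Gaussian**: Normal(mu, sigma) plus an independent
Exponential(tau), the standard positively skewed RT law; mean = mu + tau.
The study design only pins down participant-level summaries, so the
within-subject structure is a modelling convention:

| parameter | default | role |
|---|---|---|
| `base_rt_mean_ms` | 477.47 | population mean of per-participant mean irrelevant RT |
| `base_rt_between_sd_ms` | 33.28 | between-subject SD of that mean |
| `within_sd_irrelevant_ms` | 100 | trial-to-trial SD within a participant |
| `exgauss_tau_ms` | 60 | exponential component (sigma = sqrt(100² − 60²) = 80) |
| `probe_shift_mean_ms` / `probe_shift_sd_ms` | 54.91 / 32.43 | between-subject distribution of the CIT effect |
| `target_shift_mean_ms` / `target_shift_sd_ms` | 40 / 15 | additive target slowing (never analyzed; plausibility only) |
| `commission_mean` / `commission_between_sd` | 0.312 / 0.141 | no-go false-press probability, linked negatively to the inhibition latent |
| `error_prob_go` | 0.05 | wrong-button probability on go trials |

The 100 ms within-subject SD is a typical RT-CIT magnitude and is what
makes a 54.91 ms mean effect translate into dCIT ≈ 0.55 and a simulated
detection AUC ≈ 0.92; it is exposed as configuration. The commission
between-subject SD is set slightly below the observed no-go-error SD
(7.49/48) because the binomial trial noise of 48 no-go trials adds the
remainder.

A draw beyond the 1500 ms stimulus duration is recorded as an omission.
Presses on no-go trials take the habitual "unfamiliar" button and their
latencies, while recorded, never enter RT summaries.

**Known attenuation.** Because the trial filter discards presses above
800 ms and probes are shifted rightward, filtering clips slightly more of
the probe distribution than of the irrelevant one. Under the defaults the
retained-trial CIT effect averages ≈ 52.6 ms rather than the generating
54.91 ms (≈ −2.3 ms), and the retained irrelevant-RT SD is ≈ 96.5 ms rather
than 100. The generating parameters are kept at the published summary
values rather than inflated to cancel this; tests therefore compare
study-sized cohorts at their own sampling error (3 SE at n = 86 is
±10.5 ms) rather than asserting exact large-n equality.

## Latent traits and questionnaires

Four standardized latents — primary psychopathy, secondary psychopathy,
impulsivity, inhibition capacity — follow a multivariate normal whose
correlation matrix is **disattenuated** from the scored-scale targets:
latent r = target r / sqrt(alpha_i × alpha_j). With targets
r(secondary, BIS-11) = 0.516, r(primary, secondary) = 0.300,
r(primary, BIS-11) = 0.185 and reliabilities 0.80 / 0.63 / 0.84, the
secondary–impulsivity latent correlation is 0.709. Inhibition capacity
correlates negatively with the others at the observed no-go-error
correlations divided by the respective scale's sqrt(alpha) (its own
reliability is not separately identified).

Item responses are graded: item = loading × latent + noise, cut at three
thresholds into {1, 2, 3, 4}. Two calibrations make the *scored* data meet
their targets:

1. **Reliability.** The common inter-item correlation implied by the alpha
   target is obtained from the Spearman-Brown inversion
   rho = alpha / (k − alpha(k − 1)).
2. **Categorization loss.** Cutting a continuous response into four
   categories attenuates pairwise correlations by a factor a² =
   cov(X, cat(X))² / var(cat(X)) (≈ 0.88 for centred thresholds); the
   latent inter-item correlation is inflated by 1/a² so the categorized
   items, not the latent ones, hit the target.

Thresholds are unit-spaced and shifted so the expected item mean matches
the published scale mean divided by the item count (e.g. 19.03/10 for
secondary LSRP). The generator emits already-oriented items; consequently
the packaged default scoring key has **no reverse-keyed items** (LSRP items
1–16 primary, 17–26 secondary). Real data must be scored with the published
keys, supplied as a `ScaleKey`.

Post-test ratings (probe/irrelevant significance on 1–9, motivation and
felt impulsivity on 1–10) are normal draws rounded and clipped to their
scales. Because the probe-significance target (8.58) sits near the ceiling,
the latent mean is solved (Brent's method on the exact rounded-clipped
expectation) so that the *observed* mean equals the configured value.

By default the probe shift is drawn **independently** of all four latents:
the null regime in which the CIT effect carries no association with
secondary psychopathy. `probe_shift_trait_corr` injects a correlation for
power analyses.

## Exclusion rules

Trial level (go trials only): press < 150 ms, press > 800 ms, wrong
button. Omissions are retained but contribute no RT. Participant level,
evaluated on unfiltered data in fixed order: (1) incomplete session
(< 336 trials), (2) error rate ≥ 50% on any of probe / irrelevant / target
trials. An omission counts as an error for rule (2) by default — both
invalidate a go trial — with `count_omissions_as_errors=False` available
since the original rule's treatment of omissions is ambiguous. The no-go
error count uses the designed 48 no-go trials as denominator.

## Detection efficiency (ROC/AUC)

Real naive controls are unavailable by design, so the negative class is
simulated: naive dCIT ~ Normal(0, SD) with

    SD = sqrt( ((N − 1)/(N − 3)) · (4/N) · (1 + delta²/8) ),

the sampling SD of a standardized mean difference at sample size N, with
delta = 0 for naives (N = 86 gives 0.2182). `N` defaults to the observed
knowledgeable count but is a parameter. Each of 1000 bootstrap repetitions
draws a fresh naive sample of the knowledgeable group's size and computes
the rank-based AUC (Mann–Whitney U / n₁n₂, ties ½); the mean and the 2.5/97.5
percentile interval summarize the repetitions. The knowledgeable scores are
held fixed, matching the original procedure; `resample_knowledgeable=True`
additionally bootstraps them. Under binormal scores the expected AUC is
Φ(μ_k / sqrt(σ_k² + SD²)), which the test suite uses as a closed-form
oracle.

## Bayesian statistics

* **JZS t test**: Cauchy(0, √2/2) prior on the standardized effect against
  the point null. BF₁₀ is the prior-averaged noncentral-t density of the
  observed t divided by the central-t density, via adaptive quadrature
  (`epsrel` 1e-10; a doubled-resolution recomputation agrees to < 1e-6).
  Directional tests fold the prior onto the hypothesized sign, doubling
  the one-sided mass. The study's preregistered hypotheses were
  directional, and the headline BF₁₀ for the CIT effect (≈ 9.5 × 10²³ at
  t(85) = 15.7) is the one-sided value — exactly twice the two-sided one
  at such extreme t.
* **Correlation BF**: stretched beta(1/κ, 1/κ) prior on ρ with κ = 1
  (uniform), combined with the exact reduced likelihood
  (1 − ρ²)^((n−1)/2) (1 − ρr)^((3−2n)/2) ₂F₁(½, ½; n − ½; (ρr + 1)/2),
  integrated in likelihood-ratio form (against ρ = 0) to keep the
  integrand O(1). At r = 0.038, n = 86 this yields BF₀₁ = 6.99.
* **Sequential analysis**: the correlation BF recomputed on the first
  n pairs for n = 5…N, tracing the evidential flow.
* Cohen's d = t/√n; its default 95% CI is the large-sample normal
  approximation SE = sqrt(1/n + d²/2n), which reproduces the study's
  printed interval; a noncentral-t inversion is available via
  `method="noncentral"`. Bonferroni: alpha/m.

BFs are computed from summary statistics (t or r, and n) so published
values are reproducible without raw data. Independent cross-checks against
`pingouin` (a separate implementation of both defaults) agree to ~1e-4
relative error for t tests (pingouin's own quadrature tolerance) and ~1e-6
for correlations.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit `numpy` Generator; the
pipeline spawns independent substreams from one master `SeedSequence` per
stage, so re-running one stage never perturbs another. Identical seed and
configuration give byte-identical artifacts.

Default analysis sizes: cohorts of 86 participants (the study's final
sample); calibration checks use 5000 participants, where the Monte-Carlo
SE of a scale correlation is ≈ 0.010 and of Cronbach's alpha ≈ 0.01; the
detection reproduction replicates the full 86-participant bootstrap
procedure and averages replications, since a single 86-score cohort has a
mean-AUC sampling SD of ≈ 0.014 around the expected 0.920.

## Limitations

* Trial-level RT distributions, within-subject SD and the go error rate
  are conventions, constrained only by participant-level summaries;
  passing tests show internal consistency of the pipeline, not fidelity to
  any specific empirical trial-level distribution.
* No sequential trial dependencies, practice/fatigue drift,
  speed–accuracy trade-offs or countermeasure behavior are modelled.
* The ±2.3 ms filter-induced attenuation of the generated CIT effect
  (above) is accepted rather than compensated.
* Cronbach's alpha assumes tau-equivalent items; the generator's items are
  parallel, so alpha equals reliability here by construction.
* BIS-11 subscales and three-factor LSRP scorings are out of scope; only
  the totals analyzed in the study are produced.
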