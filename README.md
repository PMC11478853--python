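# rtcit

Simulation and analysis pipeline for the **Go/No-go reaction-time
Concealed Information Test** (RT-CIT), a memory-detection paradigm used in
forensic and deception research.

In an RT-CIT, an examinee classifies serially presented items as familiar
or unfamiliar. Crime- or identity-relevant *probes* (here: the examinee's
own name) must be denied among matched *irrelevant* items; resolving that
response conflict slows probe responses. The per-participant

    RT-CIT effect = mean RT(probes) − mean RT(irrelevants)

indexes concealed knowledge, and its standardized form
`dCIT = effect / SD(irrelevant RTs)` drives detection. The Go/No-go variant
adds *no-go* items (respond by withholding) to measure response-inhibition
capacity alongside *target* items that force attention.

The package covers the full analysis chain for this paradigm:

* **`rtcit.simulate`** — synthetic cohorts: trial schedules (14 items × 6
  repetitions × 4 blocks, no adjacent item repeats), ex-Gaussian reaction
  times, latent-trait-driven LSRP and BIS-11 item responses with
  calibrated reliabilities, post-test ratings.
* **`rtcit.preprocess`** — preregistered-style exclusion rules (presses
  < 150 ms or > 800 ms, wrong button; participants with ≥ 50% errors or
  incomplete sessions) and per-participant summaries.
* **`rtcit.scales`** — LSRP (total/primary/secondary) and BIS-11 scoring
  with reverse-key support, Cronbach's alpha.
* **`rtcit.detection`** — dCIT, the simulated-naive negative class with
  `SD = sqrt(((N−1)/(N−3))·(4/N)·(1+δ²/8))`, rank-based AUC and the
  1000-repetition bootstrap with percentile CI.
* **`rtcit.bayes`** — default Bayes factors by numerical quadrature: JZS
  t test (Cauchy(0, √2/2) prior, two-sided or directional) and Pearson
  correlation (stretched-beta prior, κ = 1), sequential BF trajectories,
  Cohen's d with CI, Bonferroni correction.
* **`rtcit.pipeline` / `rtcit` CLI** — end-to-end orchestration with one
  master seed and machine-readable outputs.

See `docs/methods.md` for the models, calibrations and numerical details.

## Worked example

Run the full pipeline — simulate 86 participants, apply exclusions, score
questionnaires, estimate detection efficiency, and compute the Bayesian
statistics:

```bash
rtcit report --seed 1 --n 86 --out run1
rtcit analyze --summaries run1/participant_summaries.csv \
              --scores run1/scores.csv --out run1
```

which prints

```
CIT effect 48.05 ms, t(85) = 14.76, d = 1.59, BF10 = 2.158e+22
r(CIT effect, secondary LSRP) = -0.083, BF01 = 5.61
```

Reading these numbers: this simulated cohort shows a mean probe slowing of
48 ms with overwhelming evidence against a null effect (a one-sample
Cohen's d of 1.59 and a directional JZS Bayes factor of ~10²²), while the
correlation between the CIT effect and secondary-psychopathy scores is
near zero, with the Bayes factor favoring the null about 5.6 : 1 — the
generator's default regime draws the probe shift independently of all
latent traits. `run1/run_summary.json` additionally reports the bootstrap
detection efficiency for this cohort (mean AUC 0.906, 95% CI
[0.881, 0.927] against the simulated naive group) and
`run1/correlation_matrix.csv` holds the full measure-by-measure matrix
with Pearson r below and Bayes factors above the diagonal.

The same stages are available as library calls (`simulate_cohort`,
`summarize_participants`, `score_questionnaire`, `bootstrap_auc`,
`bf_ttest`, ...) and as individual subcommands (`simulate`, `preprocess`,
`score`, `detect`, `analyze`, `validate`).

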