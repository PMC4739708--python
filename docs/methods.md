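# Methods

## Classification model

Each experiment contributes two amplitude series: the pre-pairing baseline
(default 120 sweeps at 0.2 Hz) and the post-pairing test epoch (default 120
sweeps at 0.2 Hz, at least 10 min). The normalized strength change is

    Δ_N = 100 · (mean_post − mean_pre) / mean_pre   [%]

computed over *all* retained baseline sweeps (no trailing sub-window; the
choice is configurable in spirit by slicing the series before calling the
classifier). The plasticity call combines two criteria, both required:

* magnitude — Δ_N must strictly exceed +15% (LTP) or fall below −15% (LTD);
  Δ_N = +15.0 exactly is NC ("exceeded" is read as strict);
* significance — a two-tailed two-sample t-test of pre vs post sweep
  amplitudes with p < 0.05. Classical Student's pooled-variance t is the
  default; Welch is available via `ClassificationParams(test_variant=
  "welch")`. The test runs on raw sweeps, not binned means.

Degenerate input (both epochs constant) yields p = 1 and NC when the
constants agree, p = 0 when they differ. Amplitudes are compared on their
absolute value so inward-current (negative pA) and depolarizing-potential
conventions behave identically. The joint criterion is strongly
conservative on null data: with 10% sweep noise and n = 120 per epoch the
±15% threshold sits ~11 standard errors from zero, so the null
false-positive rate is far below the nominal 5% (checked empirically over
1,000 simulated null experiments).

## Quality control

Five exclusion rules, each with its own failure code: Ra above 40 MΩ
(`ra_absolute`); Ra above 20% of the cell's input resistance
(`ra_relative`); first-to-last Ra drift above 20% of the first reading
(`ra_drift` — the first reading is the reference, a choice the drift rule
leaves open); membrane potential above −60 mV (`vm`); and a significant
OLS linear trend of baseline amplitude on time at p < 0.05
(`baseline_trend`). Missing Ra or Vm raises a structured error rather than
passing silently.

## Input-mixing Monte Carlo

An SCR is built by sequential sampling from a unitary-connection database.
The first draw picks an outcome class from the marginal class frequencies
(default 7/43, 18/43, 18/43 for LTP/LTD/NC) and then a member uniformly
within that class. Each later draw repeats the first draw's class with
probability S and falls back to the marginal frequencies otherwise, making
P(same class) linear in S with slope 1 − p(class). Sampling stops at the
first draw that brings the cumulative pre-pairing strength to 350 pA, so
every SCR satisfies `SCR_pre ≥ 350 pA` and is minimal (dropping the last
member would fall below the threshold). `SCR Δ_N` is the normalized
difference of the summed post- and pre-pairing strengths.

Design choices where the procedure was genuinely open:

* **Sampling with replacement within an SCR (default).** At S = 1 an
  all-LTP SCR needs ~18 draws from a 7-member class, which is impossible
  without reuse; the without-replacement mode is retained for sensitivity
  analysis and raises an explicit class-exhaustion error.
* **Two-stage draw** (class by probability, then uniform member within the
  class) is the maximum-entropy completion of class-level probabilities.
* **The first draw is always unbiased** — segregation conditions later
  draws on it, it does not bias it.
* `n_scr` defaults to 26 to mirror the observed ECS sample size; Monte
  Carlo checks use larger runs (1,000–10,000) for precision.
* The database size defaults to 43 entries with class frequencies 7/43,
  18/43, 18/43; both are parameters.

At S = 1 with many inputs per SCR, Δ_N concentrates near the
strength-weighted mean change of the first-drawn class, so Var(SCR Δ_N)
approaches the between-class variance of the class-mean changes under the
first-draw probabilities (`between_class_variance`); this closed form is
the oracle for the variance-monotonicity checks.

The segregation sweep compares Var(SCR Δ_N) at each S in {0, 0.1, …, 1.0}
against the variance of a reference Δ_N sample (the classified ECS
experiments) with a two-sided variance F-test.

## Statistics

* **Variance F-test**: F = s²_x/s²_y with (n_x−1, n_y−1) df and two-sided
  p = 2·min(P(F≤f), P(F≥f)). Two-sided because the variance comparison is
  stated without direction; swapping samples gives the reciprocal statistic
  and identical p.
* **Two-sample KS** with the asymptotic p-value (at sample sizes 26–43 the
  exact/asymptotic difference is immaterial at the thresholds used).
* **Shapiro–Wilk** for per-condition normality (3 ≤ n ≤ 5000).
* **Gaussian KDE** with Silverman's rule-of-thumb bandwidth by default
  (bandwidth exposed); raw densities integrate to 1 ± 1% on the default
  grid (data range padded by four bandwidths), with optional normalization
  to the peak for overlay displays.
* **ECDF** as a right-continuous step function.

## Synthetic-data generator

The generator emulates the *statistical* structure of the experiments, not
their biophysics (no membrane currents, spikes or GABAergic conductances):

* Protocol: 120 baseline stimuli at 0.2 Hz, 60 pairings at 0.1 Hz
  (postsynaptic onset leading by 10 ms — stored as a protocol constant,
  not simulated), ≥10 min of post-test at 0.2 Hz. Pairing sweeps carry no
  amplitudes; the epoch is a time gap.
* Baseline response scale: 375 pA (V-clamp) or 4 mV (I-clamp), matching
  the ~350–400 pA / 3–5 mV targets.
* Sweep noise: multiplicative Gaussian with CV 0.10. No sweep-to-sweep
  noise statistic is published; 10% keeps the printed between-cell group
  SDs dominant over within-cell measurement noise. Configurable.
* Group effect sizes: per-outcome truncated normals. The disinhibited
  composition uses the printed group statistics (7 cells at +39.9 ± 14.7%,
  9 at −38.5 ± 20.4%, 10 at −3.0 ± 7.6%), truncated at the ±15% class
  boundary because those group statistics describe *classified* cells — the
  generating ground truth must respect the class definition for round-trip
  label counts to be exact. The control composition (1 LTP, 3 LTD, 24 NC
  of 28) has no printed group statistics; plastic cells get well-separated
  ±30% effects and NC cells a null effect.
* SCS database: unitary strengths from a positive-truncated normal with
  mean 19.4 pA — forced by the 350 pA compound target divided by the
  ~18.05 mean inputs per compound response — and SD 6 pA (not published;
  configurable). Per-class strength changes default to the disinhibited
  group statistics above, since the unitary per-class statistics are not
  published. Outcome labels are multinomial with the 7/43, 18/43, 18/43
  frequencies.
* Access resistance drifts linearly from its initial value by
  `ra_drift_pct` over the recording; QC-failing fixtures use >20%.

What passing tests show — and do not show — about real data: the pipeline
correctly recovers compositions, calibrations and analytic limits under
the generator's assumptions (independent multiplicative noise, truncated
normal effect groups, linear Ra drift). Real recordings have correlated
sweep noise, run-down, seal instabilities and non-normal effect
distributions; results on real data depend on the unpublished
per-connection strengths and changes, so the observed-data statistics
(e.g. the exact S value where the variance difference vanishes) are
reproduced only qualitatively here: the S ≥ ~0.9 crossover depends on the
true unitary values and the observed ECS variance.

## Numerical choices and problem sizes

* Randomness: numpy `Generator` streams; datasets spawn independent child
  streams per cell, so results are bit-reproducible for a given seed and
  stable under count changes of other classes.
* The baseline-trend test treats a perfectly constant baseline as stable
  (slope 0) and a perfect nonzero linear fit as unstable (p → 0).
* Monte Carlo problem sizes in the checks: 10,000 SCRs for class-fraction
  limits, 1,000 SCRs per S for stopping invariants, 2,000 SCRs per S for
  the variance limit (Monte Carlo SE of a variance at n = 2,000 is ~4.5%,
  comfortably inside the 10% comparison band), ~10⁶ draws for the
  linear-bias law, 10,000 replicates for the F-test type-I calibration.

## Known limitations

* Linear summation only: no dendritic nonlinearities, inhibitory-synapse
  plasticity or GABA_B modulation.
* The external raw-data deposit (ABF/CRCNS formats) is not parsed; the CSV
  schema in `synmix.synth` is the ingestion contract.
* Round-trip relabelling of compositions whose effect distributions are
  truncated exactly at the ±15% boundary is stochastic at realistic noise:
  a draw landing within ~2 percentage points of the boundary can be
  misclassified (observation SE of Δ_N is ~1.3 points at CV 0.10,
  n = 120/epoch), so a small fraction of seeds flip one cell of 26.
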