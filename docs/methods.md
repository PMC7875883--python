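# Methods

This package reimplements, as tested simulation and inference code, the
analysis chain used to estimate test-retest reliability (TRR) and MZ-twin
familiality of stop-signal-task (SST) brain activation. Because the
original subject data are not public, two simulators stand in for them
with known ground truth: a trial-level behavioral task simulator and a
variance-component generator of parcel-level activation betas. Everything
downstream — outlier screening, ICC estimation, permutation inference, and
the factor analyses — operates identically on simulated or real tabular
inputs.

## Stop-signal task simulator

**Design.** Each run has 180 trials (150 go, 30 stop), 1 s trial duration,
uniform inter-trial interval (ITI) on [700, 1090] ms, 2 s lead-in and 5 s
tail fixation; stop trials are separated by 3–7 go trials. The stop signal
appears after the stop-signal delay (SSD) for 300 ms, truncated to
(1 s − SSD) when SSD exceeds 700 ms. The SSD staircase starts at 50 ms,
moves ±50 ms (up after a successful stop, down after a failed one), and is
clamped to [0, 900) ms, so with the default step the attainable set is
{0, 50, …, 850}. All of these are `TaskConfig` fields and can be changed;
the defaults are the task as administered.

**Race model.** Go finish times are ex-Gaussian (μ, σ, τ; defaults
400/50/60 ms — typical young-adult SST values), the stop process has a
constant per-subject latency `ssrt_true` (default 200 ms). A constant stop
latency was chosen over a stochastic one so that ground-truth SSRT is
exact, which is what the SSRT-recovery tests need. On a stop trial the
response is inhibited iff `T_go > SSD + ssrt_true`. If `T_go < SSD` the
response lands before the stop signal could be shown: the trial is counted
as a correct go and the stop signal swaps onto the following trial (kept
so per-run counts stay 150/30); if no trial follows, the displaced stop
signal is dropped and counted in `RunLog.dropped_stop_signals`. Go-trial
errors (omission, wrong direction, late response) are injected with
configurable probabilities on top of the race, and very slow natural
finishes are classified late (response during the ITI) or omitted.

**Sequencing.** A run's trial-type sequence gives every stop trial a
preceding go stretch in [3, 7] (including before the first stop) and a
trailing stretch of at most 7. The sampler starts all gaps at the minimum
and sprinkles the surplus go trials uniformly over gap slots with spare
capacity; it covers the full space of valid gap compositions (verified
against brute-force enumeration on a small design) without claiming exact
uniformity over compositions, which nothing downstream needs.

**SSD continuity.** The SSD carries over from run 1 to run 2 within a
session and resets to 50 ms at each session, reflecting that a session is
one administration of the task; the behavior is configurable
(`ssd_carryover_within_session`).

**Staircase accuracy.** A one-up/one-down staircase holds success at 50%
only once the SSD has reached the subject's critical delay. Because the
task deliberately starts easy (50 ms), each session opens with a run of
successful stops whose length is (equilibrium SSD − 50)/50, inflating the
session mean by roughly half that many trials out of 60. With realistic go
RTs (equilibrium SSD ≈ 240 ms) the grand mean lands near 53%, comparable
to the ~51% reported in real administrations of this task; with an
equilibrium near the start the mean is within a point of 50%. The tests
exercise both regimes.

**SSRT.** The integration estimator (default) takes the ceil(p·N)-th order
statistic of the pooled go RTs at p = P(respond | stop signal), minus the
mean SSD; the mean method uses mean go RT − mean SSD. The go-RT pool
contains every go trial with a recorded response (correct, wrong-direction
and late), a deliberate, documented convention that makes results
bit-stable; runs are pooled within session before estimating. p ∈ {0, 1}
yields a missing SSRT with a reason code rather than a number.

## Synthetic activation panels

Per contrast (correct-stop vs correct-go; incorrect-stop vs correct-go),
subject i, parcel p, session t, run r:

    beta = mu(p) + a(pair(i), p) + u(i, p) + s(i, p, t) + eps(i, p, t, r)

with independent zero-mean Gaussian components: pair-shared `a`
(SD `sigma_fam`), stable-individual `u` (`sigma_subj`), session state `s`
(`sigma_sess`), and run noise `eps` whose SD is
`sigma_run · (1 + kappa_motion · m_i)`. The motion trait `m_i` is
lognormal (default median ≈ 0.15 mm relative RMS) and constant across
sessions and runs — motion is modelled as a stable subject trait. Parcel
means `mu` are drawn N(0.3, 0.4²), spanning the range of group effects in
task fMRI. With `magnitude_coupled` (default on) the stable-individual SD
scales with |mu|, which produces the positive cross-parcel correlation
between reliability and effect size seen in real data; it is a modelling
choice, not a claim about mechanism.

The implied ground truth for two-run-averaged betas (at zero motion
coupling) is

    ICC_between = (σ_fam² + σ_subj²) / T,   ICC_twin = σ_fam² / T,
    T = σ_fam² + σ_subj² + σ_sess² + σ_run²/2,

and `spec_from_icc_targets` inverts these formulas so tests can dial exact
theoretical ICCs. Default component SDs (0.25/0.35/0.30/0.55) give a
between-session ICC near 0.43 and twin ICC near 0.15 — calibration knobs
chosen to produce the fair-reliability, weak-familiality regime the method
operates in, not estimates of any real variance decomposition.

**Cleaning toggle.** "Cleaned" mode emulates data-driven denoising
(ICA-FIX-like): `sigma_run` shrinks by `clean_factor` (default 0.7) and
the motion coupling by `clean_factor_kappa` (default 0). The coupling has
its own factor because such cleaning specifically removes motion-related
structured noise: with the coupling intact, parcel-averaged disparity is
an almost deterministic function of the motion trait and the
motion–instability correlation would survive any plausible overall noise
reduction, contrary to how cleaning behaves. The same seed produces the
same latent cohort in both modes, so raw/cleaned comparisons are paired.

**Dropout.** `apply_dropout` marks Time2 missing for non-returners, either
uniformly at random or with an exact count of intact pairs (the default
study layout: 44 of 56 return, 19 of 28 pairs complete).

**What the generator does not emulate:** spatial autocorrelation between
parcels, non-Gaussian tails in the betas, session-by-parcel interactions,
HRF/time-series structure, or any spatial structure in motion artifacts.
Passing tests therefore show the inference chain is correct under the
stated variance model, not that real SST data satisfy that model.

## Inference chain

**Outlier exclusion.** Per variable and per timepoint sample, values are
standardized over non-missing entries (SD with n−1) and |z| > 3 recoded
missing, reiterated exactly 10 times (a fixed count; a fixed point reached
earlier simply yields empty iterations). A zero-SD iteration excludes
nothing. Exclusion is applied first; then missingness is propagated — a
missing value forces its matched timepoint (and, for familiality, co-twin)
value missing — so complete pairs are identical across analyses.
Propagation is idempotent.

**ICC.** Reliability and familiality both use the single-measure
consistency ICC from a two-way mixed model, ICC(C,1) ≡ ICC(3,1), by
method-of-moments: (MS_rows − MS_error)/(MS_rows + (k−1)·MS_error) on
complete rows. Negative estimates are retained. For k = 2 this equals
2·cov/(var₁+var₂), which the vectorised per-parcel and permutation paths
use; tests pin the two forms together and against an explicit
sums-of-squares oracle and pingouin's ICC(C,1). Zero-denominator and
n < 3 cases return flagged undefined results instead of numbers.
Verbal bands use half-open intervals poor < 0.4 ≤ fair < 0.6 ≤ good <
0.75 ≤ excellent ≤ 1, closing the gaps the conventional verbal definition
leaves at 0.59–0.6 and 0.74–0.75.

**Permutation inference.** Family-wise error across parcels (or
behavioral variables) is controlled by the max statistic: each of B
(default 5000) permutations relabels whole Time2 subject rows (TRR) or
twin-2 pair assignments (familiality), recomputes every target's ICC with
complete-case filtering reapplied, and records the maximum. Significance:
observed ICC ≥ the ceil(0.95·B)-th order statistic of the null maxima (a
conservative quantile convention matching a "greater than or equal to the
95th quantile" rule). Per-target p-values use the add-one rule
(1 + #{null_max ≥ obs})/(B + 1), which is valid regardless of B.
Permutations are sampled with replacement from the permutation group
(identity allowed), seeded. Relabelings under which no target has 3
complete pairs contribute nothing to the null. NaN-free inputs take a
vectorised path: under row permutation only the cross-products change, so
per-permutation ICCs reduce to one einsum per chunk of permutations.

**Factor analyses.** Cohen's d is the one-sample effect size of Time1
run-averaged betas against zero (mean/SD across subjects). Cross-parcel
Pearson correlations treat parcels as independent units and are reported
as descriptive, since spatial dependence is ignored. Comparisons of ICC
sets (within- vs between-session; single- vs combined-run) are paired
two-sided t-tests on Fisher-z-transformed ICCs, with |r| ≥ 1 clipped to
0.999999 before atanh; summary means are reported on the raw ICC scale.
The motion analysis correlates each subject's run/session-averaged motion
with the mean over parcels of |Time1 − Time2| run-averaged betas.

## Numerical and design choices

- All randomness flows through `numpy.random.Generator` objects seeded
  per stage; identical seeds give byte-identical outputs.
- Quantile conventions (SSRT order statistic, permutation threshold) are
  rank-based and documented so results do not depend on interpolation
  modes.
- Undefined statistics (zero variance, too few complete cases, degenerate
  p_respond) are flagged with reason codes, never coerced to numbers;
  degenerate paired t-tests (zero within-pair variance, non-zero shift)
  report p = 0 with an explicit note.
- Problem sizes in the test suite are chosen so Monte-Carlo error is well
  inside each asserted tolerance: e.g. ICC recovery uses 500 pairs × 40
  parcels (per-parcel estimator SE ≲ 0.03, so the cross-parcel mean is
  accurate to ~0.005), and the family-wise error simulation uses 500
  replicates of a 379-parcel null panel at n = 44, B = 1000.

## Known limitations

- The race model has no trigger failures and no go/stop dependence; SSRT
  estimators other than integration/mean (e.g. Bayesian parametric
  models) are out of scope.
- The ICC is method-of-moments only; no REML/mixed-model estimation and
  no closed-form confidence intervals (significance comes from the
  permutation procedure).
- Familiality from MZ pairs alone cannot separate genetic from shared
  environmental variance; the generator likewise has a single pair-shared
  component.
- Cross-parcel inference ignores spatial dependence by design, matching
  the analysis it reimplements.
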