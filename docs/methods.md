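# Methods

## The measurement model

The package quantifies selective voluntary motor control (SVMC) of the
lower extremities from 10-channel surface EMG (five muscles per leg:
TA, PL, RF, GM, ST) recorded while a participant performs selective,
bidirectional single-joint movements — hip, knee, ankle and subtalar (STJ) —
three repetitions of roughly 2 s each, on both legs.

For one task, the pipeline computes the RMS amplitude of every channel over
each repetition window, subtracts a per-channel resting baseline (floored at
zero), and averages over repetitions, giving a nonnegative **response
vector** RV ∈ R¹⁰. The **prototype response vector** PRV is the elementwise
mean of reference-cohort RVs for that task. The **similarity index**

SI = (RV·PRV)/(‖RV‖‖PRV‖)

is the cosine of the angle between the two patterns; for nonnegative
vectors it lies in [0, 1]. The SI depends only on the *relative
distribution* of activity over muscles (it is invariant to overall scaling
of RV), which is what makes it a measure of selectivity rather than of
strength. Per-leg scores are unweighted means of the four joint SIs, the
total score the mean of all eight tasks.

Assumptions worth stating explicitly:

* the reference pattern is meaningful, i.e. the PRV has positive magnitude
  and came from enough subjects to average out individual idiosyncrasies;
* a zero RV (no activity above baseline on any channel) does **not** get
  SI = 0 — it is reported as missing with a logged reason, because "no
  recorded activity" and "maximally abnormal pattern" are different states;
* baseline activity is stationary enough that the quietest 3-s window found
  anywhere in the measurement estimates the resting level of each channel.

## Signal chain and numerical choices

1. **High-pass, 20 Hz.** Linear-phase windowed-sinc FIR (Hamming), order
   4·⌈fs/cutoff⌉ rounded to even (300 at 1500 Hz), applied in one pass with
   the constant group delay removed. The measured response therefore equals
   the designed magnitude response with zero net phase; tests check DC
   rejection, passband flatness at 100 Hz and the designed stopband value
   at 5 Hz.
2. **Mains rejection, 50 Hz.** Second-order IIR notch (Q = 30) applied
   forward–backward (zero phase) *only* to channels flagged as contaminated;
   unflagged channels are returned bit-identical.
3. **Artifact handling ("minimal cutting").** Segments documented with
   scope `all` are excised from the time axis; every later event window
   shifts left by the excised duration, and an artifact that swallows an
   entire repetition raises an error instead of silently producing an empty
   window. Segments scoped to one channel do not desynchronise the
   multichannel matrix; they exclude the overlapped (channel, repetition)
   pairs from RMS averaging, and a channel left without any usable
   repetition raises an error.
4. **Baseline.** Per channel, the minimum RMS over a sliding 3-s window
   scanned across the whole measurement. The default stride is 0.1 s — a
   ~15× speedup whose deviation from the exhaustive stride-1 scan is
   bounded (<2 % on smooth-envelope data) and checked against the
   stride-1 oracle in the tests. The baseline RMS is subtracted from
   movement-window RMS values linearly and floored at zero. Subtracting in
   amplitude (rather than in power, or from raw samples) is a documented
   interpretation choice: it is the simplest reading of "correcting for
   background activity" at the RMS stage, and the floor prevents negative
   activations. A quadrature subtraction would shrink small activations
   less; nothing downstream depends on the choice beyond that.
5. **Windows.** Seconds, 0-based; all windows are half-open [start, end)
   with sample index ⌊t·fs⌋, so adjacent windows tile without double
   counting.

## Side handling and prototypes

Channels are stored in one canonical order (right-side block, then
left-side block). Before any comparison, vectors are re-indexed
*ipsilateral-first* — the five tested-side channels first — so a left-leg
task and a right-leg task of the same joint live in the same coordinate
frame. By default the reference RVs of both legs are pooled into a single
PRV per joint (doubling the reference data); `pool_sides=false` keeps
per-side prototypes. Pooling assumes left/right symmetry of healthy
activation patterns, which holds for the synthetic generator by
construction and is the standard assumption for normative EMG references.

For the co-activation/mirror decomposition, each joint is assigned a target
agonist/antagonist pair: ankle → {TA, GM}, knee → {RF, ST}, STJ → {PL, TA},
hip → {RF, ST}. The decomposition reports the shares of the RV's squared
magnitude in (i) the target pair, (ii) the three other tested-side muscles
(co-activation) and (iii) the five contralateral muscles (mirror activity);
the shares sum to 1. The pair mapping is an interpretive choice isolated to
this report — the SI itself uses all ten channels symmetrically.

## Clinimetric battery

* **Rank correlations.** Spearman's ρ (midranks; exact permutation p for
  n ≤ 8 tie-free, t-approximation otherwise) for total/leg scores;
  Kendall's τ-b for single joints, whose tie corrections suit the 3-level
  ordinal joint grades.
* **Group tests.** Mann-Whitney U (exact when the pooled sample is tie-free
  and n₁n₂ ≤ 400, else tie-corrected normal approximation with continuity
  correction) and Wilcoxon signed-rank (zero differences dropped; exact
  sign-flip enumeration with midranks for n ≤ 12, else corrected normal
  approximation). Exactness at fixture scale is what makes the
  enumeration-oracle tests meaningful.
* **ROC.** Empirical curve; AUC by trapezoid (equal, with midrank tie
  handling, to U/(n₁n₂) — asserted on random data in the tests); Youden-
  optimal cutoff with ties broken toward higher sensitivity; classification
  rule "score ≥ cutoff → normal"; 95 % AUC CI by stratified bootstrap
  (2000 resamples, seeded).
* **Reliability.** ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — from the ANOVA mean squares, with the F-based 95 %
  CI (cross-checked against an independent implementation in the tests).
  Negative variance components are clamped to zero with a warning.
  SEM = √(σ_trial² + σ_error²) uses the session and residual components —
  note this differs from the also-common SD·√(1−ICC) form, which is
  available via `sem_mdc(..., method="classic")` but is never the default.
  MDC₉₅ = SEM·√2·1.96 exactly. A signed-rank test between sessions reports
  systematic error.
* **Multiplicity.** Bonferroni over the 11 group comparisons (8 joints +
  2 legs + total), threshold α/m.
* The battery degrades gracefully: each block runs independently and a
  block whose inputs are missing is skipped with an explicit, logged
  reason, mirroring real studies where, e.g., only part of a cohort returns
  for retest.

## Synthetic data: what it emulates and what it does not

Each channel is an interference-pattern surrogate: unit-RMS Gaussian noise
band-passed to 30–500 Hz (the acquisition bandwidth), amplitude-modulated
by a raised-cosine (sin²) envelope per 1-s movement half-cycle, plus
continuous 2 µV-RMS baseline noise and optional 50 Hz mains. Intended drive
goes to the task's agonist/antagonist pair; a fraction (1−selectivity)
leaks through a within-leg co-activation matrix (off-diagonal strength 0.8
by default) and a fraction mirror_gain to the homologous contralateral
muscles. Group distributions (in `group_defaults.yaml`): control
selectivity U(0.88, 1), CP U(0.25, 0.9) with larger mirror gains and
joint-to-joint jitter; reference adults U(0.93, 1). Synthetic ordinal joint
scores (0/1/2 at selectivity thresholds 0.45/0.8) and GMFCS-like levels are
derived from the true selectivities so validity analyses have a recoverable
ground truth; retest sessions redraw the carrier noise and add a small
between-day drift of the true selectivity (SD 0.04–0.06).

Every dataset carries the analytic noiseless activation RMS per channel and
task (amplitude × envelope RMS, with envelope RMS = √(3/8) for whole
half-cycles), which the pipeline must recover within Monte-Carlo tolerance.

What passing tests on this generator show: the pipeline recovers injected
activation levels, the SI decreases monotonically in injected co-activation,
CP-profile and control-profile cohorts separate at the Bonferroni level, and
artifact cutting restores scores to within 0.02 of the pristine twin
recording. What they do not show: behaviour under real electrode noise,
motor-unit firing statistics, spasticity dynamics, electrode-placement
variability, or non-stationary baselines — none of which the generator
models. Real-data validity cannot be claimed from these simulations.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (cohort seeds spawn
per-subject seeds deterministically; identical seeds give bit-identical
datasets). The acceptance script runs the full study scale — 31 reference
adults, 24 CP + 31 control subjects, a CP retest session, 1500 Hz. The
simulation-heavy tests run the same pipeline at a reduced problem size
chosen once as a package default for test fixtures: 750 Hz sampling and
compressed rest periods, with the repetition structure (3 × 2 s per task,
8 tasks) unchanged; statistical calibration tests use 10 000 null
replicates at n = 20 per group.

## Known limitations

* The SI is reference-cohort-dependent; prototypes built from small or
  atypical cohorts shift all scores. The CSV prototype format records
  n_reference and provenance for this reason.
* The cosine is insensitive to overall activation magnitude; a patient
  activating the correct muscles very weakly scores high. The RV magnitude
  is exposed (`magnitude`) but not validated as an outcome here.
* Baseline subtraction on RMS values is one of several defensible readings
  of background correction (see above).
* The ordinal-score and GMFCS stand-ins in the synthetic cohorts are
  deterministic functions of true selectivity plus jitter; real clinical
  scoring noise is richer.
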