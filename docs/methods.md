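# Methods

`rulatime` implements an automated Rapid Upper Limb Assessment (RULA) of
joint-angle time series, the time-weighted exposure statistics built on it,
and the nonparametric comparison design used to contrast seated cooperative
workplaces (the four classical dental workplace concepts, DWC 1–4) and the
two occupations of a treatment pair (dentist D, dental assistant DA). This
note records the model, the choices that were genuinely open, and what the
synthetic cohorts do and do not show.

## Frame-wise RULA scoring

Each frame of a recording (one row of named angle channels in degrees plus
boolean posture flags) is pushed through the published RULA worksheet:

* **Step scores.** Upper arm (1–6), lower arm (1–3), wrist posture (1–4)
  and wrist twist (1–2) per body side; neck (1–6), trunk (1–6), legs (1–2).
  Band boundaries are *closed on the lower-risk side*: a flexion of exactly
  20° scores the milder band. The worksheet does not fix this; it is fixed
  here so results are reproducible.
* **Tables.** Table A (upper arm × lower arm × wrist posture × wrist twist
  → 1–9), Table B (neck × trunk × legs → 1–9) and Table C
  (score C × score D → 1–7, saturating at rows 8+ and columns 7+) are exact
  transcriptions of the printed worksheet, kept as integer lookup arrays.
  Score C = Table A + muscle use + force; score D = Table B + muscle use +
  force. The final score is 1–7; 7 reads "investigate and implement change".
* **Combined wrist score.** The reported wrist outcome is
  `wrist_posture + wrist_twist` (range 2–6), matching the stated maximum of
  6 for the wrist outcome. Table A itself keeps the two indices separate as
  in the printed worksheet; the sum is a reporting convention.
* **Per-frame final.** Recordings carry both sides; the frame's grand score
  is the worse (maximum) of the right and left final scores. Step outcomes
  are reported per side.

### Categorical adjustments

The worksheet's check-boxes are automated with angle thresholds, all
configurable in `RulaThresholds`:

| adjustment | rule | default |
|---|---|---|
| upper-arm abduction | abduction angle strictly greater than threshold | 45° |
| shoulder raised / arm supported / arm across midline / wrist twist end-range / trunk & legs supported | boolean channels in the file (supplied flags always win; the abduction flag may also be supplied) | — |
| wrist neutral band | `|flexion|` at or below threshold scores 1 | 1° |
| wrist deviation | deviation strictly greater than threshold adds +1 | 10° |
| neck / trunk twist and side-bend | `|angle|` strictly greater than threshold adds +1 | 10° |
| trunk neutral band | seated, supported, `|flexion|` within band scores 1 | 5° |

### Muscle use

The worksheet awards +1 when a posture is "mainly static (held > 1 min) or
repeated ≥ 4×/min". `StaticWindowConfig` operationalizes this per worksheet
arm (arm/wrist channels drive group A per side; neck/trunk channels drive
group B):

* **static** — every driving angle stayed within `hold_tolerance_deg`
  (max − min, default 5°) over a *full* trailing window of `window_s`
  (default 60 s). A posture cannot count as held-for-a-minute before a
  minute of history exists, so the first window of a recording never fires.
* **repetition** — the driving step score crossed bands at least
  `repetition_threshold_per_min` (default 4) times within the trailing
  window; when less than a full window of history exists the threshold is
  scaled to the available prefix.

The force/load score defaults to 0: hand-held dental instruments are light
(< 2 kg) and used intermittently. Both force scores are run parameters.

## Exposure statistics

For a score sequence `s_1..s_n` of an outcome with maximum `M`:

* time-in-score distribution: `rel_time[v] = #{i : s_i = v} / n`;
* relative average risk score over time (rel. av. RST):
  `Σ_v rel_time[v]·v` — identically the arithmetic mean of the sequence,
  which the test suite uses as an exact oracle;
* ergonomic risk potential: `ERP = rel. av. RST / M × 100` (percent);
* median and interquartile distance `IQD = Q3 − Q1` with linearly
  interpolated quantiles.

Aggregation is **per subject first**: each subject contributes one summary
per outcome; group cells then take the median/IQD of subject medians and
the *mean* of subject rel. av. RSTs (the group ERP is recomputed from that
mean). The alternative — pooling frames across subjects — would weight
subjects by recording length; reported IQDs of half-integer medians also
imply subject-level aggregation. Rounding (half-up, two decimals) happens
only at the reporting layer.

## Comparison design

Per occupation, the four DWCs are compared on the subject-level rel. av.
RST of each outcome:

* **Friedman test** on the subjects × 4 block matrix, with within-subject
  mid-ranks and tie correction. p-values: exact enumeration of within-block
  permutations when `(k!)^n ≤ 20 000`; a seeded Monte-Carlo permutation
  null (999 resamples, add-one estimator) for panels up to 25 subjects —
  the χ² reference is measurably conservative there (size ≈ 4.3% at
  n = 15, k = 4); the classical χ²(k−1) reference for larger panels, which
  is also what a study-scale analysis (n = 75) uses.
* **Conover–Iman post-hoc** for the six pairwise contrasts, implemented
  from the rank-sum formula: `t = (R_i − R_j) / sqrt(2n(A1−C1)/((n−1)(k−1))
  · (1 − T1/(n(k−1))))` with `(n−1)(k−1)` degrees of freedom, where `R` are
  rank sums, `A1` the sum of squared within-block ranks,
  `C1 = nk(k+1)²/4`, and `T1` the tie-corrected Friedman statistic. With
  perfect concordance the variance term vanishes; a nonzero rank-sum
  difference then reports p = 0, a zero difference p = 1.
* **Bonferroni–Holm** within the family of an outcome's six contrasts.
  Contrasts are computed unconditionally but reported with the Friedman
  gate; a contrast is flagged only when the gate passes at α = 0.05 *and*
  its Holm-adjusted p is at or below α. The favored condition is the one
  with the lower mean rel. av. RST.
* **Occupations** are compared per DWC with two-sided Mann–Whitney U tests
  on rel. av. RST and on subject medians; the Holm family is the nine
  outcomes within one (DWC, measure). U uses mid-ranks; p is an exact
  enumeration over all `C(n_a+n_b, n_a)` labelings for combined n ≤ 12
  (two-sided as the probability of a U at least as far from `n_a·n_b/2`),
  otherwise a normal approximation with tie and continuity corrections.

All tests are two-sided at α = 0.05; direction is carried by the
"favored" marker, with the usual star coding (≤0.05 *, ≤0.01 **,
≤0.001 ***).

The Holm families above (per outcome for DWC contrasts, per DWC for
occupation contrasts) are one defensible reading of how such tables are
annotated; they are configuration, not dogma.

## Synthetic cohorts

Motion recordings of real dental work are not redistributable, so the
package ships a seeded generator whose output has the statistical structure
the analysis assumes.

* **Semi-Markov posture model.** A recording is a sequence of posture
  *states* — close intraoral work, raised-arm instrument reach, indirect
  mirror-view work, an assisting posture, and a short relaxed handover —
  with exponential dwell times (means 20–90 s; explicit dwell rather than a
  per-frame chain because the muscle-use rule depends on hold durations),
  Gaussian angle noise (sd 3°) around state means, and flags drawn once per
  dwell segment. The chain starts in its time-stationary distribution
  (dwell-weighted state, memoryless residual life), so finite windows carry
  no start-up bias and designed occupancies are unbiased at any duration.
* **Robust-7 working states.** The four working states are postures whose
  Table A score is 5 and Table B score ≥ 5 with the muscle-use points
  *not* required for a final score of 7 (Table C is saturated there), so
  the cohort's headline profile does not hinge on the static-detection
  heuristics. Score-critical angle means sit ≥ 10° from every band
  boundary, keeping noise-induced band hops below ~0.5% per channel.
* **Designed profile.** Default occupancies (working states ≈ 95.5%,
  handover 4.5%) give ≈ 95–97% of frames at final score 7 and a final ERP
  of ≈ 96–97%, with segment risk ordered lower arms ≳ wrists > neck >
  trunk > upper arms. The *ordering* mirrors cooperative dental work; the
  absolute segment ERPs run somewhat higher than a real cohort's because
  the worksheet couples segment scores — postures that pin the final score
  at 7 necessarily carry high arm/wrist scores. Conclusions about absolute
  segment levels in real data cannot be drawn from these cohorts; the
  cohorts exist to validate the pipeline's arithmetic, calibration and
  power, not to imitate any particular dataset.
* **Effects.** Workplace and occupation differences enter as small
  additive shifts on state-occupancy logits (`dwc_effects`), with
  per-subject logit heterogeneity (sd 0.2) shared across a subject's four
  recordings — the within-subject correlation that motivates a blocked
  design. An empty effects map yields an exchangeable null cohort. The
  ground-truth ledger stores each recording's designed occupancies and the
  implied expected rel. av. RST per outcome, computed at the noise-free
  state means (valid because the states are muscle-robust by design).
* **Defaults as study conditions.** 75 pairs, 24 Hz, 300 s per task — the
  cohort size matches a large laboratory study; the task length is this
  package's desk-scale choice for a minutes-long standardized task.

## Numerical and procedural choices

* Resampling is pure decimation (every k-th frame, first retained); scores
  are threshold functions of quasi-static posture and filtering would blur
  band crossings. Non-integer rate ratios are rejected.
* Timestamps must be strictly increasing with spacing `1/rate` within
  1 µs; larger gaps are integrity errors, never silently spanned.
* The text writer emits shortest round-trip decimals, so
  `read(write(r)) == r` bit-exactly.
* Simulation studies (error rates, power) run on the channel-array route
  (`score_channel_arrays`, `simulate_summaries`), which is tested to agree
  exactly with the per-recording route. Problem sizes used by the shipped
  validation suite — 2000 null cohorts of 12 pairs × 90 s for the type-I
  check, 24 pairs × 600 s with a −2.0 logit mirror-view shift for the
  recovery check — were chosen from pre-run size/power analyses of the
  design itself.
* Randomness flows from single integer seeds through
  `numpy.random.SeedSequence`; identical configurations reproduce
  byte-identical cohorts and outputs.

## Known limitations

* The worksheet automation thresholds (neutral bands, twist thresholds,
  static-window knobs) are this package's operationalization of a
  paper-and-pencil method; other automations are defensible and will shift
  absolute scores. All are configurable and logged per run.
* The generator emulates posture *regimes*, not biomechanics: no
  kinematic chain constraints, no autocorrelated within-posture drift, no
  hand/finger detail (wrist only), and flags are piecewise-constant.
* Exact tests are enumerative only at small sizes; beyond them the stated
  approximations apply.
* Force/load scoring and non-seated work are supported by configuration
  but not exercised by the default cohorts.
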