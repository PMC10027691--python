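# Methods

This note documents the models, parameters, and design decisions behind
`wmconn`: what each stage computes, what the synthetic generator does and
does not emulate, and where genuinely open choices were resolved.

## Task and stimuli

The task is a retro-cue auditory WM paradigm.  Each trial: visual alert,
two 1-s moving-ripple items, a retro-cue indicating which item to maintain,
a 15-s maintenance period, a probe, and a response cue.  Probes match the
relevant item in 50% of trials, match neither item in 25%, and match the
irrelevant (uncued) item in 25%.  A session has 4 runs of 24 trials, each
of the 6 ripple-velocity classes retro-cued exactly 4 times per run.

Moving ripples are broadband sounds whose carrier at octave position
g = log2(f / f0) is amplitude-modulated by

    s(g, t) = D0 + D·cos(2π(ωt + Ωg) + ψ),

with ripple velocity ω (cycles/s) and spectral density Ω (cycles/octave).
Synthesis superimposes 20 random-phase sinusoids per octave from 0.2 to
1.6 kHz.  Carrier placement is not acoustically critical and is unspecified
in standard descriptions; we use a fixed log-frequency grid with seeded
random phases so synthesis is reproducible.  Output is peak-normalized to
−3 dBFS; absolute calibration is out of scope.

The stimulus pool holds 17 velocities spaced 0.5·JND apart in log2 units
from ω = 4 cycles/s (admissible range 3–48 cycles/s); the 6 item classes
sit at 1.5·JND spacing, i.e. pool indices 0, 3, …, 15.  Whether the class
grid is anchored at the pool's low end is an open choice; we anchor at
index 0 and document rather than assert it.  The irrelevant item of a class
is offset by 0.5·JND (one pool step).

**Staircase.**  The JND comes from a transformed up-down staircase over the
log2 velocity interval.  The rule is configurable (`1d2u`, `2d1u`, `1d1u`)
with `1d2u` as the configured default; note that a literal 1-down/2-up rule
converges near the 29.3%-correct point, which is unconventional for
threshold tracking — `2d1u` (70.7%) is the conventional choice and is used
in the examples.  Steps are additive in log2 units, shrinking after 4
reversals; the estimate averages the final reversals.  Non-converging
tracks are flagged, not raised.

**Schedule balance (decisions).**  Retro-cue position is balanced 12/12
within each run, and the uncued item's class is drawn *balanced* (each
class 4x per run, never equal to the cued class).  Neither constraint is
dictated by the task description; the balanced uncued assignment keeps the
(run, class) exemplar grid complete when exemplars are relabeled by the
irrelevant item for the control analysis.

## Synthetic BOLD generator

Each subject is a set of subROI x time matrices (TR = 1.47 s, 4 runs,
default run length 620 s ≈ 24 trials at 25-s spacing plus lead-in/tail; the
inter-trial interval is a documented assumption, not a protocol value).
Signal components:

- **Content-specific coupling.**  Each class c activates a latent white
  Gaussian factor during the lagged maintenance window of class-c trials;
  the factor is added, with amplitude a = σ·sqrt(ρ/(1−ρ)), to a
  class-specific subset of subROIs (round-robin assignment, unit i in a
  ROI belongs to class i mod 6) in every ROI of the designated signal
  network.  Coupled pairs then correlate at exactly ρ (the configured
  `coupling_strength`) during their class's windows, which makes parameter
  recovery well-posed; a recovery test confirms ρ within ±0.05 over a
  session.  Class identity is thereby a *connectivity* pattern, not an
  amplitude pattern — the activation-path features carry no class signal in
  this generator, by design.  ρ < 1 keeps implied correlation matrices
  positive semi-definite; ρ ≥ 1 is rejected.
- **Evoked responses**: each event type's boxcar convolved with the HRF,
  with per-unit amplitudes (stable within subject).
- **Drifts**: cosines at 1–4 half-cycles per run (all below the 0.006 Hz
  high-pass cutoff) with per-unit loadings.
- **Confounds**: smoothed global noise channels (CSF/white-matter analogs)
  with per-unit loadings; the channels are stored with the session and
  regressed out downstream.
- **Noise**: white Gaussian, optional AR(1) (variance-preserving); the
  default is white, as no noise spectrum is prescribed.

The injection window equals the analysis's extraction window
([retro-cue onset + lag, probe onset + lag)), so recovery is well-posed by
construction.  The generator does *not* emulate voxel-level geometry,
physiological noise, motion, or scanner artifacts; passing tests show the
analysis machinery is correct and calibrated under its own assumptions, not
that it would detect coupling in any particular real dataset.

## GLM

Design matrices hold the six event regressors (alert, item1, item2,
retro-cue, probe, response cue) convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6 — the usual default; oversampled 16x
per TR), the confound channels, and a per-run Legendre polynomial drift
block of order max(1, round(2 · 0.006 Hz · run_length)) — e.g. order 7 for
a 600-s run — approximating the 0.006 Hz high-pass.  Legendre polynomials
are used for numerical stability; rank-deficient columns are pruned with a
warning.  Residualization is ordinary least squares per subROI; residuals
are orthogonal to every design column to ~1e−10 and the operation is
idempotent.

Content (per-class) boxcars spanning [retro-cue onset + 4 s, probe onset),
HRF-convolved, are used *only* on the activation path (per-run contrast
effect sizes as features).  They are excluded from the connectivity
residualization, where they would remove the maintenance signal of
interest.

**Maintenance windows.**  Extraction takes TR-grid samples in
[anchor + 4.41 s, probe onset + 4.41 s); the 4.41-s hemodynamic lag is
exactly 3 TRs (enforced: lag must be an integer multiple of TR).  Whether
the anchor is the retro-cue onset or the maintenance onset (retro-cue
offset) is ambiguous; `anchor` is exposed as configuration with
`"retrocue"` as default.  Windows snap to the TR grid by flooring the start
index and ceiling the stop index (half-open).  Trials whose window leaves
the run are dropped with a warning.

## Connectivity features

Per (run, class), segments of same-class trials are concatenated and the
Pearson correlation between every subROI pair is computed over the
concatenated series as a single sample, joins included (literal
concatenation; a per-trial variant would be a sensitivity analysis).  Raw r
is used — no Fisher z — since the downstream linear classifier is
insensitive to the monotone transform in practice; zero-variance series
yield r = 0 with a warning instead of NaN so degenerate synthetic cases
remain classifiable.  Network feature vectors concatenate the pairwise
blocks in canonical (name-sorted) order, each flattened row-major; any
fixed order is classifier-equivalent, this one is documented and stable.
The within-ROI control uses the upper triangle (diagonal excluded) of the
ROI's own subROI correlation matrix (N(N−1)/2 features).

For efficiency, the full subROI x subROI correlation matrix is computed
once per (run, class) and every network's features are sliced from it, so
the cost is shared across the candidate family.

## Decoding

libsvm C-SVC with linear kernel and C = 1 (one-vs-one voting; ties broken
by libsvm's class ordering, which is deterministic given the data), no
feature standardization by default.  Leave-one-run-out CV over 4 runs x 6
classes: 18 training and 6 test exemplars per fold.  Accuracy is the exact
count ratio (= confusion trace / total).  The default backend computes the
linear Gram matrix once and calls sklearn's low-level libsvm bindings —
prediction-identical to `sklearn.svm.SVC` (a test enforces this) but ~15x
faster, which is what makes the permutation experiments tractable on one
CPU.  Decoding is invariant to common positive feature rescaling and is
deterministic given the features.

## Inference

The family-wise null records, per permutation, the maximum over all family
units of the group-mean accuracy under labels shuffled uniformly and
independently within each run.  Within a subject and permutation the same
shuffled labels are applied to every unit — required for a valid
family-wise maximum.  Labels are permuted on precomputed exemplars: the
correlation features do not depend on the classifier's labels, so this is
equivalent to recomputing features under shuffled trial labels.  The
identity permutation is not excluded (standard Monte-Carlo practice,
negligible at the default 500 draws).

p = max(1, #{null ≥ observed}) / n_perm, ties counting against the
observation; the floor makes the smallest attainable p equal 1/n_perm
(0.002 at 500 permutations).  This k/n convention (rather than
(k+1)/(n+1)) is chosen so the minimum p at 500 permutations is exactly
0.002.

## Problem sizes

Default experiment presets run at desk scale: cohorts of 8 subjects
(4 for the error-rate sweeps), 99-permutation nulls, and families of 50
units, chosen so the full test suite and the acceptance script complete in
minutes on one CPU while leaving the statistical properties testable.  The
same functions accept the full 2500-network x 500-permutation x 20-subject
configuration (`wmconn run-all` with `max_units: null`, `n_perm: 500`).

**Detection experiment family.**  Content coupling lives on ROI pairs, so
any network containing two or more ROIs of the planted network contains an
informative pair and legitimately carries signal.  The "is exactly the
planted network flagged?" experiment therefore samples its 49 comparison
networks from those sharing at most one ROI with the planted set (occipital
control networks included).  This is a property of the question, not a
weakening of the test: with overlapping networks in the family, their
detection would be correct behavior.

## Registries

The 16-ROI connectivity registry ships as a packaged table with the subROI
counts per area (STC 34/29, MFG 43/50, IFG 23/14, SMG 34/32, AG 33/37,
SPL 76/80, OC 62/51, left/right).  Precentral counts are not anatomically
constrained here; the default 30/30 (same magnitude as neighboring areas)
is flagged `inferred` and overridable.  SubROIs correspond to icosahedral
patches of an order-3 subdivided icosahedron (V(n) = 10·4^n + 2; 642
vertices per hemisphere).

The 86-label activation registry (43 per hemisphere) reconstructs a
Desikan-derived parcellation: the 34 standard labels minus superior
temporal, transverse temporal, pre- and postcentral, plus a 9-way superior
temporal split (HG, HS, PT, pSTG, aSTG, LF, iCS, STS, and planum polare as
the inferred ninth parcel) and ventral/dorsal pre-/postcentral splits.
Unit counts in activation mode are voxel-count *proxies* at synthetic
scale; all such entries are flagged `inferred` in the fixture.

## Known limitations

- The generator's coupling model is stationary within windows and shared
  network-wide; real connectivity dynamics are richer.
- No prewhitening of GLM errors; with AR(1) noise enabled, correlation
  estimates are mildly optimistic in effective sample size.
- The activation path is exercised against this generator's null (no
  amplitude coding), not against a generator that plants amplitude
  patterns.
- Desk-scale family-wise error estimates use small uniform registries;
  they verify the test's calibration, not its power at full scale.
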