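# Methods

## The generative response model

The pipeline treats the LPS-evoked ΔΨm response of one cell as a noise-free
percent-change curve plus measurement noise. For microglia the curve is a sum
of **linear ramps**, one per progressive state: zero before the state onset,
rising linearly over the state duration, constant afterwards. A linear ramp is
the simplest shape consistent with "steep rise separated by plateaus", and it
makes slope angle and rate analytically known, so detector tests have exact
oracles. Raw intensity is `baseline_intensity · (1 + pct(t)/100)` with
additive Gaussian noise per frame (`noise_sd`, default 2 a.u. = 2% of the
100 a.u. baseline). Poisson shot noise is deliberately not modelled: additive
Gaussian keeps every tolerance analytic, and at TMRE photon budgets the
difference is immaterial for mean-over-mask traces.

Canonical parameters (defaults of `make_default_parameters`):

| quantity | value | note |
|---|---|---|
| state onsets | 363.6 / 843.6 / 1410 s | 6.06 / 14.06 / 23.50 min post-LPS |
| state durations | 121.2 / 124.2 / 180 s | 2.02 / 2.07 / 3.00 min |
| whole-cell amplitudes | 120 / 80 / 53.12 % | calibration: sums to the 253.12% endpoint and keeps ramp-rate ordering S1 > S2 > S3 |
| soma amplitudes | 100 / 15 / 10 % | calibration: soma-dominant S1 |
| branch amplitudes | 30 / 110 / 40 % | calibration: steepest branch ramp in S2 |
| endfoot amplitudes | 10 / 40 / 170 % | calibration: endfoot-dominant S3 |
| neuron plateau | 50 % by 540 s | holds to 960 s, then declines at 0.01 %/s |

The per-state timing and the 253.12% / 50% endpoints are reported quantities;
the *split* of the whole-cell total across states and compartments is not
reported anywhere and is therefore a documented calibration, chosen once to
satisfy the qualitative subcellular pattern above.

**Whole-cell vs compartments.** The whole-cell ROI is not an area average of
the three sub-compartment ROIs (its S1 amplitude, 120%, exceeds every
compartment's), so the whole-cell amplitudes are tied to the compartment
matrix by a frozen linear map: weights ≈ (soma 1.025, branches 0.542,
endfeet 0.125), solved once from the canonical matrices and used to derive
whole-cell amplitudes for *every* condition, including under attenuation.
Parameter validation enforces this identity.

**Emapunil** is modelled as multiplicative attenuation of state amplitudes:
0.40 on soma S1/S2, 0.35 on endfeet S2/S3, 0.95 on branches (all states),
1.0 elsewhere. The factors encode the observed significance pattern — strong
attenuation of soma and endfoot percent change, no significant branch effect.
The branch factor is kept close to 1 because, with realistic between-cell
variability (below) and n=10 per group, a 10% branch effect would make the
"branches not significant" outcome essentially a coin flip; 0.95 makes the
expected outcome match the observed one while still being a weak attenuation.
Baseline and emapunil-only conditions have all amplitudes zero: emapunil
alone does not move baseline ΔΨm.

**Between-cell variability** (cohort generation only): one lognormal factor
per cell and state, mean 1, CV 0.25, applied uniformly across compartments in
that state (preserving the whole-cell identity). CV 0.25 is a typical
cell-to-cell spread for evoked fluorescence responses in slice preparations.
Neurons get one factor on the plateau amplitude. `simulate_trace` itself is
deterministic given its parameters; variability lives one level up, in
`generate_cohort`, where per-cell streams are spawned from the master seed by
`SeedSequence(seed, spawn_key=(cell_index,))`.

## Rendered scenes

`render_stack` paints static morphology into channel 0 (EGFP) and the
compartment kinetics into channel 1 (TMRE): microglia are a soma disc
(r = 4 µm) with 4 gently curved branches (length 12 µm, half-width 1 µm)
ending in endfoot blobs (r = 2.2 µm); neurons are 6 µm discs. Pixel values
inside a compartment equal `background + trace(t)`; Gaussian noise
(sd 2 a.u.) is added per pixel and frame, and the manifest records the exact
masks and noise-free pixel values. Defaults (256 px field at 0.5 µm/px, 2 s
frames) keep a full 35-min recording desk-scale; validation scenes use
10-min recordings since segmentation fidelity does not depend on duration.
The endfoot radius is kept below the soma opening radius so ground-truth
geometry and the partition convention agree (see below). Not modelled, by
design: photobleaching, focal drift, slice movement, PSF optics.

## Segmentation and compartment partition

Cells are segmented on the time-averaged EGFP frame (the morphology channel
is static by construction) with Otsu thresholding + connected components;
components under `min_area_px` (50) are discarded and touching cells merge
(documented contract — no watershed). The per-cell partition:

1. **soma** — largest connected component of a morphological opening with a
   3 µm disc; remainder components that never stray farther than the opening
   radius from the soma (thin slivers produced by discrete opening) are
   absorbed back into it, so a disc-only cell is 100% soma;
2. skeletonize the remainder; skeleton endpoints farther than `endfoot_len`
   (4 µm) from the soma are process **tips**; skeleton pixels within 4 µm
   geodesic distance of a tip form leaf segments;
3. **endfeet** — remainder pixels whose nearest skeleton pixel is on a leaf
   segment; **branches** — everything else.

The partition is a true partition (disjoint, exhaustive) for any input mask;
a mask with nothing surviving the opening becomes all-soma with a warning.
The 3 µm / 4 µm defaults are geometric conventions, not measured quantities —
real hand-drawn ROIs can be supplied as mask files to bypass the automatic
partition entirely. Neurons are never auto-classified; synthetic neurons
carry class labels in the manifest and real neuron ROIs must be user-supplied.

On rendered scenes the automatic pipeline achieves median cell IoU ≈ 1.0 and
compartment IoU ≈ 0.85–0.97 against ground truth (see
`analysis/04_imaging_validation.py`).

## Kinetics

* **Percent change**: `100·(F−F0)/F0`, F0 = mean over the baseline window
  `[−300, 0) s` (half-open; ≥3 samples and F0 > 0 required). Invariant to
  multiplicative intensity rescaling.
* **Rate of change**: centered moving average (30 s, forced to an odd sample
  count, shrinking at the edges) followed by central differences; endpoints
  one-sided. 30 s suppresses frame noise while resolving ≥60 s states.
* **Slope angle**: degrees of `atan` of the least-squares %-per-minute slope.
  Reported per state as the maximum instantaneous value
  (`atan(60·max rate)` within the state window).
* **State detection**: threshold the smoothed rate at 0.25 %/s (post-treatment
  samples only); merge supra-threshold runs separated by gaps shorter than the
  minimum plateau duration (45 s) — by definition a shorter lull is not a
  plateau, and the merge makes detection robust to noise wiggles near
  threshold; drop runs shorter than 60 s; if more than 3 candidates survive,
  keep the 3 with the largest within-state gain (earliest onset breaks ties).
  The thresholds are calibrated so the canonical noise-free trace yields
  exactly the three canonical states, and all are configurable. Smoothing
  shifts detected ramp edges by up to ~half the smoothing window (hence the
  ±30 s tolerance used throughout).
* **Per-state gain** is within-state (smoothed pct at window end minus start);
  the cumulative value at state end is reported alongside
  (`pct_cumulative`), since either reading of a "per-state percent change" is
  defensible.
* **Per-compartment metrics** are measured inside the *whole-cell* state
  windows, mirroring the experimental procedure (states identified globally,
  compartments examined within them). This is necessary, not cosmetic: the
  soma-only trace has sub-threshold ramp rates in S2/S3 (15%/124 s ≈
  0.12 %/s) and would never yield three states on its own.

## Statistics

`compare_groups` wraps the standard machinery (pooled-variance t, one-way F
via scipy; subject-blocked repeated-measures F via pingouin) behind one
surface with exact degrees of freedom, and defines the degenerate case
(identical groups, zero variance) as statistic 0, p = 1. Tests are two-sided;
p-values are raw by default (Benjamini–Hochberg optional), significance at
p ≤ 0.05. The screen report compares every (cell class, compartment, state,
metric) stratum present in both conditions with n ≥ 2 per group — strata with
fewer cells are skipped with a warning, and cells missing a state are absent,
not zero. The emapunil contrast uses each compartment's **total** percent
change over the final minute of the recording (`total_pct_change`, state 0),
since per-state windows need not exist in attenuated cells (the attenuated
whole-cell S3 ramp rate, ≈0.21 %/s, sits below the detection threshold).

## Problem sizes and numerical choices

Canonical trace simulations use 1 s sampling over 2100 s (300 s baseline +
1800 s post-treatment). Cohorts are n=10 per condition — the study group
size — and the screen operates at that n. Rendered validation uses five
256×256 px scenes of 300 frames each. The 30 s smoothing window, 0.25 %/s
threshold, and 60/45 s duration minima are the packaged defaults everywhere;
no test or script overrides them.

The rendering round trip is checked statistically: each frame's mask-mean
error is exactly N(0, noise_sd/√n_pixels), so a hard 3·SE bound on every one
of T frames would fail with probability → 1 as T grows; the tests require
≥99% of frames within 3 SE, all within 5 SE, and whole-trace bias within
3·SE/√T.

## Known limitations

* The synthetic generator produces piecewise-linear responses with stationary
  Gaussian noise; real TMRE traces have drift, flicker, and amplitude/timing
  correlations the model omits. Passing tests demonstrate the *pipeline*
  (normalization, detection, partition, statistics) is correct under the
  stated model, not that the model exhausts real-data behaviour.
* Printed group statistics from slice experiments (specific F and p values)
  depend on the original raw recordings and are not reproduction targets;
  the screen reproduces directions and significance patterns, not exact
  statistics.
* Segmentation assumes a static morphology channel and non-touching cells;
  activated microglia that retract processes or contact each other need
  user-supplied ROIs.
* State onsets/durations are recovered to within the smoothing window (±30 s),
  not exactly; sub-threshold states (rate < 0.25 %/s) are invisible by design.
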