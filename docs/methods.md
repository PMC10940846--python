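# Methods

## Coordinate, unit and sign conventions

Arrays are `(rows, cols, frames)`. Row 0 is the image top, which is the
12 o'clock direction of the vessel cross-section; columns increase to
the right (3 o'clock). All geometry is physical: pixel spacing in mm,
frame interval in ms, velocity in cm/s with positive = forward
(head-ward) through-plane flow. A reader mapping a scanner's sign
convention must flip explicitly and record it (`sign_flipped` sidecar
flag). Angles are degrees in (−180°, 180°], measured clockwise from
12 o'clock; values within floating-point noise of −180° are reported
as +180°.

Aortic cross-sectional areas are reported in cm² (a 25 mm lumen is
≈ 4.9 cm²). Published cohort tables sometimes label this column mm²
while printing cm²-scale values; this package keeps the unit honest.

## Flow indices

Per frame, forward rate = `Σ_in-mask max(v, 0) · pixel_area` and the
backward magnitude analogously with `max(−v, 0)`; with area in cm² and
v in cm/s the rate is mL/s. Volumes are rectangular sums
(rate × frame interval) over the cycle or the systolic window — no
spline resampling, matching the discrete cine phases.

**Systolic window.** The maximal contiguous run of frames containing
the net-rate peak with net rate ≥ 10% of peak (configurable). Published
descriptions of systolic flow indices rarely define the window; this
rule is deterministic, scale-invariant, and recovers the analytic
support of a raised-cosine pulse to within one frame.

**Flow displacement.** FD = 100 · ‖COV − centroid‖ / (2√(A/π)), where
the centre of velocity (COV) weights pixel centres by forward velocity
only (negative pixels carry zero weight), the vessel central point is
the area centroid of the per-frame lumen mask, and the effective
diameter comes from the mask area. `FDsavg` is the unweighted mean of
the defined per-frame FD values over the systolic window; frames with
no forward flow drop out rather than contributing zeros. Frame-wise
averaging (rather than FD of the time-averaged field) is the
configurable default.

**Rotational angle.** The clockwise angle of (COV − centroid) from
image-up, gated at FD ≥ 12% per frame: below the gate the displacement
vector is shorter than the discretisation/noise scale and its direction
is meaningless, so the frame is undefined rather than zero. The
per-subject summary is the circular mean (resultant-vector angle) of
the gated systolic frames — +170° and −170° average to 180°, not 0°.
Negative angles (counter-clockwise of 12 o'clock) are allowed.

**sFRR** = systolic retrograde volume / systolic forward volume × 100.
Undefined (missing, with a warning) when there is no systolic forward
flow. Gaussian velocity noise inflates measured sFRR additively — the
rectified noise inside the lumen integrates to a spurious retrograde
volume — which is a real phase-contrast noise-floor effect, visible in
the demo cohort as a few percentage points of upward shift.

**PWV.** Path length is the Euclidean arc length of the traced
centreline polyline. The transit time is the difference between the
first upstroke crossings of half the peak value of the descending and
ascending waveforms, scanning from the cycle start to the global peak
and interpolating linearly within the crossing interval; a waveform
already at/above half-max at its first sample has no upstroke and is
rejected. Non-positive transit times are physiologically invalid and
reported missing. Linear interpolation (no sigmoid/model fit) keeps the
estimator as simple as its definition; at 40 ms sampling it recovers
20–100 ms delays within 10%, and sub-frame delays (stiff aortas) carry
proportionally larger relative error — visible in the demo cohort as
compression of the highest PWV values.

## Synthetic data

The generator emulates a single-plane velocity-encoded cine plus a
paired waveform — not MR physics: no k-space, eddy-current, background
phase or aliasing simulation (the generated peak stays below the
nominal VENC, 200 cm/s by default).

- **Lumen**: a discretised disk (radius 16 mm, 64² grid at 1 mm, ≥ 2 px
  margin), constant over the 30-phase cycle at 40 ms intervals unless
  area pulsation is requested.
- **Jet**: a blunt profile — flat plateau to 0.6 of the jet radius,
  cos² taper to zero at the jet radius (0.8 of the lumen radius) —
  because systolic ascending-aorta flow is plug-like rather than
  sharply peaked. The jet centre is offset by
  `displacement_fraction × lumen diameter` along a chosen clock
  direction, so for a fully contained jet the continuum FD equals
  100 × displacement_fraction and RA equals the chosen direction.
- **Reversal**: a near-wall crescent opposite the jet (radial support
  0.5–1.0 lumen radii, angular half-width 75°) with negative velocity;
  its amplitude is found by bisection so the noiseless field's sFRR
  hits the requested target within 0.1 percentage points (sFRR is
  monotone in the amplitude; an unreachable target raises an error
  naming the achievable maximum).
- **Timing**: a raised-cosine (sin²) systolic envelope over the first
  35% of the cycle, diastole zero.
- **Noise**: i.i.d. Gaussian per pixel per frame, inside and outside
  the lumen, seeded.
- **Truth**: all flow-index truths are computed by running the
  package's own operators on the noiseless field, so recovery tests are
  self-consistent by construction; truth RA is computed without the FD
  gate (the true direction is exact on a noiseless field) and is NaN
  at zero displacement. PWV truths are analytic: the descending
  waveform is the analytically shifted ascending pulse, so the true
  transit time is exactly the requested delay.

What passing tests show — and do not show. Recovery on these bundles
validates the estimator definitions, their discretisation behaviour and
their noise response; it does not validate segmentation (masks are
inputs), phase-offset correction, aliasing handling, or any MR
acquisition effect, and a real cohort's biological spread enters only
through the parameter distributions described next.

**Cohorts.** Synthetic index tables draw each index from a log-normal
distribution parameterised by its median and IQR (indices are
non-negative and right-skewed); the log-sd solves
`IQR = median · 2·sinh(z₇₅·σ)` in closed form. The demo pipeline's
three groups use central values typical of young controls
(FDsavg 8%, sFRR 2%, PWV 4 m/s), old controls (16%, 7%, 11 m/s) and an
HFpEF-like patient group (23%, 11%, 8 m/s) with IQR-matched spreads and
n = 10/10/23; per-subject generator parameters are drawn from those
distributions, per-subject seeds spawn from one `SeedSequence`, and
identical configs rerun byte-identically.

## Statistics

All tests are two-sided at α = 0.05; no multiplicity adjustment by
default (Holm optional on the post-hoc tests). Group summaries are
median and IQR with quantiles by linear interpolation between order
statistics — stated because median ± IQR summaries depend on the rule.

- **Mann-Whitney U**: exact enumeration when the pooled sample is ≤ 12
  and tie-free, tie-corrected normal approximation otherwise.
- **Kruskal-Wallis**: tie-corrected H, chi-square reference, df = k−1.
- **Conover-Iman post-hoc**: pairwise t statistics on pooled midranks
  with the pooled rank variance scaled by (N−1−H)/(N−k), df = N−k;
  degenerate all-equal input gives t = 0, p = 1.
- **Partial correlation**: OLS of outcome on predictor + covariates;
  r = t/√(t² + df) with the predictor's t and residual df. Collinear
  designs fail naming the offending columns.
- **ROC/Youden**: thresholds are midpoints between adjacent sorted
  unique values plus ∓∞ sentinels, so strict-inequality cut-offs
  ("> 17.7") are representable; AUC uses the rank (Mann-Whitney)
  identity with midranks; the Youden cut-off maximises
  sensitivity + specificity − 1, ties broken toward the smaller
  threshold.
- **Within-subject CoV**: 100·√(mean(dᵢ²/2)) / grand mean — the
  root-mean-square-of-paired-differences estimator, scale-invariant.
- **Age/sex matching** (`match_age_sex`): greedy exact-sex,
  nearest-age 1:1 pairing within a 10-year caliper — a labelled
  approximation for matched-subgroup designs, not a reconstruction of
  any particular study's pairing.

Calibration, measured by `scripts/acceptance.py` and the test suite:
under the null all three rank tests reject within 5% ± 2 points over
500 replicates. At cohort-scale effect sizes (n = 10 vs 23, 200
replicates) the FDsavg contrast (16 vs 23, IQRs 5 vs 10) is rejected in
≈ 90% of replicates with the Youden cut-off between the two medians in
≈ 85–90%; the sFRR contrast (7 vs 11, IQRs 6 vs 10) has only ≈ 40%
power because IQRs comparable to the medians imply heavily overlapping
groups at these sample sizes — a property of the effect size, not of
the tests.

## Problem sizes and numerical choices

Default validation sizes: 64² grids × 30 frames per bundle (one
quantification takes ~50 ms), 50 noise seeds for robustness, 500
replicates for calibration, 200 for power, grid-refinement checks at
128²/512². Bisection for the reversal amplitude runs ≤ 60 iterations to
a quarter of the 0.1-pp tolerance. Half-max crossings require the first
sample below half-max; flow curves must have a positive net peak.
Degenerate frames (no forward flow) propagate as missing rather than
zero throughout.

## Known limitations

Masks are inputs — no segmentation. No phase-unwrapping, background
phase correction, or 3-directional (4D-flow) encoding; single plane
plus a paired waveform only. sFRR carries an additive noise-floor bias.
PWV is limited by waveform sampling for short transit times. Helical /
vortical flow patterns are out of scope; FD/RA describe eccentricity of
through-plane flow only.
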