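# Methods

## Measurement model

Opto-electronic plethysmography tracks passive markers on the trunk surface.
In the supine protocol implemented here, only the anterior surface (clavicles
to pubis) carries markers — 36 in a 6-row × 6-column grid by default. The
laboratory frame is fixed throughout the package: `+x` subject left → right,
`+y` caudal → cranial, `+z` bed → anterior. The frontal view is therefore
the x–y plane, and all file readers map into this frame. Units are meters
for coordinates and liters for volumes (1 L = 10⁻³ m³).

The default grid rows are clavicular, sternal-angle, nipple, xiphisternal,
10th-costal-cartilage, and umbilical/pubic; the anterior-axillary landmarks
sit at the lateral extremes of the sternal-angle row, the 10th-costal
landmarks at the extremes of the lower costal row. Any other grid can be
declared in a YAML layout file — only the landmark *roles* (two left/right
pairs, four transverse rows) enter the formulas, not the exact grid.

## Surface construction and volumes

For each frame the anterior grid is triangulated quad by quad using the
shorter diagonal (ties broken toward the cranial-left diagonal, for
determinism) and closed onto a horizontal bed plane: every marker is
projected to `z_bed = min(z) − offset` (offset 0.01 m by default), and the
bed panel plus a perimeter skirt of vertical quads complete a closed,
consistently oriented 2-manifold (Euler characteristic 2). The enclosed
volume is the divergence-theorem sum `V = (1/6) Σ v0 · (v1 × v2)`; a final
signed-volume check flips all faces if the winding came out inward.

Because only the anterior surface is measured, the *absolute* volume depends
on the closure convention. This is deliberate and harmless: every reported
quantity (tidal volume, compartment contributions) is a volume *difference*,
which is independent of the bed offset. The bed plane is computed once per
recording (the bed does not move), never per frame.

Compartments are delimited by the xiphisternal row (pulmonary vs abdominal
ribcage) and the lower-costal row (abdominal ribcage vs abdomen). Each
compartment is closed by the same construction applied to its row band; the
vertical cut walls through the boundary rows are shared by adjacent
compartments with opposite orientation, so the three compartment volumes sum
to the chest-wall volume exactly (to floating-point round-off, < 10⁻⁹ L in
practice, which the tests assert).

Two numerical choices worth noting:

* **Fixed topology per recording.** The quad-diagonal choice is made once on
  the time-mean geometry rather than per frame. Re-triangulating every frame
  would let marker noise flip diagonals back and forth, injecting artificial
  volume steps of no physiological meaning; a fixed topology keeps the series
  smooth and lets volumes be evaluated vectorised across frames. Single-frame
  `build_surface` still triangulates the frame it is given.
* **Degenerate input.** Coincident markers (< 1 nm apart) and
  cranio-caudally non-monotonic row ordering raise geometry errors rather
  than returning meaningless volumes.

## Breath analysis

The stable quiet-breathing window (minimum 40 s by default) is selected by
brute force: breaths are provisionally segmented over the whole recording,
and among all contiguous runs of breaths spanning the minimum duration the
one minimising the coefficient of variation of breath duration wins (ties go
to the earliest window). This operationalises "stable period" as maximal
regularity of breathing rate, is deterministic, and automatically avoids
movement artifacts, which distort provisional breath durations.

Extrema are detected on a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 2 Hz — comfortably above any pediatric respiratory
fundamental (120 breaths/min = 2 Hz would be the limit; the usable range in
practice is below ~100/min) — with a minimum prominence of 25% of the
window's median breath excursion and a minimum breath duration of 0.5 s. The
excursion scale is estimated robustly as median(peak heights) −
median(trough heights) from a distance-only first pass; an excursion below
1 nL is treated as apnea/no signal. A breath spans trough → trough and must
contain a peak.

Tidal quantities are read from the **unfiltered** series at the detected
instants. This matters at high rates: near the filter cutoff the smoothed
trace is attenuated by several percent, while extremum *timing* is unbiased
(zero-phase filter), so sampling the raw series keeps V_T exact. The signed
compartment changes ΔV_RC,p, ΔV_RC,a, ΔV_AB are taken over the same
chest-wall trough → peak interval — not over each compartment's own extrema —
so they sum to exactly V_T and their percentages to exactly 100%. This
synchronous convention is also what makes a *negative* pulmonary-ribcage
contribution meaningful: the compartment moved inward while the chest wall
expanded. Paradox is flagged when the mean percentage contribution of the
pulmonary ribcage is negative.

Pattern arithmetic: RR = 60/mean(T_tot), V_T = mean tidal volume,
V_E = RR·V_T, RSBi = RR/V_T; contributions are averaged per breath.
Cohort summaries report median and interquartile range per group, and the
Spearman rank correlation (midranks; two-sided p from the t-approximation
`t = ρ√((n−2)/(1−ρ²))`) between bell index and ΔV_RC,p (%V_T).

## Bell-shaped chest index

Per-frame frontal-projection Euclidean distances between the two landmark
pairs are averaged at the end-expiratory instants supplied by the breath
segmentation (falling back to the all-frame mean, with a warning, when none
are available), and the index is mean(d_upper)/mean(d_lower). End-expiration
is chosen to minimise any breathing-phase dependence; for marker grids whose
landmark x–y positions barely move during breathing the choice is
immaterial. Distances are 2D Euclidean in the frontal plane — for
near-horizontal landmark pairs this coincides with the purely lateral
separation.

The qualitative shape classes are mapped to configurable thresholds:
index < 0.85 → bell, 0.85–1.15 → rectangular, > 1.15 → inverted triangle.
The bounds sit between the index values typical of bell-chested subjects
(~0.73–0.81) and of healthy children (~0.91–0.92); they are an explicit
operationalisation, exposed in the configuration, not a claim about a
clinical cut-off.

## Synthetic data generator

`make_torso` builds a grid whose width tapers linearly through the
sternal-angle and lower-costal rows, so the programmed
`upper_width / lower_width` *is* the ground-truth bell index, exactly, and
whose per-row anterior heights follow a gently domed child-sized profile
(trunk 0.35 m, chest width 0.18 m, heights 5–8 cm by default).

`simulate_breathing` applies anteroposterior displacement fields with
row-band weights per compartment, modulated by a raised-cosine breath
waveform (trough at end-expiration, peak at end-inspiration). Breath periods
are drawn i.i.d. with a programmable coefficient of variation (clipped to
±50%); Gaussian noise of programmable σ is added to every marker coordinate;
everything is reproducible from the seed. The key property: under the
bed-plane closure with fixed topology, compartment volumes are *linear* in
anteroposterior marker displacement, so the 3×3 sensitivity matrix of
(field amplitude → compartment volume change) computed through the actual
volume pipeline is exact, and solving it makes the programmed contribution
split (p_rcp, p_rca, p_ab) — including negative p_rcp for paradox — hold
exactly on the noise-free signal. Amplitudes that would push markers through
the bed plane or move them by more than half the trunk length raise an
infeasibility error.

Default breathing parameters (RR 30/min, V_T 0.2 L, split 0.20/0.10/0.70,
60 s at 60 Hz) represent quiet supine breathing of a healthy young child
with the abdomen dominant. The default five-group cohort spans
healthy-like to severe-like scenarios (group mean bell indices 0.92 → 0.73,
pulmonary-ribcage contributions +20% → −8%, increasingly rapid and shallow
pattern, 0.2 mm marker noise); these are *illustrative* severity profiles
for validating the pipeline, not reproductions of any patient cohort.

What the generator does **not** emulate: rib kinematics (motion is a
z-displacement field, not rotation about costovertebral axes), posterior
surface motion, scoliosis and other asymmetries, marker occlusion patterns
of real labs (gaps must be injected explicitly), cardiogenic oscillations,
sighs and swallowing artifacts. Passing recovery tests therefore shows the
*analysis chain* is correct and self-consistent at realistic signal/noise
scales; it does not validate the closure convention against a gold-standard
volume, which for tidal differences is the relevant published practice.

## Problem sizes and tolerances

Tests and the acceptance script use 10–60 s recordings at 60 Hz, 36-marker
grids, cohorts of 5 × 10 subjects, and tens of noise seeds per scenario —
small enough to run in seconds while leaving every recovery margin
(rates within 1%, tidal volumes within 2%, contributions within ±1 point
noise-free and ±3 points at 2% marker noise, index within ±0.01/±0.03)
clearly resolvable. "2% marker noise" means σ equal to 2% of the
peak-to-peak displacement of the most-moving marker.

## Known limitations

* Only the tabular CSV trajectory dialect is read; C3D files must be
  converted upstream.
* Absolute compartment volumes are closure-convention dependent (anterior
  surface only); compare only differences or contributions across systems.
* The stable-window criterion assumes the recording contains at least
  40 s of segmentable breathing; heavily artifacted recordings raise
  insufficient-data errors rather than guessing.
* The breath detector is designed for quiet breathing; it will merge
  breaths during extended apneas and is not a sleep-staging tool.
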