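# Methods

This note documents the models, conventions and parameter choices behind
`rvecv`, and what its synthetic validation does and does not demonstrate.

## Coordinate and sampling conventions

Pixel `(r, c)` occupies the half-open square `[r, r+1) × [c, c+1)`;
continuous coordinates are `(row, col)` from the top-left corner, pixel
centers at `(r+0.5, c+0.5)`. All geometry files and APIs use this
convention; anisotropic pixel spacing is supported throughout (traversal
in pixel units, lengths in mm).

**LOI supercover.** "Pixels crossed by the line" is made precise as:
pixels whose *open* interior the polyline intersects, each listed once in
first-crossing order. A line through the exact corner between pixels, or
sliding exactly along an edge, crosses neither neighbor — this
tie-breaking rule makes the diagonal case deterministic and lets the
implementation be verified against an independent per-pixel
Liang–Barsky clipping oracle (and dense point sampling) on random
polylines. Implementation: each segment is split at every integer
gridline crossing; each sub-interval midpoint identifies the containing
pixel. Per-pixel statistics are the unweighted mean and *population* SD
(divide by n) of the crossed pixels — the most literal reading of
averaging "the pixels crossed by the line"; a chord-length-weighted mean
is available behind a flag (`weights="length"`) for sensitivity analysis,
since an interactive pencil tool might effectively weight by traversed
length. NaN pixels are excluded and counted.

**ROI rasterization.** Pixel centers inside the polygon under the
even-odd rule. Boundary ties are resolved half-open (row spans `[y1, y2)`
and column intervals `[x_enter, x_exit)`), so left/top boundary centers
are in and right/bottom are out — deterministic and orientation-free.
The minimum-extent rule (default 10 mm) uses path length for LOIs and the
longest vertex chord for ROIs, because an ROI's prescribed size is a
length, not an area.

**Wall thickness.** Maximum wall thickness per ROI, in pixels, is
measured on a binary myocardium mask rendered at `supersample_factor`
(default 8) subpixels per pixel: twice the Euclidean distance transform
evaluated on the mask's medial-axis skeleton, restricted to the ROI's
pixels. The mask is first upsampled ×2 so a ribbon of any integer
subpixel width has even width in the doubled grid, which makes the
estimator exact for straight axis-aligned ribbons and removes a
half-subpixel parity bias; residual error for curved or oblique walls is
about one subpixel (1/8 px at the default supersampling). Grades follow
the clinical convention: grade 1 > 2 px, grade 2 = 1–2 px (inclusive),
grade 3 < 1 px. In clinical practice this grading is visual; the
automated measurement here is this package's own addition and is labeled
as such in outputs. On phantoms the ground-truth mask is graded; the
native-phase map is the default basis when thresholding real data.

## ECV computation

`compute_ecv` implements the ΔR1-ratio formula with T1 in ms; the rate
unit cancels, and scale invariance is tested exactly with binary
scalings. Hematocrit must lie in (0, 1]; the degenerate value 1 gives
ECV 0. A non-positive blood ΔR1 is a hard error (the measurement is
meaningless without blood contrast kinetics); a negative myocardial ΔR1
returns a *flagged negative* ECV with a warning rather than silently
clipping, so acquisition problems surface in review instead of vanishing.
`derive_post_t1_myo` is the closed-form inverse used to plant phantom
truth: `1/T1_post = 1/T1_pre + ECV/(1−Hct) · ΔR1_blood`; the round trip
is identity to machine precision.

Feasibility (`assess_feasibility`): measurable iff quality grade ≤ 2 and
wall grade ≤ 2 and both maps present; the verdict carries
machine-readable reasons (`insufficient_contrast`, `wall_below_1px`,
`missing_map`). Cohort summaries always aggregate per-subject ECVs —
never the ECV of cohort-mean T1s, which differs because a mean of ratios
is not a ratio of means. When both SAX and TRANS maps exist the table
emits both rows; downstream reports prefer SAX, where the RV wall is
typically better delineated.

## Phantom

Geometry (all in pixels, defaults chosen to resemble a midventricular
short-axis slice at 1.9 mm spacing on a 192×192 grid; the acquisition
matrix of the motivating protocol is not standardized, so this is a
declared, configurable assumption): LV cavity radius 9, LV wall 5,
RV inner-boundary radius 20, RV wall thickness configurable 0.25–4 px,
RV crescent = region between two (optionally offset) circles clipped to a
110°–250° angular sector. Between the LV epicardium and the RV wall lies
RV cavity blood; outside the heart is air (zero signal). The RV
centerline is the mid-curve between the two arcs, sampled at 0.25-px
steps. The auto-generated RV ROI is a band around the centerline with
half-width `max(wall/2 − 0.75 px, 0.5 px)`: pulled 0.75 px inside each
border when the wall allows (emulating careful contouring that avoids
boundary pixels), but never narrower than one pixel total — an operator
cannot draw a sub-pixel ROI, which is precisely why sub-pixel walls are
biased. The blood ROI is a circle at 60% of the cavity radius; the LV
ROI/LOI pair sweeps a 300° annular sector of the LV mid-wall.

Tissue T1 defaults are typical patient values at 1.5 T: native
myocardium 1018 ms, native blood 1492 ms, post-contrast blood 531 ms,
hematocrit 0.43, target RV ECV 0.31, LV ECV 0.30. The cohort generator
draws per-subject values from truncated normals with matching spreads
(ECV 0.31 ± 0.05 truncated to (0.15, 0.55) and below 1 − Hct;
Hct 0.43 ± 0.05; native myocardium ± 30 ms, native blood ± 88 ms, post
blood ± 73 ms; wall thickness uniform on 1–3 px). Post-contrast
myocardial T1 is always derived from the target ECV, so truth is exact.

**Signal simulation.** Each tissue follows
`S(TI) = A − B·exp(−TI/T1*)` with `T1 = T1*(B/A − 1)` — the standard
three-parameter apparent-recovery description of a Look-Locker readout
train. Defaults A = 1, B = 2 make the correction factor exactly 1; the
simulation plants `T1* = T1/(B/A−1)` so fit-plus-correction recovers the
tissue T1 by construction. The 3(3)3(3)5 scheme uses base TIs
120/200/280 ms and RR 1000 ms (11 readouts, TIs up to 4280 ms); the true
TI spacing of any particular scanner protocol is not modeled, and all
validation targets recovery of planted truth rather than absolute
protocol fidelity, so results are insensitive to these defaults. Noise
is additive Gaussian on the signal (phase-sensitive reconstruction;
Rician magnitude noise is out of scope), default SD 0.01 for A = 1.

**Partial volume.** Tissue masks are rendered at 8× supersampling;
per-pixel tissue area fractions mix either the *signals* (default
`signal_domain` mode: blended curve, then a real least-squares fit — the
physically faithful path; air contributes zero signal, which rescales A
and B together and leaves fitted T1 unchanged) or the *rates*
(`r1_domain`: area-weighted R1 average over non-air fractions, inverted
analytically; fast and noiseless). The two modes agree on pure-tissue
pixels to fit tolerance and differ, as they should, on mixed pixels.

**T1 fitting** is separable least squares: for fixed T1* the optimal
(A, B) are closed-form, so each pixel reduces to a 1-D search in T1*,
solved with a 48-point log-spaced coarse bracket on [40, 4000] ms plus 50
vectorized golden-section iterations — exact to ≪ 0.1 ms on noiseless
model data and fast enough to fit whole cohorts. Pixels with A ≤ 0,
B/A ≤ 1, fewer than 3 finite samples, or a result outside the
plausibility range [0, 5000] ms become NaN.

**Misregistration.** Optional per-frame integer shifts (the last-TI
frame is the alignment reference and stays put). Correction
cross-correlates signal magnitudes against the last-TI frame via FFT,
searching ±grid/4. Three details matter: magnitudes are mean-filled at
NaN edges and zero-meaned (otherwise the flat background or the edge band
swamps the structure peak), the *absolute* correlation is maximized
(inversion-recovery contrast flips polarity across the signal null, so
the true peak can be negative), and a σ = 1 px Gaussian smooth suppresses
noise-induced one-pixel jitter on the low-contrast late-TI frames.
Recovery is exact for noiseless integer shifts and, in the seeded
simulation study, exact in ≥ 95% of trials at 2% signal noise. Pixels
losing frames to edge fill are fitted on their remaining TIs (≥ 3).

## Experiments and what they show

*Feasibility sweep*: walls 0.5–3.0 px in 0.25 steps, 10 noise
realizations each, at default noise. Mean |ECV error| below 1 px is an
order of magnitude larger than at ≥ 1 px, and the mean measured ECV below
1 px is biased *upward*, toward the plasma fraction 1 − Hct — because the
only tissue a sub-pixel RV wall can blend with on its cavity side is
blood, whose ΔR1 exceeds the myocardium's. This reproduces, in a setting
with known truth, the rationale for refusing ECV measurements on walls
under one pixel.

*LOI vs ROI cohort*: 40 seeded subjects, walls 1–3 px. Both methods
sample the same wall on identical maps, so their agreement is expected to
be high; the experiment quantifies it (Pearson r ≈ 0.98, |bias| < 0.01,
limits of agreement containing zero at the default noise level) and the
acceptance thresholds (r ≥ 0.90, |bias| ≤ 0.01) leave room for noise.

**Limits of the synthetic validation.** The phantom has smooth circular
anatomy, uniform tissue T1, no trabeculation, no epicardial fat, no
through-plane partial volume, no B1/off-resonance MOLLI bias, and only
integer translational motion. Passing these tests therefore demonstrates
correctness of the *measurement machinery* — sampling geometry, fitting,
the ECV algebra, the bias mechanism — not clinical accuracy on patient
images, where operator placement, trabeculation and fat borders add
error sources the phantom deliberately omits. Problem sizes (192×192
grid, 8× supersampling, 40-subject cohorts, 10 replicates per sweep
point) were chosen so the full validation runs in about a minute while
keeping Monte-Carlo error well below the decision margins.

## Numerical details and edge cases

- Gridline crossings are merged within 1e-12 in segment parameter;
  segments lying exactly on a gridline contribute no pixels.
- Thickness grading at the exact 2-px boundary can flip to grade 1 on
  curved walls because the discrete estimator may overshoot by up to one
  subpixel; boundary semantics (1.0 → 2, 2.0 → 2, 2.0+ε → 1) are fixed
  and tested on exact straight ribbons.
- DICOM maps store ms as unsigned 16-bit with RescaleSlope 0.1
  (quantization ≤ 0.05 ms); raw 0xFFFF is the NaN sentinel. The text
  dialect stores full `repr` precision and round-trips bit-exactly.
- Maps smaller than 8×8 load with a warning rather than an error, so
  tiny didactic fixtures remain usable while real maps are screened.
- All stochastic operations take a seed or Generator; cohort and sweep
  workflows derive per-subject seeds from `SeedSequence` spawns, and
  identical config + seed reproduces CSV outputs byte-for-byte.
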