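# Methods

## Scope and design

`sicklekit` reproduces, on synthetic data, the quantitative analysis
used to show that an anti-sickling intervention reduces red-blood-cell
sickling in vitro: imaging-cytometry morphometry with sequential gating
and a Sickle Score classifier, and video-based sickling kinetics.  The
synthetic generator stands in for patient-derived cultured red blood
cells (cRBCs); every analysis step consumes only rendered pixels and
tabular manifests, so the same code runs unchanged on real single-cell
crops supplied in the same layout.

## Synthetic event generator

Each event is a multi-channel crop (brightfield, DNA stain, surface
marker) on a 0-based, row-major pixel grid; physical quantities convert
through `pixel_size_um` (default 0.5 µm/px, crop 72 px).  Brightfield is
transmitted-light-like: background ≈0.8 of full scale, dark membrane rim
(0.35), lighter interior (0.65), additive Gaussian noise σ = 2% full
scale.  Fluorescence channels have near-zero background (10⁻³–5·10⁻³)
and σ = 0.3% noise; the marker channel fills the membrane area, so its
integrated intensity scales with mask area, and the DNA channel is lit
only for nucleated events and free nuclei.

Morphology classes: disc (area-preserved ellipse with mild tilt
ellipticity), sideways (edge-on, axis ratio ~3), crescent, star (cosine
boundary modulation of order `harmonic_order`), wrinkled (random
harmonics of order 3–8; order 2 is deliberately excluded so roughness
does not leak into the 2-fold symmetry band), spiculated (crescent with
1–2 px radial fibers), plus contaminants: nucleated cells, free nuclei
(~3.4 µm), debris (1.2–2.4 µm, below the analysable-mask floor),
aggregates (chains of 2–3 touching cells).

**Crescent geometry.** A sickled cell is rendered as a bent ellipse: an
area-preserved ellipse with axis ratio `elongation` whose columns are
sheared along the minor axis by a parabolic offset scaled by
`curvature`.  The shear is exactly area-preserving (projected area is
conserved through sickling, as expected from volume conservation),
yields the classic curved spindle with tapered ends, keeps
length/thickness ≈ `elongation`, and interpolates continuously from a
disc (morph 0) to the full crescent (morph 1) for video rendering.  A
difference-of-two-ellipses lune was considered and rejected: it either
loses most of the projected area or, area-rescaled, degenerates into an
implausibly long thin arc.

**Population structure.** Class fractions default to an induced
homozygous-HbS-like mix (25% crescent+spiculated among all events, 78%
mature cell classes, 18.5% nucleated material, ~3.5% debris/aggregates,
97% marker-positive, 25% rendered out of focus), a treated mix with the
sickled classes reduced by roughly one third, and an uninduced mix with
no sickled classes.  Per-class counts are exact largest-remainder
apportionments of the fractions (remainder ties broken alphabetically);
order is then shuffled by the master seed.  Within-class variability —
cell diameter N(8, 0.9) µm, disc ellipticity 1+|N(0, 0.28)| capped at
1.8, crescent axis ratio N(2.9, 0.25) and curvature N(0.7, 0.12),
boundary roughness U(0.02, 0.10) for discs and crescents alike — was
fixed at design time so that single metrics separate induced from
uninduced cells with Fisher discriminants of order 1–2 (overlapping
distributions, as in real imaging cytometry) rather than perfectly.
These defaults are the study conditions; they are not tuned per run.

**Seeding.** One master seed per run; event k draws from
`SeedSequence(entropy=seed, spawn_key=(0, k))` (stream 1 is reserved for
per-frame video noise, stream 2 for sickling times), so any event or
frame is reproducible in isolation and sparse video rendering is
pixel-identical to dense rendering at the same indices.

## Morphometry

Segmentation inverts the brightfield crop, takes the Otsu threshold,
fills holes, applies one binary closing, and keeps the largest connected
component.  Crops whose foreground/background contrast is below 0.06
full scale (blank crops: Otsu would split pure noise) and masks under
16 px are flagged degenerate; flagged events carry NaN features and are
excluded downstream, never silently zeroed.

* **Length L**: extent of the mask projected on the major second-moment
  eigenvector.
* **Thickness**: from the Euclidean distance transform.  Tmax = 2·max
  EDT (attained on the medial axis).  Tmin = 2·min EDT over the
  *retained* skeleton: the thinned skeleton (Zhang) pruned of side
  branches shorter than max(10% of L, 1.5× the inscribed radius at
  their junction) — corner and wrinkle spurs never leave the maximal
  disk they sprout from — with the terminal 10% of the remaining path
  (geodesic, √2 diagonals) excluded, because medial-axis tips taper to
  zero thickness on every shape.
* **Shape Ratio** = Tmin/L, clipped to (0, 1.05]; **aspect ratio** =
  ratio of principal extents; **circularity** = 4πA/P² (perimeter via
  4-connected boundary count), clipped at 1.
* **Symmetry 2**: boundary radius r(θ) at 256 angles about the centroid,
  computed by intersecting each ray with the sub-pixel marching-squares
  contour and taking the outermost crossing (concave outlines use their
  outer radius; rays that never cross score 0).  S₂ = |c₂|/|c₀| of the
  DFT of r(θ).
* **Texture**: intensities inside the mask quantized to 16 grey levels
  (min–max), co-occurrences pooled over the four axis-aligned 1-px
  offsets, symmetrized and normalized; H Contrast = ΣP(i−j)², H Entropy
  = −ΣP log₂P (bits).
* **Focus**: RMS gradient magnitude over the crop divided by mean
  intensity.
* **Sickle Score** = S₂ / SR.

Numerical caveats: at the default scale a crescent is only ~5 px thick,
so Tmin is quantization-limited there (the EDT minimum moves by ~0.5 px
under 90° rotation); length and S₂ are rotation-stable to <2%.  The
analytic-shape oracle suite therefore uses flat-thickness shapes
(circles, axis-aligned rectangles, stadiums incl. rotated ones), where
the definition is well conditioned; on smoothly tapering shapes the
terminal-exclusion rule intentionally reports the thickness at the 10%
path position, not the midline maximum.

## Gating

Fixed chain: non-nucleated (integrated DNA ≤ threshold) → non-debris
(area inside range; degenerate events fail here) → mid-focus (focus ≥
lower bound; one-sided because the generator has no over-focus
artifact) → marker-positive (integrated marker > threshold).  Gates are
conjunctive, so the final set is invariant under reordering; only the
trail changes.  Calibration from a reference population: DNA and marker
thresholds by a between-class-variance-maximizing split computed on
log₁₀ intensity (integrated fluorescence is log-normal-like and the
negative mode is a small minority; on the raw scale the Otsu criterion
lands inside the broad positive mode); area range = [2.5, 97.5]
percentiles of the non-nucleated events (linear-interpolation
percentiles throughout); focus bound = 25th percentile of the focus
score, matching the generator's out-of-focus fraction of 25% — the rule
and the generator default were co-designed, and a population with a very
different out-of-focus rate would need the bound re-examined.  A
unimodal DNA (or marker) distribution falls back to an extreme
percentile with a warning recorded in the config.  On default mixes the
final set recovers true mature cRBCs with recall and precision ≥ 0.95;
residual contaminants are mostly 2-cell doublets whose area overlaps the
largest single cells.

## Sickle scoring

Fisher's discriminant uses the |μ₁−μ₂|/(σ₁+σ₂) convention (sample SDs,
n−1); a pooled-SD variant is available via `denominator="pooled"` since
the convention cannot be pinned down externally.  Metric ranking sorts
descending with alphabetical tie-break.  The training sets mimic
hand-picking: the sickle set is a tight band of canonical fully formed
crescents, while the non-sickle set spans the full uninduced range of
near-circular to moderately elliptical discs — a human picks
unambiguous sickle examples but accepts any clearly-non-sickled cell.
This asymmetry matters: because the score S₂/SR is convex in the latent
elongation, wide non-sickle spread is damped while the class gap is
amplified, which is why the combined score out-discriminates Shape Ratio
alone.

The sickle gate is the (1−spillover) linear-interpolation quantile of a
non-sickling control population's scores (default spillover 0.10, i.e.
the 90th percentile); an event is sickled when its score is *strictly*
above the threshold, matching the spillover-as-exceedance reading.
Group endpoints are compared with the equal-variance two-sample t test
(Welch via `equal_var=False`).

## Video kinetics

The kinetics model is delay + exponential: susceptible fraction p_s,
absolute delay t₀ = 4.3 min (no cell sickles earlier), hazard λ per
minute, recording window T = 30 min at 4 fps.  The delay+exponential
form is a modeling choice: only the delay, median and maximum rate are
externally constrained, not the full distribution.  Cells are stationary
on a non-overlapping grid (cells settle in the dish); each renders as a
disc until its time, then morphs to its crescent over 2 s ("rapid,
within a few seconds").

Detection samples every 256th frame (64 s at 4 fps).  For each cell and
consecutive sampled pair the mask change is 1 − IoU of the cell-window
masks (fixed threshold halfway between interior and background grey
levels, hole-filled).  A cell's event is the first sampled frame with
change > 0.25 that remains changed relative to the pre-change reference
at the next sampled frame (persistence check; the last interval is
exempt); the event time is the detecting frame's time, so detected
times are multiples of the sampling interval and never precede the true
transition.  Cells losing their mask in >20% of sampled frames are
flagged and dropped (not censored, to avoid informative censoring); all
others without an event are censored at T.  This automated detector is
a reproducible surrogate for blinded human frame-by-frame scoring; its
change threshold is exposed in the config.

Endpoints: percent sickled at T; median time to sickling over event
times only (lower median on ties — the sampling grid makes ties
routine); delay = first event time; maximum rate = max over raw sampled
intervals of (fraction sickling in the interval)/(interval seconds),
pooled over cells, without smoothing (a k-interval moving average is
available but off by default).  Group comparisons: Gehan-Breslow-
Wilcoxon — the weighted log-rank with weight n_j (total at risk) at
each event time, ties handled through the hypergeometric variance,
χ²(1), two-sided — implemented directly and cross-checked against an
independent survival library in the tests; and the two-sided rank-sum
test on uncensored event times (exact for small untied samples,
normal approximation with mid-rank tie correction under the heavy grid
ties).

## Validation scale and what it shows

The recovery study in `scripts/acceptance.py` uses 20 replicates per
arm at the study sizes (568 and 609 cells) and takes ~2 min on one CPU;
the test suite runs smaller populations (2.5–10k events, 40–500 cells)
chosen to keep the full suite under ~5 min while leaving binomial noise
well inside the asserted tolerances.  Passing tests show that the
analysis machinery recovers known generator parameters and orderings
under the stated noise model.  The generator does not emulate phase
optics, hemoglobin polymerization physics, cell motion, flow-cell
orientation effects, staining variability, or sickling reversal during
fixation — so agreement here does not certify performance on real
imagery; it certifies the statistical pipeline itself.
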