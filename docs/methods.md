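# Methods

This note records the quantitative conventions the package pins down,
the reasoning behind the genuinely open design choices, and what the
synthetic-data generators do and do not emulate.

## Image primitives

**Foreground convention.** Every threshold `T` defines foreground as
pixels *strictly greater* than `T`; objects are 8-connected. These two
choices are fixed once, here, because the interactive tools this
pipeline replaces leave them implicit and both affect counts at
object boundaries.

**Auto-thresholding.** The named modes are the classical 256-bin
histogram algorithms:

- *default_isodata* — iterative intermeans (the IsoData variant):
  starting from the midpoint of the occupied range, iterate
  `T ← ⌊(mean(≤T) + mean(>T))/2⌋` to a fixpoint. The test suite checks
  the result against a brute-force scan of all 256 candidates for the
  fixpoint condition.
- *moments* — Tsai's moment-preserving threshold: the first three gray
  level moments determine a two-level image with identical moments;
  `T` is the gray level at which the cumulative histogram reaches the
  below-threshold fraction `p₀`. Tie-break: the cumulative scan stops
  at `≥ p₀` (the lower bin). The common port stops at `> p₀`, which on
  an exactly two-spike histogram returns the upper mode and an empty
  foreground; our convention preserves the moments exactly in that
  degenerate case and differs only on exact ties.
- *intermodes* — the histogram is repeatedly smoothed with a running
  3-bin mean until exactly two modes remain; `T` is the mean of the two
  mode positions (possibly half-integral). Mode counting is
  plateau-aware: a run of equal bins flanked by strictly lower runs is
  one mode at the run center, which keeps the procedure well defined on
  the spike histograms that idealized renders produce. The smoothing
  loop is capped at 10,000 passes.
- *fixed* — a constant cutoff; used at 160 (of 0–255) for
  Hoechst-stained nuclei per the bench protocol.

A constant image has no separating threshold: automatic methods raise a
`DegenerateHistogramError` rather than silently returning 0. At the
assay level a constant channel simply means "nothing to count", so the
assay wrappers (`channel_mask_or_empty`) convert that error into an
empty mask; the distinction keeps silent zeros out of the primitive
while letting a blank field score zero objects.

16-bit images are compressed to 256 equal-width bins over the full
0–65535 range for automatic thresholding only; the bin threshold `t`
maps back to the native cutoff `(t+1)·256 − 1`, so "greater than"
comparisons agree between scales.

**Perimeter and circularity.** Perimeter is measured by a Moore
(8-connected) boundary walk over the outer contour with the
Vossepoel–Smeulders corrected step weights — 0.948 per axial step,
1.340 per diagonal step — an estimator that is unbiased for smooth
digital contours. With plain (1, √2) weights a rasterized disk of
radius 5–50 px measures circularity 0.91–0.94, i.e. a perfect circle
would fail windows meant to select round objects; under the corrected
weights disks measure 1.01–1.04 and clamp to 1.0. Circularity is
`4πA/P²` clamped to [0, 1]; an isolated pixel is assigned the perimeter
of a unit square (4 × 0.948). Interior holes are ignored (outer
boundary only), matching particle-analysis practice. All size windows
("x–y pixels") are areas in px² with inclusive bounds.

**H-maxima watershed.** Seeds are regional maxima whose *dynamics* (the
minimum descent needed to reach a strictly higher pixel) are at least
`h`; they are computed as the pixels where
`image − reconstruct(image − h, image) ≥ h`, which realizes "dynamics
≥ h" exactly, with equal-height summits counting as separate seeds
(each has infinite dynamics under the strictly-higher rule). Each seed
floods the connected superlevel set at
`peak − (peak_flooding/100)·(peak − intensity_threshold)`; at the 100 %
setting used by the axon assay this is everything down to the intensity
threshold. With splitting disabled, touching basins merge — the result
degenerates to the connected components of the flooded support — and
with splitting enabled, basins are separated by marker-driven
immersion. An image entirely below the intensity threshold yields an
empty labeling, not an error. Only the 100 % flooding setting is
exercised by any assay; the partial-flooding semantics above are our
pinned generalization.

## Screen readouts and hit calling

`quantify_well` pools punctum and nucleus counts across a well's fields
before forming P/NLS, and VAI is the mean of per-punctum mean GFP
intensities pooled over all puncta in the well (not averaged per cell
first — the per-cell alternative is not expressible without a cell
segmentation the assay does not perform). A well with zero transfected
cells has an undefined P/NLS (NaN + flag), never a silent 0; such wells
are routed to the toxic bin by the cascade, zero surviving transfected
cells being the extreme of the toxicity phenotype.

Default detection windows: puncta 5–500 px at circularity 0.6–1.0 with
Intermodes thresholding of the GFP channel; nuclei ≥ 500 px at
circularity 0.8–1.0 with the fixed 160 cutoff. Both are config
overridable.

Normalization is to the same-run vehicle mean (a "run" maps to a plate
batch in the config). The cascade applies, in order: toxic ⇔
`nls_count < 0.70 × vehicle mean` (strict); increaser ⇔ normalized
P/NLS `> 1.8` (strict). Hits require *both* normalized readouts
strictly below `mean − 2·SD`, with mean and sample SD taken over all
post-cascade determinations of the completed screen. A running-basis
variant (statistics over determinations seen so far, as used while a
campaign is in flight) is available but not the default, since final
statistics are the reproducible quantity.

Dose-dependence confirmation (3 doses, triplicate) is not a standard
formula anywhere; our pinned rule is: the top-dose mean must clear the
hit threshold, and per-dose effects must be monotone non-increasing
with dilution within a tolerance of 10 % of the top-dose effect
(config knob). A compound passes if either readout passes.

## Viability and IC50

Viable cells are particles of the Calcein ∩ Hoechst mask within
500 px–∞ and circularity 0.8–1.0, with Calcein thresholded by
IsoData/"Default" and Hoechst by Moments. The 4PL
`y = bottom + (top − bottom)/(1 + (x/IC50)^h)` is fitted by
least squares on log-dose with a variable Hill slope (the fixed-slope
variant is the other defensible choice; we fit and report `h`).
Initialization: top/bottom from the response extremes, IC50 from the
dose bracketing the half-range, `h = 1`; IC50 is constrained to
[min dose/10, max dose×10]. Technical replicates are averaged per
dose within a biological replicate, then biological replicates
averaged, in that order. Data with dynamic range under 10 % of the top
response are monotone-flat: the IC50 is undefined and `converged` is
False. Note an identifiability limit of the assay design itself: with
the 0.3125–20 µM series and IC50 near 5 µM the curve only descends to
~20 % of top within range, so the bottom asymptote — and with it the
IC50 — carries irreducible variance at realistic count noise;
individual fits scatter by tens of percent while the median recovery
stays within a few percent. The brute-force grid oracle in the tests
shows the same scatter, confirming it is the design, not the optimizer.

## Retinal quantification

RGC nuclei are connected components of the DAPI ∩ Brn3a foreground
(both channels IsoData-thresholded by default; override available
since the bench protocol does not name a mode). Per-nucleus means of
the p-c-Jun channel are averaged per field without weighting by
nucleus count, and exactly three fields average to one per-eye value —
the experimental *n*. A field with no nuclei is excluded with a
warning; an eye with none anywhere is undefined. Nuclei touching the
field border are included (an exclusion flag is a possible extension).
Inputs are 2-D maximum-intensity projections prepared by the caller.

## Synthetic data

The generators render 8-bit fields (default 1024×1024 px; the fixed
cutoffs 160 and 200 are meaningful on this scale) with objects as
intensity plateaus over a flat background of 20 gray levels, placed by
dart-throwing with minimum separations so that idealized detection is
exact. The noise model is additive Gaussian read noise, default
σ = 6 gray levels, with optional Poisson shot noise; contrasts are
chosen so every planted object stays several σ from the operative
threshold. Each generator is a pure function of (parameters, seed);
truth records serialize losslessly to JSON.

Specifics worth knowing:

- *HCS fields* — punctate cells carry uniform-brightness puncta
  (vesicles modeled as plateaus, default footprint ~13 px inside the
  5–500 px window; a Gaussian-profile option exists but a diffuse
  Gaussian tail has no second histogram mode for Intermodes to find).
  Diffuse cells spread the same integrated flux below threshold.
  Nuclei (≥ 530 px) render at 220 against the fixed 160 cutoff.
- *Axon fields* — axons are smooth random-walk dark curves (3 px
  cross-section) in per-axon horizontal bands (so planted structures
  never merge); somata sit at the proximal end and are recorded in the
  cell-body mask. Degeneration follows a dying-back rule: a distal
  fraction `bleb_density × susceptibility` (susceptibility fixed per
  axon by the seed, uniform 0.4–1.6) is replaced by beads of ~25 px,
  far below the 400-px structure window, which makes the integrity
  index monotone non-increasing in bleb density for a fixed seed.
  Marker channels render on the intact geometry: accumulations are
  ellipses of ~220–900 px placed on axons with the flanking shaft
  cleared (marker draining from shaft into the swelling), vesicle
  puncta are 5–9 px disks along axons.
- *Screen simulator* — normalized readouts of inactive compounds are
  `1 + ε`, `ε ~ N(0, σ)` with σ = 0.1 by default; toxic compounds
  draw transfected-cell counts around 40 % of vehicle; increasers
  scale P/NLS to ~2.5×. Planted hits realize their stated effect as a
  displacement of the observed readouts — `1 − effect·σ` plus a small
  potency jitter (0.25 σ) between hits — i.e. "effect" is defined at
  the level of the screen determination, with jitter modeling potency
  variation among actives rather than re-adding full assay noise on
  top of the shift.

What the generators deliberately do **not** emulate: point-spread
functions, uneven illumination, phase-contrast optics (halos), focus
drift, cell debris, overlapping or touching cells, and 3-D structure.
Passing the recovery tests therefore demonstrates that the measurement
chain is correct and stable under sensor-like noise — not that it is
robust to the full variability of real micrographs, where threshold
choice and touching-object separation dominate error.

## Problem sizes

The test suite and acceptance script run on 512×512 fields (all
detection windows are meaningful at that scale) with 6–12 axons or
12–40 cells per field, 10–20 seeds per recovery check, screens of
2,000–28,400 simulated compounds, and 100–200 IC50 curves — sizes
chosen to exercise every code path at desk scale.

## Known limitations

- The Intermodes smoothing loop can need ~10³ passes on spike
  histograms; pathological histograms that never become bimodal raise
  after the 10⁴-pass cap.
- Partial-flooding (< 100 %) watershed semantics are our pinned
  generalization, untested against the interactive original.
- The running-basis hit call reproduces order-dependence by design;
  its output depends on table order, unlike the default.
- Per-object boundary tracing is pure Python; morphometry on fields
  with ≫10⁴ particles will be slow before it is wrong.
- The toxicity filter compares to per-run vehicle means; if a run
  spans plates with a plate effect, a per-plate reference (not
  implemented) could classify borderline wells differently.
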