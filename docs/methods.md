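# Methods

`leafmorph` extracts phenetic leaf characters — lobes and sinuses, apex and
base shape, and margin tooth type — from single-leaf images, and identifies
species by nearest-neighbour matching of those characters. This note
records the model, the tunable parameters, the numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Shape signature

All shape analysis runs on the **centroid contour distance over every
boundary point** (CCD-EBP): the silhouette's boundary pixels are collected
clockwise (Moore-neighbour tracing, 8-connected, duplicate-free), and the
Euclidean distance from a reference point to each boundary pixel forms a
1-D cyclic signal `Dist_i`. Two choices matter:

* **Every boundary point, not angle sampling.** Conventional CCD samples
  one boundary point per fixed angular interval (36 points at 10°) and can
  step over narrow lobes and teeth entirely; the per-point signature cannot.
  The angle-sampled variant is kept as a reference mode
  (`ccd_angle_sampled`).
* **Incircle centre, not area centroid.** The reference point is the centre
  of the largest inscribed circle (arg-max of the Euclidean distance
  transform; ties broken by smallest row then column). The area centroid of
  a crescent-shaped or deeply lobed blade can fall outside the lamina and
  produces spurious signature structure.

Because all magnitude thresholds below are absolute pixel distances, every
silhouette is first standardised to a fixed working scale: longest side
512 px with an 8 px background pad (`standard_size`, `border_pad`).

## Lobes and sinuses

A peak/valley scan with magnitude threshold `delta` walks the cyclic
signature in alternating mode: while seeking a maximum it confirms a peak
at the running maximum once the signal has dropped by `delta`, then flips
to seeking a minimum, and symmetrically. The cyclic seam is handled by
rotating the array to start at its global minimum before the linear scan
and mapping indices back; this removes start/end artefacts and makes the
scan provably equivalent to selecting all local extrema of topological
prominence ≥ `delta` (the test suite checks this against
`scipy.signal.find_peaks` prominences on thousands of random arrays).

The right `delta` depends on lobe depth, so the scan is repeated at the
five magnitude thresholds **{15, 25, 35, 45, 55} px** and the per-threshold
peak and valley counts are consolidated by their **mode** (ties broken by
first occurrence — "first mode"). Extrema positions are taken from the
first threshold whose peak *and* valley counts both match the modes, else
the first matching the peak mode. Lobe count = consolidated peak count,
sinus count = valley count; an unlobed blade legitimately reports zero.

## Apex and base

Rays from the incircle centre to the consolidated local maxima partition
the full turn into vertex angles (law of cosines on the two ray lengths
and the chord, wrap-around vertex included), so the angles sum to 360°.
Min–max normalised angles split the maxima into a **north** and a **south**
region at `thres_norm = 0.5`: a lone tip subtends large angles to its
neighbours while the remaining lobes crowd together. Both maxima flanking
a vertex inherit its region; maxima claimed by both regions stay with the
smaller one. Each region's pole is its **median** maximum (the two middle
maxima when the count is even). The pole's contour segment runs between
its flanking local minima, capped at 25 % of the contour
(`region_cap_fraction`) because the apex region covers roughly a quarter of
the blade.

Robustness guards, needed because real (and synthetic) signatures are
noisier than the idealised picture:

* Fan poles subtending < 120° at the centroid are rejected — apex and base
  face each other; an adjacent-maxima pairing means the fan latched onto
  side bumps. The fallback pairs the strongest maximum with the maximum
  whose centroid ray points farthest away.
* When the consolidated mode exceeds 12 maxima (deep margin teeth leak into
  the 15 px threshold on broad blades), pole finding switches to the maxima
  of the largest threshold that still shows structure: apex and base are
  properties of the gross blade shape.
* With exactly two maxima they are the poles directly; with fewer, the
  signature's global maximum and the point half a contour away serve as
  poles and the region is a fixed 1/8 contour fraction
  (`pole_fallback_fraction`).

**Apex/base disambiguation** uses the mid-vein: the vein is wider where it
met the petiole (base) than at the apical end. Square windows of side equal
to the incircle radius are centred at 1/4 and 3/4 of the pole-to-pole axis;
vein pixels are classified by hue (12-bin discretisation against the
lamina's dominant bin) for colour input or as an intensity ridge below the
lamina median for greyscale; the width is the mean cross-axis run length.
The wider end is the base. If no vein is measurable the pipeline falls back
to "the sharper pole is the apex" and flags the record
(`vein_resolved = False`).

**Tip curvature** is described by the Centroid Contour Gradient (CCG): one
boundary point per interval angle {0, θ, …, 90} (θ = 15° default, must
divide 90) about the tip-region centroid, on the right side of the tip
axis; the descriptor is the absolute chord slope between consecutive
samples. Ray–point matching is nearest-in-polar-angle with a tolerance of
max(1.5°, θ/6) — solving the tangent form directly would be singular at
90°. A vertical chord is capped at `gradient_cap = 1000`, preserving
monotone comparisons. Tips are symmetric, so one side suffices; mirror
equality is verified in the tests.

**Categorical tip labels** come from flank geometry: total-least-squares
lines fitted to the two flanks give the tip angle; the rms fit residual
over chord length gives straightness (`< 0.035` = straight); the signed
bulge of the mid-flank against the tip-to-mouth chord gives convexity
(|bulge| < 0.015 = flat). Rules, in order:

* apex — *cuspidate*: local tip angle < 50° but overall angle > local+40°
  (terminal spike on a blunt shoulder); *truncate*: the tip-width fraction
  (cross-axis width just behind the tip over region width, maximised over
  candidate axes ±30°) exceeds 0.40 (flat cut); straight flanks: < 45°
  *acuminate*, 45–95° *acute*, else *obtuse*; curved flanks: incurved
  *acuminate*, outward arc *rounded*.
* base — *cordate* first (a central dip of ≥ 4 px prominence in centroid
  distance between two humps inside the base region); *oblique* when the
  two flank-to-axis angles differ by > 25°; straight: ≤ 95° *cuneate*,
  else *obtuse*; incurved *attenuate*; arc *rounded*.

## Margin

**Teeth detection.** Re-running the extrema scan at the small threshold
(2 px; 1 px amplifies rasterisation zig-zags) finds teeth together with
lobes and tips, so the large-threshold extrema are subtracted — a small
extremum within 1 % of contour length (`teeth_match_tol`) of a large one
is excluded. When this first pass already shows at least `min_teeth = 4`
teeth, a second pass at half the threshold recovers teeth whose radial
prominence is attenuated on steep flanks (see Limitations); the geometric
height filter below keeps noise out of the vote.

**Tooth measurement.** Teeth are measured on (left valley, peak, right
valley) triples built from adjacent detected peaks. Both extremum
positions are refined geometrically, because signature extrema drift along
the sloped distance baseline: the valley between two peaks is the innermost
point against their chord, and the peak is the outermost point against the
valley–valley chord (centre of the near-maximal plateau, since rounded
teeth tie over many pixels). Measurements per tooth: flank chords A and B;
tooth area (contour segment closed by the valley–valley chord, shoelace);
peak/valley triangle area; tooth height `L_teeth` (peak's perpendicular
distance from the chord); and `L_teeth2midrib`, the chord midpoint's
distance to the midrib axis. The midrib axis is the silhouette's **major
principal axis** — identical to the pole-to-pole line when the poles are
right, and robust on near-round blades where they may not be.

**Taxonomy.** A tooth enters the vote if `0 < L_teeth/L_teeth2midrib ≤ 1/8`
(above 1/8 the excursion is a lobe, not a tooth) and `L_teeth ≥ 2 px`
(shallower than the small threshold is rasterisation noise). Cuts:

* flank asymmetry `|A/B − 1| > 0.2` (`equal_tol`) → type 1 (saw-like):
  *serrate*, or *serrulate* when the majority height-to-midrib ratio is
  below 1/16 (`diminutive_bound`), or *doubly serrate* when the tooth-size
  ratios are bimodal (largest-gap split of well-measured teeth; cluster
  mean ratio ≥ 1.8 = `doubly_ratio`, minor fraction ≥ 0.3);
* equal flanks, triangularity = tooth area / triangle area ≤ 1 → type 2
  (shark-tooth): *dentate* / *denticulate*;
* equal flanks, triangularity > 1 → type 3 (rounded): *crenate* /
  *crenulate*.

Fewer than `min_teeth` valid teeth → **entire**. The **ripples ratio** —
changed-pixel fraction under disk smoothing (opening then closing with an
exact Euclidean disk of radius `incircle_radius/8`, implemented with
distance transforms; the mask is padded past the radius so the closing
cannot touch the frame) — is reported as a margin-roughness feature and is
near zero for smooth blades. It does **not** decide the entire class on
its own: measured on the synthetic conditions, diminutive teeth (4–8 px)
leave the ratio at the same level (0.002–0.005) as a smooth blade with a
sharp apex, because a disk of that radius rides over wide shallow bumps.
The measurable-teeth count separates the cases cleanly.

## Species identification

The per-leaf vector holds lobes, sinuses, valid-tooth count, ripples ratio,
apex/base angles, the two 6-component CCG vectors, and the categorical
apex type, base type and margin class. Matching is 1-NN (configurable k)
under a mixed distance: numeric columns z-scored with training statistics,
Euclidean over the CCG components, plus one unit per categorical mismatch.
Ties resolve to the first-indexed training record. Accuracy is the
fraction of test leaves whose predicted species matches the truth.

## Synthetic leaves

The generator is the ground-truth engine for every benchmark:

* **Lobed blades** (`n_lobes ≥ 1`): polar outline
  `r(φ) = E(φ)·(1 + a·cos(n_lobes(φ − 90°)))/(1 + a)` with an ellipse
  envelope `E`; lobe and sinus counts are exact by construction.
* **Unlobed blades**: a half-width profile `w(u)` along the midrib
  (`u` = 0 base → 1 apex) with a gentle envelope `1 − 0.18(2u−1)²` (no
  parallel-sided stretch — straight sides would put spurious oscillations
  in the signature) and tip caps per type: straight taper (acute/cuneate,
  taper span set by the target flank angle), concave power-2.2 taper
  (acuminate/attenuate), elliptical cap (rounded), flat cut (truncate),
  arc-plus-spike (cuspidate), asymmetric spans (oblique), and a carved
  triangular notch (cordate).
* **Teeth**: waveform displacement of the smooth outline — saw (asymmetric
  0.75/0.25 ramp, type 1), triangular^1.35 (slightly concave, type 2),
  |sin|^0.6 (fat-topped, type 3). On unlobed blades the displacement is
  along the outward normal with amplitude `teeth_amplitude ×` local midrib
  distance, so `teeth_amplitude` directly targets the ratio that separates
  diminutive (0.045) from regular (0.095) teeth around the 1/16 boundary.
  On lobed blades teeth are radial with constant amplitude. Doubly-serrate
  margins alternate full and 0.45× amplitudes.
* **Petiole** (thin basal rectangle), **mid-vein stripe** (distinct hue /
  darker intensity, half-width tapering 4.5 → 1.2 px base to apex), free
  rotation, and overall scale complete the image; polygons are rasterised
  with Pillow scanline fill on a white background.

Dataset generation draws per-species base morphologies from a fixed
palette (mixes of lobe counts, margin classes, tip types, elongations) and
jitters rotation (uniform), elongation/scale (±3 %), amplitudes (±5 %) and
tooth counts (±2) per sample, all from a single seed.

### Benchmark populations and their rationale

* Lobe recovery: k ∈ 3..9, amplitude 0.32 (lobe depth well above the
  largest threshold), 12 rotations each.
* Margin recovery: all eight classes × 50, elongation 1.15–1.35, mixed
  acute/rounded apexes and cuneate/rounded bases, random rotations, tooth
  counts 26–40. Broad blades are the envelope in which a margin is
  geometrically visible to a radial signature (below).
* Apex recovery: acuminate (26–40°), acute (52–85°), rounded × 100,
  elongation 1.5–2.0 (tip shape needs an elongated blade to be meaningful),
  random rotations and base types.
* End-to-end: 10 species × 8 samples, 2/3–1/3 split, 1-NN.

## What the synthetic benchmarks do and do not show

The generator produces clean silhouettes on uniform backgrounds with exact
waveform margins and a synthetic two-colour vein. Passing benchmarks
demonstrate that the geometry pipeline implements the intended definitions
and is rotation/scale robust — not that field photographs of real leaves
would be classified at the same rates: real images add segmentation error,
petioles, damage, venation texture, asymmetry, and margin irregularity that
no waveform models. Dataset-level accuracies on herbarium collections are
out of scope here.

## Known limitations

* **Radial attenuation of teeth.** A tooth displaced along the margin
  normal appears in the centroid-distance signal with amplitude reduced by
  the cosine between the normal and the centroid ray, and superimposed on
  the lobe/taper baseline slope; on strongly elongated, steep-flanked
  blades (both tips wedge-shaped) diminutive teeth fall below the small
  threshold and the margin reads entire. The two-pass detection recovers
  moderate cases; the steep-flank corner is a genuine limit of the method.
* Teeth on deep lobes are invisible for the same reason whenever the lobe
  flank is steeper than the tooth flanks.
* The colour vein model (hue-coherence classification) is a simple stand-in
  for real venation; leaves whose vein hue matches the lamina fall back to
  the sharper-pole heuristic.
* Apex/base labels assume a single dominant tip per region; compound
  leaves and multi-tip apices are out of scope.
* `obtuse`/`truncate`/`cuspidate` apexes and `oblique` bases are
  operationalised from verbal botanical descriptions; their thresholds
  (straightness 0.035, convexity 0.015, tip-width 0.40, asymmetry 25°) are
  exposed in code and were set from the generator's geometry.
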