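# Methods

`coronalstack` reconstructs and quantifies serial coronal brain sections
from multi-channel slide scans.  The pipeline assumes the standard
floating-section workflow: a brain cut at 40 µm on a cryostat, the
sections distributed round-robin into `k` anteroposterior (AP) ordered
series, so that slices within one series are equidistant
(`40 µm × k`; 0.32 mm for the default 8 series).  Mounting scrambles the
within-series order and places each section on the slide with an
arbitrary small rotation and offset; the pipeline recovers order and
alignment and then performs Cavalieri-style volumetry and cell-level
quantification.

## Anteroposterior sorting by contour area

Across the window from bregma +2.5 mm to −1.0 mm the cross-sectional
area of the mouse brain grows monotonically toward posterior, so the
section area is a sorting key that requires no atlas.  Two details make
the key robust:

* **Masking.** The DAPI channel is blurred (Gaussian, σ = 3 px) and
  binarized at a single threshold (explicit, or Otsu when `auto`); the
  blur homogenizes nuclear texture so one cut selects the whole slice.
* **Hole bridging.** A focal lesion removes tissue, which would shrink a
  naive foreground count on injured slices and scramble the order.  The
  sorting key is therefore the *filled outer contour*: the largest
  connected component is closed with a disc (default radius 150 µm,
  converted to pixels by the calibration — enough to bridge defects that
  clip the tissue edge) and all interior holes are filled.  An interior
  cavity of any size then leaves the key unchanged (hole-invariance).

Slices are ranked by ascending contour area (anterior = smallest).  The
monotone-growth assumption fails caudal to bregma −2.0 mm; a stack whose
calibration implies slices beyond that bound gets an explicit warning
and its caudal ordering should not be trusted.  The accuracy metric used
throughout is *exact-rank accuracy* — the fraction of slices placed at
their true AP rank — the strictest common choice.

## Line-based registration

Each slice carries one reference segment (the anatomical midline, drawn
dorsal-to-ventral; ground-truth lines in the synthetic data).  Two point
correspondences determine exactly the four degrees of freedom of a 2D
similarity, fitted in closed form in complex coordinates
(`w = a·z + b`, `a = (q1−q0)/(p1−p0)`).  Slices are resampled into the
reference frame with bilinear interpolation (out-of-frame pixels 0).
Because all series of one brain are cut from the same blockface, the
transforms estimated on the DAPI series are applied unchanged to the
Iba1/IgG/WFA series — the multiplexing contract that lets markers from
different series be combined per slice.

Elastic and polynomial warps are deliberately excluded: on injured
tissue they hallucinate structure around the cavity.  A single line can
at most determine a similarity; a degree-2 polynomial warp would need at
least six correspondences, so no such warp is offered.  The CLI aligns
to an upright, centred copy of the reference line so that the output
frame is rotation-free (and exported ROI rectangles stay axis-aligned);
the library accepts any reference line, e.g. the middle slice of the
sorted stack.

## Volumetry (Cavalieri with a fitted profile)

Per slice, three areas are measured:

* **Injury**: filled outer contour minus the actual tissue foreground —
  exactly the cavity the contour bridges (clamped at 0 on intact
  slices).
* **Iba1 / IgG**: Gaussian blur (σ = 5 px), one intensity threshold,
  8-connected components, components < 1000 px discarded as speckle
  (the printed particle filter; the equivalent µm² depends on the pixel
  size, which the scan metadata provides).

Thresholds are explicit parameters; `auto` anchors the cut to the
healthy hemisphere: the threshold is the midpoint between the
contralateral 99.9th-percentile ceiling and the ipsilateral
99.9th-percentile signal, with a central midline band (5% of the width
on each side) excluded from both so blur spillover cannot contaminate
the reference.  A plain Otsu on the contralateral half is *not* used
because a healthy hemisphere is unimodal there and Otsu would split
noise.  On a slice without pathological signal the two levels coincide
and nothing is segmented.

Slices are placed on the bregma axis by
`bregma(rank) = anchor − rank × spacing`, giving an area profile
`A(x)`.  The volume is `V = ∫ A(x) dx` of a least-squares polynomial
fit (default degree 3, configurable 1–6; low order suits the unimodal
profiles of focal lesions without oscillation).  Three policies the
formula leaves open are fixed as follows:

* **Bounds** (`auto`): from the first to the last slice with positive
  area, padded by half the median slice spacing — the marker's support.
* **Fit support**: only profile points inside the bounds inform the
  fit; distant all-zero slices carry no shape information a low-order
  polynomial could honor and would only bias it.
* **Negative clipping**: where the fitted polynomial is negative it
  contributes zero (area is physically non-negative; unclipped tails
  bias volumes downward).  Implemented exactly, by splitting the
  integration interval at the polynomial's real roots.

For noiseless polynomial profiles of degree ≤ the fit degree this
machinery is exact to ~1e-12 relative (the quadrature oracle in the
tests).  With the default geometry a drill lesion sampled at 0.32 mm is
recovered within ~0.1%.

## Perineuronal-net quantification

The perilesional band (PL) is the tissue within `band_width_mm`
(default 0.5 mm — the one free parameter of the PL definition, always
reported in output) of the lesion boundary; intersecting it with the
segmented Iba1 area yields the inflamed (Iba1+) and non-inflamed
(Iba1−) PL.  WFA+ cells are counted in rectangular ROIs of each class
and in their mirror images across the midline (the registration line is
the only midline the pipeline possesses, so it defines the mirror).

Detection per ROI pair: one shared threshold taken by Otsu's method on
the *contralateral* rectangle (bimodal: somata vs background; sharing
the cut keeps the comparison intensity-calibrated and invariant to a
global rescale), then a binary watershed seeded at distance-transform
maxima separates touching somata before the particle filter
(≥ 200 px at ~2 µm/px; scale the filter with the pixel area).  The
declumping step matters: without it, independently placed somata at
realistic density merge preferentially on the denser contralateral
side and inflate the ipsilateral fold change by ~50%.  Cell intensities
are measured on the raw, unblurred image.

Per slice and class the fold change is `n_ipsi / n_contra` (undefined
and excluded, with a warning, when the contralateral count is zero).
Classes are compared with a paired t-test over slices (slices are the
statistical N; difference taken as Iba1+ − Iba1−).  Zero-variance
difference sets are flagged rather than assigned a statistic.

## Synthetic data: what it emulates, and what it does not

The generator (`synthdata`) renders per-slice, per-channel 8-bit images
from analytic geometry so every downstream measurement can be scored
against exact ground truth:

* **Silhouette**: ellipse of fixed aspect 1.6 (width:height), area
  interpolated logarithmically from `area_start_mm2` (anterior) to
  `area_end_mm2` (posterior), plus optional Gaussian area noise.
  Defaults 14→26 mm² over 11 slices anchored at bregma +2.5.
* **Lesion**: a circular hole of the 2.1 mm drill diameter, centred
  1.5 mm lateral, carved into every slice within a contiguous AP extent
  (default 1.6 mm centred at bregma +0.94); cross-section constant
  π·(1.05)² ≈ 3.464 mm², so the lesion solid is a cylinder with exact
  volume.  The extent edges are deliberately offset from the slice
  sampling grid at 0.32/0.16/0.08 mm spacings, so support estimation is
  unbiased at every refinement level.
* **Iba1 halo**: ventral half-annulus of width 0.5 mm around the hole
  (an asymmetric inflammatory rim, leaving a genuinely Iba1− PL);
  **IgG cloud**: a slightly larger, laterally shifted disc minus the
  hole — overlapping but not identical to the halo.  Both exist only on
  lesioned slices, so marker mass is confined to the lesion's AP extent.
* **WFA+ cells**: a Poisson point process at `wfa_density_per_mm2`
  (default 120/mm², a plausible cortical density for 40 µm projected
  sections) everywhere in tissue, thinned to `wfa_retention_iba1pos`
  (default 0.2, i.e. an ~80% reduction) inside the Iba1+ halo.  Cells
  are flat-core discs of radius 18 µm with a Gaussian edge roll-off, so
  any mid-range threshold recovers ≈ π r² pixels per cell.
* **Placement jitter**: each slice is drawn with a small random rigid
  offset (σ = 2°, 100 µm) shared by all channels; the jittered midline
  endpoints are recorded as the ground-truth reference lines.
* **Intensity model**: background 25, flat tissue baselines, marker
  levels 160–200, additive Gaussian read noise (σ = 5, settable to 0
  for noise-free discretization studies).  No optics PSF, no nuclear
  texture, no section tears or folds.

Because the silhouettes are smooth ellipses and the noise is purely
additive and Gaussian, passing tests demonstrate the *algorithmic*
correctness and calibration of the pipeline — order recovery, exactness
of the similarity fit, unbiasedness of the volumetric integration,
statistical calibration of the fold-change test — not robustness to
histology artifacts (folds, tears, debris, uneven staining), which real
deployments must still check manually (broken slices warrant manual
review; the sorter warns on ties and caudal stacks for the same
reason).

`simulate_roi_patches` renders only the ROI rectangles (same cell and
noise model) so that statistical calibration experiments can run over
hundreds of simulated brains; the null-effect type-I rate of the paired
test, estimated over 200 such brains of 12 slices, stays at the nominal
5% (tested bound: ≤ 7%, allowing Monte-Carlo error).

## Problem sizes used in the test suite

Chosen so results are statistically decisive at desk scale: sorting
accuracy over 20 stacks × 30 slices at 20 µm/px; registration and
masking on 6–11-slice brains at 8 µm/px; volumetry refinement at
0.32/0.16/0.08 mm spacing (11/22/44 slices); PNN effect recovery over
8 rendered brains × 12 slices at 4 µm/px with the particle filter
scaled to the pixel area (50 px ≈ 800 µm²); type-I calibration over
200 patch-level brains.

## Known limitations

* Sorting assumes monotone area growth: valid only anterior to bregma
  −2.0 mm, and only as accurate as the area measurement is relative to
  the inter-slice area increment.
* One line per slice caps registration at a similarity; residual
  non-rigid tissue distortion is not corrected (by design).
* The volume estimator inherits the polynomial's bias for profiles it
  cannot represent; degree and bounds are configurable per marker.
* Fold changes from small ROI counts carry the ratio bias
  `E[n_i/n_c] ≈ (λ_i/λ_c)(1 + 1/λ_c)`; keep expected contralateral
  counts ≳ 25 per ROI (larger rectangles or higher density) for ≲ 5%
  bias.
* The ROI rectangles of the synthetic protocol are fixed in the
  canonical frame; real use supplies manually drawn rectangles per
  slice.
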