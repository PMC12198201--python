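# Methods

`vmoquant` quantifies fluorescence micrographs of vascularized micro-organ
(VMO) and micro-tumor (VMT) microfluidic devices: self-assembled perfused
capillary networks imaged alongside tumor spheroids, with dextran time-lapse
series for transport measurements.  This note records the models, the
parameter choices, the numerical conventions, and what the synthetic test
scenes do and do not establish about real data.

## Segmentation

Grayscale images are binarized by **iterative minimum cross-entropy
thresholding** (Li's method).  For a threshold t splitting the histogram into
classes with means μ₀ (below) and μ₁ (at or above), the objective

    η(t) = − Σ_{g<t} h(g)·g·log μ₀ − Σ_{g≥t} h(g)·g·log μ₁

is minimized by iterating t ← (μ₀ − μ₁)/(log μ₀ − log μ₁) from the image
mean until the update moves less than 0.25 gray levels.  Gray values are
shifted by +1 before taking logs so zero-intensity bins are admissible; the
returned threshold is on the original scale.  Because the continuous fixed
point can fall between discrete gray levels on strongly overlapping
histograms, the result is polished against candidate thresholds within ±2.5
gray levels and the criterion minimizer among them is returned.  Ties at the
threshold are foreground (`intensity ≥ t`).  Constant images raise a
degenerate-input error: there is nothing to separate.

Mask cleanup uses 8-connected foreground and 4-connected background
(topological duals) throughout:

* **fill_holes(max_hole_area)** — background components not touching the
  border with area ≤ the limit become foreground (default 50 px).
* **remove_small(min_area)** — 8-connected components below the minimum are
  dropped; area exactly at the minimum is retained (default 10 px).
* **edm_prune(r)** — opening through the Euclidean distance map: the core
  `EDT ≥ r` is dilated by the *open* digital disk {d < r}.  This equals
  classical opening with that footprint (erosion by {d < r} keeps exactly
  the pixels with EDT ≥ r) and removes protrusions narrower than `2r − 1`
  pixels.  Default r = 3, so 5-px vessels survive when axis-aligned.
  **Limitation:** an oblique 5-px tube has centerline EDT √8 < 3 and is
  erased — structures at or below `2r − 1` px are at the resolution limit of
  the cleaning step, and the minimum reliably preserved width is 7 px at
  arbitrary orientation.

Externally produced masks (e.g. from a trained pixel classifier) are
ingested from any two-valued TIFF; nonzero is foreground.

## Vessel morphometry

The pipeline is clean → skeletonize → junctions → branches → diameters:

1. **Skeletonization** uses topology-preserving 2D thinning
   (`skimage.morphology.skeletonize`) to a unit-width, 8-connected
   centerline.
2. **Branch points** are classified by the **crossing number** — the count
   of cyclic 0→1 transitions around a pixel's 8-neighborhood, i.e. the
   number of line directions leaving it.  A pixel is a junction candidate at
   crossing number ≥ 3 and an endpoint at exactly 1.  Raw neighbor counting
   misfires here: a staircase pixel of an oblique line touches three
   neighbors while carrying only two directions.
3. **Twig pruning.**  Thinning forks the centerline at tube end caps and
   inside the blob where wide tubes meet.  Terminal twigs adjacent to a
   branch point are deleted when their length is below the maximum local
   diameter along them (they fit inside the structure that spawned them);
   this repeats until stable.
4. **Junction clusters.**  Junction pixels within the merge distance
   (default 10 px) are merged by single linkage; the cluster count is the
   reported junction number, so a spread confluence counts once.  Clusters
   grow to adjacent ≥ 3-neighbor pixels so that removing them genuinely
   disconnects the arms.  Increasing the merge distance can only decrease
   the junction count.
5. **Branches** are the 8-connected components left after removing cluster
   members; length sums 1 per orthogonal and √2 per diagonal step.
   Fragments with both ends on the same cluster and length below the local
   diameter are junction-internal and discarded.  Branches whose mean
   intensity along the centerline (on the raw grayscale image) falls below
   the branch-mean threshold (default 50) are dropped; pre- and post-filter
   counts are both reported.
6. **Diameters.**  Local diameter at a centerline pixel is `2·EDT − 1`,
   which recovers odd drawn widths exactly on axis-aligned tubes (an 11-px
   bar has centerline EDT 6).  The distance map inflates at confluences, so
   samples within `max(merge distance, branch median diameter)` of a
   junction centroid are excluded from the branch mean; a branch entirely
   inside that zone falls back to its median.  The per-image mean diameter
   is the length-weighted mean over retained branches.

Area is the foreground pixel count; perimeter uses the corner-corrected
weighted boundary estimator (raw pixel-edge counting overestimates a disk's
perimeter by up to 8/π, which would break the circularity cap below).

## Tumor morphometry

Shape descriptors follow the host image-analysis environment's conventions:
circularity `4πA/P²` (capped at 1), roundness `4A/(π·major_axis²)` with the
major axis from the fitted ellipse, solidity `A / convex hull area`.
Multi-component masks — spheroids dispersing over time — aggregate area,
perimeter and hull over the union and take axes from the largest component.
Gray statistics (mean, modal, minimum, population SD) are computed over the
mask or the whole image; modal ties resolve to the smaller intensity.  Both
the whole-image mean gray and the mask-integrated density (mean × area) are
emitted, since "total fluorescence" is used in both senses in practice.
Longitudinal series are normalized by their baseline timepoint; a zero
baseline is an error rather than a silent NaN.

## Permeability and perfusion

The permeability coefficient uses the two-point extravasation model

    PD = 1/(I_i − I_b) · (I_f − I_i)/Δt · Vol/SA,      Vol/SA ≈ d/4

with I_i/I_f the initial/final mean intensity of an extravascular ROI
(disk, default radius 25 px), I_b a single background ROI, Δt the elapsed
time between first and last frame (default series length 3), and d the mean
vessel diameter — taken from the vessel morphometry of the same device when
available.  PD is reported in µm/s when d is in µm.  The intensity ratio is
dimensionless, so uniform offsets and gains cancel; this is asserted as a
property test.  Frames may optionally be aligned by integer-pixel phase
correlation (off by default; enable per series when the stage drifts).

Perfusion is quantified by reference-mask subtraction: leak at timepoint t
is `mask_t AND NOT mask_ref`, reported as area and mean intensity, with a
composite score defined as final leak area divided by reference vascular
area.  That ratio is one reading of a "composite perfusion score" and is
labelled as such in the result object; an empty reference leaves the
composite undefined while leak areas are still reported.

## Contour export

Vessel outlines are traced at the 0.5 iso-level with sub-pixel positions;
each 8-connected component gives one outer contour plus one per interior
hole, distinguished by orientation.  Smoothing resamples the closed curve to
N points (next power of two, ≥ 64) equally spaced in arc length, takes the
FFT of x + iy, keeps the ⌈keep%·N/100⌉ lowest frequencies symmetrically
about frequency 0, and inverts.  Frequency 0 is always kept, so the centroid
is exact; keep = 100 reproduces the resampled contour; orientation (signed
area) is preserved.  Output is minimal ASCII DXF — closed LWPOLYLINE
entities on `vessels`/`holes` layers with an $INSUNITS header — written and
reparsed by this package (the reader is a generic group-code parser, not
tied to the writer's layout).  Image y (downward) flips to CAD y (upward)
only at export.

## Synthetic scenes

The generators draw what the pipeline is meant to measure, with the drawn
geometry as machine-readable truth:

* **Vessel scenes** rasterize straight tubes by distance-to-segment with
  0.5-px anti-aliasing; the truth mask binarizes at `dist ≤ width/2`, making
  odd drawn widths exact.  Foreground/dim/background means default to
  200/35/12 on 8-bit with Gaussian noise σ = 4 — roughly the contrast of a
  well-exposed fluorescence channel.  Junction/endpoint/branch truth comes
  from an analytic construction over the segment list, cross-checked in the
  tests against an independent shapely/networkx noding of the same segments.
  Random trees are trivalent with 55–85 px arms, ≥ 55° between siblings and
  clearance checks between unrelated tubes, so the skeleton topology equals
  the drawn graph; widths draw from odd values 7–25 px (5 px sits at the
  cleaning resolution limit at oblique angles, see above).
* **Tumor scenes** place disks at a common center (compact) or scattered
  within a dispersal radius; aggregate solidity decreases with dispersal,
  emulating a spheroid dispersing under migration.
* **Leak movies** hold vessels at constant intensity and grow an
  extravascular halo linearly so that the two-point formula applied to
  noiseless ROI means returns the programmed PD exactly; ROI centers are
  chosen with the full disk inside the halo and the background ROI beyond
  it.  Frames stay floating point so the inversion is exact to 1e-9.

What these scenes do **not** model: point-spread blur, uneven illumination,
depth-dependent intensity, autofluorescence, curved or tapering vessels, and
tumor-vessel overlap.  Passing the recovery tests therefore demonstrates the
correctness of the measurement chain on ideal geometry at realistic contrast
and noise, not segmentation performance on difficult real micrographs —
which is why externally produced classifier masks can be substituted at
every stage that consumes a mask.

## Defaults and sizes

All stage defaults are the reference values used throughout: hole fill
50 px, minimum vessel area 10 px, branch mean intensity 50, junction merge
distance 10 px, EDM cleaning radius 3 px, ROI radius 25 px, series length 3.
Test scenes are 256² (motifs, batch devices) or 512² (random trees); the
batch workflow test and acceptance stage process 300 simulated vessel/tumor
pairs, matching the scale the tool is expected to handle in one session.
CSV floats are formatted at 6 significant digits so repeated runs are
byte-identical.
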