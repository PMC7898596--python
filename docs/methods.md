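# Methods

## Scope and model

`fibremetrics` quantifies the pattern of fibrillar networks in 2-D images.
The underlying model is that matrix fibres are *ridges*: curvilinear
intensity maxima of roughly known width, bright on a dark background after
polarity normalisation. Everything downstream — counts, lengths,
curvature, gaps — derives from the centreline network extracted under that
model, except HDM and alignment, which are computed from the grayscale
image itself. The pipeline is strictly 2-D: fibres from different focal
planes in a projection will be read as crossing, which inflates branch
points (consistent sectioning thickness matters more than its exact value).

## Pre-processing

Images are converted to luminance grayscale on the 8-bit scale, inverted if
fibres are dark-on-light (`dark_lines`), and contrast-stretched by clipping
`contrast_saturation_pct` of pixels (half per histogram tail) and mapping
the rest affinely onto [0, 255]. A constant image passes through with a
warning. **HDM** (high-density matrix) is the fraction of pixels at or
above `hdm_threshold` (default 185 on the post-saturation scale; `None`
selects Otsu) — an abundance measure independent of fibre tracing.

For brightfield histochemistry with a counterstain, optional colour
deconvolution (Ruifrok–Johnston) unmixes stains in optical-density space,
OD = −log10((I+1)/256); the +1 avoids log 0 and puts pure white at exactly
OD 0. Stain vectors are estimated as unit mean-OD vectors of three
user-chosen ROIs (matrix stain / counterstain / background). When
deconvolution is requested the matrix channel is analysed, and HDM is then
computed on that channel — the alternative (HDM before unmixing) would
count counterstained nuclei as matrix. Deconvolution is never automatic.

## Ridge detection

For line width *w* the detector uses Gaussian derivative scale
σ = w/(2√3) + 0.5, the scale at which a bar of width *w* maximises its
centre second-derivative response. Per pixel, the Hessian of the smoothed
image is eigen-decomposed; the eigenvector of the most negative eigenvalue
λ points across the line, and a second-order Taylor step t = −(∇f·n)/λ
locates the profile extremum. A pixel is a ridge point when λ < 0 and the
extremum lies within 0.6 px per axis (0.6 rather than 0.5 keeps
shallow-angle lines connected where the centreline passes exactly between
rows). The response −λσ² is scale-normalised so sweeps over widths are
comparable, with an absolute floor of 0.5 intensity units that suppresses
the residual bias of discretised derivative kernels on flat regions.

Hysteresis keeps ridge points above a low threshold that connect to a seed
above a high threshold. The thresholds default to fixed fractions of the
image's peak response (high 0.25, low 0.06), which adapts to overall
contrast without user input; absolute values can be given
(`contrast_high` / `contrast_low`) when cross-image comparability of the
detection threshold itself matters — e.g. when the same parameter file
must resolve the same physical fibres at two resolutions. Percentile-based
defaults were rejected: on clean images the response along a line is nearly
uniform, so any percentile of it lands inside the line population and
fragments fibres.

Where lines cross, the single-line model breaks down (both eigenvalues go
negative, the Taylor step is undefined), leaving a hole at the crossing
core. Two repairs keep arms connected: 2-D maxima (both eigenvalues
negative) adjacent to accepted line points are added to the mask, and a
morphological closing with a disk of radius ≈ σ bridges the remaining core
plateau. Pinholes below 16 px² are filled so they do not skeletonise into
micro-loops; real matrix gaps are orders of magnitude larger.

The mask is thinned to a one-pixel skeleton and traced: skeleton pixels
with ≥ 3 neighbours form junction clusters (one junction per 8-connected
cluster, so a 4-way crossing is a single branch point); maximal chains
between them become fibres, with vertex positions refined by the subpixel
offsets (accepted up to 1 px for localisation, so skeleton pixels one off
the centreline still project onto it) and a 3-point moving average that
damps the pixel-lattice zigzag (termini fixed). On noise-free synthetic
fibres this yields centreline RMSE ≈ 0.1 px and length recovery within a
few per cent, the residual being genuine response extension of ~σ beyond
the fibre end caps.

Pruning removes terminal branches shorter than `min_branch_px`
(free-ended, or degenerate self-loops on one junction), then dissolves
junctions left with two attachments by gluing the two fibres into one
through-fibre, iterating to a fixed point. A useful rule of thumb is
`min_branch_px ≈ 2.5 ×` line width, since spurious "fishtail" branches at
fibre ends scale with σ.

Widths sweep from `line_width_min_px` in increments of 5, with the maximum
force-included; the amalgamated mask is the pixel-wise union of per-width
rasterised masks (exactly — no re-thinning). Per-fibre metrics are always
computed on a single width's network (the minimum width by default), never
on the amalgam, whose overlaps would corrupt counts; the amalgam feeds the
global pattern metrics and is written as an output for visual checking.

## Per-fibre metrics

End points are termini not within 1.5 px of a junction (subpixel linking
can leave sub-pixel gaps, so attachment is tolerance-based); closed loops
contribute none. Branch points are junction loci. Total length is the sum
of polyline arc lengths, in µm when `pixel_size_um` is set. The HGU is
returned as L/E — length per fibre tip, the classical hyphal-growth-unit
convention — which makes the normalised end-point metric E/L literally its
inverse; the reciprocal convention is available via an argument. Average
fibre length is L/(0.5(E+B)), on the convention that one fibre begins at
each branch. Fibre thickness is HDM area / L.

Curvature resamples each fibre at arc-length steps of the window and
averages the absolute turning angle over all chord pairs, pooled across
fibres (long fibres weigh more; a per-fibre mean is available). Fibres
shorter than two windows contribute nothing; if none is long enough the
value is missing, not zero. On a circle of radius r the value is w/r ≈
2 arcsin(w/2r) — the chord closed form — and small windows sense fine
waviness while large windows sense coarse bends, so a window sweep
(`curvature_window_min/max/step`, step default 10 px) characterises
curvature across scales.

Normalisations: norm_endpoints = E/L, norm_branchpoints = B/L,
norm_length = L per 1000 px² of image (the scale, chosen for readable
magnitudes, is stated in the CSV header). These remove the strong
dependence of the raw counts on pixel resolution and should be used for
any cross-study comparison.

## Global pattern metrics

**Alignment** is the coherency a = (λmax − λmin)/(λmax + λmin) of the
gradient structure tensor, computed from Gaussian-derivative gradients
(σ = 1 px) with a weighting window normalised to integrate to 1 — uniform
over the full field of view by default, since the score is meant as a
single global value; a centred Gaussian window is available. A blank image
(λmax + λmin = 0) is defined as 0. Alignment is computed on the grayscale
image, not the mask, so it does not depend on detection settings; a
mask-based value can be obtained by passing the mask.

**Fractal dimension** is the box-counting dimension: occupied-box counts
at dyadic box sides 2, 4, …, extent/4, least-squares slope of log N(ε) vs
log(1/ε). The grid is anchored at the corner of the foreground bounding
box, which makes the value exactly translation-invariant (anchoring at the
image origin makes it depend on where the pattern sits in the canvas, by
up to ~0.1). A full plane scores 2, an ideal line 1; fibre masks land in
between. Patterns too small to span two dyadic scales give a missing
value.

**Lacunarity** uses the gliding-box scheme on the binary mask (per-box
mass = foreground count; a grayscale mode exists): windows of each dyadic
size slide at stride size/2, and Λ(size) = |s²/μ² − 1| from the mass
moments, averaged over sizes. Note that this printed form assigns Λ = 1 to
a perfectly uniform pattern (s = 0) and Λ = 0 when s = μ, inverting the
conventional gliding-box ordering at the low end; it is implemented
exactly as stated, and the conventional 1 + s²/μ² variant is available via
`convention="plus_one"`. Users comparing absolute lacunarity values across
tools must check which convention the other tool uses.

**Gap analysis** fits maximal inscribed circles into mask background:
repeatedly take the Euclidean distance transform of free space (fibres,
already-placed circles and — by default — the image border are obstacles),
place a circle at the global maximum with that radius, rasterise it into
the obstacle set (radius rounded up, so placed circles never overlap), and
stop when the diameter would fall below `min_gap_diameter_px`. Ties break
to the smallest (row, col), making output deterministic. Treating the
border as an obstacle avoids overstating gaps truncated by the field of
view; a flag disables it for tiled imagery. All circle sizes are written
per image so downstream analysis can use means, distribution shape or
tails.

## Synthetic data

The generator renders anti-aliased fibres (4×4 supersampled coverage of a
distance-to-centreline test, so "width" is exact to the sub-pixel),
straight, sine or arc waveforms, aligned (Gaussian orientation jitter,
default 5°) or isotropic (uniform) orientation fields, against a constant
background (default levels 10/200). Ground truth — centreline polylines,
orientations, end-point counts, crossing loci (via exact segment
intersection), total length — is returned with every scene, and everything
is deterministic in the seed.

Acquisition degradations mirror common robustness probes: Gaussian blur of
2–3 px radius, additive Gaussian noise of σ = 25 on the 8-bit scale
(seeded), block-average downsampling, and under-exposure (intensity
scaling).

One special generator, `render_cross_hierarchy`, emulates the fact that
real matrix images reveal proportionally more fine structure at higher
pixel counts: level k holds 4^k X-shaped fibre crossings of physical
length ∝ 2⁻ᵏ, the finest level drawn at half width so it falls below the
detector's resolvable width when the scene is rendered at half resolution.
Under this self-similar population, raw E, B and L scale roughly with
pixel area between a 1024² and a 2048² render while E/L, B/L and L/area
agree within ~7% — which is why the normalised metrics, not the raw
counts, are comparable across resolutions.

What the synthetic scenes do *not* emulate: uneven illumination, stain
variability, out-of-focus haze, fibre width variation along a fibre, and
true 3-D projection overlap. Passing tests therefore demonstrate the
correctness of the measurement chain on images satisfying the ridge model,
not robustness to every acquisition pathology; the degradation modes cover
the first-order deviations only.

## Batch driver and determinism

A run is controlled by a flat `key = value` parameter file (unknown keys
warn, absent keys take documented defaults, CLI flags override), which is
archived verbatim into the output directory so any run can be reproduced
from its own artefacts. Eligibility prechecks are non-interactive: images
must be readable, ≥ 16 px in each dimension and non-constant; failures are
logged and the batch continues. Outputs per image: mask(s) (per width +
amalgam when sweeping), the HDM-thresholded image, optionally the gap CSV;
per batch: one summary CSV sorted by filename (floats rounded to
6 significant digits at write time, so repeat runs are byte-identical) and
a log. Existing outputs are versioned (`summary.csv.1`, …), never
clobbered. Missing values are empty cells, never zeros.

## Problem sizes used in validation

The test suite validates on scenes chosen to run comfortably on one CPU:
384² scenes of four well-separated fibres for detector recovery (widths
3–8), 256² scenes of 10–30 fibres for alignment separation, 243²
depth-5 Sierpinski carpets and 512² planes/lines for the fractal scale,
96²–256² masks for gap analysis, and one 1024²-vs-2048² pair for the
resolution-invariance check. Larger images raise cost roughly linearly in
pixel count (the detector is a fixed number of separable convolutions plus
a skeleton trace); a 2048² image takes on the order of half a minute
end-to-end.

## Known limitations

* Wide fibres analysed at a small line width produce double edge responses
  rather than one centreline; choose widths spanning the real fibre
  thicknesses, and prefer a fixed width (or fixed range) across a study.
* Curvature from detected networks is noisier than the other metrics —
  junctions fragment fibres, and short segments drop out of large windows;
  report several windows rather than one.
* Branch-point counts on projections of thick sections include plane
  crossings; compare only images of consistent section thickness.
* The alignment score is global; it cannot describe alignment that varies
  across the field of view or between length scales.
* Absolute metric values depend on detection parameters; only values
  produced with the same parameter file are directly comparable.
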