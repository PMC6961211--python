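# Methods

## Model and assumptions

The package quantifies mitophagy from a two-channel image of a tandem
mCherry–GFP reporter. The underlying optical model is that both fluorophores
report the same reporter density outside lysosomes, so the mCherry/GFP ratio
is ≈ 1 there regardless of expression level, while lysosomal pH quenches GFP
and raises the ratio inside mitolysosomes. Three assumptions follow:

- within one experiment, acquisition settings are constant, so ratio
  contrast is comparable between images;
- neither channel is saturated or strongly bleached (the CLI warns when the
  red or green maximum sits at a typical detector ceiling, or when the mean
  red intensity is indistinguishable from the background level — both
  conditions bias the adaptive red threshold);
- analysis is 2-D: a single plane (or one frame of a time series; extra axes
  of a hyperstack are reduced to their first plane with a warning).

## Detection procedure and its numerical choices

**Median filter.** Circular kernel of offsets with dx² + dy² ≤ r² + 1 (the
ImageJ rank-filter convention: r = 1 is the full 3 × 3 square, r = 2 has 21
pixels), borders handled by edge replication, r = 0 meaning "no filtering".
Radius is a pixel-unit float; the default r = 1 suits critically sampled
widefield data, larger radii suit oversampled or noisy confocal data.

**Ratio image.** Smoothed red over smoothed green. Division by zero must not
produce non-finite values (the prominence search needs an ordered raster), so
pixels where both channels are 0 get ratio 0, and pixels where only green is
0 get a sentinel equal to the image's maximum finite ratio plus twice the
prominence — large enough to always register as maximal, finite enough to
keep every comparison defined. Sentinels matter only in pathological images
(the adaptive red gate removes dark zero-green pixels anyway).

**Peak acceptance (prominence).** The ratio threshold t is interpreted as
topographic prominence ("noise tolerance"), not an absolute cutoff: working
values (0.4–0.6) lie below the baseline ratio of 1 and only make sense as a
relative drop. The semantics are made fully deterministic:

- candidates are 8-connected plateaus of equal value with no strictly
  greater neighbour; each plateau counts once and is represented by its
  pixel with smallest (y, x);
- a candidate of height v is accepted iff its connected component within the
  sub-level set {ratio ≥ v − t} contains no pixel above v and no other
  equal-height candidate with a lexicographically smaller representative
  (equal twin peaks joined above v − t merge into one reported maximum; the
  drop must strictly exceed t to separate them);
- a constant raster has no maxima; otherwise the global maximum is always
  reported. Border pixels are eligible.

The implementation is a union-find pass over pixels in descending value
order (O(N α) after an O(N log N) sort), JIT-compiled with numba when
available, with an identical pure-Python fallback. The test suite checks it
for exact plateau-set equality against an independent brute-force oracle
that enumerates candidate plateaus and labels sub-level sets.

**Red-intensity gate.** mean + k·std of the *smoothed* red channel over the
*whole* image (population standard deviation, divide-by-N), so the threshold
and the peak intensities live in the same smoothed domain. k defaults to 0;
negative k loosens, positive k tightens. Because mean and standard deviation
are homogeneous of degree 1, the whole pipeline is invariant to a global
gain applied to both channels.

**Mitophagy mask.** The maxima-within-tolerance region of each accepted
peak — the 8-connected flood of pixels with ratio ≥ v − t — intersected with
the red gate. Tying the mask to the counted peaks keeps the area columns
consistent with the count columns. Caveat: because raising t simultaneously
removes peaks and deepens each surviving peak's flood level, the total mask
area is not mathematically monotone in t (counts are); on high-contrast
puncta whose footprint is far above background the dependence is monotone in
practice, and that is what the tests assert.

## Measurements

Per ROI: area (pixel count × pixel size²), raw-channel intensity means and
totals (detection uses smoothed channels, but intensity read-outs report the
source data), total red / total green, peak count restricted to the
rasterized ROI, mask area inside the ROI, and the derived densities. Mean
mitolysosome size divides mask area by *peak count* (not connected
components), and is reported as 0 rather than NaN when the count is 0 so the
CSV stays numeric. Overlapping ROIs are measured independently (a peak in
the overlap counts in both, with a warning). ROI polygons use the even-odd
rule evaluated at pixel centers (x + 0.5, y + 0.5) in the ImageJ coordinate
frame (origin at the top-left corner of pixel (0,0)); integer-vertex ROIs
round-trip exactly through the bundled `.roi` codec, sub-pixel vertices are
decoded best-effort. Rectangle and oval ROIs are converted to polygons
(ovals as a 128-gon, a sub-millipixel approximation at cellular scales);
line/point/polyline annotations are rejected by name.

## Synthetic scenes: what they emulate and what they do not

`mitoqc.synth` renders cells (irregular octagons at a base intensity above a
dim background) whose red and green channels are identical, plus disk
puncta: `red = base + amplitude`, `green = (1 − quench)·(base + amplitude)`
inside the footprint {(x − cx)² + (y − cy)² ≤ r²}. Hard disks make footprint
areas and ratios exactly computable, which is what the ground-truth tests
need; a Gaussian radial profile is available for softer scenes. Setting
`quench = 0` reproduces the bafilomycin-A1 control in which GFP de-quenches
and red-only contrast vanishes (both channels identical, ratio ≡ 1 — this is
the specificity test). Noise is additive Gaussian, clipped at zero,
independent per channel.

Default study conditions, chosen once to mimic a 16-bit widefield
acquisition at ~0.1 µm/pixel: 256 × 256 px scenes, background 20 a.u., cell
base 120 a.u., punctum amplitude 500 a.u., quench 0.9 (punctum ratio 10 —
about an order of magnitude of contrast, as red-only puncta show), radii
2–3 px (0.4–0.6 µm diameter mitolysosomes), puncta separated by ≥ 4× radius.
The benchmark suite alternates an induced condition (5–50 puncta per image,
the strong-induction regime) with a punctum-free control. The monotonicity
checks use 20 noisy 128 × 128 scenes (noise sd 8 a.u.) to keep the default
test run fast.

Deliberately not modelled: PSF blur, Poisson photon statistics,
photobleaching, chromatic shift, expression heterogeneity between cells, and
tissue texture. Passing tests therefore demonstrate the *algorithmic*
correctness of detection, gating, masking and bookkeeping under the stated
optical model — not robustness to every real-microscope artefact; on real
data thresholds still need the single-image tuning pass the CLI provides.

## Degenerate inputs and tie-breaks

- Constant images: no maxima, empty mask, zero counts.
- Zero-area (collinear) polygons rasterize to nothing with a warning;
  ROIs wholly outside the image are errors.
- Missing TIFF calibration falls back to 1 µm/pixel with a warning rather
  than silently mislabelled units.
- Equal-height plateau ties are broken lexicographically by (y, x); all
  processing orders (batch file order, peak output order) are sorted, so a
  rerun is byte-identical.

## Known limitations

- Peak semantics were designed to match published "Find Maxima" behaviour
  (strict prominence, plateau merging, no minimum peak separation), but
  bit-compatibility with any particular FIJI build is not guaranteed,
  especially for the mask, whose definition (peak-seeded tolerance regions
  vs a global ratio threshold) is a documented design choice.
- Only 2-D analysis; z-stacks are not projected, only the first plane is
  used.
- No background subtraction or flat-field correction — acquisition problems
  should be fixed upstream, and the CLI warnings only flag the detectable
  cases.
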