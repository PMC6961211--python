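# mitoqc

Quantification of mitophagy from two-channel fluorescence images of
tandem mCherry–GFP ("mito-QC"-style) reporters, for cell biologists who
need objective, scriptable mitolysosome counts instead of manual dot
counting or licensed image-analysis suites.

## The method

A tandem mCherry–GFP tag on the outer mitochondrial membrane emits both
fluorophores in the cytosol, so the pixel-wise ratio

```
R(x, y) = I_mCherry(x, y) / I_GFP(x, y)  ≈ 1
```

wherever healthy mitochondria sit. When a mitochondrion is delivered to a
lysosome (mitophagy), the acidic pH quenches GFP but not mCherry, so
mitolysosomes appear as "red-only" puncta with R ≫ 1. The pipeline:

1. **Median filtering.** Both channels are smoothed with a circular median
   kernel (offsets with dx² + dy² ≤ r² + 1; radius r = 1 by default, i.e. the
   full 3 × 3 neighbourhood) to suppress shot noise.
2. **Ratio image.** R = red/green pixel-wise (zero-green pixels are patched
   to keep the raster finite).
3. **Peak detection.** Local maxima of R are accepted when their
   *topographic prominence* exceeds the ratio threshold t (default 0.5): a
   maximum of height v counts only if every path to higher ground dips below
   v − t. Connected equal-valued plateaus count once. This matches the
   "Find Maxima" / noise-tolerance semantics familiar from ImageJ.
4. **Red-intensity gate.** Spurious high-ratio peaks in dim background are
   removed by requiring the (smoothed) mCherry intensity at the peak to reach
   `mean(red) + k·std(red)` computed over the whole image (k = 0 by default,
   population standard deviation).
5. **Mitophagy mask.** Each accepted peak is flood-filled over the connected
   pixels within t of its ratio value, the union is intersected with the
   red-intensity gate, and areas are measured from this binary mask.
6. **Per-ROI table.** For every user-supplied cell/tissue ROI (ImageJ `.roi`,
   `.zip`, or label mask): counts, densities (per µm² and per mean GFP,
   a proxy for mitochondrial content), total/mean/percent mitolysosome
   area, intensity statistics, and the parameters used — 18 columns, exported
   as CSV.

A synthetic-scene generator renders cells and disk puncta with exactly known
footprints (and a de-quenched "bafilomycin" mode in which no red-only puncta
exist), so every stage is testable against analytic ground truth.

## Worked example

Generate a small synthetic benchmark and analyse one image:

```bash
mitoqc simulate --out demo --n-images 2 --seed 42
# wrote 2 images, 9 ground-truth puncta to demo
mitoqc count demo/img000_dfp.tif demo/img000_dfp.zip \
    --red-channel 1 --green-channel 2 --smooth-radius 0
```

```
     Image CellROI  CellArea_μm2  greenMean    redMean  RGratio  nMitolysosomes  nML_per_um2  nML_over_green  MLtotalArea_μm2  MLpctArea  MLmeanArea_μm2  MLarea_μm2_over_green  X_tl  Y_tl  ratioThresh  redThresh  smoothRad
img000_dfp  cell_1         50.94 118.338830 128.087947 1.082383               5     0.098155        0.042252             0.89   1.747154        0.178000               0.007521    20    15          0.5  53.299255        0.0
img000_dfp  cell_2         52.80 119.450758 119.450758 1.000000               0     0.000000        0.000000             0.00   0.000000        0.000000               0.000000   144    21          0.5  53.299255        0.0
img000_dfp  cell_3         49.92 119.403846 121.862981 1.020595               1     0.020032        0.008375             0.22   0.440705        0.220000               0.001842    21   146          0.5  53.299255        0.0
img000_dfp  cell_4         56.32 118.155895 124.794034 1.056181               3     0.053267        0.025390             0.67   1.189631        0.223333               0.005670   151   143          0.5  53.299255        0.0
```

Reading row 1: cell_1 covers 50.94 µm²; 5 mitolysosomes were detected
(0.098 per µm²), occupying 0.89 µm² in total (1.75 % of the cell, mean
punctum 0.178 µm²). `RGratio` > 1 reflects the extra mCherry signal of the
puncta; `redThresh` echoes the realized adaptive threshold
(mean + 0·std = 53.3 here). The 9 detections across both rows match the 9
rendered ground-truth puncta. Batch mode (`mitoqc batch FOLDER …`) processes
every TIFF with a sibling ROI container and writes one combined CSV plus,
per image, the ratio image, mitophagy mask and an overlay of ROIs and
detected peaks.

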