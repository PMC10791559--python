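# Methods

This note documents the models behind `myoquant`: what each quantification
stage computes, what the synthetic generators emulate (and what they do
not), and the numerical choices that affect results.

## Imaging model and geometry conventions

Stacks are `(channel, z, y, x)` float grids with physical pitches attached.
Indices are 0-based; the physical position of pixel *i* along an axis with
pitch *p* is `(i + 0.5)·p` (pixel-center convention), so rasterization,
contour tests, and reslicing are all unambiguous. Areas are always
`count · pixel_area`, exactly.

Two acquisition geometries are supported as defaults: whole-cell view
(100-nm XY pixels, 300-nm Z steps) and cluster view (50-nm isotropic).
The optical blur is a separable anisotropic Gaussian with FWHM 100 nm
(lateral) and 300 nm (axial), σ = FWHM/2.3548, truncated at 4σ. This is a
deliberate simplification of a detector-array ("Airyscan") PSF: only the
resulting resolution scale matters for the statistics computed here.

**Rim definition.** The lateral-surface region is the set of cell pixels
whose exact Euclidean distance (in µm, anisotropy-aware) to the nearest
outside-cell pixel is ≤ the rim width (default 1 µm), computed by a
distance transform on the cell mask padded with one outside ring — the
image border counts as outside the cell. Width 0 gives an empty rim;
width → ∞ gives the whole cell. Manual demarcation in the original assays
has no exact definition; automation requires this one, and it is what the
brute-force distance oracle in the test suite checks.

**Background.** The background used in pixel-content calculations is the
mean over an explicit cell-free region (like the cell-free ROI in FRAP
acquisitions). The convention is recorded in every output sidecar.
Background-subtracted means can go negative in dim regions; negative
percentages are clipped to 0 only in percentage reporting, never in the raw
pixel-content value, and both are retained.

## Enrichment

Pixel content `PC(R) = (mean(I over R) − background) · area(R)` is the
expression surrogate. For a region R inside the cell,

```
%PC(R)  = 100 · PC(R) / PC(cell)
%area(R) = 100 · area(R) / area(cell)
E(R)     = %PC(R) / %area(R)
```

E = 1 means the protein is distributed uniformly; E = 4 means the region
holds four times more signal than its area share. The analysis acts on a
single caller-selected z-plane; a helper picks the plane of maximal
cell-mask area by default (the "central plane with a clearly defined
contour" convention). The ICD region is whatever the junction-marker
(nCadherin-like) channel demarcates — in phantoms the ground-truth band, in
real data a segmented, hole-filled marker mask whose settings are logged.

## Cluster analysis

Segmentation follows the demarcate → clear-outside → threshold → label
workflow: pixels at or above the threshold (computed within the ROI) form
8-connected components; components smaller than `min_size_px` (default 4)
are discarded. The three reported parameters are density (% of ROI area
occupied by clusters), average cluster size (µm²), and background-subtracted
mean intensity over cluster pixels (the raw mean is also reported). The
threshold rule is Otsu-within-ROI by default, with `mean + k·sd` and fixed
absolute value as alternatives; the rule and realized threshold are always
recorded, because the original interactive settings are not recoverable and
reproducibility beats guesswork. No watershed splitting and no 3-D
components: the assays analyzed single planes, and so does this package.

En-face ICD cluster profiles reslice the stack into YZ planes at given x
positions, segment the junction-marker channel (fill holes, keep components
above an area floor) to define the ICD ROI per plane, then run the cluster
workflow on the target channel inside it. Planes without usable marker
signal are reported as missing, not fatal.

## Thresholded colocalization

Plain Pearson correlation over a cell mask is background-dominated. The
Costes procedure fits an orthogonal (total least squares) regression line
`b = s·a + c` through the joint histogram — orthogonal because both
channels carry symmetric noise — and lowers a threshold pair
`(Ta, s·Ta + c)` until the pixels *below* both thresholds are uncorrelated.
The below-threshold PCC is not monotone in the threshold (it fluctuates
around zero at sampling-noise scale), so the implementation scans downward
from the channel maximum in steps of `tol` (default 0.5 intensity units)
and stops at the first non-positive crossing, which is also what the
exhaustive-scan oracle in the tests computes. If no crossing exists, every
pixel counts as colocalized; if the regression slope is non-positive the
thresholds are undefined and the thresholded PCC is reported missing.

The reported `pcc_above_threshold` uses pixels where *either* channel
exceeds its threshold (default; preserves genuine anti-correlation while
excluding background-dominated pixels), with `both` and `all` selectable.
The convention is part of the output. Note a selection subtlety verified in
the tests: for independent images with spatial structure, the null
distribution of the thresholded PCC fluctuates at the scale of the number
of independent structures, not pixels — null checks should average over
replicates.

## PLA density

3-D stacks are collapsed by maximum projection, segmented inside the cell
contour with the cluster machinery (minimum punctum size 2 pixels,
configurable), and density is the % of cellular area occupied by puncta.
For batch comparisons the threshold must be fixed per batch ("systemic"
segmentation), never per-image adaptive. The expression-corrected density
divides each cell's raw density by the product of its two normalized
expression pixel contents (each normalized to the batch mean), making the
statistic invariant to cohort-wide expression rescaling.

## FRAP

Acquisition convention: 25 baseline scans, photobleach, 275 recovery scans,
0.5-s interval; four ROIs (1 bleached cell center, 2 bleached cell end,
3 unbleached reference, 4 cell-free background). Processing order:

1. subtract ROI 4 from all traces;
2. divide by the reference decay, rescaled to its prebleach mean
   (`corrected = target · ref_pre / reference`) — this removes acquisition
   photobleaching exactly when the decay is multiplicative;
3. normalize to 1 at scan 25 and 0 at scan 26, using those single scans
   (a prebleach-mean variant exists but is off by default);
4. fit `N(t) = A1(1−e^(−t/τ1)) + A2(1−e^(−t/τ2))` over scans 26–300 with
   t = 0 at scan 26.

The form is anchored at N(0) = 0 with saturating recovery; `A1 + A2` is the
mobile fraction and the plateau, `1 − (A1+A2)` the immobile fraction. No
offset term: with the two-scan normalization an offset is not identifiable
and the anchored form is the parsimonious reading of a "two-exponential"
recovery fit. Amplitudes are bounded in [0, 1.5] (values above 1 are
physically suspect and flagged, not clipped), time constants in
[0.1, 10⁴] s, ordered τ1 < τ2 after fitting. The optimizer is multi-start
least squares (six τ-pairs spanning the bound range; amplitude starts
solved linearly per pair), best residual sum of squares wins. The headline
statistic, % recovery 2 min after photobleaching, is evaluated on the
fitted curve to suppress scan noise; the raw-trace value is reported
alongside. No diffusion-model interpretation of τ is attempted.

## Ensemble sodium currents

Sweep families are `(repeats, voltages, time)` in pA, inward negative, with
a strictly monotone test-voltage ladder (default −100 → +75 mV in 5-mV
steps from a −120 mV holding potential, 200-ms pulses — the membrane-voltage
mirror of a cell-attached pipette protocol). Repeats are averaged into an
ensemble per voltage. Per sweep, the mean of the 5 ms before the pulse is
subtracted (residual offset after online leak subtraction), and the first
0.3 ms of the pulse is blanked for the capacitive transient (configurable).
The maximal peak I<sub>Na</sub> is the largest-magnitude negative excursion
across the ladder; its inactivation time constant comes from a
monoexponential fit `I_peak·e^(−(t−t_peak)/τ) + c` from the peak to the
window end, with the offset `c` absorbing residual leak. Non-decaying
traces yield a missing fit with diagnostics.

The generator uses Hodgkin–Huxley-style kinetics,
`I = −gmax·m∞³·(1−e^(−t/τ_act))³·e^(−t/τ_inact)·(e_rev − V)` with Boltzmann
activation (default V½ = −50 mV, k = 4 mV, e_rev = +70 mV), which places
the maximal peak near −35 to −30 mV as observed for myocyte patches with a
zeroed resting potential. Because activation continues to rise after the
peak, the post-peak decay is not a pure exponential of τ_inact; recovery
tests therefore compare noisy fits against the fit to the noiseless
ensemble (the self-consistent reference), not against the generator's
τ_inact parameter. No stochastic gating is simulated.

## Immunoblot densitometry

Band intensities are inputs; gels are not processed. Three per-experiment
schemes: PKA/CON of like lanes (optionally Coomassie-corrected by dividing
each band by its CB lane); degree of coimmunoprecipitation [+]IP/WCL and
its PKA:CON ratio; degree of surface biotinylation biotinylated/WCL and its
PKA:CON ratio. All ratios are invariant to a per-experiment global gain.
The WCL : pulldown loading convention is 1:20; ratios are reported raw
(like lanes are compared) with an optional absolute-recovery flag applying
the factor. Coomassie correction is an explicit flag, never automatic.
Experiments excluded for missing or zero lanes are always reported, never
silently dropped. Summaries are mean ± SE across experiments with
per-experiment points retained.

## Synthetic generators (what they emulate, and what they don't)

The myocyte phantom is a stadium-shaped cell (rectangle with semicircular
ends; default 120 × 25 µm, conventional for adult rat ventricular myocytes
and configurable) in a two-channel stack: a target-protein channel with
2-µm-period striations, rim and ICD plateaus, and surface cluster disks;
and a junction-marker channel filling the ICD bands (depth 1.5 µm at each
end). The rim and ICD plateau intensities are *solved analytically* from
the requested enrichment factors and the rasterized region areas, striation
texture included, so the noiseless image's measured enrichment equals the
requested factor exactly — ground-truth recovery tests are then exact
closures, not approximations. Surface clusters are non-touching disks on
the top-surface plane, centers on pixel centers so every disk rasterizes
identically; the recorded truth (density, mean size) is the rasterized
value. Interior signal stops a standoff (default 0.3 µm) below the surface
plane so that, after axial blur, the surface cluster view is not
contaminated by interior striations — mirroring the real surface/interior
contrast at small z offsets. Noise is Poisson (scaled by `photon_scale`)
plus Gaussian read noise, the standard CCD approximation; the variance of a
uniform region is `mean/photon_scale + read_noise_sd²`, which the tests
verify. Default `photon_scale = 1` at base intensity 100 gives per-pixel
SNR ≈ 10.

What the phantom does not model: t-tubules, nuclei, sarcomere disarray,
depth-dependent aberration, detector-array reconstruction artifacts, or
autofluorescence. Passing recovery tests therefore demonstrates the
correctness of the measurement chain under the stated geometry and noise,
not robustness to every property of real myocyte images.

The FRAP generator produces the four-ROI table with biexponential recovery
scaled to the bleached span, an optional monoexponential acquisition-bleach
decay multiplying all cell ROIs, and a constant cell-free offset. The
sodium-current generator and band-table generator are described above.
Determinism is bit-exact for every generator given spec + seed.

## Problem sizes and tolerances

Recovery studies in the tests and acceptance script use: 40 × 15-µm cells
at 100-nm pixels for enrichment (exact noise-off; ±10% at SNR 10 with
PSF), 20 × 10-µm cells at 50-nm pixels with 5% cluster density and 0.25-µm
radius (exact noise-off; ±15% with PSF + noise), 10⁴-pixel colocalization
samples, 200 FRAP traces at σ = 0.02 (median relative error: slow τ < 10%,
mobile fraction < 5%), 100 sweep-family seeds at 1% peak noise with a 20-ms
analysis pulse (median τ error < 2%), 200–1000-experiment blot tables
(mean ratio within 2% at CV 0.1), and a 10+10-cell cohort with a two-fold
enrichment difference (group ratio within 10%, fully deterministic under a
fixed seed). These sizes are the package's chosen study conditions; the
generators accept larger ones unchanged.

## Known limitations

- Quantitative agreement with any particular interactive segmentation
  (thresholds, ROI tracing) is not claimable; the package's rules are
  explicit substitutes, always logged.
- The Costes scan inherits the noise of the below-threshold correlation;
  thresholds on weakly-correlated data are reproducible (seeded) but not
  meaningful beyond the tol step.
- Cell contours are inputs (or phantom truth): there is no automated
  whole-cell segmentation from raw fluorescence, and no deconvolution.
- ABF/native electrophysiology file parsing is out of scope; sweep families
  arrive as long-format tables.
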