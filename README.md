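# myoquant

Quantification pipeline for studies of voltage-gated sodium channel
(Na<sub>V</sub>1.5) redistribution in adult ventricular cardiomyocytes —
for example under persistent protein-kinase-A (PKA) activation — together
with synthetic-data generators that make every stage verifiable by
ground-truth recovery.

Chronic adrenergic stress redistributes Na<sub>V</sub>1.5 between an
intracellular reservoir, the lateral sarcolemma, and the intercalated discs
(ICDs) at cell ends. Measuring that redistribution takes several independent
assays, each with its own quantification rule. `myoquant` implements the full
set as a reusable, tested library:

| stage | statistic |
|---|---|
| `enrichment` | pixel content `PC = (mean − background) · area`; degree of enrichment `E = %PC(region) / %area(region)` for the 1-µm lateral rim and the nCadherin-demarcated ICD |
| `clusters` | surface/ICD cluster parameters: density (% of ROI area occupied), average size (µm²), mean in-cluster intensity |
| `coloc` | thresholded Pearson correlation (Costes automatic thresholds on an orthogonal-regression line) |
| `pla` | proximity-ligation puncta density, with expression correction `density / (PC₁/⟨PC₁⟩ · PC₂/⟨PC₂⟩)` |
| `frap` | FRAP correction chain and constrained fit `N(t) = A₁(1−e^{−t/τ₁}) + A₂(1−e^{−t/τ₂})`; % recovery at 2 min |
| `ephys` | ensemble-averaged cell-attached sweep families; maximal peak I<sub>Na</sub> and its inactivation time constant |
| `densitometry` | immunoblot ratio schemes: PKA/CON, [+]IP/WCL, biotinylated/WCL, with Coomassie loading correction |
| `phantom` | synthetic myocyte stacks (striations, rim/ICD enrichment, surface clusters, anisotropic PSF, Poisson + Gaussian noise), FRAP traces, sodium-current sweeps, and band tables — all with exact ground truth |
| `pipeline` / CLI | end-to-end CON-vs-PKA cohort comparison with full provenance |

The imaging model follows Airyscan-style acquisition geometry: 100-nm XY /
300-nm Z pixels for whole-cell views, 50-nm isotropic for cluster views, and
a ~100/300-nm (lateral/axial) Gaussian point-spread function.

## Worked example

```python
from myoquant.phantom import PhantomSpec, make_myocyte_stack
from myoquant.imgeo import RegionMask, estimate_background, rim_mask
from myoquant.enrichment import lateral_enrichment

spec = PhantomSpec(cell_length_um=40, cell_width_um=15,
                   lateral_enrichment=2.0, icd_enrichment=3.0, seed=42)
stack, truth = make_myocyte_stack(spec)

plane = stack.channel("target")[truth.central_z]
cell = truth.cell_mask
bg = estimate_background(plane, RegionMask(~cell.mask, cell.pixel_xy_um), cell)
res = lateral_enrichment(plane, cell, rim_mask(cell, 1.0), bg)
print(f"degree of enrichment on lateral surface: {res.enrichment:.3f} "
      f"(ground truth {truth.true_lateral_enrichment})")
print(f"% pixel content in 1-um rim: {res.pct_pixel_content_region:.1f}%  "
      f"(rim is {res.pct_area_region:.1f}% of cell area)")
```

prints

```
degree of enrichment on lateral surface: 1.992 (ground truth 2.0)
% pixel content in 1-um rim: 33.8%  (rim is 17.0% of cell area)
```

The phantom was built with a true two-fold rim enrichment; after PSF blur
and shot noise the measured degree of enrichment is 1.992 — the rim holds
33.8% of the cell's fluorescence in 17.0% of its area. With blur and noise
disabled (`apply_psf=False, apply_noise=False`) the recovery is exact to
floating-point precision.

The same round-trip works for kinetics:

```python
from myoquant.phantom import FRAPSimSpec, make_frap_dataset
from myoquant.frap import analyze_frap_table

fits = analyze_frap_table(make_frap_dataset(FRAPSimSpec(noise_sd=0.02, seed=42)))
f = fits[1]
print(f"FRAP fit: mobile fraction {f.mobile_fraction:.2f}, "
      f"tau1 {f.tau1_s:.1f} s, tau2 {f.tau2_s:.1f} s, "
      f"recovery at 2 min {f.recovery_2min_pct:.1f}%")
```

```
FRAP fit: mobile fraction 0.74, tau1 4.1 s, tau2 63.9 s, recovery at 2 min 68.0%
```

against generator truth A₁ = 0.3, A₂ = 0.4, τ₁ = 5 s, τ₂ = 60 s (mobile
fraction 0.7).

## Command line

```sh
myoquant phantom image --seed 1 --out out/phantom     # stack + truth + masks
myoquant phantom frap  --seed 1 --out out/frap        # four-ROI trace table
myoquant frap --traces out/frap/frap_traces.csv --out out/fits
myoquant report --config cohort.yaml --seed 1 --out out/report
myoquant dump-config                                  # exact defaults
```

Stages exchange plain files (OME-TIFF, CSV, JSON) and every run writes a
parameter sidecar, so any result can be reproduced from its outputs alone.

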