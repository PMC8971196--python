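# myoph — myocardial pH imaging and omics pipeline

Extracellular acidity in the early postnatal myocardium is not uniform: the
inner myocardial wall harbours acidic niches that influence the expression of
genes coding for contractile proteins. Probing this requires three distinct
quantitative layers, and `myoph` implements all of them as a tested,
reusable Python library:

1. **Tissue-scale acidity maps** — ratiometric pHLIP-Cy5.5 / Hoechst-33342
   imaging of whole heart sections. pHLIP (pH-Low Insertion Peptide) inserts
   into membranes where extracellular pH is low; dividing by a Hoechst
   density reference cancels cell density and dye penetrance. The pipeline
   estimates background statistics, subtracts and resizes (bilinear),
   thresholds both channels at 2 SD above background, ratios pixelwise,
   normalises to the median, and decomposes the ratio histogram into
   Gaussian components (EM, three components by default) with its sample
   skewness.
2. **Nuclear vs cytoplasmic pH in myocyte monolayers** — dual-emission
   ratiometric dyes (Hoechst 34580 at 440/490 nm reporting pH in the DNA
   nanodomain, pHn; cSNARF1 at 580/640 nm reporting cytoplasmic pH, pHc),
   calibrated by a nigericin/high-K⁺ clamp and fitted to a 4-parameter
   titration curve R(pH) = R_min + (R_max − R_min)/(1 + 10^(h·(pKa − pH))).
   Nuclei are segmented (Otsu + watershed), a perinuclear annulus of width
   equal to the field's mean nuclear radius defines the cytoplasmic region,
   and the nucleus-to-cytoplasm gradient ΔpHnc = pHn − pHc is computed per
   cell. Summaries are hierarchical: cells nest in isolations, and the
   isolation is the unit of replication. pH-coupling slopes (pHc vs pHe,
   pHn vs pHe) come from OLS on condition means.
3. **Cross-omics concordance statistics** — Benjamini–Hochberg FDR
   classification of differential gene/protein tables, the DEG↔DAP
   direction-concordance 2×2 table with an exact two-sided Fisher test,
   H3K27ac peak-presence summaries against the union peak set, promoter
   (TSS ± 2 kb) overlap fractions, and ChIP spike-in (dm6:rn6) scale
   factors.

A first-class synthetic-data module generates seeded phantoms — tissue
sections with an acidic inner-wall niche, monolayer fields with known
per-cell pHn/pHc drawn from an explicit coupling model, titration series,
and omics tables with controlled concordance — so every stage is testable
against known ground truth without any external download.

## Worked example

Fit a cSNARF1 titration curve from a simulated nigericin-clamp series
(9 pH levels × 10 ROIs, ratio noise SD 0.01), then recover the pH-coupling
slopes from a full synthetic five-level monolayer experiment:

```python
import numpy as np, pandas as pd
from myoph.ph_calibration import CalibrationCurve, fit_calibration
from myoph.synthetic_data import (MonolayerPhantomSpec, generate_monolayer,
                                  generate_calibration_series)
from myoph.nucleo_cyto import (segment_nuclei, build_annuli, quantify_cell_pH,
                               hierarchical_summary, ph_coupling_slopes)

truth = CalibrationCurve("cSNARF1", r_min=2.0, r_max=0.4, pKa=7.3)
series = generate_calibration_series(truth, np.linspace(6.2, 8.2, 9),
                                     noise_sd=0.01, n_rois=10, seed=7)
fit = fit_calibration(series, dye="cSNARF1")
print(f"pKa {fit.pKa:.3f}  r_min {fit.r_min:.3f}  r_max {fit.r_max:.3f}")
# pKa 7.304  r_min 2.000  r_max 0.392

spec = MonolayerPhantomSpec(seed=1)   # 5 pHe levels, 500 cells/level, 5 isolations
fields, _ = generate_monolayer(spec)
recs = []
for (pHe, iso), ch in fields.items():
    nuclei = segment_nuclei(ch["490"])
    recs.append(quantify_cell_pH(nuclei, build_annuli(nuclei),
        ch["440"], ch["490"], ch["580"], ch["640"],
        spec.curve_h34580, spec.curve_snarf, condition=pHe, isolation=iso))
summary = hierarchical_summary(pd.concat(recs, ignore_index=True))
res = ph_coupling_slopes(summary)
```

The condition summary (mean ± SEM over isolation means) and slopes printed
by this run:

```
 condition  n_cells  n_isolations  mean_pHc  sem_pHc  mean_pHn  sem_pHn  mean_dpnc
    6.2400      500             5    6.7764   0.0076    6.9725   0.0075     0.1961
    6.5400      500             5    6.8646   0.0087    7.0308   0.0087     0.1661
    6.8400      500             5    6.9575   0.0073    7.0934   0.0073     0.1359
    7.1400      500             5    7.0477   0.0073    7.1537   0.0074     0.1059
    7.4400      500             5    7.1352   0.0079    7.2111   0.0079     0.0759

pHc/pHe slope 0.300 (R2 0.9999); pHn/pHe slope 0.200 (R2 0.9998)
```

The cytoplasm tracks extracellular pH at 0.3 pH units per unit pHe while the
nucleus is more resilient (slope 0.2), so the nucleus-to-cytoplasm gradient
ΔpHnc is positive and widens in acid — exactly the coupling model the
generator encodes, recovered end-to-end through segmentation, annulus
construction, ratio inversion and hierarchical aggregation.

## Command line

Thin wrappers over the library: `myoph simulate` (phantoms from a YAML
spec), `myoph tissue-map` (ratio map + histogram fit from TIFFs),
`myoph calibrate` (titration fit to JSON), `myoph monolayer` /
`myoph summarize` (per-cell records and hierarchical summaries), and
`myoph omics concord|peaks|promoters|spike`.

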