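# casemap

Single-case structural-MRI comparison: is *this one patient's* brain outside
the normal range?

Group studies average patients together, but clinical questions are asked one
patient at a time. `casemap` compares a single subject's gray-matter
biomarkers — regional volumes, cortical thickness, surface area, curvature,
and voxelwise modulated gray-matter maps — against a small, age-matched
normative control cohort, using statistics that remain calibrated when the
control group has only 10–25 members. It also aggregates many single-subject
results into group-level atrophy maps and links them to disease progression.
The package was built with neurodegenerative disease in mind (it ships a
Huntington's disease ROI panel and the CAG-based disease burden score), but
the machinery is disease-agnostic.

## The statistics at the core

**Crawford–Howell modified t.** Given one case score *x\** and a normative
sample with mean *x̄*, sample SD *s* and size *n*:

```
t = (x* − x̄) / (s · √((n + 1) / n)),   df = n − 1
```

This treats the case as a sample of size one rather than a known population
value. The naive z-score `(x* − x̄)/s` referred to the normal distribution is
anti-conservative at small *n* (with 5 controls, |z| > 1.96 rejects ~15% of
healthy subjects instead of 5%); the modified t keeps the false-positive rate
at its nominal level.

**Pipeline.** Controls are first restricted to the subject's age ± 10 years
(configurable); volumetric measures are optionally divided by each subject's
total intracranial volume. ROI panels are corrected with Benjamini–Hochberg
FDR over the panel size (significant when adjusted p < 0.05). The voxelwise
branch smooths subject and controls with the same Gaussian kernel, applies
the modified t at every voxel of a control-derived analysis mask, and
binarizes at uncorrected p < 0.005 (GM decreases by default). Per-patient
binary maps are summed and normalized into probability overlap maps,
thresholded at consensus fractions (75% / 90%), and summarized as region
atrophy prevalence. Disease burden is `Age × (CAG − 35.5)`; imaging–clinical
associations use Pearson and first-order partial correlations; longitudinal
change is an annualized OLS slope compared between groups with a pooled
t-test.

## Worked example

`examples/roi_panel_example.py` simulates 20 controls and one patient whose
left caudate volume sits 4 control SDs below normal, then runs the full
panel comparison:

```
patient pat000, age 45.5, vs 20 age-matched controls
biomarker                                    z       t        p    p-adj  flag
Left-Caudate (volume_mm3)                -4.52   -4.42   0.0003   0.0036  BELOW
Right-Caudate (volume_mm3)                0.19    0.19   0.8532   0.9342
Left-Putamen (volume_mm3)                 0.14    0.14   0.8912   0.9342
...
rh-insula (thickness_mm)                  1.85    1.81   0.0862   0.5172
```

The implanted deficit is flagged BELOW (adjusted p = 0.0036 after FDR over
the 12-region panel); every healthy biomarker stays non-significant. Note
|t| < |z| — the modified t pays for the small control sample.

The other examples cover the voxelwise branch (`voxelwise_example.py`:
recovers an implanted atrophy sphere with Dice 0.75), group overlap maps
(`overlap_example.py`) and longitudinal rates with disease-burden
correlations (`longitudinal_example.py`). Each prints what its numbers mean.

A thin CLI wraps the same functions for shell use:

```bash
casemap simulate --seed 5 --out study/
casemap roi-compare --biomarkers study/biomarkers.csv --meta study/meta.csv \
    --subject pat000 --disease hd --out results/
casemap vbm-compare --subject pat.nii.gz --controls controls/ --fwhm 8 --out vbm/
casemap overlap --binaries maps/ --thresholds 0.75,0.90 --out overlap/
```

## Reading real data

`casemap` parses FreeSurfer-dialect segmentation tables (`aseg.stats`,
`lh/rh.aparc.stats`), long-format biomarker CSV, subject metadata CSV, and
NIfTI-1 volumes (already registered and modulated — the package never
resamples). Segmentation and spatial normalization themselves are out of
scope; run them with your preferred tools first.

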