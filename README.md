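# madwt

Left-ventricular wall-thickness **heterogeneity** analysis: from short-axis
myocardium segmentation masks to the MadWT biomarker, its risk-factor and
prognosis models, and propensity-matched hypertension comparisons — all
exercised on synthetic phantoms and simulated cohorts with known ground
truth.

## The problem and the biomarker

Left-ventricular hypertrophy is usually summarized by mass or by maximal
wall thickness, but *how unevenly* the wall thickens carries information of
its own: pathological remodelling (e.g. hypertensive heart disease) tends to
be regional, physiological adaptation (e.g. athletic training) uniform. On
the AHA 16-segment model, with `w_s` the maximal end-diastolic wall
thickness of segment `s` (mm):

```
MeanWT = mean(w_s)        MaxWT = max(w_s)
MadWT  = mean over s of | w_s − MeanWT |
```

MadWT — the mean absolute deviation of segmental thickness — is 0 for a
uniformly thick ventricle and grows with regional thickening. The package
measures `w_s` from label masks (radial ray-casting from the cavity
centroid, maximum per sector), applies within-subject outlier QC
(values above `Q3 + 3·IQR` removed; subjects with < 12 valid segments
excluded), and feeds the indices into:

- an identity-link **Gamma GLM** relating MadWT to cardiovascular risk
  factors (effects in mm per SD);
- stepwise **Cox** prognosis models (Model 1 biomarker → Model 2 + risk
  factors → Model 3 + LVEDVi/LVEF → Model 4 + LVMi), with Harrell's C,
  bootstrap **ΔC-index**, VIF and Schoenfeld diagnostics;
- **propensity-score matching** (greedy 1:1 nearest neighbour, no
  replacement) of hypertensive vs. non-hypertensive subjects within the most
  physically active strata, with Bonferroni-corrected Mann-Whitney
  comparisons of nine imaging biomarkers.

Because real cohort data cannot ship with the code, a first-class synthetic
module generates (a) stepped-annulus phantoms whose per-segment thickness is
known exactly and (b) cohorts with configured covariate distributions,
Gamma biomarker models and Weibull proportional-hazards event times — every
downstream stage has an oracle. See `docs/methods.md` for the full model
descriptions and design choices.

## Worked example

Measure a stepped phantom whose 16 design thicknesses are known, then
compute the indices:

```python
import numpy as np
from madwt import PhantomSpec
from madwt.synth import generate_phantom
from madwt.geometry import segment_wt
from madwt.indices import qc_segments, compute_wt_indices

rng = np.random.default_rng(0)
design = np.round(rng.uniform(6.0, 12.0, 16), 2)          # mm per AHA segment
spec = PhantomSpec(endo_radius=20.0, sector_thickness=design,
                   in_plane_spacing=0.5, grid_size=160, rv_insertion_angle=30.0)
profile = segment_wt(generate_phantom(spec))               # 16 measured maxima
indices = compute_wt_indices(qc_segments(profile))
```

This prints (via the obvious `print` calls):

```
design:   [ 9.82  7.62  6.25  6.1  10.88 11.48  9.64 10.38  9.26 11.61 10.9   6.02 11.14  6.2  10.38  7.05]
measured: [10.01  7.7   6.45  6.24 10.99 11.58  9.8  10.5   9.43 11.67 11.08  6.1  11.23  6.46 10.5   7.29]
max |err| = 0.255 mm
MadWT=1.862  MaxWT=11.67  MeanWT=9.19  n_valid=16
```

Every segment is recovered within 0.26 mm of design at 0.5 mm voxels, and
the measured MadWT (1.862 mm) sits next to the design value (1.879 mm). This
phantom is deliberately very heterogeneous; population values are ~0.9 mm.
(Caveat: on a *nearly uniform* profile the within-subject fence has IQR ≈ 0,
so an isolated genuinely thick segment is treated as a measurement outlier —
inherent to the QC rule, discussed in `docs/methods.md`.)

Prognosis on a simulated cohort (37 080 subjects, segment-level generation,
MACE-like endpoint with a true per-SD log hazard ratio of 0.25 for MadWT):

```python
from madwt.synth import default_config, generate_cohort
from madwt.survival import fit_cox, ModelSpec

cohort, truth = generate_cohort(default_config(n=37080), seed=7)
res = fit_cox(cohort, ModelSpec("MACE", "MadWT", level=2), per="sd")
```

```
MACE Model 2: HR per SD 1.31 (95% CI 1.22-1.40), C-index 0.656, events 680
```

The fitted hazard ratio brackets the generating value `exp(0.25) = 1.28`.

A thin CLI mirrors the library (`madwt simulate-phantom`, `measure-wt`,
`indices`, `simulate-cohort`, `fit-cox`, `psm-compare`); run
`madwt --help`.

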