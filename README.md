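# cortbs

Cortical backscatter (CortBS) simulation and analysis: a tested, reusable
implementation of ultrasonic tissue characterization of the cortical bone
shell — recovery of the frequency-dependent attenuation coefficient α(f)
and of the cortical pore-diameter distribution Ct.Po.Dm.D from pulse-echo
backscatter — together with HR-pQCT-style cortical morphometry and the
precision and PLS-LOOCV statistics used to compare imaging modalities for
fragility-fracture discrimination in postmenopausal women.

## Who this is for

Researchers in quantitative bone ultrasound and bone imaging who want to

* prototype and stress-test backscatter-based estimators of cortical
  microstructure against a ground-truth-known forward model,
* reproduce the statistical machinery of cross-sectional fracture
  discrimination studies (short-term precision, PLS-DA with leave-one-out
  cross-validation and Monte-Carlo variable selection, ROC/odds-ratio
  metrics, Hanley–McNeil AUC comparison), or
* generate realistic synthetic cohorts and micro-CT-like volumes with
  known pore microstructure.

No clinical data ship with the package; every input is simulated from
seeded generators with known ground truth.

## The model in brief

Cortical pores are fluid cylinders (marrow) in a fluid bone matrix. The
exact modal series for a plane wave on a fluid cylinder gives the
backscatter cross-section per pore, K(f, d); for a pore population with
areal density ρ_A and diameter density p(d),

    BSC(f) = ρ_A ∫ K(f, d) p(d) dd .

From pulse-echo volume scans the package computes a normalized
depth-dependent spectrum NDS(z, f) (backscatter power below the periosteal
surface in dB relative to the specular surface reflection, with
inclination gating at ±10°/±30°), estimates the attenuation line
α(f) = Ct.α₀ + Ct.α_f·f from the NDS depth slope (one-way, dB/mm), builds
the attenuation-compensated BSC(f) over 4–9 MHz × 1–3 mm, and inverts the
linear model above for p(d) by non-negative smoothness-regularized least
squares, reporting the descriptors Peak, Q10, Q90, FWHM and its crossings.
The micro-CT side computes cortical thickness, threshold (Burghardt-type)
porosity, pore density, a partial-volume local-porosity map, per-pore
diameters, and moment statistics; the statistics side implements Glüer
RMS precision, rank tests, NIPALS PLS with LOOCV, subwindow-permutation
variable selection, and ROC/odds-ratio discrimination metrics.

See `docs/methods.md` for the full model description, defaults and
numerical choices.

## Worked example

Simulate a volume scan of a slab with Haversian-type pores (median 30 μm,
15 pores/mm²) and programmed attenuation α(f) = 2.0 + 0.10·f, then run the
full estimation chain:

```python
import numpy as np
from cortbs.pores import sample_pore_population, baseline_only
from cortbs.rf import (AcquisitionGeometry, AcousticsConfig, synthesize_rf,
                       reflection_coefficient)
from cortbs.spectral import (detect_surface, compute_nds, AttenuationModel,
                             estimate_bsc, quality_score)
from cortbs.inversion import PoreSizeModel

geom = AcquisitionGeometry.small()          # reduced sweep for speed
params = baseline_only(areal_density=15.0)  # Haversian mixture, median 30 um
slab = (geom.n_lines * geom.pitch_mm + 6.5, 5.0, 4.0)
pop = sample_pore_population(params, slab, seed=7)

acoustics = AcousticsConfig(alpha0_db_mm=2.0, alphaf_db_mhz_mm=0.10, snr_db=30.0)
rf = synthesize_rf(pop, geom, acoustics, seed=7)

surf = detect_surface(rf)
nds = compute_nds(rf, surf, gate_mm=2.0, bone_speed=pop.matrix.sound_speed)
att = AttenuationModel(nds).fit()
print(att.summary())

bsc = estimate_bsc(nds, att, reflection_coefficient(pop.matrix, pop.pore_fluid))
res = PoreSizeModel(bsc.bsc, bsc.freq_mhz,
                    matrix=pop.matrix, pore_fluid=pop.pore_fluid).fit()
print(res.summary())
```

Output:

```
Cortical attenuation (linear fit over 4-9 MHz)
----------------------------------------------
  Ct.alpha0 :   2.035 dB/mm      (SE 0.045)
  Ct.alphaf :   0.087 dB/MHz/mm (SE 0.007)
  R^2       :  0.8732
  resid SD  :  0.0456 dB/mm
Pore-size distribution (Ct.Po.Dm.D)
--------------------------------------
       Peak :    20.10 um
        Q10 :    12.29 um
        Q90 :    42.26 um
       FWHM :    27.12 um
   FWHM_min :     9.55 um
   FWHM_max :    36.67 um
     lambda : 5.62e-05
   residual : 0.000241
```

The programmed attenuation intercept 2.0 dB/mm and slope 0.10 dB/MHz/mm
are recovered as 2.035 and 0.087 from this single reduced sweep (a single
sweep carries ~7–15 % speckle-limited spread; the median over repeated
phantoms is accurate to ~2 %, see `docs/methods.md`). The recovered
pore-size distribution spans the Haversian range of the generating mixture
(true median diameter 30 μm, mixture Q90 ≈ 47 μm).

Discrimination statistics run on synthetic cohorts drawn with the
published group effect sizes:

```python
from cortbs.cohort import generate_cohort
from cortbs.statsdisc import DiscriminationModel

cohort = generate_cohort(seed=0)            # 29 fractured / 26 non-fractured
model = DiscriminationModel.from_cohort(cohort, endpoint="all",
                                        features="attenuation")
print(model.fit(seed=0).summary())
```

A command-line interface mirrors the library
(`cortbs simulate / process-rf / invert / microct / precision /
discriminate / run-all / report`).

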