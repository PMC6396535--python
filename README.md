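# lungsms — standardized CT lung densitometry

Quantitative CT densitometry measures pulmonary emphysema as a loss of lung
tissue mass: the 15th-percentile density of the lung voxel histogram (PD15,
g/L) falls as alveolar tissue is destroyed.  Raw PD15 values, however, are
not comparable across scanners (calibration drift), across subjects
(lung-size differences) or across scans of one subject (inspiration level).
`lungsms` implements an integrated standardization that addresses all three
and reports lung tissue mass as a Z-score against a normative database —
the **Standard Mass Score (SMS)** — globally and for apical, central and
basal lung regions.  It is aimed at researchers and image analysts working
on emphysema quantification, particularly basal-predominant disease such as
alpha-1 antitrypsin deficiency.

## Method

1. **Densitometry.** Lungs are segmented at −380 HU with connected-component
   analysis (exterior air and the tracheal air column are removed); CT-volume
   `V_CT` is the voxel-count volume, and PD15 the nearest-rank 15th
   percentile of the voxel densities.
2. **Recalibration.** Each scan's HU values are rescaled by an affine map
   anchored to two internal references: air sampled outside the patient
   (→ 0 g/L) and blood in the descending aorta (→ 1050 g/L).  This makes
   densities invariant to any global affine drift of the scanner's HU scale.
3. **Volume correction (sponge model).** Density and volume trade off
   mass-preservingly over the respiratory cycle; empirically the log-log
   slope is slightly steeper than −1, and S = −1.1 is used:

       ρ_cor = ρ_cal · (V_CT,pred / V_CT)^S

   where `V_CT,pred = γ + δ·TLC_pred` translates predicted total lung
   capacity (ECSC/ERS reference equations, gender and height) to the
   anatomic CT-volume scale, with γ, δ fitted per gender on the normative
   cohort.
4. **Normalization.** Across normal subjects, log corrected density is
   linear in log predicted volume.  With α, β the regression coefficients
   and σ the residual SD:

       SMS = [log(ρ_cor) − (α + β·log(V_CT,pred))] / σ

   SMS ≈ 0 means normal tissue mass; |SMS| > 2 is abnormal; severe
   emphysema scores many standard deviations below zero.  For regional
   scores the lungs are cut into 12 equivolumetric craniocaudal slabs, the
   outermost two discarded, and the rest grouped apical(3)/central(3)/
   basal(4); each region has its own (α, β, σ, γ, δ).

A synthetic-data module generates voxel phantoms (body, lungs, trachea,
aorta, exterior air) and tabular cohorts with exact ground truth, built by
inverting the equations above, so the whole pipeline is testable without
clinical data.

## Worked example

```python
import lungsms as L
from lungsms.synthetic import (CohortSpec, generate_normative_cohort,
                               generate_phantom, phantom_for_subject)
from lungsms.io import SubjectRecord

# a normative cohort (n = 76) and the fitted model
cohort = generate_normative_cohort(CohortSpec(seed=7))
model = L.NormativeDensityModel(cohort, log_base="10").fit()
print(model.summary())

cv = L.loocv_sms(cohort)
print(f"held-out SMS: mean {cv.mean_sms:+.3f}, SD {cv.sd_sms:.3f}")

# a phantom with a four-sigma basal density deficit, scored end to end
spec = phantom_for_subject(model, "male", 1.76, seed=11,
                           sms_regional={"apical": 0.0, "central": 0.0,
                                         "basal": -4.0})
volume, _ = generate_phantom(spec)
print(L.score_subject(volume, SubjectRecord("demo", "male", 1.76), model))
```

prints (abbreviated):

```
Normative lung-density model
================================================================
subjects: 76    log base: 10    sponge slope S: -1.1

scope             alpha (SE)         beta (SE)     sigma
----------------------------------------------------------------
global        2.5025 (0.0357)   -0.7166 (0.0442)    0.0232
...

held-out SMS: mean +0.003, SD 1.043

Standard Mass Score report — subject demo
  recalibrated PD15 :    71.09 g/L
  CT-volume         :     7.03 L
  predicted TLC     :     6.98 L
  predicted CT-vol  :     7.03 L
  corrected PD15    :    71.10 g/L
  SMS (global)      :    -1.89  [normal]
  SMS (apical )     :    -0.01  [normal]
  SMS (central)     :    -0.00  [normal]
  SMS (basal  )     :    -4.00  [abnormal_low]
```

The fitted α, β, σ recover the cohort's generating law
(α = 2.50, β = −0.70, σ = 0.025 in log10); leave-one-out held-out scores
have mean ≈ 0 and SD ≈ 1, confirming the Z-score calibration; and the
imaging pipeline localizes the injected basal deficit (SMS_basal ≈ −4)
while apical and central regions stay normal.

A command-line interface mirrors the library:

```sh
lungsms simulate-cohort --seed 7 --n 76 --out cohort.csv
lungsms fit --cohort cohort.csv --log-base 10 --out model.json
lungsms simulate-phantom --seed 3 --out phantom.nii.gz
lungsms score --volume phantom.nii.gz --gender m --height 1.75 --model model.json
```

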