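# Methods

This note documents the model implemented by `lungsms`, the choices made
where the procedure was underdetermined, what the synthetic generators do
and do not emulate, and the package's known limitations.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement model

**Densitometry.** Lung segmentation thresholds the volume at −380 HU and
classifies the resulting connected components (6-connectivity): components
touching a lateral or inferior border are exterior air; an air component
entering through the superior border within a central in-plane band (default
half of each axis) is the trachea/main bronchi and is excluded; remaining
components above a minimum volume (default 0.05 L) are lung.  The threshold
is a parameter; lowering it can only shrink the candidate set.  CT-volume is
`voxel count × voxel volume` in liters — an anatomic quantity including
parenchyma and vessels and excluding tracheal air, hence systematically
different from physiologic TLC.

**Percentile convention.** PD15 is nearest-rank: the value at sorted rank
`ceil(0.15·n)`.  The convention is fixed and documented because interpolated
percentiles differ at small n; nearest-rank makes small-sample tests exact.

**Recalibration.** Two internal references per scan: mean HU of exterior air
(anterior to the sternum) and of descending-aorta blood.  The affine map
sending air → 0 g/L and blood → 1050 g/L is the minimal form fixed by two
anchor points.  With nominal references (−1000, +50 HU) it reduces to
ρ = HU + 1000.  Densities below measured air map to negative values and are
retained — clipping would bias PD15 upward exactly in the near-air lungs the
method targets.  The map is exactly invariant under any global affine HU
distortion when the references are re-sampled from the distorted scan; this
drift immunity is asserted end-to-end in the tests.  Automatic ROI placement
(anterior exterior band; a small cylinder at the conventional left-posterior
aorta position) is best-effort and aimed at the phantom geometry; clinical
use should pass explicit ROIs or masks.

**Volume correction.** `ρ_cor = ρ_cal · (V_CT,pred/V_CT)^S` with S < 0.
S = −1 is the strict sponge model (ρ·V conserved); the default S = −1.1 is
the empirically steeper slope reported for percentile densities, shipped as
a configurable constant because re-deriving it requires paired
inspiratory/expiratory scans that are not public.  `V_CT,pred = γ + δ·TLC_pred`
per gender; TLC_pred comes from the ECSC/ERS linear height equations stored
in `src/lungsms/data/tlc_reference.json` (male 7.99·H − 7.08 L, female
6.60·H − 5.79 L) — a configuration file, never hard-coded, so another
reference population can be substituted.

**Normalization.** The normative law regresses log corrected density on log
predicted CT-volume across controls, with σ the residual SD (n − 2 divisor).
Controls are normalized exactly like patients (recalibrate → volume-correct
→ evaluate at V_CT,pred) before fitting; this makes the training cohort's
in-sample SMS mean exactly zero (an OLS residual property, asserted at
1e−8) and its SD `≈ sqrt((n−2)/(n−1))`.  The logarithm base is a recorded
model property ('e' default, '10' supported); SMS is base-invariant because
numerator and σ rescale together, and a test asserts this.  The ±2 band is
inclusive: SMS = −2.0 is still "normal", matching the strict `< −2`
abnormality rule used everywhere (dichotomization, pattern classification).

**Regions.** Both lungs combined are cut along the craniocaudal axis into 12
slabs of equal lung volume (single global boundary set).  Boundary slices
are split voxel-wise by default so partitions are equivolumetric to within
one voxel; a whole-slice fallback exists and is flagged in the output.
Slabs 1 and 12 are discarded (partial-volume artifacts); 2–4 are apical,
5–7 central, 8–11 basal.  Each region refits its own (γ, δ, α, β, σ) on the
region's volumes and densities; regional Eq.-style scoring then mirrors the
global computation.

## Validation statistics

Cohen's κ on the 2×2 structure (SMS < −2) vs function (D_LCO < 80 %pred)
table uses the standard marginal-product expected agreement; the p-value
tests κ = 0 with the Fleiss large-sample null SE (the original analysis
software's test is not documented; this is the conventional choice).
Subjects with a missing member of the pair are excluded pairwise and
counted.  Association uses Spearman rank correlation (tie-corrected) plus
the OLS R².  Regional involvement patterns are tabulated over the eight
apical/central/basal combinations in a fixed order; the four patterns
consistent with basal-first progression (none, basal, central+basal, all
three) are flagged canonical.

## Synthetic data: what it emulates

The generators define the package's study conditions and are deterministic
given their seed.

*Tabular normative cohorts* (default n = 76, 52 male / 24 female, heights
N(1.76, 0.07)/N(1.63, 0.06) m): predicted TLC via the shipped equations;
`V_CT = (γ + δ·TLC_pred + ε_V)·f` with γ = 0.4, δ = 0.95, ε_V ~ N(0, 0.1 L)
and inspiration fraction f ~ N(1.00, 0.08) truncated to [0.75, 1.25]
(controls scanned at coached full inspiration; the spread is what makes the
inspiration-level covariate identifiable at n = 76).  Densities are written
backwards through the sponge model so that log10 ρ_cor = α + β·log10 V_pred
+ N(0, σ) holds exactly at the corrected scale, with α = 2.50, β = −0.70,
σ = 0.025.  β is deliberately shallower than S: the across-subject size
effect is weaker than the within-subject inspiration effect, which is why a
stepwise regression on raw log PD15 selects both log volume and inspiration
level.  Regional volumes are the exact 3/12, 3/12, 4/12 fractions; regional
residuals are independent draws (regional and global densities are
statistically, not voxel-wise, consistent).

*Patient cohorts* (default n = 180, 98 male / 82 female): a lognormal
tissue-loss burden (median 12 SMS units, sdlog 1.0, capped at 45 because
PD15 cannot fall below a few g/L) drives the basal region one-for-one; the
central and apical regions join after lags of 5 and 10 units (basal →
central → apical progression), each with N(0, 0.8) subject noise; the
global score is the 0.25/0.25/0.5 volume-weighted mix plus N(0, 0.3).
D_LCO %pred is linearly coupled to the standardized global score with
R² = 0.25 around a 55(19) marginal, floored at 5 %pred.  Densities are
back-computed through the normalization equations, so the tabular pipeline
recovers the generating scores to machine precision — the generators' core
inverse-construction contract.

*Voxel phantoms* (default 128³ at 3.2×3.0×3.0 mm): exterior air (−990 HU),
a superellipse-cylinder torso of soft tissue (+40 HU) with a dilated-lung
tissue shell, two ellipsoidal lungs scaled to the target volume, a tracheal
air column entering the superior border, and a blood-density aorta cylinder
(+45 HU) at the conventional position used by the automatic ROI placement.
Lung voxel densities are Gaussian (spread 15 g/L) shifted per region so each
region's nearest-rank PD15 equals its target exactly; HU values are the
inverse of the air/blood recalibration.  `phantom_for_subject` derives the
targets by inverting a normative model at requested global/regional SMS
values, using the voxelized lung volume, so pipeline scores match the
request to within percentile discreteness.  Not emulated: reconstruction
kernels and noise texture, gravity-dependent density gradients, vessels and
airways beyond the trachea, lobar anatomy, partial-volume edges (phantom
boundaries are crisp, which is why segmentation Dice is ≈ 1 rather than the
≥ 0.99 a realistic edge would give).  Passing phantom tests therefore
demonstrates the correctness of the computational pipeline, not robustness
to clinical image quality.

## Numerical and design choices

- Stepwise covariate exploration: forward entry at partial-F p < 0.05 with
  backward removal at p > 0.10 (the conventional defaults of the era's
  statistical software); categorical terms enter as dummy groups tested
  jointly; constant candidates are dropped with a warning.  With three null
  candidates, a ~5%-level entry rule admits a spurious term in roughly one
  run in seven — tests therefore assert that the true terms are found, not
  that the selected set is exactly the true set.
- Volume-translation SEs are classical OLS; heteroscedasticity-robust (HC3)
  SEs were evaluated and gave worse 3-SE coverage at the female stratum's
  n = 24, so they are not used.
- σ below 1e−12 is reported as a degenerate model (warning); Z-scores
  against a σ = 0 model raise an error rather than returning ±∞.
- Volumes are reoriented on read to a fixed convention (craniocaudal axis
  first, superior at index 0) so partitioning never depends on on-disk axis
  order; DICOM rescale slope/intercept are applied on read.
- Problem sizes in tests and the acceptance script: 200-seed calibration
  suites for parameter recovery, covariate selection and the D_LCO
  coupling; 128³ phantoms for the imaging checks — sizes at which every
  Monte-Carlo margin in the suite is several times its standard error.

## Limitations

- The recalibration is a two-point global affine; reconstruction-kernel and
  beam-hardening differences between scanners are out of scope (external
  phantom calibration and appearance normalization are known alternatives).
- Automatic aorta localization is phantom-oriented; arbitrary clinical scans
  need explicit ROIs.
- S = −1.1 is shipped as a constant; its re-estimation needs paired
  inspiration/expiration data.
- The normative machinery assumes the log-log linear law with Gaussian
  residuals; with real multi-scanner cohorts both assumptions should be
  re-examined before the Z-scores are interpreted clinically.
- No lobe segmentation, vessel removal, longitudinal progression analysis
  or survival modelling.
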