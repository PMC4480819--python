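# Methods

## Partition model

The segmentation is purely voxelwise. A voxel is MAA-positive when its
count is at least a fixed fraction (default 0.10, inclusive boundary) of
the maximum count in the MAA volume; SC-positivity is defined the same way
on the *corrected* SC volume, `max(SC − maa_scale·MAA, 0)` with
`maa_scale = 1` by default, using the corrected image's own maximum. The
subtraction exists because the SC scan is acquired minutes after the MAA
scan without moving the patient, so the lodged MAA tracer contributes to
the second acquisition. Whether the original acquisition rescaled or
decay-corrected the MAA image before subtraction is not knowable from the
outside; `maa_scale` exposes the choice. No connected-component filtering
or smoothing is applied.

The fused maps give the four-way truth table (tumour = MAA⁺SC⁻, irradiated
functional liver = MAA⁺SC⁺, unirradiated functional liver = MAA⁻SC⁺, null =
MAA⁻SC⁻ inside the liver). When no liver envelope is supplied, the envelope
is the morphological closure of the mask union — binary closing with a
6-connected structuring element followed by hole filling. Closing alone
cannot absorb a large enclosed necrotic core, yet cold cores are precisely
the dominant null-compartment structure; hole filling makes the inferred
envelope equal the voxelized liver for any phantom whose cold cavities are
fully enclosed, which is what lets noise-free recovery be exact. Voxels
double-negative and outside the envelope are background.

Volumes are voxel counts × voxel volume, reported in mL; spacing in mm;
indices 0-based.

## Dosimetry

Compartment dose is the single-compartment MIRD conversion
`(counts/total) · A · 50 / (1.029 · V)` with `A` in GBq, `V` in L, hepatic
density 1.029 kg/L and 50 Gy·kg/GBq for ⁹⁰Y. Two conventions matter:

- the normalisation denominator is the **total hepatic** MAA signal
  (tumour + FL-IR + FL-UN + null regions of the raw, unthresholded MAA
  volume), so thresholding decides attribution of numerator counts only;
  sub-threshold activity dilutes every dose rather than being
  redistributed;
- D_FL-UN ≡ 0, and D_FL-TOT spreads the FL-IR counts over the whole
  functional volume, giving the exact identity
  D_FL-TOT · V_FL-TOT = D_FL-IR · V_FL-IR.

The tumour-to-functional-liver dose ratio is reported as missing (`None`),
not infinity, when D_FL-TOT = 0. Serialized reports round doses to 0.1 Gy;
full precision is kept internally. Lung-shunt compensation is accepted as a
pre-adjusted administered activity, not computed.

Prescriptions: resin `BSA − 0.2 + LI` GBq floored at zero; glass
`D_target · m_target / 50` GBq (no decay-to-calibration correction is
modelled). Planning rules use three thresholds: D_T must exceed 32.7 Gy
(strict) for expected efficacy; cumulative functional-liver dose
(D_FL-TOT plus a scalar prior mean liver dose from DVH analysis of earlier
radiotherapy) is classified <30 Gy safe / 30–60 Gy inclusive caution /
>60 Gy (strict) high REILD risk. Activity reduction is advised in the high
band regardless of efficacy; an increase only when efficacy is unmet *and*
the cumulative dose sits in the safe band, since scaling activity raises
both doses proportionally.

## Phantom

Geometry is ellipsoid/sphere analytic: a liver ellipsoid (default
semi-axes 90 × 65 × 75 mm, ≈1.8 L) of SC-avid parenchyma containing
spherical MAA-avid tumours, each with an optional rim shell avid on both
tracers and an optional cold core. Default grid 64³ at 4.42 mm isotropic
(the matrix size of the acquisition being emulated; the voxel size printed
for that acquisition is internally inconsistent, so spacing is simply
configurable). Default relative avidities: tumour MAA 1.0, rim MAA 0.3,
parenchyma SC 1.0, background 0; default totals 5·10⁵ MAA and 5·10⁶ SC
counts (the SC tracer is administered in excess so that parenchyma
dominates the corrected image). The observed SC volume is the colloid
pattern **plus** the clean MAA counts, reproducing the residual-tracer
situation the subtraction corrects.

Degradation is an isotropic Gaussian blur (σ in mm, a resolution surrogate
— no projection/attenuation/scatter physics) applied to the clean patterns,
then voxelwise Poisson sampling seeded through `numpy.random.default_rng`.
Ground-truth labels are defined on the pre-degradation geometry; recovery
under degradation is measured as Dice overlap, and blur predictably moves
tumour-boundary voxels into the rim (FL-IR) compartment, so the
MAA-positive region is more stable than the tumour label alone. With no
noise and no blur, the default-threshold pipeline recovers the ground-truth
labels exactly and the pipeline dose report equals the closed-form
`analytic_dose` (which integrates the generative pattern over the geometric
compartments — an independent code path).

What passing noise-free tests shows is that the partition and MIRD
arithmetic are exact on data satisfying the model's assumptions; it says
nothing about reconstruction artefacts, misregistration or quantification
error in real SPECT, which the phantom deliberately does not model.

## Synthetic cohort

Each patient draws a cell type from the mix {HCC 26, CCA 18, NET 20,
CRC 29, other 29}/122, then log-normal compartment doses whose medians are
the per-cell-type cohort medians (D_T: 109.7/35/24.2/33.3/33.6 Gy;
D_FL-TOT: 55.1/24.9/23.7/27.8/29.8 Gy) with dispersion σ = 0.6 on the log
scale — a typical inter-patient spread; no dispersion is otherwise
constrained. 12 % of patients carry a prior mean liver dose (log-normal,
median 25 Gy), matching the fraction with prior hepatic radiotherapy.

Outcome models: objective response is Bernoulli with logit
`−slope·ln(32.7) + slope·ln D_T`, slope 1.2, anchored so the response
probability is 50 % at the 32.7 Gy efficacy floor. Toxicity grade change is
the number of fixed D_FL-TOT cutpoints (20/35/50/70 Gy) exceeded by a
noisy latent log dose — ordinal and monotone in D_FL-TOT on average. REILD
is Bernoulli by cumulative-dose band with risks (0, 0, 0.385). Survival is
exponential (a single printed median constrains only one parameter, so a
Weibull shape would be unidentified) with nonresponder medians
8.0/5.7/60/10.8/8.3 months by cell type (the NET median, never reached in
the emulated cohort, is represented by a finite 60 months) and a responder
multiplier 36.0/8.7 ≈ 4.14; censoring replaces the time by a uniform
fraction of it with probability 0.28 (the fraction alive at last
follow-up).

## Statistics engine

Kaplan–Meier and the unstratified log-rank delegate to lifelines; median
survival is the smallest time with S(t) ≤ 0.5 (`None` if never reached)
and survival confidence bands use lifelines' complementary log-log
(Greenwood) intervals. The stratified log-rank is computed directly:
per-stratum observed-minus-expected vectors and hypergeometric covariance
matrices (tie factor d(n−d)/(n−1)) are summed over strata
(Mantel–Haenszel pooling) and the quadratic form over any k−1 components
gives a χ²(k−1) statistic; with a single stratum this reproduces the
lifelines result, which the tests exploit as a cross-check.

Chi-squared is Pearson's statistic without continuity correction on r×c
tables with positive margins. The two-sample rank test is the two-sided
Mann–Whitney U: exact enumeration when the combined sample is ≤ 10 and
tie-free, otherwise the normal approximation with tie correction and no
continuity correction (which returns p = 1 for identical samples); three
or more groups use Kruskal–Wallis with tie correction. Toxicity grade
change is the maximum over a configurable lab panel of the per-lab
follow-up-minus-baseline increase floored at zero. REILD banding assigns
the 30 and 60 Gy boundaries to the middle band; empty bands report a
missing incidence rather than zero.

Multivariate (Cox) survival regression is out of scope; cohort tables
export as flat CSV (documented column dictionary in
`hepadose.cohort_stats.COHORT_COLUMNS`) so external fits can consume them.

## Problem sizes and numerical choices

Validation suites run phantoms at 48³ voxels (the partition is resolution-
independent, so smaller grids exercise the same logic), 100 seeds for the
noise-free oracle-equivalence check, 1000 resamples for the rank-test
type-I-error check, and n = 5000 synthetic patients for parameter recovery
(two-standard-error agreement). JSON outputs sort keys and pin float
formatting so identical inputs give byte-identical reports. All randomness
flows through seeded `numpy.random.default_rng` generators.

## Known limitations

- No projection-domain physics: attenuation, scatter, collimator response
  and reconstruction artefacts are outside the phantom's scope.
- Registration is assumed perfect (the paired scans are modelled as
  acquired without patient motion).
- The envelope inferred by morphological closure treats cold cavities
  touching the liver surface as background, not null.
- The cohort generator's covariance structure is minimal (doses independent
  within patient given cell type); real dosimetry parameters are strongly
  interrelated.
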