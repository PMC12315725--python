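# Methods

`netseg` implements a resting-state functional-connectomics analysis linking
network segregation to age and to valence bias (the tendency to judge
emotionally ambiguous faces and scenes as positive) in a cross-sectional
lifespan sample. This note documents the models, the processing rules, the
synthetic-cohort generator that stands in for raw study data, and the design
choices made where the procedure was genuinely open.

## Behavioral scoring

The valence-bias task is a two-alternative forced choice over 96 images in
four blocks (two face, two scene), each block holding 12 ambiguous and 12
clearly valenced trials (6 positive, 6 negative). Valence bias is the
percentage of answered ambiguous trials categorized as positive; clear-trial
accuracy gates inclusion at 60% (accuracy strictly below the cutoff
excludes). Omitted responses are removed from both numerator and
denominator: a non-response is not a categorization. Faces and scenes pool
into a single bias score; whether the accuracy criterion should be applied
per block is unknowable from the published rule, so it is pooled.

## Motion QC and time-series cleaning

Framewise displacement (FD) is the sum of absolute frame-to-frame changes in
three translations (mm) plus three rotations converted to mm on a 50 mm
sphere — the radius is the field's standard convention, not a published
value. The six realignment traces are low-pass filtered before differencing
(zero-phase 2nd-order Butterworth, default cutoff 0.1 Hz, configurable),
suppressing respiratory pseudo-motion so that genuine displacement steps,
not Nyquist-rate oscillation, drive censoring.

Censoring applies three rules in order, within runs only: frames with
FD > 0.2 mm are removed; surviving contiguous segments shorter than 5 frames
are removed; runs retaining fewer than 50 frames are dropped whole. Subjects
with fewer than 800 surviving frames are excluded (a reportable status, not
an error); for the rest, the earliest 800 surviving frames in acquisition
order are analyzed and later frames discarded, equalizing data quantity
across subjects.

Cleaning runs per functional run in a fixed, recorded order: demean/detrend
(OLS removal of constant and linear trend) → nuisance regression →
interpolation over censored frames → zero-phase band-pass
(0.009–0.08 Hz, 2nd-order Butterworth) → re-censoring. The nuisance design
has 27 columns: the 24-parameter motion set (parameters, backward
differences, squares of current and one-frame-lagged parameters — one
standard realization of the Volterra expansion, whose exact column count is
a convention), the global signal (mean ROI time course), and two tissue
signals. ROI-level tables carry no tissue masks, so the tissue columns are
synthesized white noise placeholders; they cost two degrees of freedom and
nothing else. Nuisance coefficients are estimated on retained frames only,
so censored spikes exert no leverage, but fitted values are subtracted
everywhere. Interpolation is linear by default (least-squares sinusoid
reconstruction available by config); it exists solely to keep censored
spikes from ringing through the band-pass filter, and censored frames stay
censored afterwards. Rank-deficient designs drop collinear columns with a
warning rather than failing. Per-subject RMS-FD is computed over all frames
of included runs (retained-only is a config choice).

## Connectivity and segregation

Pearson correlations over the selected frames (pooled across runs) are
Fisher z-transformed (|r| clipped to 1−1e−7; diagonal excluded). The
300-ROI parcellation carries 14 network labels; the two somatomotor
networks merge into one and unassigned ROIs are dropped, leaving 12
analysis networks. Negative z values are set to zero before any averaging —
global-signal regression manufactures spurious negatives — and the same
thresholded matrix feeds both segregation and the pairwise
network-to-network means used as DMN predictors (unthresholded pairwise
means are available by config).

Per network k: within-network connectivity Zw_k is the mean z over
unordered ROI pairs inside k; between-network connectivity Zb_k is the mean
z from k's ROIs to all ROIs outside k (whole-brain reading, not a mean of
pairwise means); segregation S_k = (Zw_k − Zb_k)/Zw_k, undefined with a
warning when Zw_k ≤ 0. Global summaries weight networks equally regardless
of size: W and B are unweighted means of Zw_k and Zb_k, and
S_global = (W − B)/W; the alternative global summary (unweighted mean of
S_k) is also reported. Segregation is scale-invariant and bounded above
by 1.

## Statistical models

Age is standardized; by default with sample statistics, or with a fixed
mean/SD (`AgeScale`) when mapping standardized boundaries back to years.
RMS-FD is regressed out of every connectivity measure before modeling
(residualization, not covariate adjustment); age enters the bias models as
a covariate, not by residualization. One extreme-outlier screen
(median ± 3×IQR, rule configurable — the published analysis names the
removal but not the rule) runs on global segregation before the age models.

Age models are OLS on {1, age_z} and {1, age_z, age_z²}; in auto mode the
quadratic model is reported only when its squared term is significant at
p < .05 (an interpretation: published tables show quadratic terms only
where significant), with a numerical guard treating machine-zero curvature
as absent. Per-network model-fit p-values are Benjamini–Hochberg
FDR-corrected across the 12 networks.

The DMN follow-up regresses bias on standardized age (forced) plus the 11
DMN pairwise between-network connectivities, then removes candidates by
backward elimination on the Akaike information criterion: at each step the
removal most decreasing AIC is accepted, stopping when no removal decreases
it, ties broken lexicographically for determinism. An optional
change-in-estimate guard (retain a candidate whose removal shifts any
remaining coefficient by >20%) approximates "augmented" elimination; it is
off by default because the augmentation rules of the original selection
package are not published. Each surviving term's age interaction is then
screened one-at-a-time at α = .05, and significant interactions enter the
final model jointly.

For a retained interaction, the conditional slope at moderator value a is
B_focal + B_int·a with variance V_f + a²V_i + 2aC from the coefficient
covariance; simple slopes are reported at a ∈ {−1, 0, +1} SD. The
Johnson–Neyman boundaries solve (B_f + B_i a)² = t²_crit(V_f + a²V_i + 2aC)
by the quadratic formula, using the pointwise two-sided critical t at the
final model's residual df (an uncorrected region, the common convention),
reported in standardized units and in years; with no real roots the slope
is significant everywhere or nowhere, decided at a = 0. Boundaries are
invariant to affine rescaling of the outcome. Models refuse to fit with
n ≤ terms + 2 rather than regularize silently.

## The synthetic cohort generator

The generator emulates the study conditions so the whole chain is testable
without any data deposit: 250 subjects by default, ages uniform on 6–80
(population SD ≈ 21.4 years, close to the kind of lifespan sample the
analysis targets), 300 ROIs in 14 networks of equal size with the remainder
labeled unassigned (network size is deliberately not load-bearing:
segregation is uncorrelated with size), 1000 frames per subject at TR = 1 s
in two runs.

Planted structure, all in Fisher-z units per standardized-age unit:
within-network targets 0.60 − 0.05·a plus per-network subject noise
(SD 0.05); between-network targets 0.15 + 0.02·a − 0.01·a² (an inverted U)
plus per-pair subject deviations (SD 0.14). ROI time series come from
correlated network factors: ROI i in network k is
λ_k f_k + √(1−λ_k²) ε with λ_k = √r_within,k and factor correlations
Φ_kl = r_between,kl/(λ_k λ_l), eigenvalue-clipped to the nearest
correlation matrix when indefinite. The recorded ("planted") targets are
always the realized, post-projection values, so fidelity tests are exact:
with ≥10,000 frames, empirical block correlations match them within ±0.02.
The projection is also a real constraint: independent pairwise deviations
much larger than ~0.1 z are not jointly realizable as a correlation matrix,
which caps how much subject-level between-network variance any generator of
this form can plant.

Valence bias is built from age and the planted DMN pairwise deviations
(pair z minus its age baseline): 50 + 5·a + 70·d(DMN,CO) + 20·d(DMN,VAN)
− 55·d(DMN,Reward) − 70·a·d(DMN,Reward) + N(0, 8), clipped to [0, 100]
(clipping never binds at the defaults). Three points matter here. First,
these are true-scale structural coefficients: the measurement chain
(band-pass df loss, global-signal regression, negative thresholding, PSD
shrinkage) attenuates measured pairwise z to roughly a third of the planted
scale, so recovered coefficients on measured connectivity are much larger
than their published-table analogues, and the planted values were sized by
a power analysis so each effect survives AIC selection (|t| ≳ 1.4) at
n = 250 — the generator encodes effect *directions* and detectability, not
printed magnitudes. Second, a negative DMN–Reward main effect is planted
alongside the interaction: with symmetric standardized age a pure crossover
interaction leaves cov(bias, z_Reward) ≈ 0, the main term is then
AIC-eliminated before interaction screening can ever see it, and the
published final model itself carries a negative main coefficient. Third,
trial tables draw Bernoulli responses (positive with probability bias/100),
so scoring recovers the planted bias only in expectation; an exact-counts
mode plants round(bias·48/100) positives for tests that need exact
round-trips.

Motion traces are a low-amplitude random walk (translation diffs SD
0.01 mm, rotations two orders smaller) plus sustained ~1 mm translation
steps at a spike rate that is U-shaped in age
(0.005 + 0.02·((age−43)/37)²) — children and older adults move more. Each
spike censors a small cluster of frames after FD filtering; at the default
rates nearly all subjects clear the 800-frame requirement, with occasional
realistic losses at the age extremes.

What the generator does *not* emulate: hemodynamic autocorrelation and
spatial noise structure, scanner drift/physiological confounds beyond the
nuisance placeholders, real parcellation geometry, distance-dependent
motion artifact, and any non-Gaussian behavior of real bias scores.
Passing recovery tests therefore show that the pipeline correctly extracts
the structure this model plants through a realistic processing chain — not
that it would be unbiased on arbitrary real data.

## Problem sizes and runtime choices

The heavy validation suites run at the sizes stated above: sign recovery on
100 seeded cohorts of 250 subjects through the full time-series pipeline
(the dominant cost; the generator and cleaning stages are numpy-only for
this reason), 95%-CI coverage of the planted bias-model coefficients on 200
seeded cohorts, and null-calibration (5% ± 2% rejection at α = .05) on 400
seeded cohorts. Coverage and null calibration are evaluated on the
generator's planted subject-level quantities rather than re-estimated
connectivity: they are statements about the fitting stage's calibration,
and measurement attenuation — which would bias coverage of true-scale
coefficients — is exercised separately by the end-to-end sign-recovery
suite. The demo pipeline (20 subjects) runs end to end in a few seconds.

## Known limitations

- The elimination procedure approximates the original "augmented" selection
  with plain AIC backward elimination plus an optional change-in-estimate
  guard; selection paths can differ from the original package's.
- Tissue nuisance signals are placeholders; with real CSF/WM traces the
  27-column design would remove genuine physiological variance.
- The whole-brain Zb reading and the thresholded pairwise predictors are
  documented choices among defensible alternatives, both config-exposed.
- Johnson–Neyman regions use pointwise α; no simultaneous correction.
- The generator's uniform age distribution and equal network sizes are
  simplifications; both are configurable.
- Global-signal regression recenters between-network correlations near zero
  and compresses their variance, so while the inverted-U age profile is
  planted in the between-network *targets* (and visible there), the
  measured between-network age model typically comes out flat in synthetic
  runs — a faithful reproduction of what GSR does to weak between-network
  signal, not a pipeline defect.
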