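# Methods

This note documents the models, numerical choices and limitations behind
`leafspec`, in the order data flows through the package.

## Synthetic data model

All analyses run on generated data whose statistical structure mirrors the
three study designs (leaf spectroscopy, leaf imaging, grain + RIL
genetics). The generators are first-class, tested code; every planted
effect is returned as ground truth.

**Latent growth.** One scalar per sample,
g = (DAT − min DAT)/(max DAT − min DAT) ∈ [0, 1], where DAT is days after
transplanting. The same g drives both the leaf spectra and the
transcript-cluster trajectories, which is the minimal structure under which
predicting expression from spectra is possible at all: the spectrum is
informative about expression exactly insofar as both reflect growth stage.

**Leaf reflectance** on wavelength λ is a smooth vegetation-like continuum
(dark visible region, logistic red edge near 710 nm, water dips at 1450 and
1940 nm) plus four planted effects in named windows:

| effect | window (nm) | form | default amplitude |
|---|---|---|---|
| pigment absorption | 675–695 | depth 0.09·(1 − g/2) Gaussian at 675 | decreases with growth |
| red-edge shoulder | 725–765 | 0.05·g Gaussian at 745 | increases with growth |
| subspecies (indica − japonica) | 580–655 | Gaussian at 617 | 0.02 |
| soil condition (alluvial − andosol) | 1600–1650 | flat-topped window ×(1 − g) | 0.03 at 1630 nm |

i.i.d. Gaussian channel noise, SD 0.001 reflectance — the signal-to-noise
class of a bench scanning spectrometer on dried ground samples. This is the
parameter that decides whether derivative pretreatments help or drown:
second-derivative filters amplify white channel noise by orders of
magnitude, so the noise floor is set to the instrument class the pipeline
targets, not to camera-like noise (camera noise enters the imaging study
per pixel instead, default SD 5 counts against a gain of 2000, and averages
down by the ROI size). Spectral archetypes are stylised (no
radiative-transfer leaf model); what the tests establish is recovery of
*planted* window effects, loadings and trajectories, not agreement with any
real instrument.

**Cluster expression.** Cluster j is an affine function of g:
archetypes monotone-down (−slope), monotone-up (+slope) and flat-noisy
(slope 0) cycle through the cluster list, with noise SD 0.1 on a slope of
1.0 and a subspecies offset of 0.3 on every 9th cluster. With nine design
DATs, var(g) ≈ 0.117, so a perfectly predicted monotone cluster has an R²
ceiling of var(signal)/(var(signal) + σ²) ≈ 0.92 — the headroom against
which the R² > 0.8 recovery checks operate. Flat-noisy clusters carry no
predictable signal and bound LOOCV R² at ≤ 0.

**Image cubes.** A raw capture is Ir = Id + gain·ρ (+ pixel noise), with
white cube Iw = Id + gain and dark cube Id constant; ρ is the scene
reflectance (elliptical leaf over a dark background sheet, 0.05). The
planted leaf mask is returned, so ROI extraction can be scored exactly.

**RIL panel.** Genotypes are simulated chromosome-wise as a two-state
Markov chain: start allele uniform, switch probability per interval
R = 2r/(1 + 2r) (the selfed-RIL expansion) with meiotic r from the inverse
Kosambi function of the interval length. Lines are fully homozygous; there
is no genotyping-error model. The default map places 175 markers on 12
chromosomes (15 on seven, 14 on five) at uniform 10 cM spacing —
configurable, since a real marker-to-chromosome assignment is not part of
the generated world. Phenotypes are trait baselines plus planted additive
effects (effect = A-minus-B mean difference on a ±0.5 coding) plus N(0, 1)
noise. Grain spectra per line add genotype-linked Gaussian window bumps
(width 25 nm — absorption-band-like features narrow enough to survive
second-derivative pretreatment) to a grain continuum with smooth per-line
polynomial deviations.

## Pretreatment

Pipeline order is fixed: absorbance (spectrometer data only) → SNV (if on)
→ smoother/derivative → mean-centering (± autoscaling). Choices where
conventions differ:

* SG polynomial degree 2 for both SG1 and SG2 (the common chemometrics
  default), window 11 for all smoothers; both exposed as parameters.
* Edge handling: all windowed filters return the valid interior only
  (band count shrinks by window − 1), rather than padding — fabricated
  boundary values would perturb PCA loadings. Trimming is identical across
  rows, so matrices stay rectangular.
* Derivatives are per band-index step; on a uniform grid this differs from
  d/dnm by the constant 1/step, which is immaterial after autoscaling.
* SNV precedes the derivative (matching the "SNV + SG1" naming order).
* All SDs use the n − 1 denominator. Zero-variance columns are dropped
  with a warning at the centering step; centering/scaling statistics are
  stored and re-applied to held-out rows.

SNV, smoothing and derivatives act on one spectrum at a time, so they are
computed once before cross-validation; only the column statistics (and the
models) are refit inside every fold — the leakage-free protocol.

## Imaging

Correction is elementwise Ic = (Ir − Id)/(Iw − Id); references may be full
cubes or per-band profiles (broadcast). The ROI threshold rule is not a
published constant, so the default is Otsu's method on the score image
(780 nm band for VIS-NIR, mean of 1260 and 1290 nm for NIR) followed by
keeping the largest 4-connected component; a fixed threshold can be passed
instead. Otsu on a 256-bin histogram is invariant to positive linear
rescaling of the scores, which the tests assert. The sample spectrum is the
unweighted per-band mean over ROI pixels.

## NDSI

All unordered band pairs j > i, value (Rj − Ri)/(Rj + Ri), computed on
(smoothed) reflectance before any centering — the quantity is undefined for
derivative-stage data and the code refuses it. The pair count is quadratic
in bands, so grids beyond 256 bands require an explicit `force` (the
imaging grids have 101/71 bands; the 4200-channel spectrometer grid is not
a sensible NDSI substrate without subsampling).

## PCA and PLS

PCA is the SVD of the centered (optionally autoscaled) matrix; explained
variance ratios come from the squared singular values. The sign of each
component is fixed by making its largest-magnitude loading positive, so
score plots reproduce across runs and BLAS builds. Factor loadings are
Pearson correlations between pretreated variables and a score vector;
constant variables yield NaN and a flag rather than silent dropping.

PLS uses SIMPLS; for a univariate response NIPALS produces the same
prediction operator and is kept behind a flag as an internal cross-check
(both are also checked against an external reference implementation in the
tests). The coefficient path for 1..A components is stored, so
leave-one-out CV fits each fold once and evaluates every component count.
CV quality is R² = 1 − PRESS/SST about the overall response mean (can be
negative); the squared-correlation variant of R² is easy to compute from
the reported predictions but is not the selection criterion. The best
component count is the argmax with ties resolved toward fewer components;
the cap is min(10, n − 2, p) by default.

## QTL mapping

* **Map functions.** Kosambi d = 25·ln((1 + 2r)/(1 − 2r)) cM, inverse
  r = ½·tanh(d/50); RIL expansion R = 2r/(1 + 2r) and its inverse
  r = R/(2 − 2R). Map estimation converts adjacent-marker discordance
  frequencies (marker order taken as given) through the shrink + Kosambi
  chain; intervals whose observed R reaches 0.5 are flagged unlinked and
  capped at R = 0.49 for position bookkeeping.
* **Interval mapping.** At each grid position (default step 1 cM; the
  permutation studies use 10 cM, where scan positions coincide with the
  uniform marker grid), each line's probability of the A allele is the
  Markov two-point value from its nearest informative flanking markers
  (single flank at chromosome ends or across missing calls; 0.5 with no
  information). A two-component normal mixture with those fixed per-line
  mixing weights — class means and one common variance — is fit by EM
  (tolerance 1e-6 on the log-likelihood, max 100 iterations, positions
  flagged if unconverged), and LOD = (logL₁ − logL₀)/ln 10 against the
  single-normal fit, clipped at 0. At a fully genotyped marker the weights
  are indicators, EM converges immediately, and the LOD equals the
  marker-regression closed form (n/2)·log10(RSS₀/RSS₁) — asserted to 1e-6.
  The EM is vectorised across phenotype vectors, which is what makes
  permutation studies cheap: genotype probabilities are computed once per
  position and shared.
* **Thresholds.** Phenotype permutations (default 1000; the pipeline
  default is 200 at its reduced scan grid), threshold = type-7 quantile of
  the max-LOD distribution at 1 − α. Type-7 is pinned for bit
  reproducibility. The operating-characteristic check simulates fresh null
  panels and verifies that a panel's own null scan exceeds its own
  permutation threshold in ≈ α of replicates (measured 5.5% ± 1.1% at
  α = 5% over 400 panels). Note this guarantee is about the phenotype that
  was permuted; thresholds re-used for a different, independent phenotype
  are anti-conservative because quantile-estimation noise enters the
  exceedance probability convexly.
* **Extraction.** Contiguous supra-threshold runs per chromosome collapse
  to their peak; support intervals extend while LOD stays within 1.5 of
  the peak (the community convention, configurable). Co-localization flags
  pairs of different traits with overlapping support intervals on the same
  chromosome.
* **PC-score traits.** Grain spectra per form (ground powder P, intact
  brown grain B) are pretreated with SG2 + scaling, split into
  ALL (450–2499.5), VIS (450–750) and NIR (750–2499.5 nm), and the first
  10 PC scores per form × region become 60 traits named like `P_A_PC9`.

## Pipeline and problem sizes

Each study runner expands one global seed into per-stage substreams by
hashing stable labels, so adding draws to one stage never shifts another;
runs write a manifest (config, seed, output SHA-256) sufficient for bitwise
reproduction, which the tests assert.

Defaults are chosen to keep a full run in minutes on one core while
preserving the study designs exactly: sample counts, design factors and
marker panels are never reduced, but the leaf-spectroscopy runner samples
the spectrometer range at 2.5 nm (841 channels) rather than 0.5 nm — the
planted features are ≥ 16 nm wide, so the coarser grid carries the same
information — and the grain-QTL runner scans at 10 cM with 200
permutations per trait. The acceptance script's permutation study uses the
full 96 × 175 panel with 500 permutations per replicate. All of these are
config keys, not constants.

## Known limitations

* Spectra are additive-Gaussian archetypes: no multiplicative scatter,
  baseline drift, instrument line-shape, or water-band saturation, so
  pipelines whose whole point is scatter correction (SNV) are exercised
  for correctness, not advantage.
* The growth model is linear in DAT and shared exactly between spectra and
  expression; real cluster trajectories are nonlinear and only partially
  growth-driven, so absolute R² values here say nothing about field data —
  only the contrasts (monotone vs flat, SG2 at matched SNR) transfer.
* The RIL model ignores residual heterozygosity, segregation distortion
  and genotyping error; interval mapping fits a single-QTL model per
  position (no composite interval mapping or epistasis).
* Marker order is taken as given in map estimation; ordering is not
  re-estimated.
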