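# Methods

## Parcellation and lobe grouping

The default atlas carries 34 named cortical structures per hemisphere,
grouped into six lobes — prefrontal (10 names), motor and sensory (4),
occipital (3), lateral temporal (6), medial temporal (5), parietal (6) — plus
two subcortical placeholders per hemisphere (striatum, thalamus) in an
`other` group, for 72 regions.  The placeholders exist only to give the
connectivity matrices their full 72×72 dimension; they are excluded from
every lobe-strength statistic, and the tests verify that poisoning their
edges changes no result.  Two assignments are anatomically surprising but
kept exactly as the grouping convention this package follows prints them:
*pericalcarine* and *posterior cingulate* belong to the parietal group.
Matrix order is fixed as all left-hemisphere regions in table order, then the
right hemisphere; serialization preserves indices exactly.

## rs-fMRI conditioning

Order of operations: band-pass filter, grand-mean scale, nuisance
regression, with the nuisance regressors passed through the same filter
before removal so out-of-band nuisance energy cannot leak back in.

* **Band-pass 0.01–0.08 Hz.**  Default is a zero-phase forward–backward
  Butterworth filter of order 4 (`scipy.signal.sosfiltfilt`); an ideal
  brick-wall FFT filter is available as `method="fft"`.  No specific kernel
  is canonical for this step, so correctness is specified by frequency-
  response bounds (passband RMS ≥ 0.9, stopband RMS ≤ 0.1 at 0.18 Hz with
  TR = 2.3 s), which both implementations satisfy.
* **Grand-mean scaling to a "modal value" of 100** is implemented as global
  *mean* = 100.  The mode of a continuous signal is ill-defined, and Pearson
  correlations are provably invariant to any single-scalar rescaling, so the
  interpretation cannot affect any downstream network.  After high-pass
  filtering the global mean is ~0 and the rescale is skipped as undefined
  (and, for correlations, irrelevant).
* **Nuisance regression** residualizes each series on an intercept plus the
  supplied regressors by least squares; residuals are orthogonal to every
  regressor to 1e−8 by construction.  Rank-deficient designs are refused
  with the collinear columns named.  Regressor temporal derivatives are not
  added: only the named columns (six motion parameters, white-matter and
  ventricular means) are used.

## Network construction

The structural weight A_ij = 2·Fcount_ij/(C_i + V_j) adds a fiber count
(dimensionless) to a volume (mm³).  The units are deliberately
heterogeneous; the expression is a normalization heuristic and is
implemented exactly as defined rather than "fixed".  Fibers shorter than
10 mm (strictly: length < 10 retained ⇔ excluded; a 10.0 mm fiber is kept)
and loops (seed region = end region) are excluded before tallying; "passing
through region j" is operationalized as the record's end region, since path
traversal is not reconstructible from count matrices.  Fiber counts may be
supplied pre-tallied or as raw records; both meet at `structural_network`.
Functional weights are raw Pearson r — no Fisher transform, no
thresholding — with the diagonal of both matrices fixed at 0.

## Standardization conventions in the age models

The outcome and every continuous predictor are z-scored (sample sd,
ddof = 1); sex enters as its 0/1 code, so β_sex is semi-standardized
(standardizing a binary dummy would only rescale its own coefficient).  A
standardized β for a single continuous predictor then equals the Pearson
correlation, which the tests verify numerically.

The full model's quadratic term is the z-score of **raw** age², not of
centered-age².  Raw Age and Age² correlate at ≈0.99 over a 21–80 cohort, so
the two standardized coefficients are individually inflated and can exceed 1
in magnitude while jointly describing a modest inverted U — which is how
published inverted-U effects of magnitude ≈ −1.5 arise.  Centering before
squaring spans the same column space (identical fit, residuals and
quadratic-term p-value) but cannot produce such coefficients: with an
orthogonalized design a unit-variance outcome forces |β₂| ≤ 1.  Since this
package both reports and *plants* quadratic effects on the printed scale,
the collinear parameterisation is the coherent choice.  Correspondingly, the
generator's `complement_linear` option augments the linear coefficient by
−corr(z_age, z_age²)·β₂ — the minimum-variance inverted-U — because a
planted β₂ = −1.5 alone would imply a latent variance of 2.25 > 1.

OLS inference uses t distributions (delegated to statsmodels, cross-checked
against an independent normal-equations solver to 1e−10); mediation z
statistics use the standard normal.  All three Sobel-family variants are
computed; Sobel is the default for reporting and classification.  The
Goodman variant's radicand can be non-positive, in which case it is flagged
missing (NaN), never fatal.  Bonferroni families follow the reported tables:
5 for the prefrontal–posterior family, 3 for the occipital–posterior family
(configurable); threshold α/m and adjusted p = min(1, m·p) give identical
rejection sets.

The full/partial/none mediation rule is a pragmatic operationalization:
*full* requires a significant total age effect and Sobel z with a
non-significant mediator-adjusted direct effect; *partial* keeps the direct
effect significant; everything else is *none*.

## Synthetic cohort generator

The generator emulates the study conditions end to end.

* **Demographics** default to the stratified design: decade strata of
  32/24/27/42/48 subjects (173 total) drawn from truncated normals with the
  per-decade means 25.6/34/44.8/54.8/67.4 and SDs 2.22/2.54/2.68/3.11/4.83,
  female fractions 56/50/63/60/71 %.  A uniform 21–80 mode with configurable
  n is available for simulation studies.
* **Planting convention.**  Effects are planted on the standardized scale:
  latent strength s = β₁·z(age) + β₂·z(age²) + β_sex·sex + σ·ε with σ chosen
  to complete the sample variance to 1, so the planted coefficients *are*
  the standardized estimands the stats module reports.  Mediation pathways
  use the path equations M = a·z(age) + e_M, Y = c′·z(age) + b·M + e_Y, both
  completed to unit variance; the implied total effect is c′ + a·b.
  Infeasible requests (deterministic variance ≥ 1, |a| ≥ 1) are errors, not
  silent rescalings.
* **Functional data.**  Each subject gets a target correlation matrix:
  within-lobe base 0.65, between-lobe base 0.1, planted lobe-pair blocks set
  to 0.2 + 0.2·s (clipped 0.05 below the within-lobe base, because a
  between-block correlation above the within-block level is indefinite).
  The target is projected to the nearest positive-definite correlation
  matrix by iterated eigenvalue clipping (floor 1e−6) with unit-diagonal
  renormalization to 1e−8; the projection's effect on planted block means is
  recorded per subject and is ~1e−16 under defaults (the < 0.02 diagnostic
  bound is enforced in tests).  T = 156 Gaussian samples at TR = 2.3 s
  (floor(360 s/2.3 s), the 6-minute acquisition) are drawn through the
  Cholesky factor, then a 1000-unit baseline, per-region linear drift and
  eight broadband nuisance series (six motion-like, down-weighted ×0.3, plus
  white-matter and ventricular signals) with random loadings are added; the
  nuisance series are also emitted for the preprocessing stage to remove.
* **Measurement attenuation.**  A lobe-pair mean of T = 156 band-limited
  correlations carries sampling noise of sd ≈ 0.09 (the band keeps ~1/3 of
  the spectrum, and pair errors are correlated through shared region
  series).  Recovered standardized βs are therefore attenuated by
  σ_s/√(σ_s² + ν) — classical errors-in-variables.  The between-subject
  scale σ_s = 0.2 was chosen so this attenuation stays ≈ 0.91, keeping
  end-to-end recovery of a planted β = 0.25 within ±0.05.  Structural
  strengths have no analogous noise (integer rounding only), so their
  closed loop is nearly exact.
* **Structural data.**  Per-region seed voxel counts ~ U(100, 500), volume =
  voxels × 27 mm³ (3 mm isotropic), 1000 streamlines per voxel.  Planted
  symmetric weights w (background 0.003, planted blocks 0.004 + 0.0008·s,
  floored at 0) are inverted to counts via fcount_ij = round(w_ij·(C_i +
  V_j)/2), making the forward equation the single source of truth; round-trip
  error is bounded by integer rounding (< 1%, typically < 0.01%).  Weights
  implying more fibers than were sampled are an error (infeasible density).
  An optional record mode expands tallies into per-fiber records (lengths
  U(10, 120) mm) plus decoy loops and sub-10 mm fibers to exercise the
  filter; it is practical only at toy scales.
* **Thickness** is linear atrophy: intercept 2.8 mm at age 21, default
  decline 0.005 mm/yr, Gaussian noise sd 0.05 mm, floored at 1.0 mm.  A lobe
  named as a mediation mediator instead receives mean − 0.15·M mm, tying it
  to the planted pathway with atrophy in the thinning direction.
* **Reproducibility.**  All randomness flows through `numpy` SeedSequences
  keyed by (seed, subject index, purpose stream), so cohorts are bit-
  reproducible and stable under subject subsetting; the CLI writes a
  manifest with SHA-256 checksums.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic response shape and temporal
autocorrelation of BOLD (samples are white within the target correlation
structure), spatial voxel-level structure and registration error, head
motion beyond generic broadband nuisance, non-Gaussian fiber-count
dispersion, hemispheric asymmetries, and any true biological coupling
between the functional and structural modalities (their planted effects are
independent unless a mediation pathway links them).

## Numerical choices and degenerate inputs

Exactly symmetric matrices are enforced at construction (network builders
symmetrize explicitly; file round trips re-symmetrize against decimal
formatting).  Zero-variance series, empty lobes, empty ROIs, rank-deficient
designs and constant outcomes are all named errors; empty ROIs after voxel
aggregation are flagged rather than fatal, and refused only at correlation
time.  Minimum sample sizes: 10 for the reduced/adjusted models and
mediation, 12 for the full model.  Default planted effect magnitudes mirror
the signs and rough sizes of the emulated findings (e.g. structural
prefrontal–temporal increases ≈ 0.28, occipital–lateral-temporal mediation
a = 0.42, b = 0.40, c′ = 0.12, total 0.288) and are illustrative, not
calibrated to any dataset.

## Problem sizes used in validation

The test suite and acceptance script run parameter recovery at the study's
n = 173 with 500 replicates (statistics level), mediation operating
characteristics at n = 173 with 500 replicates, the functional closed loop
at a reduced scale (18-region three-lobe atlas, n = 100 subjects, 60
replicates), preprocessing recovery over 50 subjects at T = 156, and one
full 173-subject, 72-region, two-modality pipeline run.  These sizes were
chosen to make every stochastic check reproducible in a few minutes on a
single CPU while keeping Monte Carlo error well below each tolerance.

## Known limitations

No bootstrap mediation confidence intervals or structural equation models;
no FDR alternatives to Bonferroni; no graph metrics beyond connectivity
strength (no efficiency, modularity or edge-wise statistics); no image-space
preprocessing (slice timing, motion correction, distortion correction,
segmentation) — the pipeline starts from ROI series and fiber tallies.  The
head-motion quality metric used for cohort exclusion in typical studies is
not modelled.  Which two regions complete the 36-per-hemisphere parcellation
is not defined by the grouping table; the placeholders are configurable.
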