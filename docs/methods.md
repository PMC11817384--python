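# Methods

## The measurement model

A dried-laver sheet is imaged by a SWIR pushbroom scanner as a cube of
`lines × samples` pixels by 288 bands on a uniform 980–2576 nm axis
(step ≈ 5.57 nm). Each tissue pixel follows a Beer–Lambert-style
reflectance model

    R(λ) = B(λ) · exp(−Σ_k c_k A_k(λ)) + ε,

where `B` is a smooth quadratic baseline (≈ 0.56 at 980 nm falling to
≈ 0.36 at 2576 nm), `c_k` are the constituent concentrations and
`A_k(λ)` is a sum of Gaussian absorption bands per unit concentration.
The band library places moisture (O–H) features inside 1396–1468,
1885–1984 and 2543–2576 nm; protein (amide/carboxyl) features inside
1691–1746, 1896–2032 and 2455–2576 nm; and polysaccharide (C=O / C=C)
features inside 2045–2261 and 2554–2576 nm. Cutting stress — a texture
index measured in kg·mm — enters as the concentration of a latent
polysaccharide density with an identity map onto the kg·mm scale, since
sheet toughness is carried by the polysaccharide matrix. The exponential
form is monotone in every constituent (more constituent, deeper band)
and invertible, which makes closed-form oracle tests possible.

Peak absorbances per unit concentration (0.022 at 1935 nm for moisture,
0.005 at 1964 nm for protein, 0.45 at 2150 nm for polysaccharide) were
set so that the three indices, over their realistic ranges
(moisture 6–13 g/100 g, protein 28–45 g/100 g, cutting stress
0.2–0.62 kg·mm), produce band depths of roughly 10–35% — visible
structure without saturating the exponent.

## What the generator emulates — and what it does not

A generated sheet is the record's spectrum modulated by a smooth
multiplicative spatial field (±10%, bicubic interpolation of a 5 × 5
random grid, normalised to unit spatial mean so that it models
within-sheet texture rather than sheet-level brightness, which the
white-reference calibration absorbs). Pore pixels — an exact rounded
count at the configured fraction, placed uniformly at random — are
replaced by spectrally flat bright values in 0.90–1.00, resembling the
white scanning background. I.i.d. Gaussian noise (default sd 0.01
reflectance) is added per pixel-band. Each sheet comes with a smooth
white-reference cube (±2% field around 1) whose field also multiplies
the raw sheet cube, so calibration is a real operation, not a no-op.

Quality-index values are drawn per grade combination from truncated
normals. Dried-laver articles are discrete products whose grade groups
separate under one-way ANOVA with Tukey's HSD, so adjacent grade
clusters keep margins of at least ~1.5 within-cluster standard
deviations around the grading cut points (moisture grade 1 up to
11.3 vs grade 3 from 12.15 g/100 g; protein 36.0/34.5 and 30.5/29.7;
cutting stress 0.47/0.435 and 0.345/0.315 kg·mm). Without these margins
the two quality zones are not linearly separable even given the true
concentrations — the zone rule is a logical AND over three thresholds,
and products straddling a cut make its corner unresolvable for any
linear classifier — which would contradict the Tukey-separated product
structure the generator is meant to emulate. The default class mix puts
equal weight on six grade combinations, two of them zone 1, apportioned
by largest remainder; a top-level seed fans out to per-sheet seeds via
`numpy.random.SeedSequence.spawn`, so datasets are bit-reproducible.

Deliberately not emulated: radiometric camera effects (exposure, scan
speed, detector nonlinearity), spatially correlated or heteroscedastic
noise, pore morphology (real pores are connected blobs; here they are
random pixels, which is conservative for fraction recovery but not for
morphology-sensitive methods), scattering artefacts that SNV/MSC
preprocessing targets, and the wet-lab replicate error of the reference
assays. Passing tests therefore show that the analysis chain recovers
what this model plants; they do not certify performance on real
instrument data, where scatter effects and continuous (non-clustered)
composition distributions will lower accuracy.

## Segmentation

ISODATA runs on full pixel spectra: nearest-centroid assignment
(Euclidean), removal of clusters under 20 pixels, centroid update,
merging of centroids closer than 0.02 RMS-per-band reflectance, and
splitting of clusters whose widest band standard deviation exceeds 0.05
while under the 100-class cap. Convergence is fewer than 5% of pixels
changing assignment, with at most 10 iterations. Initial centroids are
the mean spectra of 5 brightness-quantile bins, which makes the
algorithm fully deterministic and invariant to pixel ordering (a seeded
k-means++ start was considered and rejected for exactly that
invariance). A cluster is pore when its mean spectrum is bright (mean
reflectance ≥ 0.6) and flat (cosine similarity ≥ 0.995 to the white
spectrum, default a unit vector); tissue spectra, with their absorption
structure, sit near cosine 0.98 and well below 0.6 mean, so the two
thresholds are not delicate. If every cluster looks like pore the sample
is flagged suspicious and the unmasked mean is used rather than failing
the sheet.

## Chemometrics

PLS-DA uses NIPALS PLS2 on mean-centred X (autoscaling optional;
constant columns guarded) and mean-centred one-hot Y, deflating both
blocks per component; prediction is `Ŷ = X_c W(PᵀW)⁻¹Cᵀ + ȳ` and the
class is the largest indicator column, ties to the lowest class index.
Component extraction stops early, with a warning, when the residual X
or Y block is numerically exhausted. At full rank the fitted values
coincide with ordinary least squares (checked to 1e−8 against
`numpy.linalg.lstsq`, and against scikit-learn's PLSRegression as an
independent NIPALS). The inner iteration tolerance is 1e−12 on the
score vector with a 1000-iteration cap.

VIP follows the standard Wold formula with per-component explained
indicator variance `SS_f = ‖c_f‖² t_fᵀt_f`; mean(VIP²) = 1 holds by
construction and is asserted on every fit. Selection is VIP² ≥ 1;
VIP-PLS-DA refits on the selected submatrix and keeps the band map so
full-width spectra can be predicted directly.

ANN-DA is a single-hidden-layer network (10 logistic units, softmax
output, cross-entropy loss) with seeded deterministic initialisation,
fitted by L-BFGS — the reliable optimiser at these sample sizes.
PLS-ANN-DA trains the same network on the PLS score matrix.

The component count is chosen by minimum venetian-blinds CV
classification error over 1..15 (ties to the smaller model). The
venetian-blinds plan assigns sample `i` to fold `i mod 10` in dataset
order; pooled metrics are computed from all held-out predictions. A
training remainder that misses a class degrades to a constant
predictor of its single class (with a warning) instead of failing the
fold. The 80/20 holdout is stratified by zone with a seeded split.
Accuracy is the arithmetic mean over classes of the one-vs-rest
accuracy (TP+TN)/n, error rate its exact complement; R²/RMSE are
computed between one-hot indicators and continuous predictions, per
class and pooled over all indicator entries (the headline figure).

## Grading

The fixed criteria implement the printed cut points with inclusive
lower bounds for protein and cutting stress. Moisture has no second
grade; the boundary value 12.0 is first grade (the footnote convention
"≤ 12%" wins over the body's "< 12%", and the rule trace records the
decision). Zone 1 requires protein grade 1 AND cutting grade ∈ {1, 2}
AND moisture grade 1; the trace names the condition that fired,
including the moisture override of an otherwise zone-1 sheet. The
mean-rating heuristic (mean grade ≤ 1.5 → zone 1) is available as a
diagnostic only; the explicit rule is normative, and it sends the
undefined combination (moisture 1, protein 2, cutting 1) to zone 2.

Tukey grading computes one-way ANOVA plus Tukey HSD (scipy's
studentized-range implementation) and a compact-letter display by
insert-absorb; letter groups are ranked by mean — direction
configurable per index, higher-better for protein/cutting stress,
lower-better for moisture — and a sample spanning several letters takes
the best grade, saturating at 3. Zero residual variance is
special-cased: any mean difference is then significant.

## Problem sizes and numerical choices

The default study is 100 sheets of 64 × 320 pixels with a 50 × 300 ROI;
unit tests run 6–24 sheets of 52 × 304 pixels, and the pore-recovery
property uses 12 (unit suite) and 20 (end-to-end suite) seeded cubes —
sizes chosen to keep the full suite around two minutes while leaving
every stage non-trivial. Cubes are stored float32; all model algebra is
float64. Reflectance is clipped to (0, 1.2] at generation and [0, 1.5]
at calibration. The calibration guard rejects any voxel where the white
reference does not exceed the dark current, listing offending pixels.

## Known limitations

Venetian-blinds CV with a component count selected on the same data is
mildly optimistic, as in standard chemometric practice; the 20% holdout
is the unbiased check. Pore classification assumes pores show the
bright background — back-lit or shadowed pores would need a different
rule. The cutting-stress scale follows the grading table's kg·mm; the
kg/cm² scale of shear-blade instruments is a different measurement and
no conversion is attempted. ISODATA's split/merge thresholds are
reflectance-scale constants appropriate for calibrated cubes and would
need rescaling for radiance data.
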