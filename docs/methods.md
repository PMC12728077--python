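# Methods

## Colour model

All colour arithmetic happens in CIELAB, the device-independent space
colorimeters report natively: L\* (lightness, 0–100), a\* (green − / red +)
and b\* (blue − / yellow +). Derived parameters follow the CIE
conventions: chroma C\* = (a\*² + b\*²)^½; hue H\* computed with the
two-argument arctangent mapped to [0, 360) (the one-argument tan⁻¹(b/a)
form is quadrant-ambiguous); ΔE\* is the plain Euclidean distance (no
ΔE94/ΔE2000 weighting). Replicate fruit readings are aggregated to the
accession level by the unweighted component-wise mean, and all
downstream analysis operates on accession means. Stage deltas are signed
as ripeness minus harvest; the hue delta is the smallest signed angular
difference in (−180°, 180°], positive counter-clockwise, and is set to 0
when either stage is achromatic.

**Lab → sRGB.** Gradient rendering fixes the D65 white point, the 2°
standard observer, sRGB primaries and the IEC 61966-2-1 transfer
function; channels are clipped to [0, 1] (setting a `gamut_clipped`
flag) and rounded half-up to 8 bits. Colorimeters ship with their own
illuminant settings; D65/2° is an assumption of this package, not a
measured property of any instrument. The inverse conversion exists for
round-trip testing; every 8-bit sRGB colour round-trips within one
channel unit (measured error 0).

## Harvest-maturity classification

The threshold rule is evaluated in a fixed order — L\* ≥ 70 → white,
else a\* ≤ −5 → green, else purple, with b\* < −2.5 → violet vs. red —
because lightness separates white fruits regardless of hue, and the
green/purple split is meaningful only below the white boundary. The
thresholds and the precedence are configurable; the b\* boundary is
approximate by nature and exposed as a parameter. The classifier is
total: points within a configurable margin (default 2 CIELAB units) of
any boundary are flagged borderline rather than reassigned. Green-pulp
accessions near the green boundary carry an extra flag, since pulp
chlorophyll visibly pulls light-purple skins toward green; the package
surfaces these cases instead of resolving them. Striped accessions,
when present, are classified by their blended colour and reported with
the stripe flag intact.

## Clustering and model selection

K-means (Lloyd's algorithm, k-means++ initialisation, 10 restarts, best
WCSS kept) runs on raw (L\*, a\*, b\*) coordinates — the three axes share
one perceptual scale, so no per-axis rescaling is applied; PCA, in
contrast, z-scores columns first. Cluster-number selection reports both
the Elbow criterion, implemented as the maximum second difference of the
WCSS curve (the named method is a heuristic; the second difference is
its sharpest discrete form), and the mean Silhouette coefficient, with
singleton clusters contributing 0. The K = 3 ripeness solution is mapped
to descriptor states by centroid L\* descending → yellow, ochre, brown
(ties break toward higher b\*, the yellower centroid); the K = 2 purple
solution maps the lower-L\* cluster to dark and the other to
light/medium (ties break toward higher chroma). Agreement between
labelings is reported as a contingency table plus the adjusted Rand
index.

## Trait correlations

The 16-variable matrix (H-/P- stage L\*, a\*, b\* accession means plus
ten ordinal DUS notes) is correlated pairwise-complete; ordinal notes
enter Pearson correlation as numeric scores, matching common DUS
practice, with a Spearman switch available. p-values come from the
t transform on n − 2 df. IFC is structurally missing for white-fruited
accessions and handled by pairwise deletion. No multiple-testing
correction is applied at the default α = 0.05 (the conventional
per-cell asterisk display); a Benjamini–Hochberg switch exists.

## Population structure and association

The number of subpopulations is selected by the Evanno ΔK statistic
over clustering run summaries: ΔK(K) = mean over runs of
|LnPD(K+1) − 2·LnPD(K) + LnPD(K−1)| divided by the run-to-run sd of
LnPD(K), defined for interior K on a contiguous grid with ≥ 2 runs per
K. ΔK is 0 wherever the numerator vanishes (exactly linear curves) and
undefined (NaN, reported) where the sd is 0 with curvature present.
Running a Bayesian admixture MCMC is outside this package's scope; the
Q-matrix comes either from an external file or from a deliberate
surrogate: one-hot allele dosages → top K−1 principal components →
K-means → inverse-squared-distance soft memberships, row-normalised.
On the default synthetic panel the surrogate's modal assignment matches
the true subpopulation for ≥ 90% of accessions.

The association model is a fixed-effects GLM per marker × trait:
y ~ intercept + first K−1 Q columns + genotype-class indicators, with
the marker tested by the partial F against the Q-only model and partial
R² = (RSS_reduced − RSS_full)/TSS. SSR genotype classes are unordered
allele pairs treated as factor levels — multi-allelic SSRs have no
natural dosage — with classes under 3 observations pooled into a rare
class (dropped if still under 3). Missing phenotypes or genotypes are
dropped listwise per test; rank-deficient designs are reported and
skipped, never silently fitted. Significance uses a fixed p < 0.001
with no scan-wide correction (a BH switch exists); R² > 0.15 and
R² > 0.20 tiers are annotated in the output table.

## Synthetic panel generator

The generator emulates the statistical structure the analysis assumes,
with defaults frozen at the reference study design: 137 accessions,
5 fruits per accession per stage, 24 SSR markers, 2 subpopulations,
5 causal markers each explaining 20% of the latent variance.

* **Latent anthocyanin factor.** Each causal marker is a biallelic
  strong functional variant (causal allele frequency 0.35–0.5, identical
  across subpopulations so the causal signal is not confounded with
  structure); the latent factor is the r²-weighted sum of empirically
  standardised dosages plus Gaussian noise scaled to the residual
  variance. With the default five markers at r² = 0.20 the factor is
  fully genetic, which is well-defined; configurations whose causal r²
  sum exceeds 1 are rejected. Regression of the latent score on causal
  dosage recovers R² ≈ 0.20 (measured 0.204 over 50 panels).
* **Categories.** Accessions are ranked by the latent factor and cut
  into tiers by the category mix (white 12%, green 18%, light purple
  17%, medium purple 20%, dark purple 33% by default — purple-dominant,
  as in typical eggplant panels), reflecting that anthocyanin load
  orders white < green < purple intensities. Within purple tiers the
  violet/red subtype is assigned independently of intensity (anthocyanin
  type, not amount). An anthocyanin score on the 1–9 DUS note scale is a
  monotone, piecewise-linear transform of the within-tier latent rank,
  with gaps between tiers so the intensity classes are separable.
* **Colour.** Accession-mean colours are truncated-normal draws inside
  per-category boxes chosen to respect the classification thresholds
  with ≥ 1 CIELAB unit of margin (white L\* ∈ [72, 90]; green
  a\* ∈ [−20, −6]; violet b\* ≤ −3.5; red b\* ≥ −1.5), and purple/green
  lightness decreases linearly with the anthocyanin score, so colour
  traits stay continuously linked to the latent factor. Sampling uses
  scipy's inverse-CDF truncated normal (exact, reproducible from one
  `numpy` Generator). Fruit-level readings add N(0, 1.2²) per axis,
  clipped to the category box. The within-accession sd is a knob, not a
  claim — the reference study does not report it.
* **Ripening.** White/green → yellow, light/medium purple → ochre,
  dark purple → brown, encoding the observed pattern that darker
  harvest purples ripen browner; white fruits darken slightly (mean L\*
  80 → 75) while green and purple fruits lighten.
* **DUS notes.** ACH/ACS/ACL/IFC are the score plus uniform ±1 ordinal
  jitter, clipped to 1–9 (IFC missing for white accessions); FSCP jitters
  around 3/5/7 for yellow/ochre/brown; FC is weakly latent-linked; ILG
  and FG are independent noise; FPC encodes pulp colour, green with
  probability 1 for green-skinned and 0.4/0.25/0.15 for
  light/medium/dark purple accessions.
* **Genotypes.** Non-causal markers carry 4–8 alleles with
  Balding–Nichols divergence (F_ST = 0.25) between the two
  subpopulations, giving detectable structure; allele sizes are written
  as base-pair integers in two columns per marker. Markers are
  independent given subpopulation: no linkage map, no LD decay, and no
  pigment-chemistry model — the generator reproduces the statistical
  shape of such a panel, not its biology. Tests passing on this
  generator therefore show the pipeline's correctness and calibration
  under its assumed structure, not performance on any real panel, where
  striping, instrument drift and uneven category sizes are harsher.

Structure-run summaries are simulated as piecewise-linear mean LnP(D)
curves (steep rise to the true K, then a flat tail) with i.i.d. run
noise (sd 5), which makes ΔK peak at the generating K essentially
always.

## Validation design and problem sizes

The validation suite measures, per freshly generated panel: threshold
recovery of the generating categories on true accession means (20
panels; ≈ 100%), silhouette-selected K = 3 and ARI ≈ 1 on ripeness
colours (50 panels), ΔK = 2 on simulated run summaries, GLM null
calibration on 25 all-null panels (9,600 tests; type-I rate ≈ 0.05 at
α = 0.05, with p-value uniformity checked by KS on a decorrelated
one-trait-per-marker subset, since cells sharing a marker or trait are
correlated), and causal-marker power at p < 0.001 over 50 panels
(≥ 88% per marker on the latent-linked trait set) with dosage-R²
recovery within ±0.01 of the nominal 0.20. These sizes keep the whole
suite around a minute while leaving Monte-Carlo error well inside the
asserted margins.

## Known limitations

* The surrogate Q-matrix is a geometric stand-in for admixture
  estimation; with weak divergence or K > 2 its memberships are cruder
  than MCMC posteriors.
* Genotype-class coding spends one degree of freedom per class, so
  power at highly polymorphic markers is intrinsically lower than a
  dosage model would give; this is the standard behaviour of
  class-coded GLM association and is left as is.
* The Elbow second-difference criterion is unstable on WCSS curves
  without a clear knee; the silhouette criterion is the one the
  validation suite relies on.
* Threshold classification uses skin colour only; accessions whose
  appearance is dominated by pulp colour are flagged, not corrected.
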