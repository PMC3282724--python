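# Methods

## Synthetic successional scenes

The generator produces the statistical structure the texture analysis
assumes, not radiometric realism.

**Reflectance model.** Each pixel is a linear mixture
`refl = c·canopy + (1 − c)·soil + ε`, clipped to [0, 1], with per-band
endmembers (soil bright in RED, canopy dark in RED and bright in IR;
illustrative values, not calibrated to a sensor) and Gaussian sensor noise
ε (sd `noise_sd`, default 0.004 reflectance units). The cover fraction c is
Beta-distributed per pixel with stand-level mean
`cover(age) = A(1 − e^(−r·age))` (defaults A = 0.95, r = 0.08 yr⁻¹, chosen
so cover is ~55 % at 10 yr and near-saturated past 40 yr, matching the
qualitative stabilization of canopy cover along dry-forest
chronosequences) and variance `v₀·e^(−d·age)` (defaults v₀ = 0.04,
d = 0.05 yr⁻¹). The age-decaying variance is the mechanism of interest:
young stands expose substrate between crowns, so their windows are
spectrally heterogeneous; old stands are smooth. Variances below 1e−12 (or
a mean cover of 0 or 1) short-circuit to constant cover, which makes the
zero-noise degenerate case exact.

**Geometry.** Stands are axis-aligned squares on a grid, default 24 px
(≈ 62 m at the 2.6 m pixel), one plot per stand at its center, sized so the
15 × 15 analysis window samples mostly its own stand while still fitting
anywhere in the image. The default chronosequence is 14 fallow ages from
2 to 60 yr plus a mature stand coded with age 90.

**Stem communities.** Per plot, class-wise stem counts are Poisson with
saturating age trends; the large-class DBH ceiling itself grows with age
(so young stands carry low basal area); species are drawn from a geometric
rank-abundance series whose steepness decays with age (richness rises,
Simpson dominance falls); heights are lognormal around a saturating
age-dependent mean with a weak DBH allometry. All randomness flows from
the single config seed, so identical configs are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real imagery: sun–view-angle effects on texture,
geometric/atmospheric correction artifacts, crown-scale spatial structure
(crowns are not objects, heterogeneity is i.i.d. per pixel), topography,
clouds/shadows, and plot-geolocation error. Results on synthetic scenes
validate the machinery and its qualitative behavior, not field accuracy.

## Stand attributes

Nested sampling: large stems (DBH ≥ 5 cm) observed on 400 m², medium
(2.5–5 cm) on 200 m², small (1–2.5 cm) on 100 m²; every per-hectare
quantity weights a stem by 10,000/area of its class (25/50/100). Crown
area is the ellipse π(d₁/2)(d₂/2) of the two orthogonal crown diameters.
Diversity indices use expansion-weighted abundance shares, consistent with
the per-hectare scaling: H′ = −Σ pᵢ ln pᵢ (nats) and dominance D′ = Σ pᵢ²
(equal to 1 for a single species, which pins the convention). Hgt averages
eight zone maxima, the zones being pairs of adjacent quadrats (1–2, 3–4,
…, 15–16). The upper-canopy subset U is operationalized as the minimal
prefix of stems, ranked by individual crown area (ties: larger DBH, then
input order), whose cumulative expansion-weighted crown area reaches half
the plot total; U-set totals can therefore never exceed T-set totals.

## Texture features

Quantization maps each layer's **global** (whole-image) min–max linearly
onto 64 levels, flooring, with the maximum assigned to level 63 and
constant layers to level 0. Global rather than per-window scaling keeps
features comparable across plots, and makes every GLCM feature invariant
to a positive rescaling of the layer — which is why the EVI gain
convention (G = 2.5) cannot affect the co-occurrence statistics (tested).
GLCMs are accumulated symmetrically (each pixel pair in both orders) at
distance 1 and normalized to sum 1; the four directional matrices use
offsets (0,+1), (−1,+1), (−1,0), (−1,−1) in row/col coordinates. The
eight statistics use the row marginal mean μ and variance σ²; correlation
is undefined (NaN) when σ² = 0, e.g. a constant window. Entropy is in
nats; any other base rescales all entropies by one constant and cannot
change R²-based selection. First-order range and skewness
(g₁ = m₃/m₂^{3/2}, 0 when m₂ = 0) are computed on the raw, unquantized
window values. Windows touching the image edge or a masked pixel (e.g. a
non-positive EVI denominator) are skipped with a warning, never imputed.

## Model search

Responses are transformed before fitting: natural log by default,
ln(y + 1) for attributes that can be exactly zero (Shannon H′ of a
single-species plot), and a logit option for dominance D′ ∈ (0, 1]. The
search fits every subset of 1–3 of the 40 features per attribute. The
implementation centers the predictor matrix once, precomputes the Gram
matrix C = Xc′Xc and the inverses of all its k × k principal submatrices,
and evaluates R²(S) = b_S′C_S⁻¹b_S / TSS with b = Xc′y as a batched
quadratic form — ~150k candidate fits run in well under a second, and
permutation replicates reuse all precomputation because permuting rows of
X leaves C unchanged. Best-by-R² ties are broken by lexicographic
predictor order (within a size, equal R² implies equal AICc).
AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n−p−1) with p = k + 2 (slopes,
intercept, error variance); sizes within 2 of the minimum AICc are
reported "equally good". An RSS floor of 1e−300 keeps exact fits finite.

## Permutation nulls

Each replicate permutes the plot order of the whole feature table as a
block against the attribute vector — preserving the inter-feature
correlation structure exactly, which is the correct null of "no
texture–attribute association" for collinear features — then records the
maximum R² over all candidate subsets. The empirical p is the strict
fraction of null maxima above the observed value (so p = 0 is attainable),
and the null median measures the chance component of exhaustive search.
Defaults: 1,000 replicates, seeded.

## Cross-validation

All C(n, 2) leave-two-out splits; each model is refit on n − 2 plots and
predicts the two held out, on the transformed scale (back-transformed
predictions are available for reporting). ASS is the mean over splits of
the two-plot squared-error sum. R²_CV pools all n(n−1) predictions:
R²_CV = 1 − Σ(yᵢ − ŷᵢ)² / [(n−1)·Σᵢ(yᵢ − ȳ)²] with ȳ the grand mean —
numerator and denominator count each observation the same n−1 times. The
pooling convention is fixed here as the package's interpretation of the
leave-d-out predictive R²; it satisfies the required contracts exactly:
1 on noiseless data, and for the degenerate calibration-mean predictor it
equals −2/(n−2) identically (slightly below 0 at n = 15). Splits with a
singular calibration design are excluded and counted.

## Numerical and design notes

- The exhaustive-search precondition is no constant (zero-variance)
  feature column; degenerate columns make the Gram submatrices singular
  and are the caller's responsibility to drop.
- Rank-deficient designs raise in single fits and are excluded, with a
  count, in cross-validation.
- Sign-recovery experiments plant `ln BA = β₀ − β₁·RED_VAR + ε` with ε of
  sd 0.05 against a unit-sd signal. The variance-type texture features of
  these scenes are mutually correlated near 0.99, so recovering the exact
  named feature (rather than a proxy with the same sign) requires the
  planted relation to be near-deterministic; at larger ε the selected
  proxy changes but the negative sign does not.
- Problem sizes used in the shipped analyses and checks: 120 × 120-px
  scenes, 15 plots, 1,000 null replicates (199 inner replicates × 500
  outer simulations for the calibration experiment), 100 scene
  realizations for sign recovery.
- Rasters are plain float32 multiband TIFF (band order BLUE, RED, IR);
  geo-referencing is out of scope.

## Known limitations

- Endmember reflectances and the cover/heterogeneity curves are
  illustrative; no claim of radiometric calibration is made.
- The U-set definition ("above the median of the cumulative canopy-cover
  distribution") admits more than one reading; the cumulative ≥ 50 %
  prefix adopted here is one consistent operationalization.
- The exact published regression coefficients are not reproducible
  without the original image and plot geolocations; the package
  reproduces the method and its analytically pinned quantities, and the
  qualitative result pattern on synthetic scenes.
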