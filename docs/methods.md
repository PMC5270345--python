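# Methods

## Scope and data model

plumavis implements a comparative pipeline linking habitat structure to
plumage colour: (1) reflectance spectra → receptor-noise colour-space
coordinates → taxon-level contrast against natural backgrounds;
(2) per-taxon environmental means → a vegetation principal component;
(3) a Bayesian phylogenetic mixed model relating contrast to the
vegetation axis while marginalizing over phylogenetic uncertainty.  Field
and GIS acquisition are outside the package boundary: the inputs are a
spectra table (wavelength × measurement), a measurement-metadata table, a
per-taxon habitat table and a multi-tree file.

Seven body regions (head, back, breast, belly, cheek, throat, tail) form
a closed patch vocabulary; sexes are F/M.  Missing patches are allowed
(museum specimens are often damaged); 1–2 replicate spectra per patch and
specimen are expected, more are accepted with a warning.

## Spectra

Spectra cover 300–700 nm (the bird-visible range).  Negative readings —
routine spectrometer noise around dark patches — are clamped to zero on
load and logged rather than rejected.  Down-sampling to the 81-point 5-nm
grid uses centered half-open bins [w − 2.5, w + 2.5), the common
spectrometry convention; the operation is idempotent on the target grid,
and inputs that do not cover the full range are rejected with the gap
named.

## Visual model

Cone sensitivities are generated from the Govardovskii A1 pigment
template (α- and β-band) at configurable peak wavelengths, defaulting to
an average violet-sensitive (V-type) system (405, 480, 535, 565 nm) —
the appropriate observer when the predators of interest are raptors.
Ocular-media and oil-droplet filtering are folded into the effective
templates rather than modelled separately.  The double cone (achromatic
channel) is the peak-normalized sum of the M and L templates with
ω_D = 0.05 by default; both are config knobs because achromatic
parameters are rarely reported.

The bundled illuminant is CIE D65 converted to relative quanta
(energy × λ); under von Kries normalization the illuminant scale cancels,
which the tests verify.  Integration is a plain Riemann sum on the 5-nm
grid, matching the data resolution; quantum catches of zero (all-black
input) are a hard error rather than a silent −inf.

Noise-to-signal ratios follow ω_i = ν √(η_L / η_i); with ν = 0.05 and
η = (0.38, 0.69, 1.14, 1) this gives ω = (0.0811, 0.0602, 0.0468, 0.05),
printed conventionally as (0.08, 0.06, 0.046, 0.05) — note the printed
M-cone value truncates, not rounds, the third decimal.

The chromatic distance is the tetrachromatic receptor-noise quadratic
form in log-catch differences.  Its matrix is positive semidefinite with
the all-ones vector as null space (uniform intensity shifts are
achromatic) and rank 3; the xyz embedding uses the rank-3 eigenfactor
with eigenvalues descending and each eigenvector's largest-magnitude
entry made positive, so coordinates are bit-for-bit reproducible.  The
only property downstream analysis relies on — and the property the tests
pin to 1e-8 — is that Euclidean distance between embedded points equals
ΔS.

## Contrast aggregation

Averaging happens in coordinate space, not spectrum space (the two
differ; coordinate-space averaging is the deliberate choice): replicates
are averaged within an individual, individual means across individuals,
both unweighted.  Contrast per (taxon, sex, patch) is the Euclidean
distance to each background's coordinates; conspicuousness is the mean of
the green and brown contrasts.  The achromatic contrast column is
likewise the mean of the double-cone distances to the two backgrounds.

Structural (UV-reflective) colouration is flagged when UV chroma — the
trapezoid-rule integral of reflectance over 300–400 nm divided by the
integral over 300–700 nm — exceeds 0.30 (configurable).  A flat spectrum
scores 0.25, comfortably below threshold.  Percent structural coverage
uses per-region weights summing to 1 (default equal 1/7); unmeasured
regions count as non-structural with a warning.  Region weights replace
plate-derived area estimates while keeping the computation's structure.

## Habitat axis

PCA is computed on the covariance matrix of the three environmental
columns (centered, unscaled), so variables are expected on comparable
scales; `standardize=True` switches to the correlation matrix for real
data on wild scales.  PC1 is oriented so the potential-vegetation loading
is positive (higher score = denser vegetation).  Correlations
(latitude, rainfall, temperature) are Pearson, always reported with n.

## Phylogenetic mixed model

Trees are rooted ultrametric candidate phylogenies sharing one tip set;
near-ultrametric inputs (within 1e-3 of height) are repaired by extending
terminal branches, larger deviations are errors.  Subspecies are grafted
as sisters of their nominal species at terminal branch length 0.025
(configurable; 0.05 is the conventional sensitivity check), preserving
ultrametricity and all uninvolved distances exactly.  The Brownian
correlation structure is shared-path length from root to MRCA divided by
tree height.

The model is y = Xβ + Z_p u_p + Z_s u_s + e with a phylogenetic taxon
effect (covariance σ²_p C(tree)), a species-identity effect grouping
subspecies with their nominal species, and i.i.d. residuals.  Fixed
effects: intercept, vegetation PC, patch (treatment-coded over the
canonical patch order), PC × patch, latitude.  Priors: N(0, 1e8) on β,
inverse-gamma(0.001, 0.001) on variances — weakly-informative
conventions, all configurable.

Phylogenetic uncertainty is handled by tree resampling: at each outer
iteration a tree is drawn uniformly with replacement (or sequentially),
the Gibbs chain is advanced `inner` sweeps from the previous state
(warm start — a cold-start flag exists for comparison; cold starts would
need far longer inner runs), and the last state is stored; the first
`burn` stored states are dropped.  Full defaults are outer 1300 / inner
1000 / burn 300.  The sampler's full conditionals are validated by a
Geweke-style joint-distribution test on a six-taxon toy model, and the
compiled (numba) kernel is cross-checked against a pure-python reference
chain on a single-tree posterior.

λ is defined as the phylogenetic variance share
σ²_p / (σ²_p + σ²_s + σ²_e) — the standard mixed-model signal statistic.
Per-patch marginal habitat slopes are the PC main effect plus the
relevant interaction contrast.  Summaries use shortest 95% HPD intervals
(ties to the lowest lower bound); an effect is "significant" when its
HPD excludes zero.  Results are bit-for-bit reproducible given (seed,
trees, data, config).

## Synthetic data

The generator emulates the structure of the museum study the pipeline is
designed for — its defaults are the study conditions: 15 species plus 9
subspecies, 16 individuals per sex per taxon, 1–2 replicates per patch,
1300-tree posteriors, and a habitat table whose first PC explains ≥95%
of environmental variance and correlates with latitude at r² ≈ 0.4–0.7.
Spectra are built from phenomenological templates (structural UV/blue
Gaussian, carotenoid sigmoid step at 550 nm, melanin ramp; green-leaf
Gaussian and brown ramp backgrounds) on a 1-nm grid precisely so the
5-nm down-sampling path is exercised, with Gaussian measurement noise
(sd 1% reflectance) clamped at zero.

The structural template's peak is drawn from 350–410 nm: above ~415 nm a
Gaussian peak cannot place more than 30% of its reflectance below
400 nm, so higher peaks would be unclassifiable as structural under the
UV-chroma criterion by construction; the wider range remains reachable
through `GeneratorConfig.structural_peak_range`.  Sex-specific template
probabilities (structural: 8.5% female, 30% male) mirror the strong
male bias of structural colour in the emulated clade.

Taxon-level responses are generated under the mixed model itself with a
truth record for recovery scoring.  Default effect model: β_PC = 0.15,
σ²_p = 0.2, σ²_s = 0.05, σ²_e = 0.1 (the regime used for parameter
recovery).  What the generator does **not** emulate: feather
microstructure optics, spatial patterning within patches, ambient-light
habitat spectra, seasonal plumage change, or correlated measurement
error between patches — so passing tests demonstrate the pipeline's
correctness and calibration, not that real museum data would yield any
particular biological result.

## Validation problem sizes

The expensive checks run at deliberately desk-scaled sizes chosen as the
package's own test conditions: sampler calibration and recovery at 24
taxa with outer 200 / inner 200 / burn 50 over 50 replicates (planted
slope 0.15 inside its 95% HPD in ≥85% of replicates; ≤10% false
positives on pure-noise data); signal separation on a 64-tip tree over
20 replicates (median λ̂ > 0.7 for Brownian traits vs < 0.3 for i.i.d.);
and the sex-specific headline over 10 seeds.

For the headline scenario the effect model is calibrated to the regime
the emulated study reports rather than the recovery defaults: female
β_PC = 0.25 (within the reported slope magnitudes 0.039–0.265), male
β_PC = 0, σ²_p = 0.008, σ²_s = 0.006, σ²_e = 0.04, giving a phylogenetic
variance share of 0.148 (matching the reported λ ≈ 0.15) and a
between-taxon habitat R² ≈ 0.45 — a regime where the female effect is
detectable at 24 taxa despite the PC–latitude collinearity the habitat
generator builds in.  Fitted λ̂ on these data comes out ≈ 0.15–0.25.

## Known limitations

- The xyz embedding matches any receptor-noise-consistent coordinate
  convention only up to rotation/reflection; distances, not axes, are
  the contract.
- Covariance PCA is scale-sensitive by design; real-world rasters on
  wildly different units need `standardize=True` or prior rescaling.
- The inverse-gamma(0.001, 0.001) default is weakly informative but not
  uninformative near zero variance; λ estimates on very small trees are
  prior-sensitive.
- One stacked model per response with patch interactions is the default
  reading of per-patch effects; a per-patch-model mode can be emulated
  by filtering the input table to one patch.
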