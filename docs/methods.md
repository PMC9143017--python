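# Methods

## Photon transport and the scalable baseline

The medium is semi-infinite, homogeneous, and characterized by an absorption
coefficient μ_a (cm⁻¹), scattering coefficient μ_s (cm⁻¹), Henyey–Greenstein
anisotropy g, and refractive index n. Photons launch collimated and normally
incident, distributed uniformly over the source disk; at the top surface an
unpolarized Fresnel coefficient decides probabilistically between internal
reflection and escape. Specular loss at entry is not simulated — it is a
wavelength-flat factor absorbed by the reference-phantom calibration.

The *baseline* run is absorption-free at a reference μ_s,ref (default
100 cm⁻¹, g = 0.9). Every photon that escapes inside the fiber acceptance
(n_medium·sinθ ≤ NA, invariant under the exit refraction) is stored as
(exit displacement ρ from its launch point, cumulative path length L, exit
angle cosine, weight). Two exact facts make this ensemble reusable:

1. a scattering-only trajectory's geometry scales as 1/μ_s at fixed g, so a
   target μ_s′ rescales every ρ and L by s = μ_s,ref/μ_s,target;
2. absorption along a known path is a deterministic weight exp(−μ_a·L′),
   applied analytically (variance-free in μ_a).

Collected reflectance at (μ_a, μ_s′) is then Σ w·exp(−μ_a·sL)·P(sρ)/N, where
P(ρ) is the analytic probability that a displacement ρ from a uniformly
distributed source-disk launch point lands on the detector annulus
(Gauss–Legendre quadrature of the disk–annulus convolution, cached on a
log-spaced interpolation grid). Because reflectance at the target g is
approximated by the baseline ensemble at its own g through the shared μ_s′,
the model inherits the standard similarity-relation assumption; the direct
oracle below quantifies its adequacy.

**Termination.** In the absorption-free baseline the walk-length
distribution is heavy-tailed (half-space recurrence), so walks are capped at
20 000 scattering events by default. Truncated paths would carry
exp(−μ_a·L) ≈ 0 anywhere in the tissue range (μ_a ≥ 0.05 cm⁻¹ gives an
attenuation exponent > 16 at the cap for the softest scattering in the
phantom range), so the cap is irrelevant where the records are used; energy
audits at μ_a = 0 raise the cap explicitly. The direct estimator uses
Russian roulette below weight 10⁻⁴ with survival 1/10 (unbiased).

**Validation oracle.** `direct_reflectance` re-simulates the exact target
medium conventionally: interaction sampling at μ_t = μ_a + μ_s, albedo
de-weighting per collision, explicit source-disk launch and annulus
collection. It shares no scaling machinery with the baseline route; the test
suite requires agreement within 3 combined Monte Carlo standard errors over
the phantom property range, and energy conservation (collected → 1) for a
matched-boundary, all-collecting, absorption-free configuration.

**Probe geometry.** The physical probe (19 illumination / 18 detection
fibers, NA 0.22) is not dimensioned fiber-by-fiber; it is abstracted as a
coaxial source disk (radius 0.1 cm) and detector annulus (0–0.16 cm) chosen
so the modeled sensing depth is ≈ 1.5 mm in the tissue range. Refractive
indices: 1.33 (aqueous phantom) / 1.37 (tissue) inside, 1.45 (fused-silica
fiber face) outside.

## Inverse model

A reference phantom of known optical properties fixes the instrument scale
as the median over wavelengths of measured/modeled reflectance (robust to a
few noisy channels). The inversion is bounded trust-region least squares
(scipy `least_squares`) over non-negative chromophore concentrations and
scatterer parameters, restarted from three deterministic initial points;
ties are broken by lowest residual then lexicographically smallest parameter
vector. Non-negativity is enforced by the bounds, never by clipping. The fit
window defaults to 450–600 nm — the hemoglobin-dominated band where both
coefficients are well constrained — while the acquisition grid spans
420–760 nm; extracted properties are reconstructed over the full basis grid
from the fitted parameters so fluorescence channels outside the window can
be corrected. The iterative fit evaluates a cubic-spline lookup of the
scaled reflectance over a (μ_a, log μ_s′) grid, built once per baseline;
the lookup reproduces the exact record sum to ≲0.5% relative, far below the
1% measurement noise, and forward synthesis always uses the exact sum.

Mean extracted coefficients are reported over the fit window (the bundled
design's printed means are treated as 450–600 nm means; the window is
configurable and echoed in every report).

Phantom inversions fix the sphere geometry and fit only number density (the
Mie form is identifiable only when the sphere is known); tissue inversions
default to the power law μ_s′ = a·(λ/λ₀)^(−b). Hemoglobin phantoms default
to fully oxygenated stock (aerated aqueous hemoglobin), so phantom SO₂ ≈ 1.

## Fluorescence distortion and correction

Measured emission is modeled as intrinsic emission times a separable
distortion D(λ_x, λ_m) = R(λ_x)·R(λ_m): collected reflectance at the
excitation wavelength proxies the delivered-and-returned excitation fluence,
and collected reflectance at each emission wavelength the escape-and-
collection probability. This first-order factorization captures the two
dominant artifacts — overall magnitude tracking scattering, and spectral
shape carved by the absorber (hemoglobin absorption at the blue edge of the
TMRE band pushes the measured peak red of 585 nm) — and makes the correction
an exact division, so correct(model(S)) = S to machine precision. It ignores
re-absorption of emitted light by the fluorophore itself and any spatial
mismatch between excitation and emission sampling volumes.

## Synthetic data

*Mie scattering.* Bohren–Huffman series with the logarithmic derivative by
downward recurrence; validated against an independent upward evaluation from
scipy spherical Bessel functions and against the Rayleigh limit. μ_s′ is
exactly linear in number density; per-phantom densities are solved so
μ_s′(550 nm) equals the design value.

*Hemoglobin basis.* The bundled oxy/deoxy extinction table is **synthetic**:
Gaussian bands emulating the Soret region, the oxy 542/577 nm double Q-band
vs the deoxy 556 nm single band, and a deoxy-dominant red tail. The oxy
window mean (450–600 nm) is normalized to 0.003958 cm⁻¹µM⁻¹, the value
implied by the bundled phantom series' [Hb] ↔ μ_a design. The basis makes
oxygenation states identifiable and the closed loop self-consistent; it is
not a measured compendium, and absolute in vivo extractions with it carry no
metrological meaning. Tests that must be dataset-independent construct toy
bases inline.

*Fluorophores.* Unit-area log-normal lineshapes with modes at 510 nm
(Bodipy FL C16, protein-bound) and 585 nm (TMRE), widths 18 / 22 nm chosen to
sit inside the acquisition windows (505–635, 575–705 nm). Brightness
(c.u. per nM) is an instrument-defined free constant, default 1.

*Measurements.* Reflectance on 420–760 nm at 1 nm; multiplicative Gaussian
noise with CV 0.01 by default — the noise level at which closed-loop
extraction quality matches the bundled design's validation statistics.

*Cohorts.* Subjects are multivariate-normal draws per group (SO₂ truncated
to [0,1], other endpoints floored at 0). The default aging design places old
mammary groups 1.5 pooled SD below young in TMRE and [Hb] with Bodipy and
SO₂ unchanged (SDs 0.20, 0.25, 0.08, 6.0 for TMRE, Bodipy, SO₂, [Hb]);
the 4T1 design raises Bodipy, TMRE and [Hb]; 67NR duplicates mammary. The
default n = 20/group gives the rank-sum test ≥ 90% power at the designed
effect size. Uptake curves are v(t) = plateau·(1 − e^(−kt)) with k = 0.1/min
by default (95% of plateau by 30 min), plus per-subject plateau offsets and
i.i.d. residual noise in the trial generator.

What the generator does *not* emulate: probe pressure and placement
variability, physiologic drift during the 60-min session, autofluorescence
background, melanin or other chromophores, detector nonlinearity, and any
chemical interaction between probes. Passing closed-loop tests therefore
demonstrates internal consistency of the inversion chain under the stated
noise model, not field performance on animals.

## Endpoint analysis

Endpoints carry incommensurable units, so PCA z-scores each column
(SD with ddof = 1) before the SVD; components are ordered by variance, signs
fixed so each component's largest-magnitude loading is positive, and
explained variances are reported in percent of total (all components are
retained for clustering). Spectral clustering builds the full Gaussian
affinity with scale = median pairwise distance (parameter-free and stable at
n ≈ 10–40), embeds with the symmetric-normalized Laplacian's leading k
eigenvectors (rows normalized), and runs seeded k-means (n_init = 10);
k = 2 by default, matching the two true labels per analysis. Silhouettes use
Euclidean distances in PC space; singletons and the all-coincident case
score 0. Information gain discretizes a feature into equal-frequency bins
(default 3) and reports H(labels) − Σ p(bin)·H(labels|bin) in bits; the
"average entropy per class" phrasing common in applied write-ups is
ambiguous between conditioning on class and on feature bins — this package
implements the standard feature→label gain and records the convention in
the output metadata. Rank-sum tests are exact for combined n ≤ 20 without
ties, normal-approximate otherwise; no multiple-testing correction is
applied (per-comparison α = 0.05). Through-origin fits use slope Σxy/Σx²
with R² = 1 − SS_res/SS_tot about the mean of y, so a forced zero intercept
is penalized when unwarranted.

## Problem sizes and numerical choices

Defaults are desk-scale: 10⁶ baseline photons for the validation script,
1.5–3×10⁵ in the test suite and pipeline (statistical assertions are
calibrated to those ensemble sizes); reflectance lookup grid 60×48 over
μ_a ∈ [0, 4] cm⁻¹, μ_s′ ∈ [1, 40] cm⁻¹; distortion positivity floor 10⁻¹²;
all RNG flows from explicit integer seeds (numba kernel seeded via
`np.random.seed`, NumPy generators via `default_rng`), so every output is a
pure function of (inputs, seed).

## Known limitations

- Homogeneous semi-infinite medium only: no layers, no heterogeneity, no
  polarization or time resolution, no explicit multi-fiber raster.
- The similarity-relation rescaling matches media through μ_s′, not (μ_s, g)
  separately; accuracy is established empirically by the direct-MC oracle
  over the phantom range rather than guaranteed analytically.
- The separable fluorescence distortion is first-order; strongly absorbing
  or deeply layered media would need a true fluorescence Monte Carlo.
- The hemoglobin basis is synthetic (see above); swap in a measured
  extinction table for quantitative in vivo work.
- Grubbs-type outlier screening of cohort tables is out of scope; tables are
  analyzed as given.
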