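# turbispec

Quantitative fiber-probe spectroscopy of turbid media: recover tissue optical
properties and vascular endpoints from diffuse reflectance, correct measured
fluorescence to intrinsic fluorescence, and analyze multi-endpoint metabolic
datasets — all validated closed-loop against a built-in tissue-phantom and
cohort synthesizer.

## Who this is for

Biophotonics groups doing in vivo metabolic spectroscopy with fiber-optic
probes: simultaneous measurement of two exogenous fluorescent reporters —
TMRE (mitochondrial membrane potential, ex 555 / em 585 nm) and Bodipy FL C16
(fatty-acid uptake, ex 488 / em 510 nm) — together with two endogenous
vascular endpoints, total hemoglobin [Hb] and oxygen saturation SO₂. Raw
emission intensities from tissue are confounded by wavelength-dependent
absorption and scattering; this package removes that confound.

## What it computes

**Forward model (scalable Monte Carlo).** Photons random-walk in a
semi-infinite homogeneous medium (Henyey–Greenstein phase function,
unpolarized Fresnel boundary) under a coaxial disk-source / annulus-detector
probe with NA-limited acceptance. One absorption-free reference run at
scattering coefficient μ_s,ref is stored as exit records; similarity
relations rescale every record to arbitrary (μ_a, μ_s′) — geometry scales as
μ_s,ref/μ_s, absorption enters analytically as exp(−μ_a·L) — so collected
reflectance at any optical properties costs a vector sum, not a new
simulation. An independent conventional estimator (albedo weighting, Russian
roulette) serves as the validation oracle.

**Inverse model.** With a reference-phantom calibration, nonlinear least
squares over non-negative chromophore concentrations and scatterer
parameters fits the measured reflectance over 450–600 nm:
μ_a(λ) = ln10·[ε_HbO₂(λ)·c_HbO₂ + ε_dHb(λ)·c_dHb], μ_s′(λ) from Mie theory
(known sphere, free number density) or a power law a·(λ/λ₀)^(−b). Then
[Hb] = c_HbO₂ + c_dHb, SO₂ = c_HbO₂/[Hb], and measured fluorescence is
divided by the separable distortion factor D(λ_x, λ_m) = R(λ_x)·R(λ_m)
evaluated at the extracted properties, yielding intrinsic fluorescence in
corrected units.

**Synthesis.** Mie theory for 1 µm polystyrene spheres, a synthetic
oxy/deoxy-hemoglobin extinction basis, log-normal emission lineshapes, the
bundled ten-phantom dilution series (mean μ_a 0.14–0.49 cm⁻¹, mean μ_s′
5.97–16.72 cm⁻¹, [Hb] 15.09–53.89 µM), saturating uptake kinetics
v(t) = plateau·(1 − e^(−kt)), and group-structured endpoint cohorts.

**Endpoint analysis.** PCA on z-scored endpoint subsets, spectral clustering
(Gaussian-similarity graph, normalized-Laplacian embedding, seeded k-means),
per-point silhouettes S(i) = (b(i) − a(i))/max{a(i), b(i)}, equal-frequency
information gain in bits, Wilcoxon rank-sum (exact for small samples), mixed
repeated-measures ANOVA for uptake curves, and through-origin linearity fits.

## Worked example

`examples/phantom_closed_loop.py` synthesizes the bundled phantom series at
1% measurement noise, inverts each spectrum, and prints:

```
reference calibration scale: 1.0003  (1.0 = perfect)

phantom    mua ext/exp     musp ext/exp     [Hb] ext/exp (uM)   SO2
phantom_1  0.137/0.14      17.19/16.72     15.1/15.1         0.995
phantom_2  0.232/0.23      14.30/13.93     25.4/25.1         0.997
...
phantom_10 0.490/0.49      6.12/5.97      53.7/53.9         0.999

R^2 extracted vs expected mean mua : 0.9994
R^2 extracted vs expected mean musp: 1.0000
```

Each row compares the extracted mean absorption and reduced scattering
coefficients (450–600 nm) and total hemoglobin against the phantom design;
the R² values summarize how faithfully the inverse Monte Carlo recovers the
ten-phantom series through noise. The other examples cover intrinsic
fluorescence correction (`fluorescence_correction.py`), cohort clustering
(`cohort_clustering.py`) and uptake kinetics (`uptake_kinetics.py`).

A CLI mirrors the library: `turbispec simulate-phantoms | simulate-cohort |
baseline-mc | invert | correct | analyze | run`, each with `--seed`,
`--config` and `--out`.

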