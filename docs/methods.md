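# Methods

This note documents the models and procedures implemented in `msimon`, the
assumptions behind them, the defaults and why they were chosen, and the
limitations of what the synthetic experiments can establish.

## Camera and optics model

The sensor is modelled as a 272×512 array carrying a repeating 4×4 mosaic of
16 spectral filters; demosaicking collapses each 4×4 tile into one 16-band
pixel (68×128×16) with no spatial interpolation, so the mosaic↔cube round
trip is bit-exact. Spatial interpolation would be cosmetic for this
application: all downstream analyses operate on per-pixel spectra or ROI
aggregates.

A high-resolution reflectance spectrum r(λ) on the common 300–1000 nm, 2 nm
grid maps to a band measurement by the weighted mean

r_k = ∫ T·I·f_k·r dλ / ∫ T·I·f_k dλ,

with T(λ) the combined optics transmission (laparoscope × 335–610 nm
bandpass × C-Mount), I(λ) the illuminant and f_k the filter response,
evaluated by trapezoidal quadrature on the grid. Notes on the defaults:

* **Filter responses** are synthetic: Gaussian main peaks (SD 7 nm, centres
  470–620 nm) with secondary "second-order" peaks (amplitude 0.35,
  150 nm below the main peak) on bands 5–12, mimicking the qualitative
  behaviour of Fabry-Pérot mosaic filters. Amplitudes are configurable;
  real curves can be loaded from CSV.
* **Mosaic layout** is an explicit configuration field (default row-major
  0..15) because correctness of demosaicking is layout-conditional and the
  physical band↔offset map of a real sensor must be supplied, not assumed.
* **Illuminant** defaults to flat. The band integral normalizes the
  illuminant out exactly for spectrally flat reflectance and nearly so for
  smooth spectra; a tabulated xenon spectrum can be substituted.
* **Band integration on a restricted grid**: the bandpass transmission is
  exactly zero outside ~[330, 618] nm, so simulation loops may skip
  zero-weight wavelengths without changing any band value; the camera
  exposes this support as `active_mask()`.

RGB reconstruction fits a 3×16 matrix by least squares between the
transmission-scaled camera response and three Gaussian target filters
(centres 460/550/640 nm, SD 42 nm), then row-normalises so a flat band
vector maps to RGB (1,1,1). Transmission-profile smoothing averages
measurement repeats and applies a centred 19 nm rolling mean, flagging the
border regions 400–419 nm and 681–700 nm invalid.

## Tissue model and Monte-Carlo transport

Tissue is three infinitely wide slabs. Per layer: blood volume fraction
v_hb, oxygenation s, reduced scattering at 500 nm a_mie (cm⁻¹), scattering
power b_mie, Henyey-Greenstein anisotropy g, refractive index n, thickness
d (cm). Absorption combines the hemoglobin extinction spectra at a total
hemoglobin concentration of 150 g/l and molar mass 6.45·10⁴ g/mol,

μ_a(λ) = v_hb [s ε_HbO2 + (1−s) ε_Hb] ln(10) · 150 / 64500  (cm⁻¹),

and scattering follows the power law μ_s(λ) = a_mie/(1−g) · (λ/500 nm)^(−b).
Anisotropy is held constant per layer across wavelength (the simplest
reading of scalar parameter ranges). Sampling ranges: v_hb ∈ [0, 0.30],
s ∈ [0, 1], a_mie ∈ [5, 50] cm⁻¹, b_mie ∈ [0.3, 3], g ∈ [0.80, 0.95],
n ∈ [1.33, 1.54], d ∈ [0.002, 0.2] cm, all uniform and independent.

The transport kernel (numba-compiled, single-threaded, deterministic per
seed) launches photons normally from an ambient medium with n = 1, applies
specular reflection at entry, samples steps exponentially with
μ_t = μ_a + μ_s, deposits the fraction μ_a/μ_t of the packet weight per
interaction, scatters by Henyey-Greenstein, applies unpolarised Fresnel
reflection/refraction at every index boundary (ambient n = 1 below the last
layer; transmitted photons are counted as transmitted), and terminates by
Russian roulette (survival 0.1 below weight 10⁻⁴, weight-conserving in
expectation). Reported reflectance is the total upward-escaping fraction.
Verified properties: energy conservation to ≤10⁻³ at 10⁴ photons, the Beer
attenuation limit for a pure absorber, ≥0.98 reflectance for a thick
conservative scatterer, monotone response to absorption, 1/√N error
scaling, and agreement with an independently written photon loop.

**Hemoglobin extinction table.** The bundled table
(`data/synthetic_hb_extinction.csv`) is *synthetic*: a sum of Gaussian
absorption bands and smooth baselines with the qualitative features of the
real spectra (Soret band, α/β doublet vs. single deoxy band, isosbestic
crossings, low red absorption with Hb above HbO2). Real tabulated
coefficients can be dropped in via `ExtinctionTable.from_csv`; all
quantitative statements in the tests are made under the synthetic table.

## Preprocessing

Per ROI and frame: demosaic → white/dark reference normalization
(I−D)/(W−D) per pixel and band (reference repeats averaged first; pixels
with W ≤ D flagged invalid) → exposure mask (a pixel is valid iff every
band lies strictly between the under- and over-saturation thresholds) → ℓ2
normalization across bands (invariant to positive illumination scaling;
zero vectors flagged). A tracked sequence is used only if ≥95 % of its
tracked pixels are valid. Per-pixel unit spectra feed flow training and
scoring; per-ROI medians (of unit spectra for the heterogeneity analyses,
of physical reflectances for Beer-Lambert) feed everything else. ROI tracks
are inputs; tracking itself is out of scope.

Saturation thresholds default to 5 %/98 % of full scale at the module level
and are configurable. The synthetic studies use 2 %/98 %: realistic kidney
band reflectance spans roughly 0.024–0.48, so with reference-normalized
reflectance bounded near 1 the darkest blood-absorbing bands necessarily
sit below 5 % of full scale — the rule is the fixed part, the counts
threshold is an acquisition-setup property.

## Flow ensemble and WAIC index

Each density estimator is a stack of affine coupling blocks (study default
8 blocks, 64 hidden units; the full-scale configuration of 20 blocks and
256 hidden units remains available) with fixed per-block channel
permutations. The subnetworks are 3-layer ReLU MLPs whose final layer is
zero-initialised, so an untrained flow is exactly the identity; scale
outputs pass through the soft clamp 2·tanh(s/2). Inputs are z-score
normalized with statistics frozen from the training data; the z-norm
Jacobian is included in the log-determinant so log P is a density in the
original space. Forward, inverse, analytic gradients and Adam are
implemented in numpy; gradient and log-determinant correctness is verified
against finite differences in the tests.

Training minimises the exact negative log-likelihood with Adam (lr 10⁻³ as
the protocol prescribes, weight decay 10⁻⁴), additive Gaussian noise
augmentation of SD 0.05 on the z-scored scale (which also regularises the
rank deficiency introduced by ℓ2 normalization — unit spectra live on a
15-dimensional sphere), and batch size 512 (256 in the reduced study
configuration). Ensembles hold members that differ only in their seed;
member i derives initialisation, batch order and noise from base_seed + i,
and all members share the z-norm statistics. Pretraining runs 100 epochs on
ℓ2-normalized simulated band spectra; patient fine-tuning re-estimates and
freezes the z-norm on the patient data, then continues training. The
desk-scale fine-tuning budget is 120 epochs over ≤2000 subsampled pixel
spectra (~960 Adam steps per member), chosen to keep a 10-patient study
within a 15-minute single-core budget; the protocol's 10 epochs over all
~126k pixel spectra is the paper-scale equivalent.

WAIC uses the population variance over members — the criterion is a moment
of the parameter distribution, not a sample estimate — and is exactly
shift-equivariant: adding c to all member log-likelihoods changes WAIC by
−c. Frame scoring: per-pixel WAIC → ROI median → mean of the two ROIs. A
frame with only one scorable ROI falls back to that ROI's value with a
warning (live monitoring must not halt). Min-max normalization of the
per-patient index series (both test sequences pooled) is display-only and
strictly monotone, hence AU-ROC-invariant. AU-ROC itself is computed by the
tie-aware rank-sum identity, which the tests pin to exhaustive pair
counting. An ensemble-free ablation (mean negative log-likelihood) is
available via `score="nll"`.

## Beer-Lambert baseline

Band absorbances a_k = −log r_k are regressed by OLS on the band-averaged
extinction pair plus an intercept that absorbs wavelength-independent
scattering losses (the intercept is fitted, not fixed). Band averaging
weights the per-nm coefficients by each band's filter response. Outputs are
v_HbO2·l, v_Hb·l, their sum and the oxygenation ratio — *unclipped*:
implausible estimates (oxygenation above 100 %, negative concentrations)
are reported as such, because they are themselves a finding. Inputs are
ROI-median reflectances before ℓ2 normalization (absorbance needs the
physical scale; a pure scale change moves only the intercept).

On noiseless synthetic cohorts the total-hemoglobin score separates the
states cleanly, while the oxygenation score is strongly biased by multiple
scattering and second-order filter peaks: its values often exceed 1 and its
ranking direction varies between patients. The tests assert exactly this
behaviour rather than an idealised one.

## Heterogeneity analyses

Cohort rows are per-frame spectra: the ℓ2-normalized ROI medians averaged
across tracked ROIs, labelled with patient and state. PCA (centred, two
components) reports scores and explained-variance fractions. Per band, a
random-intercept linear mixed model r_ij = α + β S_ij + δ_i + ε_ij is
fitted by REML (statsmodels MixedLM); the explained-variability proportions
are β̂²·Var(S) (over the realised design), σ̂²_δ and σ̂²_ε, normalised to sum
to one. The fixed-effect-variance convention is the documented default; the
decomposition the clinical analysis cites is behind a reference we cannot
consult, so the formula is deliberately explicit and swappable.
Non-convergent fits are flagged and their proportions withheld. KDE uses a
Gaussian product kernel with Silverman bandwidth on a grid padded by
several bandwidths so each density integrates to 1 within 10⁻³.

## Synthetic sessions and cohorts

Each synthetic patient draws a perfused three-layer state (oxygenation
restricted to [0.5, 0.9] and blood volume to [0.05, 0.25] so that ischemic
deltas stay inside the simulator's global ranges); the ischemic state
subtracts 0.30 from s and halves v_hb in every layer ("clear" profile;
"hard" is −0.03/0.95, "null" 0/1). The two state spectra are simulated once
per patient (2000 photons per wavelength over the camera's active support)
and reused per pixel with independent lognormal jitter of SD 2 % — per-pixel
Monte-Carlo would add nothing but runtime at this noise level. Under the
exact null the ischemic state reuses the perfused spectrum: identical
tissue must have the identical expected spectrum, and an independent MC
realisation would implant a frozen spectral offset between the test
sequences that the detector rightly flags.

The forward model per frame: state spectrum × per-patient band gain
(lognormal, SD 8 %, shared by both states — the interpatient offset that
makes patient variance dominate state variance across a cohort) → counts
D + r·(W−D)·illumination → additive Gaussian count noise (SD 1 % of full
scale) → saturation defects (0.2 % of pixels) → mosaic assembly. The
exposure model uses a 10-bit sensor, dark level 1 %, white level 90 % of
full scale with ±5 % band variation, and a 1.8× tissue illumination boost
(the acquisition protocol adjusts the light source between the white
reference and the tissue recording). Training and test sequences differ in
illumination scale (1.0 vs 1.1) to emulate laparoscope reinsertion; the two
test sequences share one scale because the protocol records them under
comparable conditions. Two 30×30 ROIs per sequence drift by ≤2 px/frame as
bounded random walks; tracks are emitted as ground truth. Sequences default
to 80 frames; evaluation uses the first 70. Everything derives from a
single seed; two runs with equal seeds are bit-identical end to end.

**What the synthetic cohorts do and do not show.** They establish that the
whole pipeline — simulation, preprocessing, ensemble training, WAIC
aggregation, evaluation — is correct, deterministic and separates states
whose spectral difference exceeds the within-state variability, under a
synthetic extinction table and an idealised scene (no specular highlights,
smoke, blood films, fat, motion blur or tracking error, and interpatient
variation reduced to tissue-parameter and gain diversity). A perfect median
AU-ROC on the clear cohort is therefore a statement about the method's
mechanics at a clearly separated operating point, not a clinical
performance claim; clinically reported figures live on data this package
cannot access.

## Study configurations and problem sizes

The default `RunConfig` is desk-scale, sized for a single CPU core:
pretraining corpus of 200 simulated samples at 500 photons/wavelength,
sessions at 2000 photons, 5-member ensembles of 8×64 flows, ≤2000
fine-tuning spectra, 120 fine-tune epochs; a 10-patient study completes in
roughly 8–10 minutes. `RunConfig.paper_scale()` restores the full settings
(20 blocks/256 hidden, all pixels, 10⁶ photons, 5.5·10⁵-sample corpus).
Reports carry per-patient AU-ROCs, five-number summaries per sequence,
cohort median/mean, every failure with its reason, and the full
configuration; re-running from a saved manifest reproduces every CSV
byte-for-byte.

## Known limitations

* The extinction table and filter responses are synthetic stand-ins; all
  quantitative results are conditional on them.
* Collection geometry is total diffuse reflectance (no numerical-aperture
  restriction); which layers' parameters varied in the original recordings
  is unknown, and all three are sampled independently.
* The reduced architecture and small corpus trade density-estimation
  fidelity for runtime; they are sufficient for the separation studied
  here but are not the full-scale estimator.
* ROI tracking, CLAHE preprocessing, fluorescence comparison and camera
  drivers are explicitly out of scope; ROI tracks are inputs.
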