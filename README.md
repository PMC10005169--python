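# msimon — multispectral ischemia monitoring

`msimon` implements contrast-agent-free, per-patient ischemia monitoring for
laparoscopic surgery from snapshot-mosaic multispectral video, together with
everything needed to study the method end to end without access to patient
recordings: a camera/optics model, a Monte-Carlo tissue simulator, the
preprocessing chain, a Beer-Lambert baseline, variability analyses and a
synthetic session generator.

## The problem and the method

During partial nephrectomy the renal artery is clamped, and the surgeon must
verify that the kidney is actually ischemic. The standard check injects a
fluorescent contrast agent (ICG) and cannot be repeated for ~30 minutes.
A 16-band snapshot multispectral camera (4×4 mosaic of Fabry-Pérot filters
on a 272×512 sensor) observes the kidney instead, and ischemia detection is
phrased as *out-of-distribution detection personalised to the patient on the
table*: a short video of perfused kidney recorded at the start of surgery is
the only training data.

Each well-exposed pixel yields a spectrum `x ∈ R^16` (white/dark reference
normalization followed by ℓ2 normalization across bands). An ensemble of
`n = 5` invertible coupling flows `f_Θ : R^16 → R^16` is trained by maximum
likelihood on these perfused spectra, each member differing only in its
random seed. The exact log-likelihood follows from the change of variables,

    log P(x|Θ) = −½‖f_Θ(x)‖² − (n/2) log 2π + log |det J_fΘ(x)|,

and new spectra are scored with the widely applicable information criterion

    WAIC(x) = Var_Θ[log P(x|Θ)] − E_Θ[log P(x|Θ)],

which is large when the estimated density is low *or* the members disagree.
Per frame, pixel WAIC values are aggregated by the median within each of two
tracked 30×30 ROIs and the two ROI values are averaged — the **ischemia
index**. Validation scores the first 70 frames of two test sequences (one
perfused, recorded after laparoscope reinsertion; one ischemic, recorded
after clamping) and computes the AU-ROC with ischemic as the positive class.

Because patient data are not publicly available, the package ships a
synthetic session generator whose patients are three-layer tissue models
(blood volume fraction, oxygenation, Mie scattering, anisotropy, refractive
index, thickness per layer) rendered by Monte-Carlo photon transport and
pushed through the full camera chain — mosaic frames, references, noise,
saturation defects, ROI drift and all.

## Worked example

```python
from msimon import (CameraModel, IschemiaMonitor, PatientConfig,
                    TrainConfig, generate_patient)

cam = CameraModel.default()
synth = generate_patient(PatientConfig(seed=3, frames_per_sequence=80,
                                       n_photons=2000), cam)
monitor = IschemiaMonitor.from_session(
    synth.session, cam, max_spectra=2000, low_fraction=0.02,
    train_config=TrainConfig(epochs=120, batch_size=256))
results = monitor.fit(seed=3)
evaluation = results.evaluate(synth.session, cam)
print(f"per-patient AU-ROC = {evaluation['auroc']:.3f}")
print(results.summary())
```

prints

```
per-patient AU-ROC = 1.000
Ischemia monitor (coupling-flow ensemble, WAIC index)
  members:            5
  architecture:       8 coupling blocks, 64 hidden units, soft clamp 2.0
  training spectra:   2000
  epochs / lr / wd:   120 / 0.001 / 0.0001
  noise augmentation: SD 0.05 (z-scored scale)
  base seed:          3
  final NLL per member: -58.994, -59.023, -59.115, -59.345, -59.406
```

The AU-ROC of 1.0 means every scored ischemic frame received a higher
ischemia index than every perfused test frame for this synthetic patient;
the strongly negative per-member negative log-likelihoods reflect the tight
concentration of the ℓ2-normalized pixel spectra. A whole-cohort study is
one call (`run_study(RunConfig(n_patients=10, base_seed=1))`) or one CLI
invocation (`msimon run-study --patients 10 --seed 1 --out results/`);
`run_baseline_study` applies the same protocol with Beer-Lambert
oxygenation / total-hemoglobin estimates as decision scores, and the
`heterogeneity` module reproduces the PCA, linear-mixed-model
variance-decomposition and kernel-density analyses of cohort spectra.

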