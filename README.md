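# mhsidetect

Sparse-representation tumor detection for medical hyperspectral images
(MHSI), aimed at researchers prototyping pixel-spectrum classifiers for
tissue screening — e.g. tongue-tumor delineation — without access to a
clinical hyperspectral database.

A hyperspectral camera records, at every pixel, a reflectance spectrum
over B narrow bands (by default 81 bands, 600–1000 nm at 5 nm). Tumor
and normal tissue differ in their spectral signatures, so each pixel can
be classified from its spectrum alone.

## Method

Raw radiance counts are first median-filtered per band (saliva glints
and motion produce impulse noise) and calibrated to relative reflectance
against a white board in the scene and a dark-current frame:

    R(λ) = (I_raw(λ) − I_dark(λ)) / (I_white(λ) − I_dark(λ))

Training pixels of the two classes form the subdictionaries
A_nc (noncancerous) and A_c (cancerous); their concatenation
A = [A_nc A_c] ∈ R^(B×N) has unit-norm columns. A test spectrum x is
sparse-coded against A,

    γ̂ = argmin ‖γ‖₁  s.t. ‖x − Aγ‖₂ ≤ ε,

solved either by orthogonal matching pursuit (default) or by basis
pursuit. Splitting γ̂ = [α̂; β̂] into the class blocks gives the class
reconstruction residuals r_nc = ‖x − A_nc α̂‖₂ and r_c = ‖x − A_c β̂‖₂
and the decision score

    D(x) = log₁₀(r_nc / r_c),     D(x) > 0 ⇒ cancerous.

Glare saturates pixels inside tumors, punching holes in the binary
detection mask; a morphological hole fill (background components not
connected to the image border become foreground) recovers them.
Performance is reported as pixel-level FPR (false positives over all
normal pixels), FNR (false negatives over all tumor pixels) and
accuracy.

Because no public MHSI tumor database exists, the package ships a
synthetic scene simulator (smooth two-class reflectance profiles with
wavelength-dependent noise, elliptical tumors, band-contiguous glare
impulses, paired white/dark reference frames) so the entire pipeline is
testable end to end.

## Worked example

```python
from mhsidetect import PipelineConfig, SimulationConfig, run_pipeline

cfg = SimulationConfig(seed=11, separation=0.15,
                       sd_normal=0.03, sd_cancer=0.03)
detection, report, manifest = run_pipeline(cfg, PipelineConfig(split_seed=11))
print(report.to_dict())
```

prints

```
{'tp': 391, 'fp': 0, 'tn': 3703, 'fn': 2, 'fnr': 0.5089058524173028,
 'fpr': 0.0, 'accuracy': 99.951171875}
```

i.e. on a 64×64×81 scene with a class-mean separation of 0.15
reflectance units and per-band noise sd 0.03, training on 10% of the
labeled pixels, the detector recovers all but two tumor pixels (the two
ellipse tips, where the 3×3 median filter mixes in majority-normal
neighbours) with no false positives: 99.95% pixel accuracy, FNR 0.51%,
FPR 0%.

The same run is available from the shell:

```sh
mhsidetect run-all --seed 11 --out-dir run1/
```

and the individual stages as `mhsidetect simulate | preprocess | train |
detect | evaluate` (see `--help` on each).

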