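# Methods

## Model and procedure

The detector treats each pixel of a hyperspectral tissue cube as an
independent B-dimensional reflectance spectrum and assumes each tissue
class occupies a low-dimensional subspace spanned by its own training
spectra. A test spectrum x is sparse-coded against the concatenated
two-class dictionary A = [A_nc A_c] (unit-norm columns), the coefficient
vector is split into its class blocks α̂ and β̂, and the pixel is
assigned to the class that reconstructs it with the smaller residual,
through the score D(x) = log₁₀(r_nc / r_c) with r_nc = ‖x − A_nc α̂‖₂
and r_c = ‖x − A_c β̂‖₂. D(x) > 0 means cancerous; a tie (D = 0) falls
to noncancerous, the conservative side for a screening tool. Both
residuals are floored at 1e−12 before the ratio so that an exact
in-class reconstruction produces a large finite score instead of an
infinity; the sign of D, the only quantity the decision uses, does not
depend on the logarithm base.

The pipeline order is fixed: median-denoise the raw counts per band,
calibrate to relative reflectance, split labeled pixels per class into
train/test, assemble the dictionary from training pixels, classify
every pixel, fill holes in the binary mask, score against ground truth.

## Sparse solvers

*Greedy (default).* Orthogonal matching pursuit: select the atom with
maximal |correlation| with the current residual, re-fit least squares on
the support, stop when the residual norm reaches ε, when `max_atoms`
atoms are active, when the residual is orthogonal to every atom, or
when an iteration fails to decrease the residual. OMP is the pipeline
default because per-pixel supports are tiny (a few atoms) and the cube
has thousands of pixels.

*Basis pursuit.* min ‖γ‖₁ s.t. ‖x − Aγ‖₂ ≤ ε. For ε at or near zero the
equality-constrained program is solved exactly as the classical linear
program min 1ᵀ(u+v) s.t. A(u−v) = x, u,v ≥ 0 (HiGHS); vertex solutions
make the support numerically clean. For a strictly positive tolerance
the program is solved through its penalized-lasso equivalent: the lasso
residual norm is monotone in the penalty, so bisection on the penalty
finds the point whose residual meets ε, which is the ℓ1-minimal feasible
solution. Infeasible tolerances (below the full least-squares residual)
are reported as errors rather than silently relaxed.

*Exhaustive ℓ0 oracle.* For testing only: enumerate all supports up to a
size cap (budget-guarded), least-squares on each, return the sparsest
support attaining the global minimum residual (ties by residual, then
lexicographic order). Solver tests assert support agreement and oracle
dominance against it; the pipeline never calls it.

Coefficients below 1e−10 in magnitude count as numerical zeros when
reporting supports, so exact zeros from the LP and coordinate-descent
dust are treated alike.

## Parameters

| parameter | default | meaning |
|---|---|---|
| spectral grid | 600–1000 nm, 5 nm, B = 81 | camera band set |
| median window | 3×3 | smallest window that removes single-pixel speckle without eroding tumor margins; edge handling is edge-including reflection |
| calibration guard | 1e−9 | entries with \|white − dark\| below it are zero-filled and logged (dead bands) instead of producing NaN |
| ε (solver tolerance) | 0.05·‖x‖₂ | relative, because reflectance noise scales with signal; ε = 0 reproduces the equality program |
| max_atoms | 10 | sparsity cap for OMP |
| residual floor | 1e−12 | keeps D(x) finite at exact reconstructions |
| atom normalization | on | unnormalized atoms bias selection toward bright spectra |
| train fraction | 0.1 | 10%/90% per-class split of labeled pixels |
| hole-fill connectivity | 4 (background) | pairs with 8-connected foreground, avoiding the topological paradox of like-connected complements |

## Synthetic scenes

The simulator generates what a clinical acquisition would provide: a raw
radiance cube, a white-board frame, a dark-current frame and a
ground-truth mask. Class mean spectra are smooth synthetic curves — a
logistic rise across the red edge for normal mucosa (≈0.56 → 0.75) and a
tumor curve sitting below it by a Gaussian-shaped gap whose supremum is
the `separation` parameter, peaking near 720 nm; per-band standard
deviations rise from 0.02 to 0.05 toward the NIR, the tumor class
slightly noisier. These magnitudes are design choices for realistic
class separability, not measurements. Tumors are rasterized ellipses
(parametric ground truth with exact areas; arbitrary masks can be
supplied as files). Saliva glare is modeled as per-pixel Bernoulli
impulses (default 1%) that saturate a random contiguous band range at
1.5 reflectance — specular highlights are broadband and exceed the white
reference. Raw counts invert the calibration equation against a
halogen-like lamp spectrum (2000–3500 counts) and a 100-count dark level
with 0.5 counts of read noise, which exercises the division guard
realistically. One integer seed drives everything; identical seeds give
bit-identical scenes.

What the simulator does **not** emulate: spatial texture within a tissue
class (pixels are i.i.d. around the class mean), tongue motion blur,
shot noise proportional to signal, inter-patient spectral variability,
or partially annotated scenes beyond the 255-label mechanism. Passing
tests therefore demonstrate correctness of the algorithmic chain and
its behavior under the stated noise model, not clinical performance.

## Numerical choices and degenerate inputs

- Reference scale: the default test and acceptance problem is a
  64×64×81 scene with separation 0.15 and sd 0.03, 5 seeds — large
  enough for stable rates (~20k labeled pixels pooled), small enough
  that the whole suite runs in well under a minute.
- The two persistent errors on that reference scene are the ellipse
  tips, where the 3×3 median replaces the tumor-tip spectrum with
  majority-normal neighbours; they are a property of the geometry, not
  of the noise seed.
- Stored sample type on disk follows the in-memory array dtype (uint16
  for integer camera counts, float32/float64 for calibrated data); the
  ENVI header's `data type` field governs reading, and a nonstandard
  `cube kind` key preserves the raw/reflectance distinction.
- Masks use {0, 1, 255} with 255 = unlabeled so partially annotated
  scenes are expressible; unlabeled pixels are excluded from training
  and scoring but still classified.
- Ties in the decision rule (r_nc = r_c exactly) go to noncancerous.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; run manifests record seeds and a config hash and
  are byte-identical across repeated runs.

## Known limitations

- Per-pixel classification ignores spatial context except through the
  median filter and hole filling.
- The lasso-bisection basis-pursuit path is accurate but slow for large
  dictionaries; OMP is the practical choice for full cubes.
- FNR/FPR are undefined when a scene lacks the corresponding class;
  they are reported as not-applicable rather than 0.
- The simulator's class subspaces are one-dimensional (mean ± isotropic
  noise), which flatters any subspace classifier; real tissue spectra
  span richer subspaces.
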