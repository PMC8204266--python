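# ddes — double-diffusion-encoding spectroscopy analysis

`ddes` simulates and analyses **angular double diffusion encoding (DDE)**
experiments of the kind used in diffusion-weighted MR spectroscopy (DDES) to
measure *microscopic* diffusion anisotropy in brain tissue — the anisotropy
of individual cellular microdomains (axons, dendrites, astrocytic
processes), independent of how those domains are oriented across the
measurement volume. It is written for researchers modelling compartmental
diffusion in gray and white matter who need a tested, reproducible pipeline
from raw angular-DDE signal tables to microscopic diffusivities, µFA and
intracellular tortuosity, without access to scanner data.

## The model

Each microdomain is an axially symmetric Gaussian diffusion tensor **D**
with axial and radial diffusivities D<sub>∥</sub> ≥ D<sub>⊥</sub> ≥ 0
(µm²/ms). A DDE block applies two encodings in a plane (e₁, e₂), the second
rotated by θ from the first. For an ensemble of N rotations R<sub>j</sub>
of the domain (a "powder"):

S(b, θ) = S₀/N · Σ<sub>j</sub> exp(−b/2 · e₁ᵀD′<sub>j</sub>e₁) ·
exp(−b/2 · (cos²θ · e₁ᵀD′<sub>j</sub>e₁ + sin²θ · e₂ᵀD′<sub>j</sub>e₂)),
D′<sub>j</sub> = R<sub>j</sub>D R<sub>j</sub>ᵀ

with b in s/mm² (b·D is made unitless by 1e−3). The θ-modulation of S
carries the microscopic anisotropy: it is flat for isotropic domains and
deepest for "sticks" (D<sub>⊥</sub> = 0). Estimates of
(D<sub>∥</sub>, D<sub>⊥</sub>) are obtained by non-linear least squares
under the prolate constraint, and summarised by

µFA = (D<sub>∥</sub> − D<sub>⊥</sub>) / √(D<sub>∥</sub>² + 2 D<sub>⊥</sub>²),
  T = √(D<sub>free</sub> / D<sub>∥</sub>)

where T is the intracellular tortuosity against the free diffusivity at
37 °C (water 3.0, tNAA 0.78 µm²/ms).

The package covers the full study design: acquisition-scheme bookkeeping
(3 orthogonal planes × 8 angles × 2 gradient polarities per b block),
polarity geometric-mean cross-term correction, plane averaging and b = 0
normalization, single-b metabolite fits and two-b water fits whose fitted
S₀ tracks the progressive suppression of extracellular water and CSF with
b, Monte-Carlo noise propagation, and cohort-level regression of
D<sub>∥</sub> on white-matter fraction with pure-tissue extrapolation.

## Worked example

```python
from ddes import (AxisymmetricTensor, build_scheme, generate_dataset,
                  reduce_to_powder_signal, fit_theta_modulation,
                  microscopic_fa, tortuosity, uniform_orientations)

ori = uniform_orientations(256)                      # Fibonacci powder
stick = AxisymmetricTensor.stick(0.47)               # tNAA-like thin fiber
scheme = build_scheme("metabolite")                  # b = {0, 7199}, 294 records
table = generate_dataset(stick, scheme, snr=35.0, seed=1, orientations=ori)
fit = fit_theta_modulation(reduce_to_powder_signal(table), orientations=ori)
print(f"D_par={fit.d_par:.3f}  D_perp={fit.d_perp:.3f}  uFA={fit.mu_fa:.3f}")
print(f"T(tNAA) = {tortuosity(0.78, fit.d_par):.2f}")
print(f"uFA(WM water) = {microscopic_fa(1.83, 0.06):.2f}")
```

prints

```
D_par=0.473  D_perp=0.001  uFA=0.998
T(tNAA) = 1.28
uFA(WM water) = 0.97
```

i.e. the noisy metabolite protocol recovers the stick substrate (with a
small noise-rectification bias in D<sub>⊥</sub>, quantified in
`analysis/03_noise_propagation.py`), the neuronal tortuosity in white
matter is ≈1.3, and the white-matter intracellular water tensor
(1.83, 0.06) µm²/ms corresponds to µFA = 0.97.

The numbered drivers under `analysis/` run the full study-shaped analyses
and write their tables under `results/`: forward-signal surveys
(`01_forward_signals.py`), noiseless metabolite/water fits with S₀
suppression across b pairs (`02_fit_metabolites_and_water.py`), noise
propagation over an SNR grid (`03_noise_propagation.py`), and synthetic
cohort regression with group statistics (`04_cohort_regression.py`), e.g.

```
water: D_par = 0.974 + 0.0099 * WM%  (R^2 = 0.90, p = 8.7e-10, n = 19)
  pure WM: D_par = 1.96 +- 0.11 um^2/ms,  T = 1.24 +- 0.03
  pure GM: D_par = 0.97 +- 0.11 um^2/ms,  T = 1.75 +- 0.10
```

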