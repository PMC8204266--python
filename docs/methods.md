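# Methods

## Signal model

A microdomain is an axially symmetric Gaussian diffusion tensor with axial
and radial diffusivities `d_par >= d_perp >= 0` (µm²/ms). One angular-DDE
condition applies two diffusion encodings of weighting b/2 each in a plane
spanned by orthonormal vectors (e₁, e₂); the second encoding is rotated by
θ from the first within the plane. For a domain rotated so that its
symmetry axis is the unit vector u, the quadratic forms reduce to
`q(e) = d_perp + (d_par − d_perp)(e·u)²`, and the attenuation is

```
S(b, θ | u) = exp(−b/2 · q(e₁)) · exp(−b/2 · (cos²θ q(e₁) + sin²θ q(e₂)))
```

The powder signal is the arithmetic mean of this expression over an
orientation set approximating the uniform distribution on the sphere;
the default is a 256-point Fibonacci lattice (deterministic, low
discrepancy; its mean outer product deviates from I/3 by ~1e−4, and its
powder averages differ from a 28 800-node Gauss–Legendre × trapezoid sphere
quadrature by ≲0.1% for all study-relevant tensors at b = 7199 s/mm²).
A seeded isotropic-random alternative exists for oracle testing.

Units: b in s/mm², diffusivities in µm²/ms, so exponents carry a factor
1e−3 (b = 7199 with D = 3 gives b·D = 21.597 — CSF attenuated to 4e−10,
i.e. fully suppressed at the highest b).

**Cross-term variants.** The default exponent (`variant="no_cross_term"`)
uses only the diagonal quadratic forms, as written above.
`variant="full_quadratic"` adds the off-diagonal term
`2 sinθ cosθ · e₁ᵀD′e₂` that the quadratic form of the rotated second
encoding direction produces. The cross term averages to zero over a powder
at first order, but inside the exponential it survives at second order
(convexity of exp), so the two variants agree within 0.5% only for
`b·(d_par − d_perp) ≲ 0.6`; at b = 7199 s/mm² the full form is brighter at
intermediate angles by ~7% for a tNAA-like stick and ~21% for a
white-matter-water-like tensor. Which exponent a given published analysis
used therefore matters at high b; both are provided, and all defaults use
the diagonal form.

**Ordering of angular conditions.** For any domain and any b,
`E[X²] ≥ E[X·Y]` with X, Y the two per-encoding attenuations
(Cauchy–Schwarz), so the parallel powder signal S(θ=0°) always exceeds the
perpendicular S(θ=90°); the parallel/perpendicular contrast grows with the
unitless weighting b·MD and with µFA. The model is symmetric under
θ → 360° − θ (exactly for the diagonal variant; to Monte-Carlo tolerance
for the full quadratic) and has no parallel/antiparallel (0° vs 180°)
contrast — a nonzero antiparallel contrast in data flags time-dependent
(restricted or exchanging) diffusion outside this model.

## Acquisition scheme and synthetic data

One protocol block per nonzero b contains, per average: one b = 0 record
plus 3 planes × 8 angles (0°–315° in 45° steps) × 2 gradient polarities of
DW records — (3·8·2 + 1)·n_averages records per block. Defaults: the
metabolite protocol b = {0, 7199} s/mm² with 6 averages (294 stored
acquisitions) and the water protocol b = {0, 918, 2066, 4050, 7199} with
2 averages (4 blocks of 98). The encoding planes are spanned by the
orthogonal triplet [1 1 −0.5], [−0.5 1 1], [1 −0.5 1] (normalized); plane k
pairs v_k with v_(k mod 3)+1. Sequence timing (δ = 31 ms bipolar lobes,
τ = 10 ms, Δ = 45 ms, t_m = 5.3 ms) is carried as metadata only; b values
are inputs, not derived from waveforms.

Synthetic datasets add, in order: (1) per-condition multiplicative polarity
cross-terms exp(±c), c ~ N(0, `cross_term_scale`) — the minimal structure
that the polarity geometric mean cancels exactly; (2) Gaussian noise of sd
S₀/SNR per stored acquisition (Rician optionally, for magnitude data near
the noise floor; at SNR ≥ 20 the two give fitted parameters differing by
less than the parameter spread). SNR is defined against the b = 0 amplitude
of a single stored acquisition; averaging gains accrue in the reduction.

The generator emulates amplitude-level data only: no spectral lineshapes,
quantification (LCModel-style) noise correlations, eddy currents, motion,
cardiac pulsation, or residual macroscopic order across the volume. Passing
tests therefore validate the pipeline's mathematics and its noise response,
not robustness to those spectral-domain effects.

## Reduction

Per (b, θ): average repeats, geometric-mean the two polarities
(√(S⁺·S⁻), cancelling multiplicative cross-terms exactly), average the
three planes (the emulated powder average), and normalize by the mean
b = 0 amplitude. On scalar amplitudes these steps commute up to noise, so
one code path serves metabolite and water modalities. Polarity pairs in
which either side is nonpositive (possible at extreme noise) are excluded
from the geometric mean and counted in the provenance rather than clipped —
transparency over silent repair.

## Fitting

Non-linear least squares of the powder model against the normalized series,
initialized at (D_par, D_perp, S₀) = (1, 0, 1). The prolate constraint is
enforced by the parameterization D_perp = f·D_par with f ∈ [0, 1] inside a
bounded trust-region solver (scipy `least_squares`, `x_scale='jac'`,
ftol = xtol = 1e−15, gtol disabled). These tight tolerances matter: at
b = 7199 an isotropic substrate attenuates to ~1e−8 and looser settings
stall ~1e−2 from the optimum. The model averages the same three encoding
planes as the reduction, so noiseless data are recovered exactly
(worst-case error ~1e−5 over d_par ∈ [0.2, 2.5] and all prolate ratios);
with a single-plane model the finite lattice's plane anisotropy leaves a
~2e−3 bias. Optional jittered multi-starts are available but unnecessary in
practice — random initializations reach the same optimum.

Modes: `metabolite` fits (D_par, D_perp) to the 8 θ-points of a single
nonzero b with S₀ fixed at 1 (only one b = 0 point exists after averaging);
`water` fits (D_par, D_perp, S₀) to two consecutive b values, attributing
the result to the higher b of the pair — pairing (0, 918) → 918,
(918, 2066) → 2066, (2066, 4050) → 4050, (4050, 7199) → 7199, so the
lowest pair's fitted S₀ is 1 by normalization. For mixtures containing
fast isotropic compartments the fitted S₀ decreases monotonically across
pairs, and the highest-pair tensor approaches the intracellular component.
Exactly isotropic data drive f to its boundary; the result is reported as
d_par = d_perp with µFA = 0 rather than an error.

Derived metrics: µFA = (D_par − D_perp)/√(D_par² + 2 D_perp²) — the
normalization without the √(3/2) DTI prefactor, which reproduces the
reported (D_par, D_perp, µFA) triples, e.g. (1.83, 0.06) → 0.97 and
(1.43, 0.12) → 0.91 — and tortuosity T = √(D_free/D_par) with
D_free(water) = 3.0 and D_free(tNAA) = 0.78 µm²/ms at 37 °C. The square
root is deliberate: it is the convention that reproduces all the reported
tortuosity values (e.g. √(3/1.83) = 1.28), whereas the plain ratio does
not (3/1.83 = 1.64).

## Noise propagation

For a stick substrate the positivity constraint rectifies noise into a
positive bias of fitted D_perp and a negative bias of D_par, both shrinking
with SNR. The Monte-Carlo driver generates noisy realizations of the
metabolite protocol per SNR, runs the full reduction and fit on each, and
aggregates means and sds (1000 realizations for the headline check;
250 per SNR point in the survey driver).

What the stated SNR refers to changes the answer by an order of magnitude,
because the metabolite protocol averages 36 stored acquisitions into each
reduced θ-point. With SNR per stored acquisition (the default semantics
everywhere in this package), SNR 35 gives a mean fitted D_perp of
~0.001–0.002 µm²/ms. If instead the SNR is referenced to the
condition-averaged dataset (`snr_reference="condition_average"` — raw
acquisitions then have SNR ≈ 2, typical of single-shot metabolite spectra),
the same nominal SNR 35 gives a mean fitted D_perp ≈ 0.03 with sd of the
same order, at the cost of occasional nonpositive amplitudes near the noise
floor. Both references are computed and reported by the analysis driver;
the ambiguity is irreducible at the amplitude level and documented rather
than resolved.

## Cohorts and regression

Synthetic cohorts draw per-subject GM/WM/CSF fractions from per-VOI normal
distributions (defaults: PWM 15.1/82.8/2.1, OGM 50.1/36.2/13.7,
sOGM 67.7/19.8/12.5 percent means with the matching sds; group sizes
8/7/4), clip at zero and renormalize to 100. Each molecule's true tensor
interpolates linearly in w = WM/(GM+WM) between pure-tissue endpoints
(defaults, µm²/ms: water D_par 0.97 → 1.95, D_perp 0.14 → 0.05;
tNAA D_par 0.25 → 0.51, D_perp 0.05). The water substrate at the highest b
is modelled as its intracellular tensor alone, on the assumption that CSF
and extracellular signal are suppressed there; CSF is likewise excluded
from the fraction denominator before regression.

Ordinary least squares (statsmodels) of fitted D_par on the WM percentage
of (GM + WM) gives slope, intercept, R², and endpoint extrapolations at 0%
and 100% WM. Endpoint uncertainties default to the prediction-interval SE
(the formula that treats an endpoint as a new observation); the
confidence-of-the-mean SE is available, as is a seeded bootstrap — the
construction behind published ± values on extrapolations is rarely stated,
so it is configurable rather than guessed. Endpoint tortuosities use the
delta method, se_T = se_D·T/(2 D). Tortuosity-vs-fraction can be computed
both ways (transform the D_par endpoints, or regress per-subject
tortuosities); T(w) is convex in w, so the transform-then-fit line sits
below the fit-then-transform endpoints outside the data hull — the
endpoint-transform convention drives the reported values.

Group comparisons: Welch's unequal-variance t-test per metric,
Benjamini–Hochberg FDR across the metric family (default α = 0.05) or
Bonferroni for the fixed family of 4 regression tests (per-test threshold
0.05/4 = 0.0125).

## Problem sizes and reproducibility

Defaults everywhere: 256 orientations, the 294-record metabolite and
4×98-record water protocols, cohorts of 19 subjects, 1000 noise
realizations for the headline noise check, 250 per SNR point in the survey,
and 200 seeded cohorts for the regression-coverage check. Every stochastic
component takes a seed (numpy `default_rng`); Fibonacci orientation sets
and noiseless pipelines are fully deterministic.

## Known limitations

- Gaussian, time-independent compartments only: no restriction, exchange,
  or mixing-time effects; oblate tensors are rejected by construction; the
  monodisperse assumption means distributions of tensors are out of scope.
- Amplitude-level simulation only (see above); no spectral quantification
  or debiasing of magnitude data near the noise floor (none is applied to
  the lowest-S₀ water fits either).
- b values are protocol inputs; no gradient-waveform b-matrix computation.
- The two-b water fit attributes its estimate to the higher b of the pair;
  other attributions are configurable but untested against published
  conventions.
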