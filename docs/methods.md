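# Methods

## The estimation problem

Total iron content in soil (TICS, g/kg) is a trace constituent: its imprint
on vis-NIR reflectance (350–2500 nm) is a set of weak, broad modulations of
absorption-feature depths, superimposed on much larger iron-independent
variation (albedo, moisture, texture, organic matter). Raw reflectance
therefore correlates poorly with TICS, and the estimation chain is a
sequence of transforms that strip the confounds while keeping the signal:
smoothing → wavelet-packet denoising → first derivative → correlation band
screening → harmonic feature extraction → PCA → a small regression network.

## Transforms

**Five-point weighted average.** Interior points are replaced by
`(v[i−2]/4 + v[i−1]/2 + v[i] + v[i+1]/2 + v[i+2]/4)/2.5`. The weights sum
to 2.5, so the output is a true weighted mean: constants are preserved
exactly and, by symmetry, so are straight lines at interior points. The
first two and last two points are copied unchanged — the window is
undefined there, and fabricating edge values would corrupt the derivative.

**First derivative.** Central difference
`R'(λ_i) = [R(λ_{i+1}) − R(λ_{i−1})]/(λ_{i+1} − λ_{i−1})` at interior
points, one-sided at the ends; units reflectance/nm. This removes additive
offsets exactly and converts linear background into a constant, which the
subsequent correlation screen ignores.

**Wavelet-packet denoising.** Full packet tree with db10, symmetric signal
extension, default depth 3 (on 2151 bands every level-3 subband keeps
> 250 coefficients). The best basis is chosen bottom-up by additive-cost
comparison (parent cost vs sum of child costs). The cost is the Shannon
entropy of squared coefficients normalised by total signal energy, so
node costs add across any disjoint cover; a log-energy cost is available.
Coefficients of every best-basis node except the pure low-frequency
(approximation) node are soft-thresholded,
`sign(x)·max(|x|−t, 0)`, with the universal threshold
`t = σ̂·√(2 ln L)`, `σ̂ = median(|d₁|)/0.6745` estimated from the
finest-scale detail coefficients. With threshold 0 the transform
round-trips to the input (perfect reconstruction), which the tests verify
to 1e-8. Because the best basis can mix node depths and the signal length
is not dyadic, the inverse transform is assembled bottom-up with each
`idwt` output trimmed to the recorded parent coefficient length.

**Harmonic analysis.** A length-N curve is treated as one period and
expanded as a discrete Fourier series with 1-based index k = 1..N:
`A₀/2 = (1/N)Σv_k`, `A_h = (2/N)Σv_k cos(2πhk/N)`,
`B_h = (2/N)Σv_k sin(2πhk/N)`, `C_h = √(A_h²+B_h²)`. The printed phase
form `tan⁻¹(A_h/B_h)` is quadrant-ambiguous and undefined at `B_h = 0`;
the implementation uses the two-argument arctangent `φ_h = atan2(A_h, B_h)`,
which makes `C_h sin(2πhk/N + φ_h)` identical to the (A, B) expansion for
all sign combinations, and sets `φ_h = 0` when `C_h < 1e-12`. The k-index
origin matters: phases differ under 0-based indexing, so the 1-based
convention is fixed throughout. Orders alias as `A_{N−h} = A_h`,
`B_{N−h} = −B_h`, so decomposing to order N (the default, mirroring the
150-band/150-order convention) is redundant above N/2 — documented, not
hidden. The model uses the fixed 12-parameter set
`[A₀/2, A₁, A₂, A₃, B₁, B₂, B₃, C₁, C₂, C₃, φ₁, φ₂]`: low orders carry the
broad energy structure of the screened-band curve while per-band noise
spreads over all N orders, which is the denoising payoff of the
compression. The direct O(N·H) sums are the definition of correctness; at
these sizes (N = 150) no FFT path is needed.

**Band screening.** Pearson correlation of every band with TICS; bands
with |r| above the 0.55 cutoff are ranked by |r| and the top 150 kept,
re-sorted by wavelength. If fewer than 150 pass — routine for the FD
variant under realistic noise — the selection falls back to the global top
150 by |r| and the result is flagged `relaxed` rather than silently
shrinking the feature count; downstream stages expect a fixed width.
Pearson (not rank) correlation is used throughout: the alternating-sign
behaviour of derivative spectra against a constituent is a linear-dependence
signature.

**PCA.** Columns are centred and scaled to unit sample variance
(correlation-matrix PCA) because the harmonic parameters mix units —
amplitudes in derivative-reflectance units against phases in radians.
Eigenvalues are reported as score variances (ddof = 1), identical to the
correlation-matrix eigenvalues; contributions are percentages of total
variance (= column count). Exactly five components are returned, with a
warning when they capture less than the 90 % guideline; component signs
follow the largest-|loading|-positive convention so scores are reproducible
across linear-algebra backends. Constant columns are dropped with a
warning rather than imputed.

**BP network.** 5–3–1 feed-forward network: tanh hidden layer, linear
output. Full-batch gradient descent with an additional momentum term
(learning rate 0.01, momentum 0.9, at most 2000 iterations, early stop
when the training MSE in scaled space reaches 0.001). Inputs and targets
are min–max scaled to [−1, 1] before training — tanh saturates otherwise —
and predictions are inverse-scaled to g/kg. The stopping goal is defined
on the scaled targets (configurable); on raw g/kg a goal of 0.001 would be
unreachable for any realistic soil dataset. Weights initialise from a
seeded uniform [−0.5, 0.5] draw, making training bitwise reproducible.
R² defaults to the squared Pearson correlation between measured and
predicted values (the measured-vs-estimated scatter-fit convention);
`1 − SSE/SST` is available via `r2_mode="sse"`. Splits are seeded uniform
draws with the fixed stratum counts — loessial 51 → 35/16, sandy
33 → 20/13, mixed 84 → 45/39 — falling back to the corresponding training
fraction (with a warning) when a dataset's size differs.

Band screening and PCA are fitted on the full dataset before splitting,
and the mixed-soil run pools all samples for screening; per-type runs
re-screen independently. This matches the original workflow; the mild
selection leakage it implies is a property of that workflow, not of the
evaluation code.

## Synthetic data: what it emulates, and what it does not

No field data are deposited, so the generator plants a known
TICS → spectrum link and the tests measure whether the chain recovers it.
Per sample:

* TICS from a normal distribution truncated (by exact rejection sampling)
  to the published per-stratum ranges: loessial n=51, mean 23.26, SD 2.28,
  range [15.42, 27.51] g/kg; sandy n=33, mean 19.20, SD 4.60, range
  [7.20, 27.18]; mixed = the 84-sample concatenation.
* A smooth monotone baseline (0.15 → 0.60 reflectance, saturating
  exponential) plus a per-sample brightness offset (SD 0.07) and spectral
  tilt (SD 2×10⁻⁵ /nm), both independent of TICS. These dominate raw
  band variance, which is why raw reflectance correlates weakly with TICS
  while derivatives do not see them at all.
* Six Gaussian absorption features (450, 550, 900, 1400, 1900, 2200 nm)
  whose depths grow linearly with TICS. The dominant iron coupling
  (0.005 reflectance per g/kg) sits on the 1900 nm feature, so the
  informative derivative bands concentrate around its shoulders; the
  screened-band curve is then smooth and its energy lands in the low
  harmonic orders that the 12-parameter set keeps.
* A structured perturbation per sample — eight random cosines with
  10–40 nm periods, total SD 0.002 — standing in for iron-independent
  compositional variation (moisture films, particle-size scattering,
  overlapping constituent absorptions). Its short correlation length is
  the load-bearing property: it largely survives smoothing and wavelet
  thresholding, is amplified by differentiation, but decorrelates across
  the screened-band sequence, so harmonic compression averages it down
  while the per-band variants keep it.
* White measurement noise, SD 0.004 reflectance — the component wavelet
  thresholding removes well, which is what separates WPT-FD from FD.

Reflectance is clipped to [0.01, 0.99]; configurations whose pre-clip
values leave [0, 1] in more than 5 % of bands are rejected.

These amplitudes were fixed as a package-level calibration so that the
synthetic study exhibits, at n = 84, the qualitative structure the method
is designed around: raw spectra uninformative, derivative bands moderately
informative, denoised derivatives better, harmonic parameters best. Under
these conditions the ten-seed mixed-soil study gives mean held-out R² of
roughly 0.84 (FD), 0.88–0.90 (WPT-FD) and 0.92–0.93 (WPT-FD-HA).

What passing tests do **not** show: performance on real soils. The
generator is phenomenological — linear depth–TICS coupling, Gaussian
features, stationary noise; it omits nonlinear constituent interactions,
inter-sample moisture/texture covariance, instrument detector-junction
artefacts and any radiative-transfer physics. One visible consequence:
the single-soil profiles inherit the published TICS spreads, so loessial
(SD 2.28 g/kg) carries half the signal variance of mixed against the same
noise floor, and its synthetic recovery is accordingly weaker — the
opposite of the field finding, where within-type spectral homogeneity made
single-soil models the stronger ones. The synthetic study validates the
machinery, not the field accuracy.

## Numerical choices and degenerate inputs

* Derivative endpoints: one-sided differences (keeps output length equal
  to input length for band bookkeeping).
* Zero-variance bands/components get r = 0 with an explicit flag, never
  NaN.
* A constant target widens its scaling window by ±0.5 so the inverse
  transform stays defined; constant feature columns are a training error
  (scaling would not be invertible).
* NaN/overflow in the training loss raises immediately with the iteration
  number and a suggestion to lower the learning rate.
* `wpt_denoise` refuses depths beyond `pywt.dwt_max_level` and reports the
  admissible maximum.
* Harmonic phases live in (−π, π]; zero-amplitude components take phase 0
  by convention.

## Known limitations

* The BP network is a fixed small topology by design; no hyperparameter
  search, regularisation, or uncertainty quantification.
* Screening-before-splitting (see above) overstates absolute held-out
  accuracy slightly; comparisons across variants share the bias.
* The harmonic parameter set is fixed at the 12 low-order terms; a
  per-dataset |r|-driven selection is not implemented.
* Binary instrument formats (.asd) are out of scope; spectra enter as
  delimited text.
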