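# ferrospec

Estimation of **total iron content in soil (TICS, g/kg)** from vis-NIR
reflectance spectra (350–2500 nm), for soil scientists and chemometricians
working with ASD-style field/lab spectrometer exports.

Iron gives soil spectra only a weak, broad imprint: raw reflectance barely
correlates with TICS because sample-to-sample brightness and composition
variation swamps the narrow iron-coupled absorption features. This package
implements a feature-engineering chain that digs the signal out:

1. **Five-point weighted smoothing** —
   `S_n = (S_{n-2}/4 + S_{n-1}/2 + S_n + S_{n+1}/2 + S_{n+2}/4)/2.5`
2. **Wavelet-packet denoising (WPT)** — full db10 packet tree, best basis by
   minimum Shannon cost, universal soft threshold, inverse transform
3. **First derivative (FD)** — central difference
   `R'(λ_i) = [R(λ_{i+1}) − R(λ_{i−1})]/(λ_{i+1} − λ_{i−1})`, removing
   additive baseline and linear background
4. **Band screening** — the 150 wavelengths with the largest |Pearson r|
   against TICS (cutoff |r| > 0.55)
5. **Harmonic analysis (HA)** — the screened 150-band curve of each sample is
   expanded as a discrete Fourier series
   `V(k) = A₀/2 + Σ_h [A_h cos(2πhk/N) + B_h sin(2πhk/N)]`, and the 12
   low-order energy parameters `A₀/2, A₁..A₃, B₁..B₃, C₁..C₃ (C_h = √(A_h²+B_h²)), φ₁, φ₂`
   are kept as features
6. **PCA** — five correlation-matrix principal components (≈ 90 % variance
   guideline) form the model inputs
7. **BP regression** — a 5–3–1 back-propagation network (tanh hidden layer,
   linear output; 2000 iterations, learning rate 0.01, momentum 0.9, goal
   MSE 0.001), evaluated by R², RMSE and MAE on held-out samples
   (splits 35/16 loessial, 20/13 sandy, 45/39 mixed)

Three feature variants are compared end to end: **FD**, **WPT-FD** and
**WPT-FD-HA**. A seeded synthetic-spectra generator (truncated-normal TICS
matched to published per-soil-type statistics, Gaussian absorption features
with iron-dependent depths, realistic brightness/structured/white noise)
makes the whole chain testable without the original field data.

## Worked example

```bash
ferrospec synth --profile mixed --seed 3 --out mixed.csv   # 84 samples
cat > run.yaml <<EOF
synth_profile: mixed
soil_handling: pooled
seed: 3
outdir: demo_run
EOF
ferrospec run --config run.yaml
```

prints (seed 3):

```
soil_type   variant  r_squared     rmse      mae  n_train  n_test
    mixed        FD   0.830248 1.367581 1.035888       45      39
    mixed    WPT-FD   0.912681 0.964048 0.731682       45      39
    mixed WPT-FD-HA   0.930753 0.853901 0.711431       45      39
```

Each row is one feature variant trained on the same 45-sample split and
scored on the 39 held-out samples: R² (squared Pearson correlation of
measured vs predicted TICS), RMSE and MAE in g/kg. Denoising before the
derivative (WPT-FD) beats the plain derivative, and the harmonic parameters
(WPT-FD-HA) do best — the expected ordering when residual spectral noise
survives denoising. The run directory contains the report, selected bands,
PCA tables, serialized models, per-sample predictions and a stage log;
re-running from the persisted `config.yaml` reproduces every number
bit-identically.

The same works from Python:

```python
from ferrospec import RunConfig, run_pipeline
report = run_pipeline(RunConfig(synth_profile="mixed", seed=3, outdir="demo_run"))
```

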