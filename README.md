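# dermabss

Blind separation of skin chromophore concentration maps — melanin,
oxyhemoglobin and deoxyhemoglobin — plus shading, from four-band (Blue,
Green, Red, Infra-Red) multispectral dermatological images.

Skin reflectance under the Lambert–Beer law is
`Id(λ, u) = G(λ) · Ed(λ) · w(u) · exp(-2 Σ_j μ_j(λ) ℓ_j(λ) C_j(u))`, so the
negative log of each band is a linear mixture `X_i(u) = Σ_j m_ij S_j(u) + n_i`
of the three chromophore concentrations and a shading term, with unknown
mixing coefficients `m_ij = 2 μ_j(λ_i) ℓ_j(λ_i)`.  Recovering the `S_j` from
the four bands alone is a blind source separation problem that this package
solves in four steps:

1. **AMUSE** (second-order ICA) on the Red and IR mixtures, where hemoglobin
   absorption is negligible: whiten, diagonalize a one-pixel-lag covariance,
   and label the two components melanin vs. shading by their border
   concentration.
2. **Deflation**: remove the melanin and shading estimates from the Blue and
   Green mixtures by second-moment projection.
3. **Sparse separation** (ratio-of-mixtures, enhanced TEMPROM): detect
   mono-source raster segments where the Green/Blue ratio variance vanishes,
   read off the two column ratios `r1 = m21/m11 < r2 = m22/m12`, and
   reconstruct `Y_oxy = r2·X1' - X2'`, `Y_deoxy = r1·X1' - X2'`.
4. **ALS-NMF** of the full 4×N mixture matrix, warm-started with the step-3
   sources, yielding non-negative maps, an estimated mixing matrix, and
   scale-free per-source contributions `(Σ_i m_ij)·S_j(u)`.

Dropping the IR band and shading gives the baseline `BCS-rgb` variant; the
three-step and four-step IRGB variants are `BCS-Irgb` and `BCSnmf-Irgb`.
A simulator generates ground-truth artificial dermatological images (lesion
melanin, complementary-sparse hemoglobin with unit total, edge vignette
shading, perturbed mixing matrix), and the metrics module provides the
histogram mutual-information criterion and the signal-to-interference ratio
(SIR) used to evaluate separations.

## Worked example

```python
import numpy as np
from dermabss import SimulationConfig, simulate_image, run_bcsnmf_irgb, sir

config = SimulationConfig()                       # 128x128 study conditions
image, truth, mixing = simulate_image(config, np.random.default_rng(0))
result = run_bcsnmf_irgb(image)

print("eigen gap:", round(result.diagnostics["eigen_gap"], 3))
print("estimated mixing matrix:")
print(np.round(result.mixing_estimate, 3))
for name in ("oxy", "deoxy", "melanin", "shading"):
    print(f"SIR {name}: {sir(truth[name], result.sources[name]):.1f} dB")
```

prints

```
eigen gap: 0.145
estimated mixing matrix:
[[0.    0.183 0.386 0.227]
 [0.189 0.    0.358 0.228]
 [0.    0.    0.199 0.218]
 [0.    0.    0.072 0.219]]
SIR oxy: 24.7 dB
SIR deoxy: 46.4 dB
SIR melanin: 34.4 dB
SIR shading: 59.9 dB
```

The eigen gap (0.145) is the AMUSE identifiability diagnostic — the spread
of the whitened lagged-covariance eigenvalues; a small gap would mean melanin
and shading have indistinguishable spatial smoothness.  The estimated mixing
matrix is non-negative and reproduces the structural zeros of the model
(near-zero hemoglobin coefficients in the Red and IR rows); each SIR line
compares one refined map with the simulator's ground truth after centering
and variance normalization, so 24.7 dB means the interference residual
carries about 0.3% of the oxyhemoglobin map's power.  Columns of the mixing
matrix (and the maps) are recovered up to positive per-source scale factors,
which is why contributions `(Σ_i m_ij)·S_j` are the reportable quantity.
Note the hemoglobin maps are exactly complementary in the simulation
(`S1 + S2 = 1`), so an estimated "oxy" map is shape-identical to a deoxy map
up to sign and offset; the SIR is invariant to that indeterminacy.

## Command line

```sh
bcs simulate --n 5 --seed 0 --out sim/            # images + ground truth
bcs run --method irgb-nmf --input sim/image_000/image.tiff --out out/
bcs study --seed 0 --out study/                   # full 30-image study
```

`bcs run` also accepts four labeled band files
(`--input blue=b.png --input green=g.png ...`), in any order.

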