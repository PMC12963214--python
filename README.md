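# spectherm

Spectral-CT thermometry for thermal-ablation monitoring.

During microwave ablation of liver tissue, clinicians need to know how hot
the tissue actually got — margins that stay below ~60 °C may harbour viable
tumour, and nearby critical structures must stay cool. Dual-energy
(spectral) CT offers a non-invasive readout: warming tissue expands, its
electron density (EDW, expressed as % of water's) falls, and that drop is
measurable on electron-density maps even next to a metal probe once
artifacts are masked. `spectherm` implements the full analysis as a tested
Python library, for imaging scientists who want to calibrate, validate or
simulate CT thermometry:

* a synthetic ablation-phantom generator (temperature fields, 1 Hz
  thermocouple logs, co-registered spectral volumes with metal/gas
  artifacts) so every stage is testable without scanner data;
* artifact masking on 70 keV virtual monoenergetic images (valid =
  [0, 80] HU; metal > 80, gas/beam-hardening < 0 excluded);
* 3 mm spherical ROI extraction at thermocouple tips, paired with
  concurrent temperature readings;
* temperature calibration: Spearman correlations with Fisher-z CIs,
  polynomial fits (orders 1–4) with RMSE and fivefold cross-validation, and
  the physical thermal-expansion model

      EDW(T) = EDW(T₀) / (1 + ∫_{T₀}^{T} α(T′) dT′),   α(T) = b·T² + c·T + d,

  fitted by nonlinear least squares to recover the volumetric
  thermal-expansion coefficient α(T) of the tissue;
* residual diagnostics: raw error (measured − estimated temperature) versus
  distance to the probe's emitting point, with Breusch–Pagan
  heteroscedasticity tests;
* voxelwise temperature maps, 60 °C-isotherm zone segmentation
  (26-connected) and ablation-zone metrics (volume, probe-aligned long and
  short axes).

## Worked example

`examples/` holds one short script per capability. The end-to-end run
(`python examples/full_pipeline.py`, 2 subjects × 8 scans × 4 sensors,
~15 s) prints:

```
paired samples: 64 (candidates 64, excluded 0)
mean ROI EDW: 103.25 % of water
Spearman rho(T, edw): -0.779  (p = 3.3e-14, 95% CI [-0.869, -0.639])
Spearman rho(T, zeff): +0.216  (p = 0.087, 95% CI [-0.035, +0.441])
Spearman rho(T, hu): -0.410  (p = 0.00078, 95% CI [-0.602, -0.172])
in-sample RMSE by polynomial order (degC): {1: 6.41, 2: 6.1, 3: 5.09, 4: 4.97}
5-fold CV RMSE, linear model: 6.55 degC
expansion fit: EDW(T0) = 103.97, c = 8.23e-06, d = 4.37e-05
Breusch-Pagan (heating phase): F = 0.05, p = 0.826 on n = 48
subject 01 60-degC zone: 5.0 cm^3, 2.6 x 2.0 cm
subject 02 60-degC zone: 5.8 cm^3, 2.8 x 2.2 cm
```

Reading it: EDW anti-correlates with temperature and more strongly than
conventional HU (the thermometry signal and its channel ordering); a linear
EDW→T calibration predicts held-out temperatures to ~6.5 °C; the expansion
fit recovers liver-like α(T) coefficients from 64 noisy ROI samples; and
thresholding the calibrated map at 60 °C yields centimetre-scale ablation
zones elongated along the probe.

A pipeline run writes everything to disk too: `samples.csv` (paired ROI
table), `fits.yaml`, `residuals.csv`, per-scan temperature maps
(NIfTI-1) and `report.yaml`.

From Python, the pieces compose directly:

```python
import numpy as np
from spectherm import ExpansionParams, edw_forward, fit_expansion

truth = ExpansionParams(edw_t0=104.0, t0=37.0, c=7.9e-6, d=9.6e-5)
rng = np.random.default_rng(42)
T = rng.uniform(29.0, 99.0, 192)
edw = edw_forward(truth, T) + rng.normal(0.0, 0.2, 192)
fit = fit_expansion(T, edw, t0=37.0, fix_b=True)   # -> c ~ 8.2e-6, d ~ 8.8e-5
```

There is also a thin CLI for shell use:
`thermo run-all --config cfg.yaml --seed 1 --out run_out/` (subcommands
`simulate | extract | calibrate | map | run-all`).

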