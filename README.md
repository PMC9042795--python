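# granulekit

Quantitative image analysis of RNP granules — mesoscale ribonucleoprotein
condensates such as the *oskar* mRNA transport granules of the *Drosophila*
oocyte. The package implements, as a tested and reusable pipeline, the
measurements used to characterize such granules in fluorescence microscopy:

* **Segmentation & morphometrics** — intensity thresholding (including the
  Intermodes histogram method), connected-component labeling, per-granule
  volume, equivalent diameter, and aspect ratio from FWHM line profiles
  along the principal axes; Gaussian fits of the diameter distribution.
* **FRAP kinetics** — double normalization of recovery traces and
  least-squares fitting of the single-exponential model
  `FRAP(t) = I₀ + I₁·[1 − e^−(t−t_bleach)/τ]`, with the immobile fraction
  `(1 − I₀ − I₁)/(1 − I₀)` and half-time `t½ = τ·ln 2`.
* **Absolute abundance** — single-molecule unit intensity from a 1D
  Gaussian-mixture (EM) fit of smFISH spot intensities (the dominant
  component's mean), copy numbers, and molar concentration
  `copies/(N_A·V)`; a linear fluorophore calibration curve for protein
  concentrations.
* **Colocalization** — object-based nearest-neighbor statistic within a
  250 nm window against a randomization null (target objects re-placed
  uniformly in the confinement region, 100 iterations);
  `frequency = observed − null mean`.
* **Partition coefficient** — mean intensity inside condensates over the
  dilute phase.
* **AP polarity** — displacement of the signal's centre of mass from the
  geometric centre of the cell mask along the anteroposterior axis.

Raw imaging data is not required: a seeded synthetic-microscopy generator
(`granulekit.synthetic`) produces granule fields, two-channel images with
controlled true colocalization, FRAP traces, intensity populations,
polarity fields and calibration ladders with exact ground truth, so every
stage is validated end-to-end by parameter recovery. It is aimed at
researchers quantifying biomolecular condensates (or validating their own
quantification code) and at anyone who needs ground-truthed synthetic
microscopy for testing.

## Worked example

```python
from granulekit import (fit_recovery, normalize_trace)
from granulekit.synthetic import FrapSimParams, generate_frap_trace

trace, truth = generate_frap_trace(
    FrapSimParams(I0=0.2, I1=0.5, tau_s=10.0, noise_sd=0.02, seed=1)
)
fit = fit_recovery(normalize_trace(trace))
print(f"tau = {fit.tau_s:.2f} s, t1/2 = {fit.t_half_s:.2f} s, "
      f"immobile fraction = {fit.immobile_fraction:.3f}")
```

prints

```
tau = 10.20 s, t1/2 = 7.07 s, immobile fraction = 0.380
```

— the fitted recovery time constant (generating value 10 s), its
half-time `τ·ln 2`, and the immobile fraction, i.e. the share of
fluorescence that never recovers (generating kinetics give
`(1−0.2−0.5)/(1−0.2) = 0.375`).

The `analysis/` directory holds numbered narrative drivers for each stage
(`01_granule_field_morphometrics.py` … `06_full_pipeline_demo.py`); each
prints what it found and writes its tables under `results/`. For example
`python analysis/03_abundance_calibration.py` reports

```
mixture: BIC selects K=2; unit intensity 997.8 (generating value 1000)
copy calls: 99.7% exact on the 1-2-copy population
42 copies in a 400 nm sphere (3.351e-17 L) = 2.081 uM
```

A command-line interface wraps the same library:

```sh
granulekit simulate granules --config field.yaml --seed 7 --out sim/
granulekit segment --input sim/image.tif --method intermodes --out seg/
granulekit coloc --ref a.csv --target b.csv --mask mask.tif --window-nm 250
```

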