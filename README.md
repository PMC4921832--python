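# specdemux

Reconstruct high-resolution reflectance spectra from ordinary RGB camera
measurements.

A color image sensor behind a Bayer color filter array (CFA) collapses the
light spectrum arriving at each pixel into three numbers. For many imaging
tasks — material analysis, microscopy, biomedical imaging — one would rather
have the spectrum itself. `specdemux` is for researchers who want snapshot
multispectral imaging from a low-cost RGB sensor: it models the sensor's
measurement formation and learns numerical inverses ("demultiplexers") that
map a 3-channel measurement back to a 61-point reflectance spectrum,
per pixel.

## The model

Measurement formation is linear. With the spectrum sampled on an n-point
wavelength grid (default: 61 points, 410–710 nm in 5 nm steps),

```
C = S Λ,        Λ = R ⊙ E
```

where `C ∈ R^p` is the p-channel measurement (p = 3 for RGB), `S ∈ R^{p×n}`
is the sensor's spectral sensitivity (one response curve per channel,
obtainable by narrowband characterization — probing the sensor one
wavelength at a time), `R ∈ [0,1]^n` is the surface reflectance and `E` the
illuminant spectrum. The experiments work with detrended reflectance
(`E ≡ 1`), matching the convention of dividing measured spectra by a
near-perfect white reference.

Recovering Λ from C is severely under-determined (n = 61 ≫ p = 3), so the
inverse `S⁻¹(·)` is *learned* from populations of plausible spectra pushed
through the forward model:

- **WEM** — classical Wiener estimation, `W = (A Cᵀ)(C Cᵀ + εI)⁻¹`, trained
  on a small fixed 24-spectrum prior set (a synthetic stand-in for a
  ColorChecker chart);
- **DEMUX-WEM** — the same Wiener mathematics trained on thousands of
  spectra generated through the characterized forward model;
- **DEMUX-RFM** — a non-linear multi-output random-forest regression trained
  on the same generated pairs (8,000 trees at full scale).

Fidelity is scored with PSNR = 10 log₁₀(1/MSE) in dB, with peak 1 because
reflectance is normalized to [0, 1]. Sensor responses are treated as linear
(no gamma) throughout.

## Worked example

```sh
python examples/04_simulation_experiment.py
```

trains all three demultiplexers at reduced scale (2,000 training spectra,
500 held-out test spectra, 300 trees) and prints:

```
method        mean PSNR (dB)
DEMUX-RFM             18.856
DEMUX-WEM             17.910
WEM                   17.604

ranking (best first): DEMUX-RFM > DEMUX-WEM > WEM
```

Each number is the pooled PSNR of a method's reconstructions over the
500-spectrum test set: the forest reconstructs the diverse random spectra
best, the forward-model-trained Wiener comes second, and the Wiener trained
on the small mismatched prior set comes last. The other examples cover the
forward model (`01`), narrowband characterization (`02`), single-spectrum
reconstruction (`03`), and the spatial test-icon pipeline with band
extraction at 490/550/610 nm (`05`).

The same pipeline is available from the shell:

```sh
specdemux synth-sensitivity --out sens.csv
specdemux train --method rfm --sensitivity sens.csv --n-train 2000 \
    --n-trees 300 --out rfm.joblib
specdemux demux-image --model rfm.joblib --image scene.png --out cube.tif
specdemux extract-band --cube cube.tif --wavelength 550 --out band550.png
```

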