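# Methods

## Forward model and its assumptions

The measurement model is `C = S Λ` on a uniform wavelength grid, default
410–710 nm in 5 nm steps (n = 61). Assumptions baked into the model:

- **One sensitivity per channel.** The per-pixel sensitivity `S(i, j, λ)` is
  collapsed to a single p×n matrix: narrowband characterization uniformly
  illuminates a large sensor region, so the per-filter average is the
  natural estimate and per-pixel variation is ignored.
- **Post-demosaic view.** Every pixel carries all p channels; the Bayer
  mosaic's spatial subsampling and any demosaicing algorithm are out of
  scope. `forward_image` is therefore exactly per-pixel `forward`.
- **Linear sensor.** Responses are treated as gamma-free and continuous;
  optional k-bit quantization (`quantize`) is available but off by default,
  since the model itself is agnostic to bit depth.
- **Units.** Sensitivities are relative (dimensionless); reflectance is a
  fraction in [0, 1]; radiance Λ = R·E is only required to be nonnegative.
  Absolute radiometric calibration is out of scope.
- **Illumination.** The simulation experiments use E ≡ 1, i.e. the target
  quantity is the reflectance itself. `detrend_by_illuminant` implements the
  white-reference correction (`measured / white × 0.99` with a 99%
  reflectance target, clipped to [0, 1]) used to obtain such targets from
  real measurements; a zero anywhere in the white spectrum is an error that
  names the offending wavelength.
- **Noise.** `add_measurement_noise` adds i.i.d. zero-mean Gaussian read
  noise per channel (deterministic per seed). Signal-dependent (shot) noise
  is not modeled, and all reference experiments here run noise-free.

## Sensor characterization

`characterize_from_narrowband` averages replicate p-vector readings per grid
wavelength; under the forward model the response to the unit impulse
spectrum `e_k` is exactly column k of S, so noise-free probing recovers S to
machine precision (a test pins this). Negative column means — possible with
noisy readings — are clipped to 0 on physical grounds. The unit-intensity
convention (each probe delivers the same integrated intensity at every
wavelength) is a choice; real monochromator output would need per-wavelength
exposure normalization first.

Because measured RGB response curves are not bundled, `synth_sensitivity`
provides a parametric Gaussian filter bank. Defaults: B/G/R peaks at
460/530/600 nm, common width 35 nm, peak amplitudes 0.8/1.0/0.9, so green
exceeds red ≈ blue in peak response as in typical consumer sensors.

## Synthetic spectra generator

`generate_random_spectra` draws each spectrum as a flat baseline plus m
Gaussian bumps, clipped to [0, 1]:

- m uniform in {1, …, 3} by default; bump centers uniform over the grid
  range; widths uniform in 20–80 nm; amplitudes uniform in 0.2–1.0;
  baselines uniform in 0–0.2.

These defaults make smooth unimodal-to-trimodal curves of the kind measured
off natural and painted surfaces, and a population of ≥ 1,000 covers every
wavelength (the across-set range straddles 0.5 everywhere — tested).
Clipping rather than renormalizing keeps the bump geometry interpretable.
What the generator does **not** emulate: sharp absorption/emission lines,
spectra correlated across a scene, metamerism structure of any real material
database, or measurement noise. Passing tests therefore demonstrate the
pipeline's correctness and the methods' relative ordering under a smooth
prior, not absolute performance on real reflectance libraries.

The WEM baseline trains on `prior_spectra`: a fixed synthetic 24-spectrum
set (18 single-bump chromatic patches + 6 neutral flats from 0.05 to 0.95)
emulating the shape statistics of a ColorChecker chart. It is deliberately
small and not drawn from the generator, which is what makes WEM the
"mismatched prior" baseline.

The block test icon (`make_test_icon`, default 5 vertical strips of
8×8 px) uses the same generator restricted to 1–2 bumps, giving patch-like
section spectra for the spatial end-to-end experiment.

## Demultiplexers

**Wiener.** `W = (A Cᵀ)(C Cᵀ + εI)⁻¹` with non-centered correlation
matrices — the standard convention in Wiener spectral estimation; the
exact-inverse limit (p = n, S invertible ⇒ W = S⁻¹) holds either way and is
tested to 1e−8. The ridge ε defaults to 1e−8 × trace(C Cᵀ); ε = 0 requests
the unregularized solve and raises on singular auto-correlation (e.g. all
training spectra identical). The ridge also subsumes any noise-covariance
term of a noise-aware Wiener filter. Degenerate/ill-conditioned systems are
detected via the condition number (threshold 1e12).

**Random forest.** One scikit-learn multi-output `RandomForestRegressor`
mapping the p measurements to all n outputs jointly: 8,000 trees at full
scale, unlimited depth, min leaf size 1, bootstrap on, all p features per
split (p = 3 is tiny), seed mandatory. A per-output mode (one forest per
wavelength, splitting the tree budget evenly) exists behind
`per_output=True`; the joint mode is the default because it is markedly
cheaper and measured no worse (in peak-recovery experiments the per-output
variant was strictly worse).

All demultiplexed spectra are clipped to [0, 1] after prediction, for every
method: reflectance is physically bounded.

## Evaluation

PSNR uses peak = 1.0 (normalized reflectance) — absolute dB values depend
directly on this choice. Aggregation over many spectra defaults to
**pooled-MSE PSNR** (pool the squared errors over all spectra and
wavelengths, then take one log) because the per-spectrum PSNR of an exact
reconstruction is infinite and would poison a plain average;
`mode="per_spectrum"` averages finite per-spectrum PSNRs instead. Exact
reconstructions report an `inf` sentinel (serialized as the string `"inf"`).

Experiment harnesses (`run_simulation_experiment`, `run_icon_experiment`)
echo their full configuration in the report and are bit-reproducible for
fixed seeds. A leakage guard warns when training and test generator seeds
coincide.

## Problem sizes

Full scale is 10,000 training spectra, 10,000 test spectra and 8,000 trees.
The test suite, the examples and `scripts/acceptance.py` run a reduced scale
of 2,000 training / 500 test spectra with 300 trees, which preserves the
method ordering (DEMUX-RFM > DEMUX-WEM > WEM, verified stable across
independent seed choices) while keeping a full run in tens of seconds. The
icon experiment uses 5 sections of 8×8 px.

## Known limitations

- **Spectral blind regions.** The default Gaussian filter bank has
  negligible response above ~650 nm and weak response below ~430 nm. In
  those regions a single bump's center and amplitude are nearly
  unidentifiable from 3 channels (only one channel responds, and its gain
  trades off against amplitude). Concretely, the unimodal peak-recovery rate
  (reconstruction argmax within ±10 nm of the true bump center) measures
  ~65–70% over the full grid at reduced scale, and a nearest-neighbor oracle
  in measurement space does no better — the ceiling is informational, not a
  model defect. Real camera sensitivities with broad, overlapping red
  response curves do not have this blind region.
- Absolute PSNR values depend on the synthetic sensitivity curves and the
  generator's spectra distribution; only the method ordering and the
  algebraic limits (exact inverse, characterization round-trip, least-squares
  optimality) are calibration-free.
- No demosaicing, optics (PSF, vignetting), color management, or
  illumination-variant training augmentation.
- 16-bit multi-channel PNG is not writable (codec limitation); use TIFF for
  16-bit color images. 16-bit grayscale PNG works.
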