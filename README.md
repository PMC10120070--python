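# ommapol

Ommatidial-alignment analysis and robust polarization-vision modelling
for butterfly compound eyes.

## The problem

Butterflies with rhabdomeric photoreceptors can sense the linear
polarization of light: each ommatidium contains two orthogonal microvillar
channels whose responses a first-order opponent interneuron contrasts.
Such a unit is *polarization blind* whenever the angle of polarization
(AoP, ɸ) lies 45° from its microvillar axis. Eyeshine microscopy of
lycaenid eyes shows that neighbouring ommatidia are often *misaligned* —
their microvillar principal axes Σ differ by up to 45° — which suggests a
way out: a second-order neuron summing rectified opponent outputs from a
misaligned pair responds at **every** AoP.

This package provides the full computational chain behind that analysis,
for vision scientists working with depolarized-eyeshine imaging:

1. **synthgen** — synthetic Σ fields on a hexagonal lattice, rendered
   depolarized-eyeshine image stacks over eye roll angle θ, polarization
   image pairs of known DoP, reflectance spectra, behavioural counts.
2. **photometry** — hex grids of circular ROIs over registered stacks,
   giving one intensity-versus-θ series per ommatidium.
3. **alignment** — the Σ estimator and the axial difference ΔΣ.
4. **hexarray** — classification of the mosaic into edge-detector (ED)
   chains and polarization-detector (PD) pairs, with patch-level metrics.
5. **opponent** — the two-channel opponent model, polarization state
   space, second-order summation, and worst-case (robustness) analysis.
6. **wingoptics** — wing DoP from orthogonally analysed image pairs,
   angular-contrast trend fits, spectral peaks, tetrahedral colour space.
7. **behavior_stats** — site-level summaries of approach-count trials.

## The model

Depolarized eyeshine of an ommatidium with principal axis Σ varies with
roll angle θ as

```
I(θ) = a + b·sin²(2(θ − Σ)),        Σ ∈ [0, 90°)
```

so minima repeat every 90° with maxima halfway between. Since the
noiseless signal contains only DC and the 4θ harmonic, Σ is recovered
exactly from the discrete Fourier phase at that harmonic:

```
c₄ = Σₖ I(θₖ)·exp(i·4θₖ),     Σ̂ = arg(c₄)/4 + 45°   (mod 90°)
```

A receptor with axis α and polarization sensitivity PS responds to light
of intensity I, degree of polarization d and AoP ɸ with the
two-mechanism Malus law; the first-order opponent output is

```
O(ɸ) = (R∥ − R⊥)/(R∥ + R⊥) = d·(PS−1)/(PS+1)·cos 2(ɸ−α)
```

— intensity independent, and zero at ɸ = α ± 45°. The second-order sum
S(ɸ) = |O₁| + |O₂| of a pair with axial difference ΔΣ has worst case

```
min_ɸ S(ɸ) = d·(PS−1)/(PS+1)·sin(2·ΔΣ)
```

which is why pairs with ΔΣ ≥ 20° make robust polarization detectors,
while ED chains require runs of ≥ 3 collinear ommatidia within ±5°.

## Worked example

```python
from ommapol import photometry, synthgen
from ommapol.model import PatchAlignmentModel

# a 12x12 patch with the calibrated misalignment mixture, rendered and
# photometered with mild detector noise
field = synthgen.generate_sigma_field(
    12, 12, synthgen.AlignmentParams.fig3d(seed=42))
stack = synthgen.render_eyeshine_stack(
    field, optics=synthgen.OpticsParams(noise_sd=10.0), seed=42)
grid = photometry.grid_from_stack(stack, radius=6.0, n_rows=12, n_cols=12)

results = PatchAlignmentModel.from_stack(stack, grid).fit()
print(results.summary())
```

```
Patch alignment fit
===================================================
Ommatidia (series)                              144
Passing QC (mod >= 0.20)                        144
Median modulation depth                       0.587
Interior ommatidia                              100
Adjacent pairs (>=1 interior)                   339
---------------------------------------------------
% ED (chains, +/-5 deg)                       86.0%
% PD (delta >= 20 deg)                        38.0%
% ED only                                     59.0%
% PD only                                     11.0%
---------------------------------------------------
Adjacent-pair axial differences:
  exactly aligned                             20.6%
  within +/-5 deg                             52.5%
  >= 15 deg                                   19.8%
  >= 20 deg                                   10.9%
===================================================
```

All 144 series pass the modulation-depth QC; 38% of the 100 interior
ommatidia belong to at least one PD pair (ΔΣ ≥ 20°), 86% sit in at least
one aligned ED chain, and the adjacent-pair ΔΣ distribution of this
single patch scatters around the calibrated population fractions
(22% / 50% / 30% / 15%). The opponent model quantifies why the PD
threshold matters:

```python
from ommapol.opponent import robustness
for d in (0, 5, 20, 45):
    print(f"delta={d:>2d} deg  worst-case response = {robustness(0.0, d):.3f}")
```

```
delta= 0 deg  worst-case response = 0.000
delta= 5 deg  worst-case response = 0.142
delta=20 deg  worst-case response = 0.526
delta=45 deg  worst-case response = 0.818
```

An aligned pair is completely blind at some AoP; at ΔΣ = 20° the
worst-case response is already 64% of the theoretical maximum
(PS−1)/(PS+1) = 9/11 reached by an orthogonal pair.

The same stages are scriptable from the shell:

```
ommapol simulate sigma-field --rows 12 --cols 12 --mixture fig3d --seed 42 --out sigma.csv
ommapol simulate stack --sigma-csv sigma.csv --out stack.tif
ommapol extract --stack stack.tif --rows 12 --cols 12 --out series.csv
ommapol estimate --series series.csv --out estimates.csv
ommapol classify --sigma estimates.csv --out metrics.json
```

or end to end with `ommapol run --seed 42 --out outdir`.

## Documentation

`docs/methods.md` describes the intensity model, the estimator, the
classification rules, the synthetic-data calibration and its limits, and
the numerical conventions in detail.
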