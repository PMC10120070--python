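# Methods

This note documents the models, estimators, classification rules and
numerical conventions implemented in `ommapol`, the choices made where
the design was genuinely open, and what the synthetic-data generators do
and do not emulate.

## Eyeshine intensity model

Depolarized eyeshine arises when linearly polarized light travels down a
birefringent rhabdom, reflects from the tapetum, and returns through a
crossed analyser. The exact waveguide-mode optics of this process is not
modelled; instead the package adopts the phenomenological law

    I(θ) = background + baseline + amplitude · sin²(2(θ − Σ)) + ε,

with θ the eye roll angle, Σ the ommatidium's principal axis, and ε
additive Gaussian detector noise. The law reproduces every qualitative
feature the analysis relies on: zeros of the modulated term at θ = Σ
(mod 90°), maxima at Σ + 45°, and a strict 90° period, i.e. two minima
per 180° with maxima halfway between. Because only these features are
identifiable from intensity-versus-θ data, a more detailed physical
model would add parameters without adding testable content.

Angles are degrees throughout. Σ is axial with period 90° and reported
in [0, 90); the axial difference between two axes,

    ΔΣ = min(|a − b| mod 90, 90 − |a − b| mod 90) ∈ [0, 45],

is a true metric on the axial circle (verified exhaustively in tests).

## Σ estimation

The noiseless model signal contains only a DC term and the 4θ harmonic,
so the estimator computes the discrete Fourier component

    c₄ = Σₖ I(θₖ) · exp(i·4θₖ),    Σ̂ = arg(c₄)/4 + 45°  (mod 90°),

over a uniform θ grid covering a whole number of 90° periods. The
default acquisition is θ = 0–180° inclusive in 5° steps (37 frames); the
θ = 180° sample duplicates θ = 0° for a period-90 signal and is dropped
before the transform. Under these conditions the estimator is *exact*
for the model class (machine-precision recovery at zero noise, any Σ,
any grid phase) and equivariant: shifting the θ grid by δ shifts Σ̂ by δ
mod 90°. Fitted amplitudes give the modulation depth

    m = b/(a + b)  ∈ [0, 1]

(the relative dip of the fitted curve). Ommatidia whose optical axes lie
outside the ~21° illumination cone show little modulation; the quality
filter excludes estimates with m below a configurable threshold,
defaulting to 0.2. No published numeric cutoff exists, so the threshold
is explicit and conservative: in noiseless synthetic renders, in-beam
spots have m ≈ 0.6 and out-of-beam spots m ≈ 0. Constant series yield an
undefined Σ (NaN) and fail QC rather than erroring.

Channels: depolarized eyeshine is predominantly red, so R is the
canonical channel; synthetic RGB renders scale G and B modulation to
0.5× and 0.25× of R. Channels are estimated independently.

## ROI photometry

ROIs are circles on a pointy-top hexagonal lattice in axial coordinates
(q, r), pixel position x = s(q + r/2), y = s·(√3/2)·r for spacing s. The
per-frame statistic is the arithmetic mean over pixels whose *centres*
fall inside the circle — no partial-pixel weighting — which makes
linearity and background tests exact. Grids must be non-overlapping
(radius < spacing/2) and fully inside the image. Registration of the
stack is an input contract, not an operation; a before/after control
frame can be summarised as a bleaching ratio but no correction is
applied.

## Lattice classification

An **interior** ommatidium has all six axial neighbours measured; all
patch percentages use interior ommatidia as the denominator so boundary
truncation does not bias them.

**ED chains** are maximal contiguous runs along one of the three lattice
axes whose members' axes mutually deviate by at most 2·ed_tol (default
±5°, so spread ≤ 10°), with length ≥ 3. "Deviate from parallel by no
more than ±5°" is operationalised as the max pairwise axial difference
within the run (a symmetric, reference-free criterion); a run like
(0°, 5°, 10°) sits exactly on the boundary and qualifies. Maximality
means no extension along the axis preserves the condition; overlapping
maximal windows on the same line are all reported. Chain membership for
an interior ommatidium may include boundary chain-mates.

**PD pairs** are adjacent pairs with ΔΣ ≥ 20° (configurable). An
interior ommatidium counts as PD if any of its six pairs qualifies, the
partner possibly non-interior. ED-only/PD-only are the set differences.
The pair-level ΔΣ summary (fractions exactly aligned, within ±5°, ≥15°,
≥20°) is computed over pairs with at least one interior member; "exactly
aligned" means ΔΣ < 0.5° by default, since exact zero is measure-zero
for continuous estimates.

A note on geometry: the triangular adjacency graph contains 3-cycles, so
no two-valued axis pattern can make *every* adjacent pair differ — the
extreme all-PD mosaic used in tests is the three-phase tiling
(q + 2r) mod 3 → {0°, 30°, 60°}, which yields ΔΣ = 30° on all three
axes.

## Opponent model

Receptor: two-mechanism Malus law. For axis α, sensitivity PS ≥ 1,
stimulus (I, d, ɸ):

    R = I·[(1 − d)·(PS+1)/2 + d·(PS·cos²(ɸ−α) + sin²(ɸ−α))].

First-order opponent: O = (R∥ − R⊥)/(R∥ + R⊥), computed as the ratio
(not the closed form) so intensity invariance is structural; it equals
d·(PS−1)/(PS+1)·cos 2(ɸ−α) identically. PS defaults to 10.

Second-order summation: the package implements S(ɸ) = |O₁| + |O₂|, a
*rectified* sum. This is a design choice: a signed sum of two equal-
frequency cosines is itself a cosine and stays polarization blind at
some ɸ for any pair, contradicting the defining property of the robust
detector; rectification is the minimal nonlinearity that delivers
"never blind" for misaligned pairs. The signed variant remains available
behind `rectified=False` for comparison. Other monotone variants (e.g.
squaring) would preserve every qualitative statement; none is
identifiable from available data.

Robustness is min over ɸ of S on a dense grid (default step 0.1°, 0.01°
or finer in verification). For the rectified sum it equals
d·(PS−1)/(PS+1)·sin(2ΔΣ) — zero for aligned pairs, strictly increasing
to the orthogonal-pair maximum. Numerically the minimum sits at a
rectification kink, so a scan that misses the kink overshoots the
analytic value by up to (slope/2)·step, *linearly* in the step; tests
therefore check a one-sided bound for arbitrary phases and exact
agreement when the grid hits the kink.

State-space loci (O₁(ɸ), O₂(ɸ)) are summarised by their shoelace
(enclosed) area, which for this model is π·g²·|sin 2ΔΣ| with
g = d·(PS−1)/(PS+1): zero on the identity line for aligned pairs, a
circle of radius g at ΔΣ = 45°, and strictly increasing in between.

## Wing optics

DoP = |I_H − I_V|/(I_H + I_V) over total masked image intensity, with H
the component perpendicular to the plane of incidence. DoP is reported
unsigned with a separate dominant-channel label. Angular contrast is
θ_inc + ɸ_det, with |θ_inc| < ɸ_det as an acquisition constraint. Trend
fits regress DoP on an orthonormal polynomial basis of angular contrast
(QR of the centred Vandermonde, the same construction as R's `poly()`)
via ordinary least squares (statsmodels), orders 2 and 3 being the cases
of interest.

Colour: quantum catches are flat-illuminant integrals of reflectance ×
sensitivity on the 350–700 nm, 1 nm grid (trapezoid rule; inputs
resampled by linear interpolation). The tetrahedral colour space is the
fixed linear map xyz = V·(u, s, m, l)_relative with vertex matrix

    u = (0, 0, 3/4)
    s = (−√6/4, −√2/4, −1/4)
    m = ( √6/4, −√2/4, −1/4)
    l = (0,  √2/2, −1/4)

— a regular tetrahedron, centroid at the origin (achromatic point),
centre-to-vertex distance 3/4. Colour differences are unweighted
Euclidean distances in these coordinates; receptor-noise (JND) weighting
is deliberately out of scope for lack of the required Weber fractions
and receptor densities.

## Synthetic data: what it emulates, and what it does not

**Σ fields.** Two generators:

* *Copy-with-jitter*: sweep the lattice in row-major order; each cell
  copies a uniformly chosen already-assigned neighbour's axis plus
  axial Gaussian jitter with probability `p_align`, else draws
  Σ ~ Uniform[0, 90). This produces spatially correlated mosaics of
  locally aligned domains; `p_align = 1, jitter 0` gives a perfectly
  aligned array, `p_align = 0` gives i.i.d. axes whose adjacent-pair ΔΣ
  is Uniform[0, 45].
* *Calibrated mixture* (`AlignmentParams.fig3d()`): a random global axis
  plus i.i.d. per-cell signed offsets from a nine-atom categorical
  (0, ±2.5, ±7.5, ±16, ±30°). The weights were solved once so that the
  axial difference of two independent draws reproduces, in expectation
  on every lattice edge, the four cumulative dissimilarity fractions
  measured in a real ommatidial patch: 22% exactly aligned, 50% within
  ±5°, 30% ≥ 15°, 15% ≥ 20°. An earlier candidate — drawing pair
  differences directly and propagating along a spanning path — cannot
  satisfy these marginals on off-path edges (compositions of path steps
  drift toward the uniform folded law) and was rejected.

  Only those four pairwise marginals are constrained. The mixture field
  is spatially uncorrelated beyond them and its ΔΣ histogram is discrete
  at the atom differences; real mosaics have continuous ΔΣ and unknown
  spatial correlation (only the pairwise marginals were published).
  Passing calibration tests therefore demonstrates correct pair
  statistics, not realistic domain structure.

**Stacks.** Gaussian spots (default σ = 2 px) at lattice positions
(default spacing 20 px), centre intensity following the eyeshine law,
per-pixel additive noise, optional per-ommatidium amplitude scaling to
emulate spots outside the illumination cone. Spacing ≥ 3σ is enforced by
a warning; the default spacing keeps inter-spot crosstalk below 1e-10 of
the signal so the render → photometry → estimate round trip is exact to
better than 1e-9 degrees. Not emulated: optical blur between facets,
tapetal spectra, bleaching, registration error.

**Other generators.** Polarization image pairs realise an exact target
DoP in channel means (excess in H) before noise. Reflectance templates
are a Gaussian bump (default FWHM 120 nm, amplitude 0.35) on a 0.05
pedestal, peaking at 521 nm (female forewing) and 545 nm (male) — the
published peak positions, not fitted spectral shapes. Receptor
sensitivities are unit-peak Gaussian stand-ins at 360/450/520/600 nm
(the true curves are not published in tabular form); they are fixtures,
not estimates. Behavioural counts are per-site binomials.

All generators are deterministic given a seed (numpy `default_rng`).

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → extract → estimate → classify →
report from a single validated configuration dict; every output carries
the configuration hash and seed, and reruns are byte-identical. The
acceptance script regenerates its inputs at run time and recomputes each
anchor quantity by running these same stages; its calibrated-patch check
uses a 64×64 field (≈ 11.8k interior-touching pairs) so the reported
percentage has a binomial standard error of ~0.33 points.

## Known limitations

* The estimator is exact only for uniform θ grids covering whole 90°
  periods; irregular grids would need a least-squares fit (not
  implemented).
* Chain/pair percentages depend on the boundary convention (boundary
  ommatidia may serve as chain mates and pair partners of interior
  ones); the alternative strict-interior convention would lower %ED and
  %PD on small patches.
* Mixed-effects inference across sexes and eye elevations, multivariate
  colour tests, and image registration are out of scope; the package
  emits the per-patch metrics tables such analyses would consume.
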