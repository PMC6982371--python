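# Methods

This note records the models, the numerical choices behind them, and what
the synthetic-data generator does and does not emulate.

## Scattering models

All globular form factors are built from the normalized sphere amplitude
`F(x) = 3(sin x − x cos x)/x³`, evaluated by its Taylor series below
`x = 0.01` so the `x → 0` limit is exact rather than a 0/0 division.
Intensities follow the convention

    I(q) = scale · |Σᵢ Δρᵢ Vᵢ Fᵢ(q)|² + background,

so the forward limit is `I(0) − background = scale·(Σ Δρᵢ Vᵢ)²`. Scattering
length densities are relative: measured curves here carry no absolute
calibration, only contrasts matter, and the free `scale` absorbs units.

**Core–shell ellipsoid.** The amplitude at tilt α uses the sphere kernel at
the effective radii `r(α) = sqrt(R_eq² sin²α + R_pol² cos²α)` of the core
and outer (core + uniform shell) surfaces; `P(q)` is the average of |A|²
over `α ∈ [0, π/2]` with measure `sin α dα`. The average uses fixed-order
Gauss–Legendre quadrature, default 76 nodes — for these smooth integrands
order doubling changes the result by < 10⁻⁶ relative (asserted in tests),
and an optional `convergence_rtol` re-evaluates at twice the order and
raises with the achieved tolerance if the check fails. The finite cylinder
uses the standard `2J₁(x)/x × sinc` amplitude under the same average;
`length < 2·radius` is reported as the disc regime.

**Vesicle.** Defined, and implemented, as the core–shell sphere with
`sld_core = sld_solvent` — the reuse is exact (bit-identical), not a
re-derivation.

**Lamellar patterns.** Bragg orders are Lorentzians centred at
`q_n = 2πn/d` with a common half-width at half-maximum, on a power-law
baseline `A·q^(−p)`. The lineshape is a package choice (diffraction data
of this kind do not pin one down); it is symmetric, so peak positions are
unbiased, and it is swappable without touching the indexing code.

**Mixtures.** Exactly `Σ wᵢ Iᵢ(q)` with non-negative weights and no
renormalization; co-existing populations in one sample add incoherently at
these dilutions.

**Polydispersity** is off by default (the fits the package targets are
monodisperse); no structure factor is multiplied in — an interparticle
correlation peak is interpreted on the analysis side from its position
only, via `d = 2π/q`.

## SAXS analysis

`q = 4π sin θ/λ` takes θ as HALF the scattering angle 2θ; the
`BeamConfig.half_angle` field name enforces the convention. `d = 2π/q`
converts peak positions to real-space distances, with optional rounding
for "ca." values.

**Peak detection** is `scipy.signal.find_peaks` on (optionally smoothed)
intensity with a prominence threshold given as a fraction of the maximum,
followed by 3-point parabolic interpolation on log-intensity for sub-grid
positions (the log of both Gaussian and Lorentzian peaks is locally
quadratic). A broad low-q hump will also register as a "peak" at low
prominence thresholds; discriminating Bragg reflections from form-factor
humps is left to the analyst (sharp width, harmonic companions) — the
package does not claim an automatic classifier.

**Lamellar indexing** searches assignments in which the lowest-q peak takes
order 1..max_order and the remaining peaks the nearest harmonics, solving
`min_d Σ (qᵢ − 2πnᵢ/d)²` in closed form per assignment and keeping the
smallest rms residual; ties resolve to the lowest orders. A single peak is
indexed as first order.

**Model fitting** is bounded trust-region least squares (via lmfit), at
most 5000 evaluations, weights `1/σ²` when uncertainties are present.
Without uncertainties, profiles spanning more than two decades are fit in
log-intensity space — SAXS dynamic range would otherwise let the low-q
points dominate the objective. Reduced χ² is reported in the space the fit
ran in. 1σ uncertainties come from the covariance estimate; when it is
unavailable they are reported as missing, never as zero. Because the
orientationally averaged ellipsoid has a near-degenerate twin with polar
and equatorial radii exchanged (the prolate/oblate ambiguity), fits that
free both radii automatically restart once from the axially swapped
starting point and keep the lower-χ² solution. Reported micelle "sizes"
are total outer diameters per axis, `2·(core radius + shell thickness)`,
with core dimensions also available.

## Diffusion NMR

`b = γ²G²δ²(Δ − δ/3)` is computed from the pulse parameters (γ defaults to
the ¹H value 2.6752 × 10⁸ rad s⁻¹ T⁻¹, overridable), so the gradient ramp
is the single source of truth; a b-column input mode exists for external
data. The monoexponential fit initialises from a log-linear regression and
refines by nonlinear least squares in linear space; two points reduce to
the closed form, and non-decaying data return D = 0 with the convergence
flag down and a warning. Stokes–Einstein sizing uses the exact Boltzmann
constant and, by default, pure-water viscosity from the Vogel-type
correlation `η = 2.414×10⁻⁵ · 10^(247.8/(T−140))` Pa·s (≈1% accurate over
the liquid range); a dilute buffer's viscosity increment is neglected
unless an explicit η is supplied. 37 °C is stored exactly as 310.15 K.
The fast-exchange average `D_obs = f·D_free + (1−f)·D_agg` with
`f = min(CMC/c_total, 1)` quantifies the monomer correction; for a 15 mM
sample with a CMC of at most 80 μM it is ~1%, i.e. negligible next to the
fit uncertainty.

## Packing geometry

The Tanford length `l = 0.15 + 0.12·n_c` nm estimates the fully extended
acyl chain; the micelle diameter is taken as twice the fully stretched
molecular length (chain + headgroup), endpoint-wise over a headgroup
interval. The headgroup contribution is accepted as a direct length
interval rather than derived from residue counts: for branched
oligosaccharides the effective extension along the micelle radius is
shorter than the summed residue lengths, and no single multiplication is
defensible — `headgroup_length` exists as an explicit helper for the
simple linear case. The consistency report compares closed intervals
pairwise (gap 0 when they touch) and is invariant to input order.

## Synthetic data

The generator emulates the statistical structure the analyses assume:
smooth globular-micelle curves with a minimum near 0.06 Å⁻¹ and a broad
peak above 0.1 Å⁻¹ (the `gm1_micelle` preset: oblate core–shell ellipsoid
with total polar/equatorial diameters 9/10 nm, a 22 Å shell, and relative
SLDs 0.240/0.380/0.334 chosen once to reproduce those features),
two-order lamellar patterns at 60 and 64 Å, vesicle-dominated mixture
curves, and monoexponential echo decays (δ = 2 ms, Δ = 150 ms, 32 linear
gradient steps, D = 1.04 × 10⁻¹⁰ m²/s in the preset).

Noise is multiplicative Gaussian at 2% by default (1% for the lamellar
presets), or a Poisson-like count model; the level is a package choice —
reduced instrument curves do not reveal their counting statistics — so
recovery results quantify performance under the declared noise model, not
under any particular detector. Real data additionally carry instrument
resolution smearing, incoherent/buffer backgrounds with structure,
interparticle structure factors at high concentration, and polydispersity;
passing the recovery tests here does not bound errors from those effects.
Randomness is pure function of seeds: replicate i of master seed s draws
from `numpy.random.SeedSequence([s, i])`, making every study
bit-reproducible.

Default q-grid: 200 log-spaced points in [0.01, 0.5] Å⁻¹, covering the
feature range of the curves above. Problem sizes in the shipped studies
(25 fit replicates, 50 indexing replicates, 100 decay replicates) keep the
whole suite in seconds while giving stable medians.

## Known limitations

- No absolute-intensity calibration, resolution desmearing, 2-D detector
  handling, or structure-factor fitting.
- The Bragg/hump discrimination is manual by design (see above).
- The ellipsoid swap-restart makes the common two-radii fit robust, but
  heavily parameterised mixture fits remain sensitive to starting points,
  as in any SAXS fitting software.
- Multi-exponential or distribution (ILT) diffusion fitting is out of
  scope; a single species (or fast-exchange average) is assumed.
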