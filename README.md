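# lipidscatter

Quantitative analysis of co-existing lipid self-assemblies — micelles,
vesicles, discs and multilamellar stacks — from small-angle X-ray
scattering (SAXS) and pulsed-field-gradient stimulated-echo (PFG-STE)
diffusion NMR, with a Tanford-type packing-geometry estimator and a seeded
synthetic-data generator for end-to-end validation.

The package is aimed at membrane biophysicists characterising
ganglioside–phospholipid mixtures (the shipped presets model GM1/DOPC
dispersions), but every model and fit is generic.

## What it computes

**SAXS form factors** (`lipidscatter.scattering_models`). Orientationally
averaged intensities built on the sphere kernel
`F(x) = 3(sin x − x cos x)/x³`:

- core–shell sphere (closed form) and core–shell ellipsoid of revolution
  (Gauss–Legendre tilt average), the model used to size slightly oblate
  glycolipid micelles;
- vesicle (a bilayer shell with a solvent-filled lumen — algebraically the
  core–shell sphere with the core SLD set to the solvent);
- finite cylinder (Bessel-J1 radial × sinc axial amplitude), whose
  `length < 2·radius` regime describes lipid discs;
- multilamellar Bragg patterns (Lorentzian orders at `q_n = 2πn/d` on a
  power-law baseline);
- exact weight-linear mixtures `I(q) = Σ wᵢ Iᵢ(q)` for samples in which
  several particle populations co-exist.

**SAXS analysis** (`lipidscatter.saxs_analysis`). `q = 4π sin θ/λ` and
`d = 2π/q` conversions, Bragg peak detection with sub-grid parabolic
refinement, least-squares lamellar indexing over integer order
assignments, and weighted least-squares model fitting (`lmfit`-backed,
with 1σ uncertainties and reduced χ²).

**Diffusion NMR** (`lipidscatter.nmr_diffusion`). The Stejskal–Tanner
decay `I(b) = I₀ exp(−bD)` with `b = γ²G²δ²(Δ − δ/3)`, monoexponential
fitting, pure-water viscosity, Stokes–Einstein sizing `R = kT/(6πηD)` and
the fast-exchange monomer/micelle average
`D_obs = f·D_free + (1−f)·D_micelle`.

**Packing geometry** (`lipidscatter.geometry`). Tanford chain length
`l = 0.15 + 0.12·n_c` nm, headgroup extension, micelle diameter ≈ twice
the stretched molecular length, and a cross-technique size-consistency
report.

**Synthetic data** (`lipidscatter.synthetic_data`). Seeded, bit-reproducible
generators for all of the above, with the generating truth attached.

## Worked example

```python
import numpy as np
from lipidscatter import nmr_diffusion as nmr
from lipidscatter import saxs_analysis as sa
from lipidscatter import synthetic_data as syn

# 1. lamellar indexing: simulate a DOPC-like stack and recover d
ds = syn.preset("dopc_lamellar").simulate(seed=7)
peaks = sa.detect_peaks(ds.data, min_prominence=0.05)
idx = sa.index_lamellar(peaks, max_order=3)
print(f"repeat distance: {idx.repeat_distance:.2f} A")

# 2. size a micelle from its diffusion coefficient at 37 C
ctx = nmr.HydroContext(temperature=310.15)      # water viscosity looked up
radius = nmr.stokes_einstein_radius(1.04e-10, ctx)
print(f"hydrodynamic diameter: {2e9 * radius:.2f} nm")
```

prints

```
repeat distance: 59.95 A
hydrodynamic diameter: 6.33 nm
```

The indexed repeat distance recovers the generating 60 Å stack to well
within the peak width, and a diffusion coefficient of 1.04 × 10⁻¹⁰ m²/s at
37 °C corresponds to a ~6.3 nm micelle — consistent with the 8–10 nm
outer diameter from scattering fits once the loosely hydrated sugar
corona is taken into account.

A command-line interface wraps the same workflow
(`lipidscatter simulate | fit-saxs | index-lamellar | fit-diffusion |
size-report`); every run writes a provenance sidecar with the config,
package version and master seed.

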