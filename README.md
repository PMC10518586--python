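# membrane-probe

Quantitative analysis of model lipid bilayers perturbed by a lipid-peroxidation
product (dodecanedioic acid, DDA) and protective flavonoids.  The package
covers the four measurement channels such studies combine — molecular
trajectory statistics, small-angle X-ray scattering (SAXS), spin-label EPR,
and atomic force microscopy (AFM) — plus a synthetic-data generator that
plants every structural feature of interest with exactly known ground truth,
so the whole pipeline is testable without external data.

It is intended for membrane biophysicists who want reproducible, scriptable
post-processing of bilayer data: leaflet assignment, density profiles and
maps, radial distribution functions, hydrogen-bond graphs and aggregates,
water-wire detection, inter-leaflet thickness maps, electron-density-profile
fitting, order parameters, and force-curve mechanics.

## Models at the core

**SAXS.** The electron density across the bilayer is a symmetric combination
of three Gaussian-smoothed slabs,

    ρ(r) = ρ₀ + ½ Σᵢ (ρᵢ₋₁ − ρᵢ) [erf((r − Rᵢ)/(√2 σᵢ)) − erf((r + Rᵢ)/(√2 σᵢ))],

with solvent baseline ρ₀, step positions R₁ < R₂ < R₃ and widths σᵢ.  Its
form factor has the closed form F(q) = Σᵢ (ρᵢ − ρᵢ₋₁) · 2 sin(qRᵢ)/q ·
exp(−σᵢ²q²/2), validated in the tests against adaptive quadrature.
Multilamellar interference follows modified Caillé theory (stack of N
lamellae, repeat d, fluctuation parameter η), and the measured intensity is
I(q) = scale/q² · |F(q)|² · [f_diffuse + (1 − f_diffuse) S(q)].  Fitting is
weighted least squares with the step ordering enforced by construction.

**EPR.** From the outer/inner hyperfine splittings 2A∥ and 2A⊥ of a doxyl
stearate probe, the order parameter is the polarity-corrected

    S = (A∥ − A⊥) / (A_zz − (A_xx + A_yy)/2) · a₀/a′,

with a′ = (A∥ + 2A⊥)/3 and a₀ = (A_xx + A_yy + A_zz)/3; the default tensor is
(6.1, 6.1, 32.9) G.  The rotational correlation time is
τ_c = 1/(6·(D_x D_y D_z)^⅓).

**AFM.** Breakthrough ("jump") events in approach force curves give the
bilayer yield force and thickness; elasticity uses the Hertz sphere model
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} (ν = 0.5); height maps are first-order
plane-flattened before R_a/RMS roughness statistics.

**Trajectories.** Frames carry positions (nm), species tags, molecule ids,
electron counts and an orthorhombic box.  All pair quantities use the
minimum-image convention, and the H-bond criterion is geometric
(D···A ≤ 0.35 nm, D–H···A ≥ 150°, configurable).

## Worked example

```python
import numpy as np
from membrane_probe import analysis, epr
from membrane_probe.synthetic import BilayerSpec, ThinPatchSpec, build_trajectory

# synthetic bilayer with a planted 1.5 nm-radius thinned patch
spec = BilayerSpec(
    lipids_per_leaflet=64, lateral_box=(10.0, 10.0),
    patch=ThinPatchSpec(center_xy=(5.0, 5.0), radius=1.5, head_plane_offset_inside=1.35),
    seed=42,
)
traj = build_trajectory(spec, n_frames=1)
tmap = analysis.interleaflet_distance_map(traj, cell=0.5)
xx, yy = np.meshgrid(tmap.x_centers, tmap.y_centers, indexing="ij")
inside = np.hypot(xx - 5.0, yy - 5.0) < 1.5
print(f"patch thickness : {tmap.distance[inside & tmap.valid].mean():.3f} nm")
print(f"bulk thickness  : {tmap.distance[~inside & tmap.valid].mean():.3f} nm")

for rec in epr.example_records()[:3]:
    print(f"{rec.sample:28s} S = {epr.order_parameter(rec).S:.3f}")
```

prints

```
patch thickness : 1.497 nm
bulk thickness  : 2.499 nm
DOPC+5-DSA (control)         S = 0.608
DOPC+5-DSA+DDA               S = 0.582
DOPC+5-DSA+DDA+MCE           S = 0.623
```

The thickness map localises the planted thinning (the patch is ~1 nm thinner
than the surrounding bilayer, whose leaflet centre-of-mass planes sit at
±1.25 nm), and the order parameters show DDA fluidising the membrane
(S drops from 0.608 to 0.582) while the flavonoid restores order.

A full demonstration dataset plus every analysis stage runs from the shipped
configuration:

```sh
membrane-probe run --config examples/demo.yaml --outdir runs/demo
```

## Layout

- `src/membrane_probe/synthetic.py` — generators with planted ground truth
- `src/membrane_probe/analysis.py` — trajectory statistics
- `src/membrane_probe/trajio.py` — PDB / GRO / extended-XYZ readers and writers
- `src/membrane_probe/saxs.py`, `epr.py`, `afm.py` — the three experimental channels
- `src/membrane_probe/pipeline.py`, `cli.py` — YAML-driven orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
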