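# cuticleflex

Multiscale mechanics of curved arthropod cuticle in bending: reduce scanning
wide-angle X-ray diffraction (WAXD) line scans to chitin fibril strains,
invert a large-deflection curved bilayer beam model for layer moduli, and
extract shear-lag strain-transfer parameters that link fibril strain to
tissue strain.

The package targets experiments in which a naturally curved cuticle strip
(a stiff, mineralised outer **exocuticle** of modulus `E1` on a softer inner
**endocuticle** of modulus `E2 = η E1`) is compressed or stretched stepwise
between pinned grips while a microfocus X-ray beam maps the (002) chitin
reflection across the thickness. It is aimed at researchers who run (or
simulate) such beamline experiments and need a tested, seedable pipeline from
detector frames and load traces to layer moduli and fibre–matrix coupling
parameters.

## The models

**Fibril strain from diffraction.** A cake-shaped azimuthal sector around the
(002) reflection is integrated to `I(q)`, fitted with a Gaussian on a linear
background; the lattice spacing is `D₍₀₀₂₎ = 2π/q₍₀₀₂₎` and its percentage
change relative to a site-matched unloaded reference is the axial fibril
strain. The total intensity over 11.85–19.05 nm⁻¹ locates the specimen along
the scan and separates the layers.

**Bilayer elastica.** The specimen is an extensible, unshearable circular arc
(radius `R`, central angle `α`, width `b`, thickness `h = t1 + t2`) with
pinned ends and a prescribed chord change. With forces scaled by `E1 b h` and
lengths by the arc length `L = Rα`, the half-arc equilibrium is integrated
from the apex and the end conditions are enforced by a shooting method. The
end decomposition satisfies

    H̄₀ = N̄₀ cos(α/2 + θ₀) − Q̄₀ sin(α/2 + θ₀),     H₀ = E1 b h H̄₀,

with `N̄₀`, `Q̄₀` the tangential/normal internal force components and `θ₀` the
end-rotation change. Because the nondimensional problem depends only on the
geometry and `η = E2/E1`, the joint `(E1, η)` least-squares fit to stepwise
load–displacement data is separable in `E1`.

**Shear-lag strain transfer.** Fibril strain is a fraction of the local
tissue strain, `ε_F = A_F(κ) ε_T`, with

    A_F(κ) = 1 − tanh(κ/2)/(κ/2),      κ = √(G_M/E_F) · ξ_F / √(ln(1/φ_F)),

so a measured `A_F` inverts to κ and, with fibril aspect ratio `ξ_F` and
volume fraction `φ_F`, to the matrix-to-fibril modulus ratio `G_M/E_F`.

A seeded **phantom generator** renders complete synthetic datasets (detector
frames with Poisson noise, scan manifests, stepwise load-relaxation traces)
from known ground truth — including the ~0.15% exo-to-endo pre-strain offset
of the unloaded tissue — so that every reduction and inversion stage is
testable end to end without beamline data.

## Worked example

```python
from pathlib import Path
from cuticleflex import phantom, pipeline

spec = phantom.PhantomSpec(seed=3, noise=phantom.NoiseModel(load_sigma_N=0.05))
cfg = pipeline.RunConfig(outdir=Path("out"), seed=3, phantom_spec=spec,
                         n_samples=3)
results = pipeline.run_synthetic(cfg)
print(results["moduli"]["median_eta"], results["shearlag"]["AF"],
      results["prestrain"]["mean_diff_pct"])
```

This simulates three specimens in stepwise compression, reduces every line
scan, and prints (seed 3):

```
0.3087269619288981 0.400008783617028 0.15128255933462612
```

i.e. a median recovered modulus ratio `η ≈ 0.31` (truth 7/24 ≈ 0.29, so the
endocuticle is correctly found ~3× softer than the exocuticle), a fitted
strain-concentration factor `A_F ≈ 0.40` (truth 0.39, corresponding to
`κ ≈ 3.0` and a fibril-to-matrix stiffness contrast `E_F/G_M ≈ 680` at
`ξ_F = 100`, `φ_F = 0.20`), and a recovered exo–endo pre-strain difference of
~0.15% strain. The full bundle (per-scan CSVs, `strain_pairs.csv`,
`samples.csv`, `results.json`) is materialised under `out/`.

The same stages are available from the shell:

```sh
cuticleflex simulate --config spec.yaml --out ds/
cuticleflex reduce --manifest ds/manifest.csv --geometry ds/geometry.yaml --out red/
cuticleflex beamfit --loads steps.csv --arc arc.toml --mode compression --out fit.json
cuticleflex shearlag --pairs pairs.csv --xi 100 --phi 0.20 --out shearlag.json
cuticleflex run-all --out run/ --seed 3
```

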