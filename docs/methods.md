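# Methods

## Scope and data model

The package analyses stepwise flexural loading of a curved bilayer cuticle
strip observed by scanning WAXD. Three physical scales are linked:

1. **Nanoscale** — the (002) chitin reflection near q ≈ 12.2 nm⁻¹; its
   spacing `D = 2π/q` tracks axial fibril strain. Strains are stored in
   percent throughout; q in nm⁻¹, D in nm, moduli in GPa, stresses in MPa,
   loads in N, specimen dimensions in mm.
2. **Mesoscale** — the through-thickness tissue strain field ε_T(S, Z) of the
   bent arc (S arc coordinate from the apex, Z depth from the outer
   exocuticle surface).
3. **Macroscale** — the horizontal grip load H₀ at each prescribed chord
   change.

## Bilayer elastica

The specimen is a planar, extensible, unshearable rod with an initially
circular centreline and a two-layer rectangular section. Assumptions: no
distributed load (the internal force is constant along the rod), symmetric
deformation about the apex, moment-free pinned ends, linear elastic layers,
no shear deformation, no contact or plasticity. The section enters through
the modulus-weighted centroid depth

    z_n = [t1²/2 + η t2 (t1 + t2/2)] / (t1 + η t2),

the dimensionless axial stiffness `EA̅ = (t1 + η t2)/h` and bending stiffness
`EI̅ = ∫ (E(z)/E1)(z − z_n)² dz / (h L²)`. Nondimensionalisation: lengths by
L = Rα, forces by E1 b h, moments by E1 b h L. The half-arc ODEs integrated
from the apex (θ = 0, V̄ = 0, M̄ = M̄_apex) are

    x̄' = (1+ε) cos θ,  z̄' = (1+ε) sin θ,  θ' = α + M̄/EI̅,  M̄' = −(1+ε) Q̄,

with N̄ = H̄ cos θ, Q̄ = −H̄ sin θ, ε = N̄/EA̅. The shooting unknowns (H̄,
M̄_apex) enforce the prescribed half-chord position and M̄ = 0 at the pin.
θ₀ is reported as the *change* of end rotation from α/2, so the end-force
identity reduces to H̄₀ = N̄₀ cos(α/2) − Q̄₀ sin(α/2) at zero load; for every
converged solution the reconstructed H̄₀ equals the applied horizontal force
to ≤1e-8 (a built-in invariant, tested). Compression means chord shortening
and carries negative H₀ and axial force.

The tissue strain field is affine through the thickness:
ε_T(S, Z) = ε_axis(S) + (z_n − Z)·Δκ(S) with Δκ = M̄/(EI̅ L). With the
exocuticle on the convex side, compression (curvature increase) stretches
the outer surface and compresses the endocuticle, reproducing the layer
asymmetry seen in bending experiments.

**Numerics.** Adaptive RK45 with rtol 1e-8 / atol 1e-10; damped Newton (2×2
finite-difference Jacobian, step halving, tolerance 1e-10, ≤50 iterations)
warm-started from a virtual-work estimate. Halving the integrator tolerance
changes H₀ by far less than 0.01%. The independent linear oracle is the
unit-load (virtual work) chord compliance of the pinned arch evaluated by
quadrature on the undeformed geometry; the shooting stiffness converges to
it within 1% as the prescribed displacement → 0.

## Layer-modulus inversion

At fixed η the model load is `H₀ = E1 · C(δ, η)`, so E1 is profiled out
analytically and the remaining 1-D objective in η is minimised over a coarse
grid (0.05…1.0, covering the multistart points 0.1/0.3/0.5/0.8) followed by
bounded scalar refinement (xatol 1e-5). Residuals are weighted by 1/|H_obs|:
load-cell error over the stepwise range is predominantly multiplicative, and
with unweighted residuals the largest step dominates and the modulus ratio
becomes unidentifiable at realistic noise. A flat profiled objective
(variation below 1e-6 of the weighted load scale) sets
`eta_identifiable=False`: with load data alone, η is informed only by the
*shape* of the nonlinear load–displacement curve, which is a genuinely weak
signal for deep arches. Standard errors come from the numerical Hessian of
the weighted SSE at the optimum. Compression and tension data are fitted
separately (the two modes may yield different effective moduli).

## Shear-lag analysis

`A_F(κ) = 1 − tanh(κ/2)/(κ/2)` is strictly increasing and bounded in (0,1);
inversion uses bracketed root finding (Brent, |ΔA_F| ≤ 1e-12) on
κ ∈ [1e-6, 1e3], with a series expansion below κ/2 < 1e-4 for numerical
stability. The κ definition uses the **natural** logarithm of 1/φ_F — the
only reading consistent with the standard Cox shear-lag parameter and with
the reference numeric chain κ=3, ξ_F=100, φ_F=0.20 → G_M ≈ E_F/690.
Defaults ξ_F = 100 and φ_F = 0.20 are literature values for chitin
fibre/matrix composites and are overridable.

`fit_AF` regresses fibril strain on tissue strain **through the origin**
(the model is proportional; an intercept would absorb reference-matching
offsets), per specimen, at the first load level only (elastic regime), and
reports the across-specimen mean ± s.e.m.

## Phantom generator

The phantom emulates: a through-thickness pre-strain profile blending the
exocuticle mean (default 0%) to the endocuticle mean (default 0.15%, the
reference exo–endo offset) with a logistic transition spanning 10% of the
thickness centred at the layer interface (the real gradient is continuous;
its exact shape is not known); stepwise loading to 0.5/1.0/1.5/2.0%
macroscopic strain at 0.05% s⁻¹ with 150 s relaxation holds (single
exponential, τ = 30 s, amplitude 10% of the step load — only the plateau
values matter downstream); line scans at 20 µm steps offset 25 µm along the
arc between strain levels; and detector frames whose (002) arc is Gaussian
in azimuth (σ = 20°, a free parameter — the real azimuthal breadth of this
tissue is not established) with fixed strain-free rings at 13.9 and
17.0 nm⁻¹ standing in for the (110)/(013) reflections. Counts are Poisson
with additive Gaussian read noise; a full dataset is byte-identical for the
same (spec, seed).

Default specimen: R = 12 mm, α = 0.42 rad (chord 5.0 mm, matching the
~5 mm gauge), b = 0.7 mm, h = 0.5 mm with the exocuticle at 35% of the
thickness, E1 = 24 GPa and η = 7/24 (midpoints of the compressive ranges
for the two layers). The default arc is *shallower* (rise ≈ 0.26 mm) than a
real abdominal tergite: the strong geometric softening of a shallow arch is
what makes η identifiable from loads alone at 1% load noise. Consequently
the synthetic loads (≈6–15 N over the step range) are larger than the
few-newton loads of comparable experiments; the inversion itself is
scale-free in this respect.

Two detector geometries are provided. The default is a 64×64-pixel frame
with the beam centre ~200 pixels off the active area: the (002) ring then
crosses the frame nearly radially with ~0.05 nm⁻¹ effective q sampling,
giving full-fidelity reduction at desk-scale cost. A Pilatus-like 1475×1679
geometry (172 µm pixels, 14 keV) is available for full-frame realism.

**What the phantom does not model:** the 3-D Bouligand (helicoidal) fibre
orientation distribution, pore-canal texture, detector panel gaps and
distortion, radiation damage, specimen-thickness variation along the scan,
and exposure normalisation between frames (frames are equal-exposure).
Passing recovery tests therefore demonstrates correctness of the reduction
and inversion chain under the stated forward model, not robustness to these
real-data effects.

## Frame reduction

Pixel → q uses the flat-detector map q = (4π/λ) sin(½ atan(r/d)) with
λ = 1.23984/E[keV] nm; pixels are 0-based, origin top-left. The cake sector
is ±15° about the azimuth of the brightest pixel in the q window (the arc
meridian), pooled with its mirror at +180°; binning is uniform, 400 bins
over 11.0–20.0 nm⁻¹; empty bins are flagged, never zero-filled. The peak
fit (Gaussian + linear, window 11.8–12.6 nm⁻¹) uses the *mean pixel q per
bin* as abscissa — with the geometric bin centre, sub-bin quantisation
rescales small peak shifts by ~1%, a bias the mean-q abscissa removes.
Moment-based initial values; non-convergence, escaped centres and
amplitude below 5× the residual scatter are flagged, never raised, and
propagate as missing values; a layer mean requires ≥3 valid points.

Segmentation takes the longest run of scan points whose total intensity in
11.85–19.05 nm⁻¹ exceeds 3× the median of the three lowest-intensity
(background) points. The exo/endo boundary is placed at a configured
fraction `t1_fraction` of the thickness: the intensity criterion
distinguishes sample from background robustly but the layer interface
itself is not quantitatively encoded in total intensity, so the fraction is
a required input (the phantom's ground truth supplies it in tests).
Normalised depth runs 0 (exocuticle surface) to 1; strain references are
site-matched by nearest normalised depth in the unloaded scan, since scans
at successive load steps are laterally offset and exact site identity is
impossible.

## Statistics

Wilcoxon signed-rank (paired layers, zeros dropped with warning) and
Mann–Whitney U (mode comparisons, Holm step-down over the family) use exact
null distributions for small samples without ties (n ≤ 25 and n1+n2 ≤ 12
respectively), normal approximations with tie correction otherwise. The
aligned rank transform (ART) analysis aligns the response for each effect
(subtracting all other estimated effects), ranks the aligned values, and
runs a classical split-plot ANOVA — mode tested against subjects-within-
mode, layer and interaction against the layer×subject residual; group
sizes may differ between modes (unweighted cell means). Post hoc: paired
Wilcoxon between layers within each mode, Holm-adjusted. Constant data
yields NaN statistics flagged `degenerate` rather than a spurious p value.
Normality screening is reported upstream of these tests but never gates
them.

## Synthetic study sizes

The bundled studies are sized for a single CPU: modulus-ratio recovery uses
4 load steps × 20 noise seeds at 1% multiplicative load noise; pre-strain
recovery uses one unloaded line scan of ~34 frames at the 64×64 geometry;
the end-to-end pipeline default is 3 replicate specimens × 5 strain levels.
Medians are reported for the modulus ratio because the per-seed estimator
is heavy-tailed when the profiled objective is shallow on its upper branch.

## Known limitations

- η from loads alone is weakly identified for deep arches; fitting loads
  jointly with fibril-strain profiles would sharpen it but is not
  implemented.
- The elastic model cannot represent the yielding suggested by tension-mode
  discrepancies in real cuticle; large prescribed displacements (>5% of the
  chord) are rejected.
- The strain reference is the unloaded scan; creep between steps and
  radiation-induced drift are not modelled or corrected.
- `segment_scan` assumes exactly one contiguous specimen per scan.
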