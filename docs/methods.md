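# Methods

`myofat` simulates fixed-end (isometric) contraction of a tibialis
anterior (TA)-like muscle whose tissue is a mixture of contractile muscle
and intramuscular fat, to quantify how the *location* of fatty
infiltration — not only its amount — modulates force-generating capacity.
This note records the model, the synthetic data it runs on, the numerical
choices, and what the desk-scale results do and do not show.

## Constitutive model

Each muscle element is an uncoupled solid mixture weighted by its fat
fraction `X` (percent):

    W = (1 − X/100) · W_muscle^iso + (X/100) · W_fat^iso + (K/2)(ln J)²

A single volumetric penalty with the muscle bulk modulus `K` enforces
near-incompressibility for the whole mixture (the fat phase carries no
bulk term of its own). All deviatoric terms are evaluated on isochoric
kinematics `F̄ = J^(−1/3) F`.

**Muscle** is transversely isotropic and hyperelastic with
`W_muscle^iso = W_λ(λ, a) + G_φ φ² + G_β β²`, where `λ = √I₄` is the
along-fiber stretch, `a ∈ [0, 1]` the activation, and the shear measures
are the invariant forms

    φ² = I₅/I₄² − 1,
    β  = acosh( (I₁ I₄ − I₅) / (2 √I₄) ),

which vanish in the reference state and linearise to engineering shear in
the corresponding simple-shear modes (a unit test enforces both
properties, since these formulas come from the transversely isotropic
model family rather than being re-derivable from the mixture ansatz).
The fiber energy is defined through the fiber Cauchy stress,

    λ ∂W_λ/∂λ = σ_max · f_total(λ/λ_ofl, a) · λ/λ_ofl,
    f_total = a·f_active + f_passive,

with the standard normalised curves: a piecewise-quadratic active
force–length curve supported on `[0.4, 1.6]·λ_ofl` with peak 1 at
`λ_ofl`, and an exponential passive curve `P₁(e^{P₂(λ/λ_ofl−1)} − 1)` that
continues linearly (C¹) beyond `λ*`. `W_λ` is integrated in closed form
so energy-consistency tests can difference it directly.

**Fat** is an isochoric neo-Hookean solid, `W_fat = (G_f/2)(Ī₁ − 3)`.
The alternative printed coefficient convention `2 G_f (Ī₁ − 3)` is
selectable (`fat_energy_convention="printed"`) for sensitivity
exploration; the conventional form, which makes `G_f` the shear modulus,
is the default.

**Aponeurosis** tissue is a Mooney–Rivlin matrix
`C₁(Ī₁−3) + C₂(Ī₂−3) + (K/2)(ln J)²` plus tension-only
exponential-power-law fibers `ξ/(αβ)(exp[α(I₄−1)^β] − 1)`; with the
default `α = 0` the fiber energy is its limit `(ξ/β)(I₄−1)^β` for
stretched fibers and zero in compression (the power law is undefined or
non-monotone there for non-integer `β`).

Default constants (MPa where dimensional): muscle `K=75`,
`G_φ=3.87e−3`, `G_β=2.24e−2`, `P₁=0.04`, `P₂=6.6`, `λ_ofl=1`, `λ*=1.4`,
`σ_max=0.3`, `G_f=4.19e−3`; aponeurosis `K=500`, `C₁=5`, `C₂=0`, `α=0`,
`β=2.5`, `ξ=1.5`. Units are mm–N–MPa throughout, so reaction forces come
out in newtons.

## Fiber architecture

Fiber directions are generated by solving a Laplace problem on the tet
mesh: Dirichlet 1 on the fiber-origin surfaces (the proximal aponeurosis
interface plus the tibial-origin strip for the muscle; the sheet ends for
the aponeuroses), 0 on the insertion surfaces (the central aponeurosis
interface; the distal sheet end), natural zero-flux conditions elsewhere.
For incompressible irrotational flow the velocity is the potential
gradient, so this reproduces the streamline topology of a pressure-driven
slip-wall flow between the same surfaces without a CFD solver. Per linear
element the unit fiber direction is the normalised negative gradient,
sign-disambiguated against the distal-pointing long axis. Elements whose
gradient norm is below 1e−12 of the domain maximum inherit the direction
of the nearest resolved element (reported to the caller).

A known artifact of this stage on the synthetic geometry: potential decay
in the long channel between the origin region and the embedded sheet
leaves the distal interior nearly stagnant, and directions there turn
perpendicular to the long axis as the streamlines dive into the sheet.
The affected elements are geometrically small (the volume-weighted mean
fiber angle to the long axis is ≈ 40°, against ≈ 50° unweighted), but
their active transverse contraction axially extrudes the sheet and
slightly *reduces* the transmitted control force; see Limitations.

## Synthetic geometry

The generator emulates a fusiform TA: length 300 mm (subject range
roughly 260–370 mm), elliptical cross-section with belly semi-axes
20 × 15 mm (volume ≈ 125 cm³), taper profile `p(ζ) ∝ ζ^m (1−ζ)²` floored
at 0.45 of the belly scale and peaking at 60% of length from the distal
end — where the real muscle attains its maximum cross-section. The
central aponeurosis is a 3 mm solid sheet with shared nodes spanning 80%
of the section width and the distal half of the length; a 15 mm extrusion
of the most proximal section stands in for the proximal aponeurosis, and
the tibial/fascicle-origin surface is a circumferential band over the
proximal 30% of muscle length (wrapping the section keeps the anterior
and posterior halves architecturally equivalent, which the cross-half
fat comparisons presume). Template cross-sections are radially rescaled so each
polygonal section has exactly the analytic elliptical area; mesh volume
then tracks the analytic profile volume to well under 1% even at coarse
resolution.

Design notes: the sheet's thickness/width were chosen so its axial
stiffness is physiological *in series with the muscle* given the soft
aponeurosis constants above — a thin sheet stretches tens of percent
under the ≈ 100 N the muscle delivers, which is both unanatomical and
numerically hostile. The sheet is meshed on the mid-plane; a posterior
offset (`apo_offset`) is available and more anatomical, but breaks the
symmetry, adds soft sheet-bending modes and roughly doubles solve times,
so the symmetric default is kept for desk-scale work. The distal free
tendon is truncated: the distal sheet end stands in for the
aponeurosis-to-tendon junction and is where the model force is read.

## Fat mapping

Anatomic schemes reproduce an imaged distribution at four levels of
detail: per-element voxel averages (voxel centers located exactly in
tets, with centroid interpolation for elements missed by the coarse 4 mm
slices), a 50% threshold binary map (≥ 50 → 100%), length-third regional
means, and the uniform volumetric mean. Regional and total maps conserve
the volume-weighted mean exactly by construction.

Pseudo maps place beta-distributed fat in one of eight regions — length
thirds, distal third plus proximal 20%, and medial/lateral/anterior/
posterior halves split at 50% of each length-slab's extent along the
respective axis. With the first shape parameter fixed at 2, the second
follows from the target regional mean `γ = α/(α+β)`; `γ = 100%` is the
degenerate constant assignment. Draws are i.i.d. per element and
reproducible per seed. Aponeurosis elements never receive fat.

## Quasi-static solver

Total-Lagrangian displacement FEM on 10-node tetrahedra (promoted from
the generator's linear mesh; linear tets remain available for smoke tests
but lock volumetrically at these bulk-to-shear ratios and overestimate
stiffness). A 4-point Gauss rule integrates each element; the residual is
the discrete gradient of the total strain energy, and the tangent is
assembled by forward-differencing the element force vectors (batched
across degrees of freedom). Dirichlet constraints fix the aponeurosis
ends and the tibial origin; reactions are the residual sums over each
constrained set, and the scalar "model force" is the magnitude of the
distal-aponeurosis resultant.

Activation ramps 0 → 1 in (default) 10 increments with adaptive halving
and a secant predictor. Each increment is equilibrated by a trust-region
Newton method on the energy: the Newton direction is damped with a
Levenberg shift until the step fits the trust radius, the radius grows
geometrically on accurate steps (gain ratio) and shrinks on rejection,
and element inversion simply rejects the trial. This globalisation is
what makes the problem tractable: the activated muscle is soft in shear
(`σ_max/G_φ ≈ 75`), the equilibrium path crosses long nearly-flat valleys
(fiber shortening against the compliant aponeurosis), and residual-norm
line searches crawl where the trust region strides. Batch runs
warm-start from related converged states (the fat-free control, or the
previous fat level of the same scheme) and then solve directly at full
activation — a continuation in the fat field verified to land on the same
equilibria as cold ramps on spot checks.

Convergence is declared at residual ≤ max(1e−8 × the increment's initial
imbalance, the configured absolute floor — 1e−3 N by default, 1e−2 N in
the batch study, both far below the ~100 N force scale); at the converged
control the volume ratio satisfies |J − 1| < 2% in over 99% of elements.

The constitutive evaluations inside assembly run through a numba kernel
(`myofat/_kernels.py`) that reproduces the reference numpy implementation
in `myofat/materials.py` to machine precision (a unit test compares the
two routes); without numba the solver transparently falls back to the
numpy route.

## Problem sizes

The shared coarse study (tests and `scripts/acceptance.py`) uses the
default muscle at a coarse discretisation (4 × 4 × 10 template cells →
~1.3k quadratic tets, ~6.8k degrees of freedom), a 4-increment control
ramp, pseudo-scheme levels `γ ∈ {50, 100}%` for the four length-wise
regions and `γ = 100%` for the cross-section halves (their monotonicity
is checked against the fat-free control; the reproduction script runs
one half per axis, the test suite all four), uniform 30% and 100% fat
models, and fat shear moduli {1, 15, 500} kPa. Full 8 × 10 sweeps with
per-level seeds are available through `myofat.analysis.pseudo_sweep` and
the `myofat sweep` CLI.

## What the synthetic data does and does not show

The generator reproduces the architectural features the pipeline needs —
fusiform taper with the maximum section at 60% length, an embedded
aponeurosis with origin/insertion topology, heterogeneous and regional
fat patterns with Dixon-like anisotropic voxels — so passing tests show
the *pipeline* (mapping, mixture mechanics, force extraction, scheme
comparisons) behaves correctly and reproduces the qualitative regional
findings: middle-third infiltration is by far the most damaging, distal
infiltration the least, and cross-sectional (medial/lateral/anterior/
posterior) placement barely matters. They do not validate subject-level
predictions: real TA geometry, fascicle curvature, fat microstructure and
clinical strength correlations require the original imaging data, which
is not deposited.

## Known limitations

* The distal Laplace stagnation zone gives near-perpendicular fibers
  around the anchored sheet; their transverse active contraction subtracts
  a few percent from the control force, so the *distal-third* and
  *proximal+distal* pseudo schemes show a small (≈ +2–5%) force *increase*
  instead of a flat curve — a synthetic-architecture artifact (cold ramps
  and warm continuations agree on it), flagged red in the acceptance
  suite rather than tolerated away.
* Linear fat scaling of material parameters, i.i.d. per-element beta
  draws (no spatial correlation), no fibrosis/edema compartments, no
  viscoelasticity or dynamics, no tendon slack or joint mechanics.
* Displacement-based elements with a volumetric penalty: quadratic tets
  keep locking acceptable at the coarse resolutions used, but stresses
  near the sheet are under-resolved; refinement studies beyond the 1%
  volume check were not run at desk scale.
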