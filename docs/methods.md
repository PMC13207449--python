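# Methods

## Scope

`tpmsbone` simulates the first ~100 days after implanting a polylactic-acid
(PLA) bone scaffold with a triply periodic minimal surface (TPMS)
architecture. One periodic unit cell — the representative volume element
(RVE), a 1 mm cube — is discretized into voxels carrying one of three
phases: PLA scaffold, a thin interfacial (cartilage-like) layer, and soft
tissue. Under a held compressive displacement, two per-element processes
compete day by day: hydrolytic scaffold degradation, accelerated by local
stress, and mechanostat-driven bone deposition in the tissue, triggered by
local stress. The package computes the geometry census, static effective
moduli, and the daily coupled trajectories.

## Geometry and the calibrated shell convention

The three surfaces are the level sets

- Schwarz P (S): `cos x + cos y + cos z`
- Fischer–Koch S (F): `cos 2x sin y cos z + cos 2y sin z cos x + cos 2z sin x cos y`
- lidinoid (L): `0.5 [sin 2x cos y sin z + …] − 0.5 [cos 2x cos 2y + …] + 0.15`

with one cell spanning `[0, 2π)` per axis, plus the linear S/F fusion
`a f_S + b f_F`, `a + b = 1`. A shell of dimensionless thickness `t` (0.3
by default) around `f = 0` is voxelized on an `N³` grid (N = 50 by
default, 0.02 mm voxels).

A band rule `|f| ≤ t` alone does not determine the three-phase split, and
reasonable-looking conventions give materially different counts. We
therefore calibrated the convention against a reference element census for
all three surface types jointly (`calibrate_shell_convention` scans the
candidate set). The unique zero-residual rule is:

- per-element scalar = the **trilinear interpolant at the centroid**, i.e.
  the mean of the 8 corner-node values `f(2πi/N, …)`;
- **scaffold**: `|f̄| ≤ 0.8 t`;
- **interface**: `0.8 t < |f̄| ≤ t` (a band ring, not a morphological
  dilation — the dilation alternative produces interface layers roughly
  twice too thick and is kept only as `grow_interface`);
- **tissue**: everything else.

This reproduces the reference counts exactly (S: 16 904 scaffold / 4 752
interface / 103 344 tissue of 125 000; F: 29 944 / 7 408 / 87 648;
L: 44 512 / 8 144 / 72 344). Porosity is `(1 − scaffold/total)·100`.
The period offset is count-invariant and, for these surfaces, shifting by
half a period maps the label field onto itself, so it is fixed at zero.

## Voxel finite elements

All phases are meshed solid. Elements are trilinear 8-node hexahedra with
full 2×2×2 Gauss quadrature rather than the reduced-integration C3D8R
voxel element common in commercial solvers: single-point integration needs
hourglass stabilization whose parameters vary by implementation, while
full integration is parameter-free and deterministic; it is mildly
stiffer, which stays well inside the tolerance we quote on effective
moduli.
Units are mm/MPa/N. All phases share ν = 0.3.

Linear systems (≈ 4·10⁵ unknowns at N = 50) are solved by conjugate
gradients with Jacobi preconditioning to a relative residual of 1e−8
(175–450 iterations at N = 50); daily solves warm-start from the previous
displacement field.

Two boundary-value problems:

- **Uniaxial compression** (the σ–ε measurement): bottom-face nodes fixed
  in all translations ("hinged" = pinned, voxel nodes carry no rotations),
  top-face nodes driven down by `ε·L` with in-plane motion free, lateral
  faces traction-free.
- **Periodic homogenization**: displacement = macro-strain affine part +
  periodic fluctuation; the fluctuation of every node on a max-face is tied
  to its min-face partner by projecting all `(N+1)³` nodes onto the `N³`
  master nodes (edges and corners resolve automatically since all their
  slaves share one master). One master node is pinned to remove rigid
  translation. Each unit macro-strain case yields a column of the
  effective stiffness from the volume-averaged stress; engineering moduli
  come from the inverted compliance (so `E11 = E` exactly for a
  homogeneous grid). Normal cases suffice for E11/E22/E33; shear cases are
  optional.

Per-element stress is the elasticity tensor applied to the
quadrature-averaged strain; principal values come from `eigvalsh` and the
von Mises stress from the principal-difference form.

At N = 50 the three-phase RVEs give PBC apparent moduli of 47.2 (S),
139.8 (F) and 203.0 (L) MPa, about +6 %, +1.5 % and +6 % relative to the
reference values obtained with reduced integration. The uniaxial σ–ε
modulus agrees with PBC within 3 % (F) and 5 % (L); the S type measures
~32 % below its PBC value because its load path crosses the lateral faces
at mid-height and traction-free faces sever what periodicity would close.
This deviation is intrinsic to the boundary-condition choice and is
reported rather than hidden.

## Constitutive evolution

**Hydrolysis.** Normalized molecular weight `β` (1 at implantation)
follows pseudo-first-order kinetics with a Zhurkov-type stress
acceleration, `β' = β·exp(−λ_eff Δt)`, `λ_eff = λ₀·exp(A σ/(R T))`, with
σ the element's von Mises stress in MPa (`A σ` read as J/mol; the quoted
units of A are dimensionally inconsistent and this is the standard
resolution). Defaults: λ₀ = 0.0075/day, A = 22, R = 8.314, T = 310 K.
Scaffold modulus follows
`E(β) = (E_S0 − E_T)·e/(e−1)·(1 − e^{−β}) + E_T`, anchored at
E(1) = 1350 MPa and E(0) = 10 MPa with `E_T` held at its initial value.
When β drops below 0.01 the element leaves the scaffold phase and becomes
fresh tissue (initial tissue modulus, remodelable): the solid three-phase
mesh has no void phase and a fully degraded polymer approaches the tissue
modulus anyway.

**Remodeling.** The daily stimulus for the single load case is
`φ = n^{1/m}·σ_vM` (n = 1000 cycles/day; the load weight factor m has no
canonical value — we default to m = 4, the common choice in the
daily-stress-stimulus literature, and expose it in the config). The
density rate has a dead zone: zero for `(1−ω)k ≤ φ ≤ (1+ω)k`
(k = 50 MPa, ω = 0.1), `B(φ−(1+ω)k)` above, `B(φ−(1−ω)k)` below, with
B = 1 (g/cm³)/(MPa·day). Density maps to modulus by `E = 3790 ρ³`, and is
clamped to [0.01, 2.0] g/cm³ to keep the power law physical (the rate law
itself is unbounded). Interface elements follow the same law with their
initial density from the inverse power law at 50 MPa; a config switch can
freeze them instead.

**Resorption branch.** The daily loop applies formation only by default
(`resorption=False`). With B = 1 in these units, tissue sitting 5–40 MPa
below the lower threshold — which is the generic situation for 10 MPa
tissue at 10 % strain — would be driven to the density floor within a
single day, which contradicts every trajectory this model is meant to
produce; the procedure description the model follows mentions only "inside
the dead zone: unchanged" and "above the threshold: deposit". The full
two-branch law is implemented and unit-tested, and the flag enables it.

**Loop ordering.** Each day uses one stress field (the solve that starts
the increment): degrade, remodel, then apply state changes. A config
toggle re-solves between degradation and remodeling; tests show the
difference is small.

**Bone volume.** Three readouts are emitted per day, since "osteogenic
volume" admits several definitions: element count with
`E > 2·E_T(0)` *and* above the element's own initial modulus (so the
50 MPa interface does not count as bone at day 0), integrated Δρ, and
integrated ΔE.

## Problem sizes and what the tests show

The test suite exercises geometry and algebra at N = 12–20, the static
moduli at the full N = 50, and the coupled loop at N = 24 (the package's
reduced-resolution mode; trajectory acceptance uses relative tolerances
there). The acceptance script uses N = 50 for the census and static
moduli and N = 24 for the evolution runs.

## Known limitations

- The default kinetic constants are internally inconsistent with the
  reference 10-day modulus collapse: mean scaffold von Mises stress is
  fixed by statics at ~31 MPa (S) / ~65 MPa (F, L) under 10 % strain, so
  `λ_eff ≤ 1.7 λ₀` and the mean β after 12 days is ≈ 0.85 — far from the
  β ≈ 0.13 needed for an 80 % modulus loss. Reproducing those decays
  requires an effective stress scale `R T / A ≈ 14–18 MPa` instead of the
  117 MPa the default constants give (8.314·37/22 = 14.0, suggesting a
  temperature entered in °C somewhere upstream). We keep the default
  constants; the trajectory-shape comparisons are reported as measured.
- Uniform hydrolysis kinetics: no autocatalysis, pH, or crystallinity.
- Isotropic linear elasticity; no contact, buckling, or large-strain
  effects despite the nominal 10–20 % strains.
- The synthetic fixtures (homogeneous cubes, series laminates) validate
  the solver against closed forms; they do not emulate biological
  variability — passing tests certify the numerics, not in-vivo accuracy.
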