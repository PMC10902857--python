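# bemamr

A charge-based quasi-static boundary element solver with adaptive h-refinement
for the forward problems of transcranial electrical stimulation (TES),
transcranial magnetic stimulation (TMS) and electroencephalography (EEG).

## The problem

Neurostimulation dosimetry and EEG source analysis both require solving the
quasi-static Maxwell equations in a head made of nested compartments of
homogeneous, isotropic conductivity. In a conductor, charge cannot accumulate
in the volume; it accumulates as a surface density ρ(r) on the interfaces
between tissues of different conductivity. Those induced charges fully
determine the secondary electric field, so the total field at any point is

    E(r) = E^p(r) + E^s(r),

where E^p is the primary field of the source (a coil's −∂A/∂t, a scalp
electrode, or a cortical current dipole) and E^s is the Coulomb field of the
interface charges.

On each interface with conductivity contrast K = (σ_in − σ_out)/(σ_in + σ_out)
the charge density satisfies a Fredholm integral equation of the second kind:

    ρ(r)/2 − K(r) n(r) · ∫_S (1/4π) (r − r′)/|r − r′|³ ρ(r′) dr′
        = K(r) n(r) · ε₀ E^p(r),    r ∈ S.

Voltage electrodes (patches held at a fixed potential) instead obey the
first-kind constraint that the single-layer potential equal the enforced
voltage; those rows are preconditioned by the explicitly inverted
electrode–electrode block.

The surfaces are triangulated and the charge density expanded in pulse
(facet-constant) bases — a Galerkin discretization that requires no mesh
conformity. The resulting system `R c = b` is solved matrix-free with GMRES:
far interactions use facet centroids through a pluggable acceleration backend
(the shipped backend is exact chunked direct summation), and facet pairs
within a few circumradii are corrected with Galerkin double integrals built
from the closed-form potential and field of a uniformly charged triangle.

## Adaptive h-refinement

Pulse bases fail where the charge density varies faster than the mesh can
represent — under electrodes, near dipole clusters, between closely spaced
shells. The adaptive loop alternates Solve and Refine:

1. rank the facets of each surface by total charge |Q_m| = |c_m A_m| and take
   the top `ceil(r · M_s)` per surface (default rate r = 1 %);
2. split each selected triangle 4:1 at its edge midpoints (children are
   coplanar and similar; no connectivity repair — pulse bases do not need it);
3. children inherit the parent's charge density verbatim (density is per unit
   area, so total charge is conserved exactly);
4. re-solve with GMRES warm-started from the inherited vector;
5. stop when the field (or potential) in a region of interest changes by less
   than 1 % between passes, or after 30 passes.

Closed-form models describe the cost: after k passes at rate r the mesh holds
M′ = M (1 + 3r)^k facets, a facet refined on every pass has edge l / 2^k, and
the total runtime is about t₀ Σₙ (1 + 3r)ⁿ.

## Worked example

A homogeneous sphere (radius 10 cm, σ_in = 0.275 S/m — gray matter) embedded
in a better conductor (σ_out = 1.654 S/m — CSF) in a uniform 1 V/m applied
field. The classical solution has a uniform interior field of
3σ_out/(σ_in + 2σ_out) ≈ 1.3849 V/m:

```python
import numpy as np
from bemamr import (HeadModel, SolverSettings, UniformFieldSource,
                    build_nearfield, evaluate_E, make_icosphere, solve,
                    uniform_field_interior_factor)

model = HeadModel([make_icosphere(0.1, 3)], sigma_in=[0.275], sigma_out=[1.654])
nearfield = build_nearfield(model)
source = UniformFieldSource(np.array([0.0, 0.0, 1.0]))
charges, stats = solve(model, source, SolverSettings(), nearfield, initial=True)

points = np.array([[0.0, 0.0, 0.0], [0.04, 0.0, 0.0], [0.0, -0.03, 0.03]])
E = evaluate_E(model, charges, points) + source.primary_E(points)
print(f"GMRES iterations: {stats.iterations}  (residual {stats.final_residual:.1e})")
print(f"interior E_z at 3 points: {np.round(E[:, 2], 4)}")
print(f"analytic interior field:  {uniform_field_interior_factor(0.275, 1.654):.4f} V/m")
```

prints

```
GMRES iterations: 3  (residual 1.0e-06)
interior E_z at 3 points: [1.3876 1.3875 1.3874]
analytic interior field:  1.3849 V/m
```

i.e. a uniform interior field within 0.2 % of the exact value at 1280 facets.
The solved charge pattern is the classic cos θ surface charge; its total is
zero to rounding.

The full STD/AMR/REF study protocol (standard solve, adaptive solve, and a
globally 4:1-refined reference, with pairwise L21/RDM or ΔV/ΔV_RDM error
tables) runs from a YAML config:

```sh
bemamr study --config study.yaml --out out/
```

`bemamr phantom` emits nested-sphere mesh bundles (STL/PLY/OFF plus a
manifest with conductivities and electrode labels); `bemamr solve` and
`bemamr amr` run single stages.

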