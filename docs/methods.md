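# Methods

## Model and formulation

The solver treats the head as an ordered set of closed triangulated
boundaries, each separating an inner tissue of conductivity σ_in from an
outer one of σ_out (air, σ = 0, outside the outermost surface). Three
assumptions are made: compartments are homogeneous, linear and isotropic;
wavelengths are long compared to the head (quasi-statics); and secondary
magnetic fields are negligible. Under these assumptions all induced charge
lives on the interfaces, and the surface charge density is the single
unknown. The governing equation is a second-kind Fredholm equation scaled by
the contrast K = (σ_in − σ_out)/(σ_in + σ_out); facets belonging to voltage
electrodes are instead governed by the first-kind constraint that their
single-layer potential equal the enforced voltage.

Charge density is expanded in pulse (facet-constant) bases and the equations
are discretized by the Galerkin method. Pulse bases are insensitive to mesh
conformity, which is what makes the refinement strategy below possible: a
4:1-split facet needs no neighbor repair.

### Operator application

The matrix R is never formed. One application `R c` is computed as

* a far-field pass: monopoles q_m = c_m A_m at facet centroids, summed by the
  acceleration backend (potential and gradient at all centroids). The shipped
  backend is exact chunked direct summation, compiled with numba when
  available; any backend honoring the same contract (targets, sources,
  charges → potential and gradient at stated precision) can be plugged in.
* a sparse near-field correction: for facet pairs whose centroid distance is
  below `multiplier ×` the mean of the two circumradii (default multiplier 3;
  the admissible range in the literature is 2–5), the centroid term is
  replaced by the Galerkin double integral, evaluated with a symmetric
  7-point Gauss rule on a 4^level subdivision of the outer triangle times the
  closed-form (per-edge logarithm plus solid angle) inner integral. Default
  levels: 1 for near pairs, 2 for touching pairs (centroid distance below the
  sum of the circumradii), 3 for the weakly singular electrode self terms.
* row assembly: `(1/2) c_m − K_m ⟨n_m · E⟩` on standard rows (the 1/2 is the
  exact planar self term; K is applied at assembly so the cached geometric
  integrals survive conductivity changes), and the facet-integrated
  single-layer potential on electrode rows.

"Facet radius" is implemented as the circumradius — the largest of the
standard triangle radii, hence the conservative choice for near-pair
discovery, which the literature leaves undefined. Pair discovery uses a k-d
tree on centroids; its contract (tested) is output-set equality with the
brute-force O(N²) filter.

### Deflation of the insulated-outer null mode

When the outermost boundary faces air, its contrast is K = 1 and the
continuous second-kind operator is singular: a uniform charge density on that
surface produces no interior field and is annihilated by its own rows. The
discrete operator is then nearly singular, and discretization noise in that
mode appears as a spurious charge monopole — harmless for interior fields but
ruinous for EEG scalp potentials, which are small and strongly attenuated.
Since every excitation handled by the pure second-kind path (coils, dipole
clusters) is charge-neutral, the physical solution carries zero total charge,
and a rank-one deflation term proportional to the total charge can be added
to the insulated-outer rows without changing the true solution. This removes
the singular mode; it is disabled automatically whenever electrode rows are
present (electrodes break the null mode, and electrode problems may
legitimately hold net charge).

### Field recovery

E and V at observation points are Coulomb sums over the facet charges, with
the centroid (point-charge) term of any facet within one circumradius of the
observation point (configurable) replaced by its exact analytic integral. The
single-layer potential is continuous across the surface, so potential readout
at skin facet centroids — the EEG observation set — is exact and allowed; the
E-field normal component jumps across a charged facet, so field evaluation
rejects points that coincide with a facet centroid.

For the injected current of a TES electrode, the field "just inside" the skin
is evaluated via the jump relation n·E_in = n·(E^p + E^s_other) − c_m/(2ε₀),
where E^s_other excludes the facet's own principal-value contribution (whose
normal component vanishes on a planar facet). This avoids near-singular point
evaluation and is exact for pulse bases.

## Sources

* **TMS**: the coil is a list of elementary current segments; the primary
  field is −∂A/∂t of their vector potential. The drive is a sinusoid of
  amplitude I₀ and frequency f solved at peak slew rate 2πfI₀. The generic
  figure-8 phantom coil replaces any proprietary winding geometry: two
  coplanar counter-wound loops tangent at the centerline, placed along the
  local skin normal with a configurable housing standoff (default 10 mm).
* **TES (voltage)**: electrode facets carry enforced potentials (+1 V center,
  −1 V returns in the five-electrode focal ring montage, circular 5 mm
  patches at 30 mm center-to-center separation); the solution is afterwards
  rescaled linearly so the center electrode injects the target current
  (default 1 mA). A preemptive local refinement (two 4:1 passes of the skin
  within a sphere enclosing the montage, radius 1.2 × (separation + electrode
  radius)) resolves the electrode edges once, after which the skin is
  excluded from adaptive refinement — unsupervised refinement of electrode
  facets would grow the dense preconditioner block 16-fold per pass.
* **TES (current)**: a uniform-flux electrode variant (primary field from the
  injected current density over the interior conductivity) is provided but
  secondary to the voltage variant.
* **EEG**: finite-length current dipoles on the midlayer, oriented along the
  local surface normal, with moment surface density 1 nA·m/mm² (the empirical
  cortical constant) times the represented area; each dipole is expanded into
  ±I point current monopoles at its endpoints and the primary field follows
  from Coulomb's law with the source-compartment conductivity. Right-hand
  sides use centroid quadrature for smooth coil fields and the 7-point rule
  for dipole fields.

## Adaptive refinement

Selection is by total facet charge |Q_m| = |c_m A_m|, the top
`ceil(rate × M_s)` facets per non-excluded surface (rate applies to the
*current* per-surface count; ceiling guarantees progress on small surfaces;
ties break by ascending index for deterministic reruns). Subdivision is
barycentric 4:1; children inherit the parent density verbatim, conserving
total charge exactly. The near-field block is updated incrementally —
corrections between surviving unchanged facets are carried over, every pair
touching a changed facet is rediscovered and recomputed — with a
full-recompute flag kept for oracle parity. Each pass re-solves warm-started;
iteration counts fall as the solution converges. Termination: the ROI
quantity (total E-field compared in the L21 sense, or potential in the
Euclidean sense) changes by less than the threshold (default 1 %) between
passes, or the pass cap (default 30) is reached.

The growth predictors M′ = M(1+3r)^k, l′ = l/2^k and
t ≈ t₀ Σ_{n=0}^{N} (1+3r)ⁿ are exposed as closed forms and verified against
the realized facet trajectories.

## Solver settings

Defaults: backend precision 1e−6 (the direct backend is exact), GMRES
relative residual 1e−5, iteration caps 100 (initial solve) / 50 (warm-started
solves), full non-restarted GMRES within the cap. The electrode block is
assembled exactly as the operator computes it (centroid terms plus stored
corrections), so the preconditioned electrode-only problem converges in one
iteration.

## Phantoms and what they do and do not show

All inputs are generated: nested-sphere head surrogates (default validation
phantom: brain/skull/scalp at radii 8/9/10 cm with conductivities
0.33/0.0042/0.33 S/m), electrode patches and the focal-ring montage, midlayer
observation sets, dipole clusters, and the figure-8 coil. Conductivity
presets for 7- and 14-tissue head models ship verbatim. Generators are
deterministic.

Sphere phantoms exercise every code path against closed-form references —
the two-medium interior field, sphere capacitance, and a multilayer-sphere
dipole potential series (assembled per spherical-harmonic degree from
continuity of V and σ∂V/∂r at each interface plus an insulated outer
boundary; cross-validated against MNE-Python's sphere model). They do not
reproduce what makes real heads hard: sharp curvature, sulci, thin unevenly
spaced layers, or non-closed tissue boundaries. Passing the sphere suites
shows the discretization, solver and refinement bookkeeping are correct and
convergent, not that any particular subject-level accuracy is reached.

## Numerical choices and sizes used

* Internal unit is meters; mm accepted at I/O with an explicit unit field.
* Child vertices are never merged across neighbors; duplicate coordinates are
  permitted (pulse bases need no conforming mesh).
* The EEG three-layer accuracy check runs at ~15k facets with near-pair
  multiplier 5: at that resolution the inter-shell gap (10 mm) sits at 2–3
  mean facet radii, i.e. exactly at the default threshold, and cross-surface
  pairs must be exactly integrated. The area-weighted potential RDM against
  the series is then < 0.05 for radial and tangential dipoles.
* The aggregate field magnitude in the scale-invariant RDM uses the Frobenius
  norm of the stacked N×3 field array (a spectral-norm option is exposed).
* Dense assembly, kept for oracle duty, is limited to ≤ 4000 facets.
* Test problem sizes (320–15k facets) were chosen so the full suite and the
  acceptance script each complete in minutes on one CPU while still sitting
  in the asymptotic regime of every convergence check.

## Known limitations

* The shipped backend is O(N²); beyond ~10⁵ facets an FMM backend should be
  plugged in (the contract is three arrays in, two out).
* Secondary magnetic fields and frequency-dependent permittivity are out of
  scope, as are remeshing, smoothing, curvature-recovering refinement and
  mesh repair.
* Charge-based selection refines where charge is largest, which is not always
  where a given observable's error is largest; on smooth sphere phantoms with
  smooth sources its advantage over global refinement is modest, consistent
  with its purpose of resolving geometrically complex regions.
* p-refinement is deliberately not implemented; the method is h-refinement
  only.
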