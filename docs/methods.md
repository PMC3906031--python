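# Methods

This note documents the models, numerical choices and limitations of
`mdfconn`: what each component computes, which parameters matter, and what
the synthetic morphologies do and do not represent.

## Morphology generator

The generator is a phenomenological stochastic outgrowth model, not a fit
to reconstructed neurons. Its purpose is to produce ensembles with the
qualitative architecture of layer 2/3 pyramidal cells — one axon rooted
downward, one apical dendrite rooted upward, 4–8 basal dendrites rooted
laterally/downward, extensive branching, statistical cylindrical symmetry
about the apical (+z) axis — so that the density-field and connectivity
machinery can be exercised and validated end to end on data whose
generating process is fully known.

At each of `n_steps` fixed time increments (default 180), every growth
cone elongates by a per-arbor-kind step length in a direction drawn from a
von Mises–Fisher distribution centred on its current direction, and
bifurcates with probability `branch_prob · 2^(−order_decay · order)`,
where *order* is the centrifugal order (branch points between the terminal
and the root). Root directions are drawn uniformly within per-kind polar
intervals (axon 160–180°, apical 0–20°, basal 95–150°, measured from +z)
and the first step follows the root direction exactly, so root-orientation
constraints hold by construction. Setting `turning_concentration = 0`
(helper `isotropic_params()`) makes every post-root step direction i.i.d.
uniform on the sphere — the reference condition for validating the
uniform-orientation estimator and the orientation histograms.

Defaults (µm, per step): step length 3.0 / 1.4 / 2.2 and branching
probability 0.012 / 0.006 / 0.010 for axon / basal / apical, turning
concentration 12, branch concentration 4, `order_decay` 1. These were
chosen once for qualitative plausibility at desk scale: they give roughly
1.5–3.5 × 10³ segments per neuron, an axon of ≈1.1 mm, dendrites of
≈3.1 mm total, and arbor extents of 120–300 µm — deliberately smaller than
biological L2/3 pyramidal cells (whose axons alone reach tens of mm), so
that thousand-neuron ensembles are cheap. Consequently absolute K values
are specific to this generator; all validation is internal-consistency
and trend based, not a comparison against published connectivity tables.

Determinism: every public entry point takes a seed; per-neuron seeds are
spawned from the master seed via `numpy.random.SeedSequence`, so a given
(parameters, seed) pair reproduces segment coordinates bitwise.

## Morpho-density fields

The MDF ρ̂(r, z) estimates expected segment length per unit volume around
the soma, per arbor class (axonal vs dendritic = apical + basal).
Estimation follows three steps: superimpose all morphologies (somata at
the origin, apical axis = +z); deposit each segment's **exact**
line–voxel intersection lengths on a cubic grid of edge `h` (incremental
plane-crossing traversal, not midpoint dumping, which removes O(h) bias);
pool all voxels whose centre radius falls in the same Δr = h radial bin at
each height. Somata deposit no mass.

Numerical conventions:

* Grid corners at integer multiples of h, voxel centres at half-integers.
* Radial bin volumes are the summed volumes of member voxels (not analytic
  annuli), which makes mass conservation exact: `total_mass` equals the
  mean per-neuron arbor length to ~1e-15 when nothing is clipped.
  Segments outside the extent are clipped with a warning giving the
  fraction lost; `covering_extent(params)` returns an extent that provably
  contains any morphology the generator can produce.
* `sample_density` interpolates bilinearly between bin centres, clamps
  radii inside the innermost centre, and decays linearly to zero over one
  bin width beyond the outermost centres.
* Default h = 1 µm (configurable). Azimuthal averaging is exact only for
  lattice-preserving (quarter-turn) rotations; under arbitrary common
  rotations the binned field differs at the voxel-discreteness level
  (O(h) per bin, vanishing under bin pooling), while total mass is exactly
  invariant.

## Connectivity estimators

A potential synapse is a **contact site**: a location where an axonal
segment of the pre-synaptic neuron and a dendritic segment of the
post-synaptic neuron pass within the threshold distance s (default 2 µm,
the conventional spine-reach scale; configurable). By cylindrical symmetry
the expected count K depends on the soma displacement only through
(ρ, ζ), and the displacement vector is fixed to (ρ, 0, ζ).

**K_U** (uniform orientations) integrates
(π/4) · 2s · ρ̂_a(x) · ρ̂_d(x − d) over a cubic lattice covering the
support overlap (default step 2 µm; halving the step changes smooth-field
results by <1%). The prefactor is the thickness 2s of the contact slab
times E|sin θ| = π/4 for independent uniform orientations.

**K_O** (actual orientations) replaces each field by a 7-channel
orientation template: each segment's mass is assigned to the nearest of
seven sign-free canonical axes expressed in the local cylindrical frame at
the segment midpoint (the vertical axis; three equatorial axes at azimuths
0/60/120°; three oblique axes at polar 45°, azimuths 0/120/240°). The
integrand weights each channel pair by |sin θ_ij| between the axes rotated
into the global frame at the two evaluation points. Channel-summed
templates equal the plain MDF exactly; on isotropic ensembles the channel
masses match the axes' solid-angle Voronoi weights and K_O reproduces K_U
to ≈1% — which is how the π/4 constant is cross-validated. The default
integration step is 4 µm (the estimator is ~50× more expensive per point).

**K_S** (Gaussian kernel) operates on two *individual* segment
inventories (position, length, orientation per segment). Both clouds are
notionally convolved with an isotropic Gaussian of standard deviation σ
(10–30 µm); the product integral collapses analytically, so
K_S = 2s Σ_ij ℓ_a,i ℓ_d,j |sin θ_ij| g(m_i − m_j − d) with g a trivariate
Gaussian of per-axis std √2·σ. Segment mass is collapsed to midpoints
(σ is much larger than any segment). For a single neuron pair K_S need
not be monotone in σ (smoothing can first bridge separated arbors); the
pooled mean over a neuron pool decreases strictly with σ, which is the
reported trend.

**Direct counter.** `count_potential_synapses` computes exact clamped
closest-point distances between all candidate segment pairs (k-d-tree
pruned) and, by default, counts contact sites: connected components of
qualifying pairs, where two pairs belong to one site if their segments are
identical or share an endpoint in both trees. Site counting is the
quantity the overlap integrals estimate; with s comparable to the segment
discretization one geometric contact spans several adjacent segment
pairs, so the raw pair count (`mode="pairs"`) exceeds the site count by a
geometry-dependent factor (≈7 under the defaults). Distinct sites between
the same neuron pair are *not* merged.

K(ρ, ζ) surfaces are tabulated on a user lattice and interpolated
bilinearly (zero outside the hull) for network generation.

## Networks and efficiency

Somata are placed uniformly in a cylinder (radius R, height H) by
rejection sampling with a hard 20 µm minimum centre distance (soma radius
≈10 µm); requests beyond the densest-sphere-packing bound, or exhausting
the attempt budget, raise a dedicated error. For each ordered pair,
K_ij is read off the surface at (ρ_ij, ζ_ij = z_j − z_i); the edge
indicator is Bernoulli with p = 1 − e^(−K) (probability of ≥1 potential
synapse under a Poisson count) and the weight is w = K/p, extended by its
continuous limit w = 1 at K = 0 so that weights are defined for every
ordered pair. This pair satisfies E[a·w] = K exactly.

Efficiency follows the weighted-graph formulation: path length = sum of
reciprocal edge weights, E(G) = mean of 1/d_ij over ordered pairs
(0 for unreachable), global efficiency E(G)/E(G_ideal) with the ideal
graph having every (positive-weight) edge present, local efficiency the
mean over vertices of the normalized efficiency of the subgraph induced by
the union of in- and out-neighbours (vertices with <2 neighbours
contribute 0), and cost Σ a_ij w_ij / Σ w_ij (complete graph → 1).
Shortest paths use Dijkstra (scipy.sparse.csgraph); an edge with a = 1 and
w = 0 is rejected as invalid. All three measures are exact against
exhaustive path enumeration on small graphs.

## Experiments and problem sizes

The scripted studies run, per replicate, the full grow → estimate →
integrate chain:

* *Sparse-data variability*: 20 replicate ensembles per sample size
  (default ladder 10/40/160, geometric for desk runtime; the arithmetic
  ladder 10–1000 is available by configuration), reporting
  mean/std/min/max of K_U per displacement. The std scales as n^(−1/2).
* *Kernel sweep*: 10 neurons, each neuron's axonal inventory against its
  own dendritic inventory, σ ∈ {10, 20, 30} µm, pooled over
  cylindrically equivalent displacement vectors (equal |ρ|, ζ), which are
  identical by construction since displacements are canonicalized.
* *Network study*: equal-volume cylinders (130, 500), (200, 212),
  (500, 34) µm; the full-scale configuration (n = 2000) realizes
  75,000 neurons/mm³ and triggers a density warning if misconfigured.
  The default n = 200 at the same shapes keeps the study inside desk
  runtime; efficiency values then reflect the scaled density, and only
  bounds and the shape trend (flat disc cheaper than tall pipe, because K
  decays faster in ρ than in ζ) are asserted.

## Limitations

* The generator's parameters are not fitted to experimental
  reconstructions; absolute K values, efficiencies and costs are specific
  to the generator's defaults. Passing tests demonstrate correctness and
  internal consistency of the estimators, not biological accuracy.
* MDFs are marginal densities: they carry no within-neuron spatial
  correlation, and per-morphology joint densities are out of scope.
* Axo-axonic/dendro-dendritic contacts, synapse formation, laminar
  placement and neuron-type mixtures are not modelled.
* The seven canonical axes are one reasonable discretization of
  orientation space; other axis sets would change K_O at the percent
  level.
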