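# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and what the tests do and do not
demonstrate.

## Tissue domains and coordinates

All geometry is parametric: rectangle/box (`planar_*`), disc/cylinder
(`circle_*`), and a hemispherical shell of outer radius R = 1300 µm and
thickness T = 100 µm. 2D variants have zero thickness (positions confined
to the plane) and represent a cornea of thickness T only through the
density normalisation (2D cell volume = area × T), so 2D and 3D densities
are directly comparable.

The limbus coordinate ξ is the axial coordinate (planar), R − r (circle),
or the geodesic arc length R·(π/2 − θ) from the equator (hemisphere, θ the
polar angle). On the hemisphere mid-surface (radius R − T/2) the spatial
gradient of ξ therefore has magnitude R/(R − T/2) ≈ 1.04; the fixed
VEGF field inherits this factor in its spatial gradient.

**Pellet placement.** In planar and circular domains the pellet's near
interface sits at ξ = h + ε, which is where the fixed field reaches c_p.
With the default parameters this places the pellet disc exactly at the
centre of the circular domains (R = h + ε + r_p) and flush with the far
edge of the planar ones (H = h + ε + 2 r_p); moving the pellet to
h = 0.7 mm breaks the circular symmetry. On the hemisphere the pellet is a
true cylinder, centred on the mid-surface at the polar angle whose
top-down projected height above the limbus equals h exactly (as the height
would be measured in an assay image), with its axis along the local
surface normal.

The pellet interior is excluded from the tissue ("resolved") whenever the
dynamic VEGF model is used; the fixed-field model does not resolve the
pellet, which is unreachable within the simulated times anyway (the front
advances at most s·t ≈ 850 µm from the initial vessel in 85 h).

## Growth rules

The per-step order is migrate → anastomose → sprout → anastomose; all
stochastic draws come from one per-realization RNG stream in a fixed
order (migration angles and retries, audit shuffles, sprout uniforms in
node-index order, sprout directions), so runs are bitwise reproducible.

**Lateral inhibition is permanent by default.** A node selected for
sprouting suppresses sprouting within 1/E_L = 20 µm indefinitely — the
reading of "a node that has already been selected" as a lasting Delta-
Notch-like patterning of sprout spacing. This choice is load-bearing: a
short inhibition memory makes the no-anastomosis ensembles grow
near-exponentially and inflates every anastomosis fold-change several
fold. A finite memory window is available (`AngioParams.inhibition_window`,
hours) for sensitivity studies.

**Baseline χ = 0.5, σ = 0.** The study's parameter ranges are
χ ∈ [0, 0.5] and σ ∈ [0, 20]°. The baseline ensembles use the
fully-persistent, strongly chemotactic corner (χ = 0.5, σ = 0); the
feature toggles de-activate chemotaxis by χ = 0 and de-activate
persistence by σ = 20° — in a persistent random walk, *low persistence
means large angular noise*, which is also why reduced persistence moves
the tip-density peak toward the limbus. σ > 0 adds tortuosity and
increases tip collisions, so anastomosis fold-changes grow with σ
(roughly +75% from σ=0 to σ=20° in 2D).

**Containment.** Only the epithelial/endothelial surfaces repel softly;
lateral/limbal boundaries (and the 2D in-plane edges) are hard: an update
that would exit the tissue redraws its persistence angle up to 10 times,
then the tip waits one step. When `|∇c| = 0` the chemotactic term is
defined as zero (continuous extension of the model's 0/0).

**Anastomosis details.** Candidate segments are found with a KD-tree over
segment midpoints (query radius r_ana + L_max/2, guaranteeing no candidate
with point-to-segment distance < r_ana is missed); distances are exact
clamped projections, identical to brute force. Segments incident to the
tip or its parent node are excluded, as is the tip's entire own vessel
(each sprout event starts a lineage that its trail inherits), so a
meandering tip never fuses with its own trail. Tip-to-vessel events relocate the tip
onto the foot point and split the segment there, making the tip the
degree-3 junction; tip-to-tip events merge the tip into the neighbouring
migrating endpoint and de-activate both. If the fusion loop already
exists in the graph (the merge would duplicate a segment) the tip simply
de-activates. The audit repeats until no event fires, so afterwards no
active tip lies within r_ana of a non-excluded segment.

## VEGF transport

Internal units are µm / h / nM (D = 2.52×10⁵ µm² h⁻¹, κ_v = 300 µm h⁻¹,
k_ec = 4×10⁵ nM µm³ h⁻¹ per cell from 4×10⁻¹⁹ mol h⁻¹).

* **κ_p units.** The literature value for the pellet-interface
  permeability is quoted as 1.12×10⁻⁷ in units that are internally
  inconsistent (µm h⁻¹ alongside κ_v in m h⁻¹). Read literally the flux is
  ~10⁻⁷ of the free pellet concentration and no measurable VEGF ever
  enters the tissue; read as m h⁻¹ (κ_p = 0.112 µm h⁻¹) the early-time
  interface concentrations are ~5–25 nM across domains, matching the
  dynamic-model behaviour this assay exhibits. The m h⁻¹ reading is the
  default; either value can be configured. Pellet depletion is dominated
  by decay (λ_p c_f) regardless, so the depletion kinetics are insensitive
  to this choice.
* **Initial loading.** c_p(0) = (m/MW)/Ω_p with m = 300 ng, MW = 45 kDa
  and Ω_p = π r_p² T_p ≈ 5.03×10⁻³ mm³ gives 1.33×10⁶ nM.
* **EC binding sink.** The binding term uses the tip density n literally
  (`n k_ec c/(c+c₅₀)`); an alternative reading that scales with
  endothelial-cell density (ρ E_L) is available off by default
  (`VegfParams.ec_sink_uses_line_density`).
* All vessel segments count toward the perfusion sink (no perfusion
  state is modelled).

**Discretisation.** P1 simplex elements, assembled stiffness + lumped
mass; forward Euler with sub-step = min(0.05 h, 0.9·2/λ̂_max) where λ̂_max
is a Gershgorin bound over diffusion, decay, both sinks (the
Michaelis–Menten sink bounded by its slope at 0) and the Robin row;
nodal concentrations are clipped at 0 after each sub-step. The pellet ODE
is advanced with the same sub-steps, and the interface quadrature uses the
same lumped facet weights as the Robin term, so with all reactions off the
coupled discrete system conserves mass to round-off. Concentrations at
tips/nodes are sampled by linear shape functions (element lookup cached by
KD-tree + barycentric test; points that fall marginally outside the mesh
use nearest-element extrapolation with a one-time warning); gradients are
centred differences with probe offset δ = 5 µm per axis.

**Meshes.** Target edge 30 µm for 2D domains and planar 3D boxes
(structured, with grid planes snapped to the pellet faces so interface
facets are exact); the cylinder extrudes a Delaunay disc triangulation
whose point set contains exact rings on the outer and pellet circles; the
hemisphere triangulates an azimuthal-equidistant projection of the cap
(uniform hexagonal lattice; no pole slivers) and extrudes it radially
through layers snapped to the pellet's radial faces. The hemisphere and
cylinder default to a 60 µm edge: the explicit diffusion step scales as
edge⁻², and at 60 µm an 85 h hemisphere run stays within minutes on one
CPU while the shell volume is still captured to 0.1%. The hemisphere
pellet is carved by removing elements whose centroid lies in the exact
cylinder; because the flat cylinder cuts across curved shell layers the
carved lateral surface is a staircase whose area exceeds the smooth
cylinder's — this only affects the (negligible) leakage quadrature, not
the tissue volume or the sprouting/migration rules, which use exact
analytic geometry.

## Metrics

Densities are deposited on a structured grid (default spacing 40 µm,
distinct from the FE mesh) by exact clipping of segments to half-open
cells, so total length and tip count are conserved at any resolution.
Two Gaussian smoothing passes (SD 1 cell, truncation radius 2 cells) are
applied before profiling; the kernel is renormalised near the array
boundary in the mass-preserving direction (each cell redistributes its
entire content over the in-grid support), so totals are conserved exactly
for arbitrary inputs, at the cost of not leaving a uniform field exactly
unchanged in the outermost few cells. Profiles average (not sum) over
in-tissue cells equidistant from the limbus (bin width = grid spacing);
threshold locations (half-max, 1%-of-max "front distance") interpolate
linearly between bin centres, taking the outermost crossing. The
vascularized fraction uses the raw, unsmoothed occupancy (any positive
line density) over in-tissue cells only. The maximum tip/line density
reported for cross-domain comparisons is the maximum of the smoothed,
equidistant-averaged profile. The initial limbal vessel is included in
the line density.

## Problem sizes and reported comparisons

The ensemble comparisons use the study protocol directly: 85 simulated
hours, five realizations per scenario, c_p = 20 nM for the fixed field.
These run in seconds (2D) to tens of seconds (3D) per realization. The
dynamic-model front-location comparison is verified on a three-domain
subset (hemisphere, planar 2D, circular 2D — the reference geometry plus
the two most common caricatures) with one realization per domain; the
front location is the least seed-sensitive metric (replicate spread ≈
0.5%), and the full seven-domain battery is available through
`micropocket.runner.front_location_comparison` / `reproduce fig5`.

## Known limitations

* No blood flow, vessel regression, EC proliferation, VEGF-dependent
  migration speed, tip–tip chemoattraction or ECM mechanics: migration
  speed is constant, so front velocity is approximately constant by
  construction.
* Forward Euler + lumped mass only; no implicit solver, no adaptivity, no
  curved elements, no re-meshing.
* The sink-term coupling deposits network densities per element
  (sub-segment midpoint sampling at ≤ 5 µm), which makes the PDE solution
  mildly mesh-dependent — inherent to this class of hybrid models.
* The synthetic scenarios emulate the assay's geometry and transport, not
  its biology in detail: passing ensembles show that the implementation
  reproduces the geometric comparisons under the stated rules, not that
  those rules capture real corneal angiogenesis.
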