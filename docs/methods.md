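# Methods

This note documents the models, numerical choices and limitations of the
package, in the order the pipeline runs.

## Relaxation model and fitting

The surface stress after a step dilatation is modelled as
γ(t) = a·exp(−(t/τ₁)^β) + b·exp(−t/τ₂) + c, time zeroed at the post-step
stress extremum. The KWW term carries the step response; the regular
exponential describes interfacial aging, which is present even without
deformation, and decouples it from the relaxation of interest. All
stresses are in mN/m and times in seconds; reduced LJ units are confined
to the simulation modules.

**Extremum location.** The fit starts at the maximum (expansion) or
minimum (compression) of γ within a search window after the step start,
defaulting to 3× the step duration — long enough to catch instrument
overshoot, short enough that the relaxation itself cannot displace the
extremum.

**Optimizer.** KWW fits are multi-modal: β trades off against τ₁ and the
aging background. The fitter therefore runs bounded trust-region nonlinear
least squares (`scipy.optimize.least_squares`) from a multi-start grid of
4 log-spaced τ₁ ∈ [1, window/2] × β ∈ {0.4, 0.6, 0.8, 1.0}; at each start
the linear amplitudes (a, b, c) are seeded by ordinary least squares with
the nonlinear parameters held fixed. Bounds are 0.05 ≤ β ≤ 1 and τ₁ > 0.
Identifiability of the aging term is enforced structurally: the optimizer
works in the ratio r = τ₂/τ₁ with r ≥ 5, so the two exponentials can never
collapse onto each other; τ₂ is initialized at 10× the window (aging is
the slow background). The best restart is chosen by residual sum of
squares, ties broken toward the largest β — preferring the
less-stretched explanation avoids spurious tiny-β minima. Samples are
weighted uniformly (no published weighting scheme exists for these
instruments). Standard errors come from the Jacobian-based covariance at
the optimum, σ²(JᵀJ)⁻¹, computed in the natural six-parameter coordinates;
entries are NaN when a parameter sits at a bound and the covariance is
singular (e.g. β̂ = 1). Non-convergence is flagged in the result, never
silent.

**Asymmetry.** Δβ = β_comp − β_exp and the τ₁ ratio quantify the
expansion/compression asymmetry; a "dynamic heterogeneity" flag is set per
phase when β < 1 by more than its standard error.

## Synthetic tensiometry

The generator emulates a drop-tensiometer protocol: an adsorption phase
b′·exp(−t/τ′) + c (default τ′ = 2000 s, amplitude 8 mN/m — adsorption of
complex stabilizers has much longer tails than the step relaxation, and is
characterized only qualitatively, so these are package choices), a linear
actuator ramp over the 2 s step to the post-step extremum a + b + c, then
the model relaxation with i.i.d. Gaussian noise (the dominant instrument
noise at ~0.1–1 s sampling). Defaults: 1 s sampling; fixture constants
a = 5, b = 1, τ₂ = 2000 s, c = 50 mN/m, chosen once as representative of
protein-stabilized air–water interfaces (published tables report β and τ₁
but not these four constants). Same spec + seed ⇒ bit-identical traces.

What the generator does *not* emulate: drift of the instrument baseline,
correlated (1/f) noise, area-control feedback transients, or non-affine
deformation of the film. Passing the generate→fit→recover loop therefore
demonstrates correctness of the estimator under the model's own
assumptions, not robustness to every instrumental artifact.

## Coarse-grained MD engine

Bead-spring model in reduced units (ε = σ = m = k_B = 1, time unit
σ√(m/ε)). Species: solvent W, oil O, hydrophilic H and hydrophobic T
copolymer beads, all of equal size and mass. Non-bonded pairs interact via
truncated-and-shifted LJ with per-pair cutoffs: 2.5σ keeps the attractive
branch, 2^{1/6}σ gives a purely repulsive (WCA) interaction. For the
symmetric liquid–liquid systems, identical pairs plus H–W and T–O are
attractive and all other pairs repulsive; for liquid–vapor systems W, H
and T–T attract while W–T and H–T are repulsive (the published
supplementary parameter tables are not available, so these matrices are
package defaults, overridable field by field).

Bonded terms: harmonic bonds (default k_b = 1000 ε/σ², l₀ = 1σ — stiff
enough to fix the bond length without constraining the time step), FENE
springs (k = 30 ε/σ², l₀ = 1.5σ), harmonic angles (k_a = 50 ε, θ₀ = π) and
cosine dihedrals k_d(1 + d·cos φ) (k_d = 5 ε, d = 1) applied to triblock
middle blocks to make them rigid. Harmonically bonded (1–2) pairs are
excluded from the non-bonded loop; FENE-bonded pairs are **not** excluded,
because the FENE spring has no repulsive core — retaining the pair
repulsion (the Kremer–Grest convention, which places the bond minimum near
0.97σ) is what keeps chains from collapsing. 1–3 and 1–4 pairs are always
retained. An overstretched FENE bond (l ≥ l₀) aborts the step with a
diagnostic.

**Integration.** Velocity Verlet at dt = 0.006; canonical runs use a
Langevin thermostat with the BAOAB splitting (exact Ornstein–Uhlenbeck
velocity update, damping default 1.0 time units), which has the smallest
configurational time-step bias of the common splittings and is local and
robust for slab+vapor geometries. Kinetic temperature uses dof = 3N (the
thermostat does not conserve momentum). Measured NVE drift for a
500-particle LJ liquid at the ρ = 0.8, T = 0.723 state point is computed
in the test suite; the residual energy noise comes from the force
discontinuity of the truncated potential at the cutoff, and the secular
drift is measured as the difference between first- and last-decile energy
means (the instantaneous energy also carries a reversible O(dt²)
fluctuation).

**Neighbor search.** Linked-cell pair build with a Verlet skin (0.4σ),
rebuilt when accumulated displacement bounds exceed half the skin; boxes
too small for 3 cells per dimension fall back to an O(N²) build internally
(the public `build_cell_list` raises instead, as the contract requires).
Minimum images are taken in fractional coordinates of a possibly
xz-tilted (triclinic) cell, valid for |tilt| ≤ Lx/2 — the tilt is reduced
modulo Lx, a lattice-equivalent transformation.

**Slab construction.** Bulk liquid is thermalized from a jittered cubic
lattice, then the box is extended along z by the protocol factor
(92.96/46.77 ≈ 1.99), leaving a liquid slab with two interfaces; the
liquid–liquid mode fills the whole box with an O layer between two W
layers of exactly equal particle count (the count is rounded down to
even). Copolymer insertion converts *adjacent* solvent particles near an
interface into chain beads (identity swap ⇒ density unchanged): a seeded
nearest-neighbor walk grows each chain along the interface normal from
the W side toward the other phase, so that the H→T species switch lands
where the target species lives; chains alternate between the two
interfaces and placement retries are bounded at 100 per chain.

**Pressure and surface tension.** The virial pressure tensor is
P = (Σ m v⊗v + Σ r⊗f)/V with all pairwise and bonded contributions; the
Kirkwood–Buff surface tension of a slab is
γ = (L_z/n_interfaces)·[P_zz − (P_xx + P_yy)/2].

## NEMD and the friction coefficient

Shear is driven by Lees–Edwards sliding-brick boundaries (the tilt grows
at rate·L_z per time unit; particles crossing the z boundary pick up the
conjugate position and velocity shifts). This is the closest
boundary-driven analogue of shearing the box without introducing wall
physics. During shear the thermostat acts only on the y and z velocity
components, leaving the flow direction unthermostatted, so no profile-
unbiasing is needed. The first 2/3 of the steps (desk presets: 1/2) are
discarded as run-in; afterwards frames are sampled every 50 steps.

The reported shear stress is the mechanical σ_xz = −P_xz, positive for a
positive velocity gradient. Its kinetic part uses lab-frame velocities:
the streaming contribution couples to ⟨v_z⟩ = 0 and therefore adds noise,
not bias. Velocity profiles are computed per frame and averaged over
frames, with frame-to-frame standard errors; empty (vapor) bins are
flagged, never zeroed.

Interfaces are located at the equimolar plane of the solvent profile
(liquid–vapor) or the W/O crossing plane (liquid–liquid). For the
friction estimate, the bulk velocity is fitted linearly over
[interface + 3σ, interface + 10σ] on the bulk side and extrapolated to the
interface plane; the surface velocity is the mean over ± half the film
thickness (FWHM of the copolymer density) around the film's density peak,
capped at ±2.5σ and clipped so the regions never overlap — the film's
velocity is nearly constant in z, which is what makes a single surface
velocity meaningful. ζ_xx = σ_xz/(v_x − v_xˢ) with uncertainty propagated
from the fit covariance, the bin standard errors and the stress standard
error. When the velocity jump is smaller than its own uncertainty the
estimate is reported as *unresolved* (perfect-coupling limit) instead of a
number. The two interfaces have opposite orientation, so the literal
formula yields opposite signs on the two sides; the combined estimate is
the inverse-variance-weighted magnitude.

Desk-scale presets (boxes 10–12σ across, ~1700–2100 particles, 3×10⁴
shear steps at rate 0.1) resolve the jump with relative uncertainties of
order tens of percent; the block-size trend (ζ_xx decreasing with n,
ζ_xx·n roughly constant because the jump scales with film thickness) is
therefore checked at factor level, not as a precision comparison. The
publication-scale protocols (50.56σ boxes, ~10⁵ particles, 5×10⁵ steps)
are shipped as presets but are long-running and not exercised by the test
suite.

## Morphology classification

Copolymer beads are clustered by single-linkage connectivity at 1.5σ (the
first-neighbor shell of the LJ liquid). Clusters are unwrapped across the
periodic boundaries by BFS; meeting an already-visited bead through a
different periodic image marks the cluster as percolating in that
dimension. Per cluster the gyration tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃,
thickness along the film normal and lateral extent are computed; the
dominant cluster decides the class:

- **film_3d** — laterally percolating and thicker than a bead monolayer
  (1.5σ);
- **strand** — one dominant axis (λ₁/λ₂ ≥ 8) and thin along the normal;
- **in_plane_cluster** — two comparable axes with the small one
  (λ₂/λ₃ ≥ 8) along the normal (within 30°);
- **cluster_3d** — everything else.

The continuous score d_e = 1 + Σ min(λᵢ/λ₁/f, 1) over the two smaller
eigenvalues (f = 0.1) maps line → 1, disc → 2, ball → 3; percolating films
are pinned to d_e = 3 because a box-spanning object has no meaningful
finite gyration spectrum. All thresholds are declared configuration with
the defaults above — the discrete classes have no unique physical
definition, and the classifier says so in its output. The d_e score is
guaranteed monotone under flattening for blobs whose lateral eigenvalues
dominate the normal one; a needle oriented along the normal passes through
disc-like shapes while being flattened, which is a property of the
geometry, not of the score.

## I/O and reproducibility

All file formats are plain text: two-column CSV + JSON sidecar for traces,
extended-XYZ and LAMMPS-style dump for snapshots, YAML for run
configuration, JSON for results. HDF5 is deliberately not used — at the
scales this package targets, text trajectories remain inspectable and
diff-able. Every run can write a provenance record (SHA-256 config hash,
seed, package version); all stochastic stages draw from explicitly seeded
generators, so any result regenerates bit-identically from its recorded
configuration.

## Known limitations

- No electrostatics, long-range tail corrections, constant-pressure
  ensembles, or frequency-domain (oscillatory) dilatational moduli.
- The friction analysis covers only the xx component under steady shear.
- Desk-scale NEMD uncertainties are large; quantitative ζ_xx values at the
  publication state points require the long-running presets.
- The pair-interaction matrices and bonded constants for the equilibrium
  systems are package defaults standing in for unavailable published
  tables; morphology outcomes at a given surface concentration depend on
  them quantitatively, though the four structure classes themselves are
  robust.
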