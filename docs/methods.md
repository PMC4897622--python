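# Methods

## Model

A SAS-6 homodimer is a rigid body of five spheres: two N-terminal heads of
radius R_N = 1.979 nm forming a dumbbell, and the first six heptad repeats
of the coiled-coil as a string of three spheres of radius R_CC = 1.182 nm
along the spoke axis (optionally extended by further spheres up to the
~50 nm native coiled-coil; the extension changes diffusion, not
affinities).  Homodimers are the smallest assembly unit because coiled-coil
dimerization (K_D ≈ 1 μM) is ~60-fold stronger than the head–head contact
(K_D ≈ 60 μM) that drives oligomerization.

Each homodimer carries one donor and one acceptor reaction patch in its
heads.  A bond snaps the partners into a unique relative pose encoded by
center-to-center and torsion vectors: adjacent spokes subtend 40°, all hubs
are coplanar, and composing the bound transform nine times is the identity.
Consequently every oligomer of size n is the same rigid arc of the ideal
ring; the open 9-chain and the closed ring share identical geometry and
differ only in bond count.  Patch placement is fully determined by the ring
constraints (18 head beads in contact on a circle of radius
R_N/sin 10° ≈ 11.4 nm, hub diameter ≈ 22.8 nm); flexible binding angles and
8-/10-fold rings are outside the model.  Donor/acceptor polarity forbids
branching and like-with-like bonds, so bond graphs are chains and rings
only.

Two charge sites per homodimer sit on the head surfaces facing the ring
axis (where the cartwheel inner densities abut the heads); they are the
handles for scaffold attraction.

## Brownian dynamics

Clusters move by anisotropic rigid-body Brownian dynamics.  Diffusion
tensors come from a Kirkwood–Riseman bead-model computation: the
translational grand mobility with Rotne–Prager pair blocks (generalized to
unequal radii) is inverted to a friction matrix, contracted onto rigid-body
motion, and given the standard rotational volume correction, so a single
bead recovers the Stokes–Einstein and Stokes–Einstein–Debye limits exactly;
tensors are evaluated at the center of diffusion (where the
translation–rotation coupling is symmetric) and cached per species.
A shell-model refinement of the homodimer agrees with the five-bead tensor
to better than 15% (translation).  Hydrodynamic interactions *between*
clusters are neglected.

One step of length Δt (default 1–2 ns) applies drift μ·F·Δt and a Gaussian
displacement of covariance 2DΔt in the body frame at the center of
diffusion, then updates position and quaternion (renormalized).  The unit
system is nm / ns / k_BT at 293 K with water viscosity 1.0 mPa·s.

## Reactions and calibration

Association is two-step: clusters diffuse until a free donor/acceptor pair
is inside the *encounter window* — anchors within w_d, center-to-center
vectors anti-aligned within α, torsion vectors aligned within β — then the
bond forms with probability 1 − e^(−k_a Δt) and the partners snap to the
bound pose.  Bonds dissociate with probability 1 − e^(−k_d Δt); the
fragments are re-placed by a uniform draw from the window (translation
uniform in the tolerance ball; rotation uniform on SO(3) restricted to the
angular window, conjugated into the patch frame).  Fragments created in a
step do not react again within that step; this makes the per-step cycle
(dissociate → associate → propagate) satisfy detailed balance exactly, and
the stationary bound:unbound odds for one donor–acceptor pair in volume V
are (p_a/p_d)·(v_b/V), with v_b the window's configuration volume, which
factorizes exactly into the tolerance ball times a Monte-Carlo-evaluated
orientational fraction.

Calibration imposes the per-bond two-state equilibrium

    (1 − e^(−k_d Δt)) = (1 − e^(−k_a Δt)) · K_D · N_A · v_b ,

with K_D = 60 μM; the probability form keeps the equilibrium exact at
finite Δt.  k_a is chosen large (k_aΔt ≳ 1) so binding from an encounter is
effectively diffusion-limited.  A homodimer pair binds through two
distinguishable channels (either donor with either acceptor); affinity
measurements account for this multiplicity g = 2.  At the wide default
window the two channel windows overlap slightly, making the additive
two-channel prediction a few percent generous — visible as a ~3–4% shift in
very long calibration runs and well inside the reported confidence
intervals.

The rigid 9-chain holds its free ends permanently in the bound
configuration, so closing the last bond needs no diffusional search; it is
attempted every step at the enhanced rate k_ring = k_a e^(−E/k_BT) with
ring stabilization E ≤ 0.  A ring bond opens at the ordinary k_d, leaving a
single connected 9-chain; two simultaneous openings are needed to fragment
a ring.

**Encounter-window defaults.**  The window is the one convention the
experiments do not pin down directly, and it controls two things: the
calibration volume v_b, and through it the *ring-closure effective
molarity* c_eff = 1/(N_A·v_b) — the concentration the pre-organized chain
ends present to each other, which sets the ring:9-chain equilibrium
[R]/[C9] = c_eff·e^(|E|)/(9·K_D).  The defaults (w_d = 3 nm,
α = β = 75°) give v_b ≈ 16.3 nm³ and c_eff ≈ 0.10 M, a textbook value for
rigid macrocyclization, and place the long-time ring fractions at 5 μM at
~0.9% (E = −9.2 k_BT) and ~19% (E = −13.8 k_BT).  Much tighter windows
imply effective molarities of tens of molar and ring fractions an order of
magnitude larger at the same E, which is inconsistent with the bulk
behavior the model is meant to capture.  Two presets are exposed: set 1
(the defaults above, Δt = 1 ns) for bulk work, and set 2 (3.5 nm/85°,
Δt = 2 ns) with a larger reaction range for the slower scaffold scenarios;
equilibria follow the same calibration either way.

Between reactions clusters are mutually ideal (no excluded volume): this
makes the calibration contract exact and is consistent with the dilute
regimes simulated.  A bond whose snapped configuration would self-overlap
(any merge beyond nine members) or bury beads in a scaffold core or wall is
rejected.  An explicit `resolve_overlaps` relaxation (harmonic push of the
newly formed cluster, others static) is provided for excluded-volume
workflows.

## Scaffolds and reservoir

Scaffolds (cylinder along the periodic z axis, sphere, or semi-sphere
embedded in a planar wall at z = 0) have a soft harmonic core starting at
R_s = 9 nm felt by all bead centers, and an attractive layer of width
ΔR_s = 3 nm exerting a constant radial force l·k_BT/ΔR_s on each charge
site (total layer depth l·k_BT per site; the semi-sphere attracts only
above the wall).  The core stiffness defaults to 2 k_BT/nm², the stability
bound of the explicit Euler update at Δt ≤ 2 ns (mobility·k·Δt < 1);
stiffer cores catapult penetrating clusters and corrupt the near-scaffold
Boltzmann statistics, which we verify directly against a Boltzmann
Monte-Carlo oracle (agreement within a few percent, improving as Δt
decreases).  Net scaffold force and torque scale with cluster size — the
origin of size-dependent retention and hence local cooperativity.

The cylinder scenario is open: monomers are exchanged with an ideal
reservoir at concentration c_r in a 5 nm frame at the lateral box faces,
far from the scaffold.  Each exchange event makes two symmetric μVT
attempts (insertion or deletion with probability ½, acceptance
min(1, N̄/(N+1)) or min(1, N/N̄), N̄ = c_r·V_ex·N_A); the stationary region
count is exactly Poisson(N̄) and the box equilibrates to c_r.  Only free
monomers are exchanged; bonds are never touched.  Sphere and semi-sphere
scenarios run closed (fixed particle number).

## Rate equations

Bulk kinetics uses coagulation–fragmentation ODEs over chains 1–9 plus the
ring (μM, seconds).  Forward kernels are diffusion-limited: either the
Smoluchowski-with-window estimate 4π(D_i+D_j)·w_d·f_rot (frozen-orientation
lower bound, deterministic), or a BD first-passage measurement of the
monomer rate scaled by (D_i+D_j)/(2D_1); rotational averaging makes the
measured rate several-fold larger than the frozen-orientation estimate.
Chain+chain merging carries the two-channel factor for unlike sizes; every
backward rate is k_ij·K_D by detailed balance, so the chain equilibrium is
isodesmic.  Equilibrium observables are identical between the two kernel
routes; only time scales differ.

Because microscopic ring closure is instantaneous on ODE time scales,
the 9-chain and ring are one lumped species partitioned at every instant by
the closure equilibrium ρ = c_eff·e^(|E|)/(9K_D), with only the open part
fragmenting.  A finite closure rate would add an arbitrarily stiff mode
with no physical content (its prefactor cancels from every observable) and
in practice stalls stiff integrators on roundoff of the near-equilibrated
closure flux.  Integration uses LSODA (rtol 1e-9); steady state is declared
when the mass-weighted populations change by less than 1e-8 per decade of
time, and the result matches a kinetics-independent mass-action root-solve
(the equilibrium oracle) to better than 1e-7 relative, with total mass
conserved to ~1e-8.

With K_D = 60 μM and c_eff ≈ 0.1 M this reproduces the bulk picture: at
75 μM a sub-second quasi-steady state with dimers and trimers the leading
oligomers; at 5 μM dominant monomers, ~1% ring mass at E = −9.2 k_BT and
~20% at E = −13.8 k_BT, rings accumulating far more slowly than small
oligomers equilibrate.

## What the generator emulates, and limits

Synthetic initial states are uniform random placements of monomeric
homodimers at a target molar concentration (e.g. 150 in a 368 nm box
≈ 5 μM), overlap-free by rejection.  The scenarios emulate the study
conditions: bulk boxes at 5–75 μM, the cylinder in (scaled versions of)
a 200×200×60 nm box with c_r = 5 μM, and 20–150 homodimers around spheres
and semi-spheres at l = 4.  Desk-scale defaults shrink boxes, particle
numbers and step counts so scenarios finish in minutes; orderings
(occupancy vs l, cooperativity, ring orientation) are insensitive to this
scaling, while absolute capture curves at full scale are not attempted.

Known limitations: no excluded volume between clusters away from reaction
events; no hydrodynamic coupling between clusters; fixed binding angle and
ring size (no 8-/10-fold rings); the absolute time scale of the
diffusion-limited kernel is known only to a small factor
(frozen-orientation vs rotation-averaged); the encounter-window convention
is calibrated, not measured.  None of these affect the equilibrium
statements, which are pinned by K_D and c_eff; they temper quantitative
claims about absolute assembly times on real cartwheels.
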