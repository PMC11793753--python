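# Methods

`nucwrap` simulates a torsionally constrained, stretched DNA molecule that
spontaneously wraps histone cores, and measures how the wrap redistributes
the molecule's linking number. This note records the model, its numerical
choices, the conventions behind every threshold, and what the synthetic
protocols do and do not show about real chromatin.

Units everywhere: pN, nm, s, rad; energies in pN·nm; kBT(298 K) = 4.114 pN·nm.

## The DNA model

The double helix is a discrete twistable worm-like chain: N segments of
equilibrium length l0 = 3.4 nm (10 bp), vertices r_i, and a right-handed
orthonormal material frame {f_i, g_i, e_i} per segment with e_i the unit
tangent. Bending at joint i is β_i = arccos(e_{i−1}·e_i); twist is
θ_i = α_i + γ_i measured through the auxiliary vector p_i = e_{i−1}×e_i
(parallel-transport convention), wrapped to (−π, π]. The energy is

    E = Σ kBT/(2 (l0 α_s)²) (l0 − s_i)²      stretching, α_s = 0.1
      + Σ kBT α_b β_i²                        bending,    α_b = 7.32
      + Σ α_t/(2 l0) θ_i²                     twisting,   α_t = 400 pN·nm²
      + Σ_pairs A q² e^{−κ r}/r               Debye–Hückel screening

with λ = 5 point charges per segment, each carrying q = ρe·l0/λ = 5.447 e
(ρe = 8.01 e/nm), κ = 1.261 nm⁻¹ (150 mM monovalent salt) and an 8 nm
cutoff. Pairs on the same or adjacent segments are excluded — those
interactions are represented by the bonded terms. A constant 15 pN
repulsion acts between non-bonded charge sites closer than 2 nm
(impenetrability of the duplex).

The Debye–Hückel amplitude is carried as one folded constant
A = kBT·lB with lB = 0.714 nm, i.e. calibrated so two unit charges in
water reproduce the standard screened-Coulomb energy. (Numerically this
equals q²/D_e with the rationalized dielectric constant
D_e = 4πε0εw ≈ 8.9×10⁻⁹ F/m, which resolves the apparent unit oddity of
quoting a dielectric "constant" of that magnitude.)

Bare mechanical consequences (used as test oracles): twist equipartition
⟨θ²⟩ = kBT·l0/α_t = 0.0350 rad², stretch fluctuation ⟨(l0−s)²⟩ ≈ (l0 α_s)²
(plus a ~6% radial-Jacobian correction for an isolated bond, included
exactly in the tests), and bending persistence length Lp = 2 α_b l0 =
49.8 nm. The persistence-length check samples a short chain (12 segments) with
the electrostatic term off and fits the tangent correlation at short
lags: screened repulsion adds an electrostatic contribution on top of the
bare Lp (physical, but not what the closed-form oracle describes), and
the large-separation correlation of a long chain relaxes only through
global tumbling — far slower than any desk-scale run — so it would
remember its straight start and fake extra stiffness.

Analytic forces: stretching and bending gradients are standard; the twist
angle's dependence on the vertex positions (through the co-moving frames)
uses the curvature-binormal identity dθ_i = kb_i·(ds_{i−1}/2s_{i−1} +
ds_i/2s_i) with kb = 2 e_{i−1}×e_i/(1 + e_{i−1}·e_i). Twist torques about
the segment axes telescope: T_i = −(α_t/l0)(θ_i − θ_{i+1}). Every analytic
force and torque is verified against numerical gradients of the energy
under the same frame-transport convention to better than 1e−6 relative.

## The histone core

A sphere of radius |a| = 4.5 nm carries 22 adsorption sites equally spaced
in phase along a left-handed helix: axial extent 5.5 nm, two turns, end
diameters 8 nm. Those three printed dimensions are mutually inconsistent
with an on-sphere path, so the sites lie on the slightly larger sphere
√(4² + 2.75²) = 4.854 nm; the Morse minimum 1 nm outside a site is then
already clear of the excluded shell, so adsorption and exclusion never
fight. A geometric consequence worth stating: a full two-turn wrap at
this radius occupies ~60 nm ≈ 180 bp of DNA, more than the ~147 bp of a
real nucleosome — the model trades core-particle fidelity for a clean
two-turn binding path.

DNA–histone adsorption is a Morse well per DNA charge site,

    U(r) = ε[(e^{−α(r−δ)} − 1)² − 1],  α = 1.26 nm⁻¹, δ = 1 nm,

evaluated against that site's **nearest** binding site of the histone
(saturating adsorption), truncated at δ + 6/α. The saturation matters:
with an unrestricted double sum over all site pairs the chain condenses
into an over-adsorbed globule around the core (40+ segments adsorbed,
never resolving), and the adsorption energy density comes out ≈ 2.4ε
kBT/nm; with nearest-site saturation the density is ≈ 1.5ε kBT/nm, which
reproduces the standard correspondence ε = 4, 5, 8 kBT ↔ ≈ 6, 8, 11
kBT/nm for charge sites 0.68 nm apart, and nucleosome-like wrapping
actually occurs. ε defaults to 5 kBT and is the principal experimental
dial (4–8 kBT).

A half-harmonic shell of stiffness k = 8 kBT/nm² keeps DNA sites outside
|a| + r0 = 5.5 nm of the center (r0 = 1 nm the DNA radius); histone pairs
repel below 2|a| = 9 nm with the same stiffness. The core translates with
Stokes friction ζ = 6πη|a| and rotates with ζ_rot = 8πη|a|³ (the cubic
power is required dimensionally for a rotational friction). Orientation
is stored as a full body-frame rotation matrix; the torque component
along the helix axis A advances the spin angle Ψ, the perpendicular
component tips A, and rotational noise is an isotropic rotation vector of
per-axis variance 2(kBT/ζ_rot)dt — equivalent to the axis/spin-split
angular Langevin equations but free of spherical-coordinate poles.

## Integration

A two-stage (predictor–corrector) Brownian dynamics step: a tentative
first-order move with forces F(t) and the thermal noise, then the final
move from the original state with the mean of F(t) and F(t+Δt) and the
*same* noise realisation. Vertex positions use the diagonal diffusion
constant D = kBT/(6πη R_H), segment twist angles use
D_rot = kBT/(4πη R_d² l0), with R_H = 1.3 nm, R_d = 1.2 nm, Δt = 25 ps.
After every positional move the material frames are parallel-transported
onto the new tangents; twist updates then spin each frame about its own
axis. Histones advance through the equivalent overdamped rigid-body
scheme inside the same two stages.

Degenerate-step control: a step whose corrector displacement exceeds l0/2
anywhere (or that collapses a segment) is rejected and retried at half
the step size with fresh noise; rejections are counted in the run record
and are rare (none in millions of steps under standard conditions).

Neighbour lists (electrostics/excluded volume, histone adsorption) carry
a 2.5 nm skin and rebuild on a 0.4·skin displacement trigger, with a
segment-midpoint prefilter on the O(M²) site scan. All kernels are
compiled (numba); one CPU advances a 1000-bp chain with six histones at
roughly 10⁴ steps/s.

Randomness: one compiled-RNG stream per integration chunk, seeded
deterministically from (master seed, chunk counter). Identical
configuration and seed reproduce a trajectory bit for bit.

## Boundary conditions and supercoil injection

The setup emulates a magnetic-tweezers experiment. Vertex 0 and its frame
are clamped; a constant force f pulls the last vertex along +z; the
terminal tangents are restrained toward +z by a stiff harmonic (50 kBT).
Two repulsive planes make the chain's linking number a true invariant: a
surface just below the anchor and a bead plane riding on the held vertex
(a micron-scale bead is effectively an infinite plane at these scales).
Without them, coils loop over the free end and the injected supercoils
leak away within microseconds.

Torsionally clamped end frames are pinned to lab-fixed reference
f-vectors (projected onto the tangent-normal plane each step) rather than
parallel-transported: transporting a clamped frame pumps a geometric
phase as the end tangent wanders and leaks linking number. Supercoils are
injected by rotating the held end's reference about +z at 10⁻⁵
turns/step (one turn per 2.5 µs — slow against twist relaxation across
the chain; the printed experimental rate of a few turns/s is unusable at
Δt = 25 ps), then the rotation is frozen and the chain relaxes.

## Topology bookkeeping

Excess twist: ΔTw = (1/2π) Σ θ_i. Writhe: the discrete Gauss double sum
over non-adjacent segment pairs, each pair evaluated by the exact
solid-angle construction (the standard discrete method; a pure-Python
reference path and the compiled path agree to 1e−9). Open-chain writhe is
used as printed — no artificial closure is added to the reported Wr.

Two subtleties are made explicit by the implementation:

- ΔTw + Wr of the *open* chain is not exactly the conserved invariant of
  the clamped system: it fluctuates by ±0.1–0.3 turns at f = 0.3 pN as
  the coil moves relative to the anchoring verticals. The conserved
  linking number adds the cross-writhe with the two closure rays the
  chain cannot cross — up through the bead plane and up from below the
  surface into the anchor — each computed by the analytic H→∞ limit of
  the four-point solid-angle formula. With it, injection of 3 turns lands
  at 3.00 and drifts < 0.015 turns over 10⁶ steps (and no strand passage
  occurs: the minimum non-bonded approach stays near 3 nm, above the
  2 nm core).
- The unconstrained-DNA quantities ΔTw^un, Wr^un restrict the sums to
  segments not wrapped on a histone. A segment is wrapped when its
  midpoint lies within |a| + r0 + 0.5 nm of a core *and* one of its
  charge sites is Morse-bound (r < δ + 1/α). Joints are attributed to
  their higher-indexed segment so twist is exactly additive over a
  partition. Cross-writhe between wrapped and unconstrained segments
  belongs to neither part; the reported Δ quantities average five
  snapshots to tame the open-chain fluctuation.

## Wrapping states and kinetics

Contact machinery: a binding site is bound when its nearest DNA charge
site lies within δ + 1/α = 1.79 nm; touch radius 2 nm. The instantaneous
label of a designated histone is

    free / touching      < 6 sites bound
    partial              ≥ 6 bound, left-handed, ordered
    mis_wrapped          ≥ 6 bound but wound right-handed or out of order
    complete             ≥ 20 of 22 bound, left-handed, ordered

"Ordered" is operationalized as distance-from-monotone ≤ 1: the number of
bound contacts that must be dropped for the DNA site index to progress
monotonically along the binding path (either traversal direction).
"Left-handed" uses the geometric winding of the adsorbed DNA about the
core axis: the azimuth increment in the body frame, signed by axial
progression, summed over consecutive adsorbed sites (adsorbed = within
the bound radius + 0.5 nm of some binding site). An ideal full wrap
scores ≈ −2 turns; a flat adsorbed blob scores ≈ 0; coil merely
transiting the neighbourhood is excluded by construction.

Completion sustained over 1000 integration steps promotes a trajectory's
label timeline to a first-passage event: τ is the interval from first
touch to sustained completion, censored trajectories are excluded from
MFPT means but always counted — matching the convention that points with
no completed runs report "no data" rather than a biased mean.

**Two notions of "a nucleosome has formed".** The strict label above
requires the contact sequence to follow the site order. Dynamically, full
left-handed adsorption (≥ 20 sites, winding ≤ −1.4 turns) is reached in
microseconds under favourable supercoiling, while annealing of the exact
traversal order requires global unwrap–rewrap rearrangements that do not
occur on microsecond horizons at ε ≥ 5 kBT (their cost is several bound
sites' worth of adsorption energy). The assembly census and the
completion trigger of the wrapping protocols therefore default to the
geometric criterion (`is_assembled`: count + winding), which is the only
notion compatible with microsecond-scale assembly counts; the strict
ordered notion remains available everywhere (`ordered=True`,
`completion="strict"`). The threshold of 1.4 left-handed turns sits
between a half-wrap and the ~1.7 turns of a canonical nucleosome and was
fixed once, as a convention, before the ensemble experiments were read
out.

A caveat the implementation surfaced and which the analysis must respect:
on a torsionally *relaxed or positively supercoiled* chain, microsecond-
scale wrapping is often topologically neutral — DNA covers the sites and
winds locally, but entry/exit arms compensate and ΔLk^un barely moves.
Generating the +1 linking displacement requires torque generation and
slow reorganization. On negatively supercoiled DNA the stored negative
writhe feeds directly into genuinely linked wraps, which is the
microscopic reason assembly prefers negative supercoiling: at equal
adsorption gain, the negative template pays no torsional toll.

## Synthetic protocols and their scope

All inputs are generated programmatically: straight or pre-twisted
chains, relaxed plectonemic states produced by injection, an ideal
wrapped-nucleosome fixture (DNA threaded along the binding helix at the
Morse minimum, 22/22 bound, winding −2.1), and planted two-nucleosome
configurations. The ensemble drivers share one equilibrated injected
chain per condition and vary the histone placement and thermal history
per replicate.

Problem sizes are chosen for a single CPU: 500-bp chains for single-wrap
ensembles (caps of 2.5 µs simulated time per replicate, 5 replicates —
the adsorption plateau forms within ~2 µs and the reported topology
differences are insensitive to longer caps, which was checked at 11 µs),
1000 bp with six histones to a 10 µs horizon for the assembly census, and
10⁶-step conservation audits. These reproduce the topology bookkeeping,
the mechanics, and the negative-supercoiling assembly preference at
reduced scale; they do not reach the millisecond first-passage times of
weakly adsorbing or positively supercoiled conditions, so ensemble mean
first-passage curves across the full (ε, ΔLk, f) grid are outside the
desk-scale envelope (the machinery to compute them is all here and scales
linearly in trajectory count).

What the generator does not emulate: sequence-dependent elasticity,
hydrodynamic coupling beyond the diagonal mobility, histone tails/H1,
partial unwrapping under force, or exchange of histones with solution.
Passing tests demonstrate internal consistency of this coarse-grained
model, not quantitative chromatin energetics.

## Known limitations

- The wrapped arc of a two-turn path at this core geometry is ~180 bp;
  wrapped-set sizes run 15–19 segments rather than the ~14.5 a 147-bp
  nucleosome would give.
- The open-chain ΔTw + Wr reported frame-by-frame is the printed
  observable, with its ±0.1–0.3 turn boundary fluctuation; conservation
  statements use the closed-circuit linking number.
- Strand passage through the 15 pN excluded-volume core is
  thermodynamically possible (~15–20 kBT barrier) though not observed in
  10⁶-step audits; very long runs at high supercoiling densities should
  re-audit.
- The strictly site-ordered "complete" state is kinetically inaccessible
  on desk-scale horizons at ε ≥ 5 kBT; results that depend on it (rather
  than on the geometric assembly notion) require cluster-scale runs.
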