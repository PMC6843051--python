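# Methods

## Model

The chain is reduced to one bead per residue at the Cα position.  Local
geometry is encoded by pseudo-bonds d_i (i, i+1), pseudo-angles θ_i
(i..i+2) and pseudo-dihedrals φ_i (i..i+3); θ and φ together determine the
secondary structure of a Cα-only chain, which is why the force field can be
parameterized on them alone.  The potential is split into bonded terms and
non-bonded Morse pairs; every rest value (d0, θ0, φ0, r0) is read from a
chosen reference structure, making that structure a built-in minimum
(a Go-like structural bias).  Two reference states A and B give two force
fields FF_A and FF_B; transitions are sampled by simulating from one state
under the force field of the other, the rationale being that the two states
are effectively distinct molecules (different ligation states), so each
deserves its own biased field.

Functional forms and constants (kcal/mol, Å, radians):

| term | form | parameters |
|---|---|---|
| bond | holonomic constraint at d0 (or stiff harmonic) | d0 from reference (≈ 3.8 Å) |
| angle | ½ kθ (cosθ − cosθ0)² | kθ = [B·(sin βθ0 / βθ0)² + k0]/sin²θ0; B = 3000, k0 = 10, β = 1.667 rad⁻¹ |
| dihedral | A[1 − cos(φ − φ0)] | A = 25 if \|φ0\| ≤ 80°, else 5 |
| local pair | ε[(e^{−α(r−r0)} − 1)² − 1] | pairs with reference r0 < 8.5 Å; ε = 3.8 e^{−(r0/6.1)⁸} + 0.05, α = 2.2 e^{−(r0/6.1)⁸} + 0.70 |
| non-local pair | same Morse | all other \|i−j\| > 3 pairs; r0 = 9.5, ε = 0.05, α = 0.70 |

The damped-sinc angle law comes from equipartition against reference
fluctuations (k′ = k_B T/⟨δθ²⟩, with a 1/sin²θ0 factor converting to the
harmonic-cosine form); its floor min kᵢ = k0 sits at the sinc zero
θ0 = π/β ≈ 108°, which is what makes helices (≈ 90°) stiff and strands
(> 110°) soft.  The dihedral rule compares |φ0| to the 80° threshold —
helices sit near +50° and the rule is taken symmetric in sign; the
threshold itself is inclusive (80° counts as helical).  Pairs with
|i−j| ≤ 3 are covered by bonded terms and excluded from both pair lists; a
reference distance exactly at the cutoff classifies as non-local (strictly
"less than" is local).

### Numerical choices

- **Angle-stiffness clamp.** kθ diverges as 1/sin²θ0 near collinear
  reference geometry; θ0 is clamped to [5°, 175°] (with a warning) before
  evaluating.
- **Non-local truncation.** The generic well is truncated and shifted to
  zero at 25 Å (the shift is ≈ 2·10⁻⁶ kcal/mol, cosmetic).  The systems in
  scope are single chains of at most a few hundred beads, where evaluating
  the precompiled non-local pair list directly is cheaper and simpler than
  maintaining a neighbour list; all kernels are numba-compiled.
- **Dihedral convention.** Signed dihedrals, right-handed (IUPAC), range
  (−π, π]; a right-handed helix has φ ≈ +50°.  The four-site gradient
  formulas are locked in by a finite-difference property suite (relative
  error ≤ 3·10⁻⁸ over random conformations) plus exact zero-net-torque
  checks.
- **Overlaps.** Non-bonded distances below 0.1 Å raise an error naming the
  pair (the Morse exponential would overflow silently otherwise).

## Dynamics

Canonical-ensemble Langevin dynamics with the BAOAB splitting, chosen for
its configurational accuracy at the standard dt = 0.01 ps.  Bonds are
holonomic by default: SHAKE-style Gauss–Seidel distance resets (tolerance
10⁻⁸ Å, ≤ 500 sweeps) after each drift substep, with velocity corrections
Δr/Δt and a RATTLE-style projection (r_ij·v_ij = 0) after every kick and
Ornstein–Uhlenbeck update.  The multipliers use the current bond direction
rather than the pre-step one — adequate for thermostatted configurational
sampling, which is all the model is used for.  A stiff-harmonic bond mode
(k = 100 kcal mol⁻¹ Å⁻²) is provided; with γ = 0 BAOAB reduces to velocity
Verlet, and this mode is the one with a clean conserved energy (drift
≤ 0.1% over 10⁴ steps at dt = 0.001 ps, scaling as O(dt²)).

Bead masses default to a uniform 110 amu (the mean residue mass), with an
optional per-residue table; equilibrium configurational averages are
mass-independent, so this choice only affects time scales.  Kinetic
temperature uses n_dof = 3N − (N−1) in constraint mode (the thermostat does
not conserve total momentum, so no COM correction).  Units are Å/ps/amu
with energies in kcal/mol (1 amu Å² ps⁻² = 10 J/mol exactly);
k_B = 1.9872041·10⁻³ kcal mol⁻¹ K⁻¹.  Default dumping is every 10 ps
(0.1 ps⁻¹).  A run is bit-reproducible given its seed.

## Transition analysis

σ(r) = ½(RMSD_A − RMSD_B)/RMSD_AB + ½, each RMSD after an independent
Kabsch superposition (SVD with determinant correction; proper rotations
only) onto its reference, so σ is a pure shape coordinate with the exact
endpoint identities σ(A) = 0, σ(B) = 1.  σ is not clipped: conformations
farther from one state than the other reference is can fall slightly
outside [0, 1].  Because σ projects the (RMSD_A, RMSD_B) plane onto the
A–B line, the scatter of the two RMSDs is kept alongside it.  Energy
profiles are raw per-bin means of the potential energy over regular σ
intervals (default 20 bins, matching the default 20 path representatives;
last bin right-closed; sample standard deviations; empty bins flagged, not
interpolated) — these are *not* free-energy profiles.  The two biased
fields have incomparable absolute energy scales; `align_energy_scales`
makes the usual fix explicit: shift one profile so the bin means agree at a
σ* where the two trajectory ensembles pass through similar structures
(σ* ≈ 0.4 in practice).

## Principal-path clustering

Frames are Kabsch-aligned onto endpoint A and flattened to 3N vectors (the
same roto-translation removal σ uses; the clustering metric is therefore
plain Euclidean in that space).  The cost is the k-means within-cluster sum
of squares plus s·Σ‖W_{j+1} − W_j‖² over consecutive representatives, with
W_0 and W_{K−1} pinned to the A and B conformations.  Alternating
minimization (nearest-representative assignment; exact tridiagonal solve
for the interior representatives) decreases the cost monotonically by
construction.  Interior representatives are initialized on the linear
interpolation A → B, making fits deterministic.  Empty clusters keep their
representative tethered by the spring term (at s = 0 it simply stays put,
with a warning).

The regularization weight is selected by maximizing a Laplace approximation
of the marginal likelihood of the posterior ∝ exp(−cost), read as Gaussian
likelihood × Gaussian-process spring prior.  The prior enters *normalized*:
its partition function scales as s^{−(K−2)D/2}, which penalizes s → 0;
without that factor the evidence is monotone in s and the selection would
always return the smallest candidate.  Both log-determinants reduce to
(K−2)-size scalar tridiagonals (posterior: diagonal 2(n_j + 2s),
off-diagonal −2s; prior: 2s·tridiag(−1, 2, −1), determinant (2s)^{K−2}(K−1)),
so selection over the default grid — 10 log-spaced values spanning
[10⁻³, 10³] × the mean squared frame-to-frame displacement — is cheap.  On
noisy-polyline data the selected s is finite and interior to the grid.

## Synthetic fixtures

`toybuilder` provides the test systems.  The helix (rise 1.5 Å, radius
2.3 Å, 100°/residue) lands in the stiff regime (θ ≈ 90.4°, φ ≈ +50.0°,
(i, i+4) contacts at 6.2 Å); the planar zig-zag strand (rise 3.5 Å, ±25°
bond tilt) in the soft one (θ = 130°, φ = 180°, no contacts).  The
two-state hinge toy is built from internal coordinates (NeRF chain
construction): two helical arms joined by a four-residue loop (θ0 = 100°,
φ0 = −150°, soft strand amplitudes, so the transition is loop-mediated),
with one central loop dihedral switchable between χ_A and χ_B.  The two
states therefore share every internal coordinate except that dihedral —
state B is state A with one arm rigidly rotated about the hinge bond.  The
loop geometry is chosen so the default χ_A = 30° folds the arms into mutual
contact (34 inter-arm local pairs, min distance 4.6 Å — a contact-stabilized
closed state) while χ_B = 120° swings them fully apart (min distance
12.8 Å, no contacts).  At 130 K the closed basin is rigid (σ excursions
< 0.05 over 1 ns) while the open state, having no inter-arm contacts,
breathes broadly on the σ scale (σ ≈ 0.55–1.0) — so "transition completed"
is judged by σ exceeding 0.8 during a run, not by the final frame.

What the toys do *not* emulate: real contact-map heterogeneity and
sequence-dependent interactions (the non-local term is deliberately
amino-acid independent), competing misfolded intermediates, solvent or ion
effects.  Passing the toy transition demo shows the machinery (bias,
thermostat, σ, clustering) works end-to-end; it says nothing about the
kinetics or intermediates of any real protein.

## Problem sizes used in the checks

The shipped checks run at desk scale: 10–40-bead chains, 1 ns thermostat
and basin runs, 10 ns × 5 seeds for the transition demo, 200 ps for the
equipartition recovery, 300–500-point clouds for clustering.  These sizes
give comfortable statistical margins for the stated tolerances (e.g. the
3-standard-error window on a 90-frame temperature mean) while keeping the
whole suite in the minutes range.

## Known limitations

- Single chains only: no multi-chain topologies, no explicit ligands or
  ions (binding is represented implicitly by the choice of reference).
- The bond-angle clamp makes near-collinear reference geometry artificially
  soft rather than refusing it.
- SHAKE with current-direction multipliers is not symplectic; microcanonical
  studies should use the harmonic bond mode.
- The Laplace evidence assumes the quadratic expansion at the fitted path is
  adequate; for strongly multimodal assignment landscapes the selected s is
  a heuristic (only its order of magnitude matters in practice).
- Energy profiles are potential-energy averages, not potentials of mean
  force; no committor or kinetic analysis is provided.
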