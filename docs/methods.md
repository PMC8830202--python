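# Methods

## The model

`ring_atg` simulates a melt of `M` nonconcatenated, unknotted, semiflexible
ring polymers confined in a repulsive sphere, with one contiguous "hot"
segment per ring. It is the standard Kremer–Grest bead–spring model in
reduced Lennard-Jones units (lengths in the bead diameter σ, energies in ε,
masses m = 1, times in τ = σ√(m/ε), k_B = 1):

- **Excluded volume.** All bead pairs (bonded ones included) interact by the
  purely repulsive, cut-and-shifted Lennard-Jones (WCA) potential
  U(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + ε for r < 2^{1/6}σ, zero beyond.
- **Bonds.** FENE springs U(r) = −½K r_max² ln(1 − (r/r_max)²) with
  K = 30 ε/σ² and r_max = 1.5 σ. Together with the WCA repulsion the
  combined bond potential has its minimum at r* ≈ 0.961 σ and makes chains
  effectively uncrossable, so ring topology is conserved.
- **Bending.** U(θ) = k_θ(1 + cos θ) with k_θ = 1.5 ε, θ the bond angle at
  the middle bead (straight trimer: θ = π, zero energy). At the working
  density this stiffness corresponds to an entanglement length N_e ≈ 28.
  The constant offset is chosen so straight chains carry zero energy; any
  other offset would shift all energies by a constant and leave every force
  unchanged.
- **Confinement.** A smooth, structureless sphere of radius R applying the
  same WCA barrier to the distance d = R − |r| between a bead center and
  the sphere. R follows from the total monomer density ρ = 0.85 σ⁻³ via
  R³ = 3MN/(4πρ); e.g. R = 13.72 σ for M = 46, N = 200.
- **Activity.** A contiguous block of N_h = N/8 monomers per ring couples
  to a Langevin bath at T_h = 3 ε; the rest stays at T_c = 1 ε. The labels
  are attached to material monomers, so "tank-treading" means monomers (and
  the hot block with them) advancing along the ring's spatial contour.

## Integration

Velocity Verlet with per-monomer Langevin friction and noise in the LAMMPS
convention: at each force evaluation the total force is
F_cons(x) − mγv + ξ, with γ = 2/3 τ⁻¹ interpreted as a friction *rate* and
ξ Gaussian noise of per-component variance 2mγk_BT_i/Δt at the monomer's
own bath temperature (fluctuation–dissipation per monomer). The time step
is Δt = 0.005 τ. Noise streams derive from a single seeded generator in
fixed-size chunks, so a run is bit-reproducible given (parameters, seed,
output schedule).

With γ = 0 the integrator is plain velocity Verlet; its energy error is a
bounded oscillation whose envelope shrinks as Δt². For this stiff force
field the envelope is ≈2×10⁻² ε/monomer at Δt = 0.005 τ and the secular
drift ≈2×10⁻⁴ ε/monomer per 10⁴ steps (≈3×10⁻⁵ at Δt = 0.002 τ); the test
suite asserts boundedness and the Δt² scaling rather than a fixed constant.

Pair forces use a linked-cell neighbor list with a 0.3 σ Verlet skin,
rebuilt when any displacement exceeds half the skin. Angular-momentum
zeroing (for equilibrium reference runs) removes the rigid-body rotation
about the sphere center computed from the total angular momentum and the
inertia tensor; it is **off** by default because the active steady state
develops physical coherent rotations. Strictly, removing ω×r changes the
total linear momentum by −m_tot ω×r_cm, which vanishes only when the
center of mass sits at the sphere center; for confined melts r_cm ≈ 0 and
the change is negligible.

## Initialization

Production studies of this model traditionally inherit equilibrated
configurations from long precursor runs; this package instead builds its
own starting states so that everything is reproducible from a seed:

1. **Placement.** Each ring starts as a circle of radius a ≤ 1 σ (shrunk
   adaptively until the placement fits) with centers placed by random
   sequential addition, pairwise separated by more than 2a + 1.2 σ. Two
   circles separated by more than twice their radius cannot be linked, and
   the extra 1.2 σ puts them outside WCA range of each other.
2. **Push-off.** Bead overlaps within a ring are removed by ramping a
   capped soft pair potential A(1 + cos(πr/r_c)) from 0 to 150 ε, while
   beads of *different* rings keep the full WCA repulsion throughout — so
   rings can never cross one another and nonconcatenation is preserved by
   construction. During the ramp, bonds are temporarily harmonic
   (K = 300 ε/σ², r₀ = 0.9 σ, unbreakable), the step is Δt/5 and friction
   is raised to 5 τ⁻¹, making the inflation quasi-static. The net
   soft-pair force per bead is capped (100 ε/σ) so local pile-ups cannot
   snap the chain.
3. **Hand-over and burn-in.** Overlaps are then relaxed under full WCA
   with bonds still harmonic until every bond is below 1.2 σ, after which
   bonds switch to FENE and a passive Langevin burn-in at T_c runs for
   2×10⁴ steps (desk default; long-run presets use more).
4. **Verification.** All pairwise Gauss linking numbers are computed and
   must vanish; otherwise the initialization retries with a fresh
   placement (bounded retries).

This equilibrates local structure (bond lengths, density profile) but not
ring-scale conformations; observables that depend on the global equilibrium
ring statistics (e.g. the precise P(s) exponent of the passive melt) are
not converged at desk scale, and the desk benchmarks therefore assert
directions of change under activity rather than absolute passive values.

The bond-length distribution peaks at the combined FENE+WCA minimizer r*
in the dilute limit (measured mode 0.967 σ vs r* = 0.961 σ); in the dense
confined melt the peak shifts down to ≈0.936 σ under melt pressure. Very
small rings in very small spheres (N ≲ 20 at ρ = 0.85) are a jammed,
marginally stable regime the initializer refuses with a descriptive error.

## Observables

- **Shape.** Gyration tensor G = (1/N)Σ(r−r̄)(r−r̄)ᵀ, eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃, R_g² = tr G; spanning distance R_ee² as the mean over i of
  |r_i − r_{i+N/2}|². Table-style summaries time-average per ring first,
  then average over rings, with standard errors from ring-to-ring scatter.
- **Contact probability.** P(s) is the fraction of (frame, ring, start)
  triples with |r_i − r_{i+s}| < 2^{1/6}σ, s ≤ N/2 (the profile is s ↔ N−s
  symmetric on rings). The hot (cold) variant requires *both* endpoints
  hot (cold), so the hot curve extends to s = N_h − 1. Power-law exponents
  come from a least-squares fit of log y vs log s in a caller-chosen
  window.
- **Threading.** The minimal disk-like surface on a ring contour starts as
  a centroid fan, is refined by 1→4 subdivision (boundary midpoints stay on
  the polygonal contour) and relaxed by backtracking gradient descent on
  the total triangle area with the boundary fixed — monotone area decrease
  by construction, stopping at a relative change below 10⁻⁵ per sweep. A
  planar circle's area is reproduced within the polygon discretization
  (<1% at 64 boundary points). Crossings of another ring's bonds are
  counted by strict-interior Möller–Trumbore segment–triangle tests; any
  hit within ~10⁻¹¹ of a face/edge boundary triggers a deterministic,
  seeded 10⁻⁹ σ jitter of the probing contour and a recount, so counts are
  reproducible. Rings i and j are threading partners when either pierces
  the other's surface at least once; n_tn counts distinct partners.
  Concatenation is monitored independently via the exact discrete Gauss
  linking number (signed solid angles of all segment pairs). A closed
  curve unlinked from the boundary crosses any spanning disk an even
  number of times — threading without linking therefore always shows an
  even crossing count, which the fixtures reflect.
- **Demixing.** x(t) is the like-type fraction among each monomer's
  *interchain* neighbors within r_c = 2^{1/6}σ, averaged over monomers
  with at least one such neighbor; Φ(t) = x(t)/x(0) − 1 with x(0) averaged
  over a short window (default 10 frames) at the activity onset. Choosing
  interchain neighbors as the denominator makes x a pure mixing measure,
  independent of local density; the all-neighbor variant is available as an
  option. A well-mixed system with hot fraction p gives x = p² + (1−p)².
- **Tank-treading.** Two diagnostics: the squared distance between the
  hot-segment midpoint monomer and its contour antipode (fixed at onset) —
  constant under rigid motion, modulated by tank-treading — and a direct
  contour offset: the cyclic label shift k minimizing
  Σ_i |r_i(t) − r_{i+k}(t₀)|², which reads the number of positions the
  material has advanced along the contour.
- **Dynamics.** g₃ is the MSD of ring centers of mass measured relative to
  the instantaneous global center of mass (uniform translations drop out
  exactly), averaged over rings and all start times in the steady window;
  g₃,rel replaces positions by scalar COM–COM pair distances and is
  therefore exactly invariant under global rotations. The TACF follows the
  unit vector joining monomers N/2 apart (averaged over start monomers,
  rings, start times); τ_uu integrates it by trapezoid to the first
  sustained zero crossing (3 consecutive non-positive lags) plus an
  exponential-tail extrapolation fitted to the last decaying stretch; if
  the TACF never decays below 1/e within the window, τ_uu is flagged a
  lower bound. Scalar autocorrelations (R_g²(t), d_ee²(t)) are
  mean-subtracted, ring-averaged and normalized to one at zero lag.
- **Coherent motion.** C_s(r; Δt) = ⟨Δr_i·Δr_j⟩ over pairs binned by their
  initial separation (bin width 0.6 σ, first bin [0.6, 1.2] σ), averaged
  over start frames; reported profiles are normalized by the first bin
  (centered at 0.9 σ), so any overall prefactor cancels. L_corr integrates
  the normalized profile from the first bin center to the first sustained
  zero crossing (3 consecutive non-positive bins), capped at 2R; a profile
  non-positive past the first bin returns the bin width as a floor. Pair
  loops may subsample monomers uniformly (unbiased for a pair average).

## Synthetic fixtures

Every observable is testable without MD through seeded, pure generators:
circles (exact chord/area/gyration laws), canonical two-ring geometries
(Hopf link (Lk, crossings) = (1, 1); separated (0, 0); hairpin pins that
thread without linking (0, 2); the (2,4) torus link with |Lk| = 2), rigid
rotation/translation trajectories (exact invariances), Brownian-bridge
Gaussian rings (⟨d²(s)⟩ = b²s(N−s)/N and the matching chi-square contact
law), and uniform two-species mixtures in a sphere (binomial mixing
baseline). The Gaussian rings and random mixtures emulate only the
*statistics* the estimators need — closure, isotropy, uniform filling —
not melt correlations, so passing those oracles validates the estimators,
not the simulator's physics; the desk-scale MD benchmark covers the latter
qualitatively.

## Desk-scale benchmark and problem sizes

The cluster-scale steady states (M = 46, N up to 1600, 10⁷ τ) are encoded
as presets only (`ring_atg.presets.LONG_RUN_SYSTEMS`). The package's own
benchmark (`run_desk_atg`) uses M = 10 rings of N = 100 with N_h = 12,
5×10⁵ steps (2.5×10³ τ) of which the first 10⁵ are passive, frames every
2×10³ steps. At this size the activity response is unambiguous within
minutes on one core: mean R_g² rises by ~15–20%, the mean number of
threaded neighbors grows from ≈0 to ≳1, Φ(t) rises to a clearly positive
plateau, and Φ's half-rise precedes R_g²'s — the demixing-precedes-arrest
ordering. Magnitudes at this size are not comparable to the large systems
(the sphere holds only ten short rings), which is why the benchmark and
its tests assert directions and orderings, not values.

## Numerical choices and edge cases

- Bond angles clamp cos θ to [−1, 1] against round-off; degenerate
  (zero-length) bonds raise rather than NaN.
- A FENE bond at r ≥ r_max or a bead at |r| ≥ R aborts the run with a
  diagnostic ("bond broken" / "monomer escaped") instead of propagating
  NaNs.
- Exact degeneracies in segment–triangle intersection are resolved by
  seeded ε-jitter (10⁻⁹ σ), never left undefined.
- The discrete Gauss linking integral reports its rounding residual and
  warns above 0.1.
- Trajectory files store absolute positions (no wrapping — the system is
  confined, not periodic); readers re-sort atoms by id, validate counts,
  monotonic times and ring structure, and name the offending line in
  errors.

## Known limitations

- Desk-scale passive states are locally, not globally, equilibrated; the
  crumpled-globule statistics of large equilibrium ring melts are out of
  reach at these sizes.
- The initializer guarantees nonconcatenation but does not *prove*
  unknottedness of individual rings; self-knotting during the quasi-static
  inflation of a small circle is geometrically implausible but not
  excluded by an invariant check.
- Single-core, desk-scale throughput (~4×10³ steps/s at 10³ beads): the
  multi-million-τ horizons of the large systems are configuration presets,
  not tested paths.
- No hydrodynamic interactions (free-draining Langevin dynamics).
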