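# Methods

## Scope and intent

`ionatmos` implements the mean-field and particle-counting layer of
ion-atmosphere analysis: cylindrical Poisson–Boltzmann (PB) theory, the
ion-counting excess formalism, helicoidal density maps, and inner-sphere
binding-pattern statistics.  It does not run molecular dynamics; instead a
seeded synthetic generator produces particle configurations with known
ground truth, so the estimators can be validated end to end.  Quantities
that in the literature derive from long MD trajectories (ion-specific Γ
values, empirical pattern probabilities of real helices) are therefore
*inputs* or *demonstrations* here, not predictions.

## Units and constants

Lengths nm, concentrations mol/L, energies k_BT, charges in e.  The reduced
potential is φ = eψ/k_BT.  Conversion mol/L → nm⁻³ is N_A·V_f with
V_f = 10⁻²⁴ L/nm³ (so 1 M = 0.602 nm⁻³).  Default Bjerrum length
l_B = 0.714 nm (water at 300 K); `debye_length` scales it as 300/T when
given a temperature, and every solver entry point accepts an explicit
`bjerrum_nm`.

## The PB solver (`ionatmos.pb`)

Geometry is an infinite cylinder of radius R with constant surface charge
density σ; the mobile ions live on the annulus [R, R_max].

* **Equation.** (1/r)(r φ′)′ = −4π l_B Σ q_i n_i exp(−q_i φ − V_i(r)), with
  n_i the bulk number density.  The extended variant includes tabulated PMFs
  V_i(r); the standard variant is the same code path with V ≡ 0, so the
  zero-PMF reduction is bitwise.
* **Boundary conditions.** Neumann φ′(R) = −4π l_B σ at the surface
  (Gauss's law) and Dirichlet φ(R_max) = 0.  R_max defaults to R + 10 Debye
  lengths: the residual field there is O(e⁻¹⁰), making the closure error
  from the truncation negligible against the 1% acceptance band.  A
  cell-model (Neumann outer) closure is deliberately not used — the profiles
  are meant to reach bulk.
* **Discretization.** Uniform grid in x = ln r (default 2000 points), where
  the radial operator becomes e^(−2x) d²φ/dx²; second-order ghost-point
  treatment of the Neumann row.  The logarithmic grid concentrates points
  near the highly charged surface where c_+ varies by e-folds per 0.1 nm.
* **Iteration.** Damped Newton with the analytic tridiagonal Jacobian and a
  halving line search; a five-step surface-charge continuation ramp is the
  fallback (not needed for any of the studied parameter sets, where the
  Debye–Hückel initial guess converges in < 15 iterations).  The residual
  is ‖F‖∞ scaled by the source magnitude; default tolerance 1e-10.
* **Consistent cylinder length.** The length h enters only through Γ.  When
  not given it is set to q_NA/(2πR|σ|) with q_NA = 64, which makes the
  printed triples (R, σ, q_NA) mutually consistent: h = 11.44 nm for the
  B-form cylinder and 9.45 nm for the A-form one.
* **PMF handling.** Tables are linearly interpolated, held at their first
  value below the tabulated range, clamped to zero beyond it, and rejected
  if they fail to decay (|V(R_max)| ≥ 10⁻³ k_BT) or do not overlap the
  grid.  PMFs are treated as opaque user-supplied tables; no functional
  form is assumed.

Verification: the solver is checked against an independent closed-form
oracle — the linearized (modified-Bessel K₀/I₀) annulus solution — at weak
charging (σ = −0.001 e/nm², agreement to < 0.5% everywhere), and against
the electroneutrality sum rule Σ q_i Γ_i = 2πRh|σ| for monovalent and
divalent electrolytes (met to ~10⁻⁴ relative at the default grid).

## Ion excess (`ionatmos.profiles`)

Γ_i(r) = N_A V_f h ∫₀^r (c_i − c_i∞) 2π r′ dr′, evaluated by trapezoid on
bin centers (particle profiles) or on the PB grid.

* For PB solutions the integral runs over the annulus only: the hard core
  r < R carries no ions *and no depletion term*, so an uncharged cylinder
  has Γ ≡ 0.  Particle-derived profiles naturally include the (empty) core;
  the charge-weighted sum Σ q_i Γ_i is identical either way because bulk
  electroneutrality cancels the core contribution across species.
* c_i∞ is the mean over the outermost 20% of the radial range
  (configurable).  A plateau test flags profiles whose bulk trend is both
  larger than 1% of the mean over the window *and* statistically
  significant (> 2 standard errors of the fitted slope) — the second clause
  keeps shot noise on genuinely flat profiles from flagging.
* h in Γ is the axial extent actually analyzed (after end trimming), not
  the full helix; both conventions are reachable by choosing the window.
* Binning is half-open [r_k, r_{k+1}); an ion exactly on an edge belongs to
  the upper bin.  Default bin width 0.05 nm; 36 angular bins for the 2-D
  maps.  Note that with binary floating point only exactly representable
  edges (multiples of 0.25, 0.5, …) are literal edge cases; this matters
  for determinism tests, not for physics.
* Γ* = |q_i||Γ_i|/q_NA is reported positive for both the attracted-cation
  and excluded-anion roles.

The untwisted helicoidal map rotates each ion's cylindrical angle by minus
the accumulated twist (twist_per_bp · z / rise_per_bp) before binning,
collapsing the helical symmetry so groove features align; integrating the
map over angle reproduces the 1-D profile exactly (same counts, same
shells).

## Idealized duplexes (`ionatmos.helix`)

The site model carries only cation-binding-site atoms — phosphate oxygens
O1P/O2P, sugar oxygens O3′/O4′/O5′ (plus O2′ for RNA), and base acceptors
N7 (purines), O6 (G), O2 (C), O4 (T/U) — wound on per-atom-type cylindrical
shells (radius, phase, axial offset) with fixed rise and twist.  Defaults:
B-form 0.34 nm / 36.0°, A-form 0.28 nm / 32.7° (canonical fiber values);
phosphate oxygens sit near the PB cylinder radius (1.0 nm B, 1.3 nm A) and
base acceptors near the axis.  The 5′-terminal residue of each strand has
no phosphate, giving the charge identity q_NA = 2(n_bp − 1).  Strand-1
sequences are read 5′→3′; the complementary strand is generated by
Watson–Crick pairing and runs antiparallel.

This is an explicit geometric stand-in: no sugar puckers, no
sequence-dependent helical parameters, no groove relaxation.  All analysis
operations accept any `SiteModel`, including one parsed from a real PDB
(`site_model_from_pdb`), so the idealization is a default, not a
constraint.  The shell parameter set (`GrooveGeometry`) is overridable from
config files.

## Binding patterns (`ionatmos.patterns`)

Contacts are closed-interval d ≤ d†, restricted to O/N site atoms of
residues retained after trimming (default 3 bp per end, matching the usual
end-fraying exclusion).  Default cutoffs (nm): Li⁺ 0.28, Na⁺ 0.32, K⁺ 0.36,
Cs⁺ 0.42, Ca²⁺ 0.32, Sr²⁺ 0.35, Ba²⁺ 0.38 — first-minimum-of-g(r)
defaults, fully overridable, with optional per-atom-name refinement (O vs N
granularity).  Detection uses a KD-tree over site atoms and is
property-tested for bitwise equality against an all-pairs brute-force
oracle.

p_x = events(x)/(N_m·N_frames), per pattern *class* (multiset of atom
names); raw events keep full site identities for strand-bridging
classification (none / intrastrand / interstrand-bridge).  The denominator
counts every cation in the box, following the literal normalization
convention; a shell filter can be applied upstream by the caller by
restricting the frames.  Patterns with more than five atoms are retained
and flagged rather than truncated — the five-atom ceiling is an empirical
observation, not a rule.

## Synthetic generator (`ionatmos.synth`)

The generator emulates an equilibrated mean-field atmosphere:

* **Diffuse ions** are drawn from a radial law c(r) (uniform, annular,
  tabulated, or a PB solution's c_i(r)) via inverse-CDF sampling of
  p(r) ∝ c(r)·r, uniform in angle and z, inside a cylindrical domain.  The
  CDF grid includes the law's own breakpoints, so hard-core steps are
  sampled exactly.  Counts are either fixed (rounded Poisson mean, or an
  explicit N_m; multinomial over shells) or per-frame Poisson (ragged
  frames, which the pattern machinery rejects since it needs every cation
  in every frame).
* **Planted events** relocate a cation, per (cation, frame) with the target
  probability, to distance d† − 0.05 nm from each atom of a concrete
  realization of the pattern class (least-squares placement for multi-atom
  classes; the 0.05 nm margin keeps the contact safely inside the closed
  cutoff under coordinate round-off).  Residues with the fewest extra base
  atoms are preferred as anchors so the realized contact set is exactly the
  requested class (an N7 plant lands on adenine, not guanine).
  Geometrically infeasible classes (atoms farther apart than 2(d† − 0.05))
  raise in strict mode.  Every event is logged as ground truth.
* **Determinism.** One `default_rng(seed)` stream, fixed draw order; the
  planting stage uses a child seed derived via `SeedSequence([seed, 1])` so
  adding plants does not perturb the diffuse sample.

What the generator does *not* emulate — ion–ion correlations, excluded
volume, water structure, sequence-specific binding free energies, helix
breathing — bounds what passing tests show: they validate the estimators
(binning, integration, counting, normalization) and the PB solver, not the
fidelity of mean-field theory to real trajectories.

## Problem sizes and defaults used in validation

The shipped validation suite solves PB on 2000-point grids (t1/t2 closures
converge to ~10⁻⁴ relative), samples 5000 frames (~520 ions/frame) for the
particle round trip (Γ₊ − Γ₋ recovered within 3 block-averaged Monte-Carlo
standard errors of 64), and plants pattern frequencies 0.20/0.05/0.02 on
4 cations × 5000 frames (recovery within 3 binomial standard errors).
These sizes were chosen so each Monte-Carlo check has enough statistics for
a 3-standard-error criterion to be meaningful while the whole suite stays
interactive (~10 s).

## Known limitations

* Mean-field PB: no ion-size (Stern) corrections beyond the PMF term, no
  dielectric discontinuity, 1-D radial symmetry only.
* The idealized helix cannot reproduce trajectory-derived groove widths or
  relaxed structures; helicoidal maps of ideal helices are qualitative.
* Outer-sphere (water-mediated) coordination is out of scope by design.
* Mg²⁺ is intentionally absent from the default cutoff table: its
  inner-sphere exchange is too slow for the equilibrium counting framework
  the defaults represent; users may supply their own entry.
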