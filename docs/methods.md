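# Methods

## Couplings and constants

A dipolar coupling is evaluated as D_k = D_k^c (r⁰/r)³ P₂(cos θ_k), with
D_k^c = −μ₀ h γ₁ γ₂ / (8π³ (r⁰)³) carried in Hz.  The numerical
convention is pinned by four reference constants that the implementation
reproduces to their printed precision: D^c(¹⁵N–¹H, 0.100 nm) = +24.36 kHz,
D^c(¹⁴N–¹H, 0.100 nm) = −17.37 kHz, D^c(¹³C–¹H, 0.109 nm) = −46.66 kHz and
D^c(¹H–¹H, 0.178 nm) = −42.60 kHz, using CODATA/IUPAC gyromagnetic ratios
(γ(¹H) = 2.6752219×10⁸, γ(¹³C) = 6.728284×10⁷, γ(¹⁴N) = 1.9337792×10⁷,
γ(¹⁵N) = −2.712618×10⁷ rad s⁻¹ T⁻¹; configurable through
`PhysicalConstants`).  The sign of D_k^c is opposite to that of γ₁γ₂.

Internally all molecular quantities use GROMOS basic units (nm, u, ps, K,
e; hence kJ/mol for energies).  Couplings stay in Hz at every interface
with restraint force constants in kJ mol⁻¹ Hz⁻², the equivalent of the
native THz convention with a single 10¹² scale factor
(`constants.HZ_PER_THZ`); no unit round trips occur inside the code.

When averaging over orientations the distance and angular factors may be
averaged separately (`ensemble_rdc(..., separate_averaging=True)`), the
approximation appropriate when bond-length fluctuations are fast and
uncoupled from tumbling.  For constrained bonds — the only case the
restraining machinery handles — the distance factor is held at the value
implied by the frame geometry, and the molecule-side forces treat it as
constant.

## Flat-bottom restraint on time-averaged couplings

The restraining energy per coupling is piecewise in the deviation
x = D̄_k − D_k⁰:

* |x| ≤ ΔD^fb                     : 0
* ΔD^fb < |x| ≤ ΔD^fb + ΔD^h      : ½ K (|x| − ΔD^fb)²
* |x| > ΔD^fb + ΔD^h              : K ΔD^h (|x| − ΔD^fb − ½ ΔD^h)

with value and first derivative continuous at both junctions (junction
points assigned to the inner regime; the ½K convention follows the usual
half-harmonic force-field form).  Defaults ΔD^fb = 2.0 Hz (matching the
estimated 0.5–1.8 Hz experimental accuracy of measured RDCs, with margin)
and ΔD^h = 1.0 Hz.  The linear branch bounds the force factor at K·ΔD^h.

Restraints act on the exponentially damped running average
D̄(t_n) = e^(−Δt/τ) D̄(t_{n−1}) + (1 − e^(−Δt/τ)) D(t_n), whose recursion
is validated against a brute-force evaluation of the weighted sum.  The
derivative of D̄(t_n) with respect to the *current* configuration carries
the factor (1 − e^(−Δt/τ)) ≈ Δt/τ; the force keeps this factor (making
restraining forces proportional to K/τ) and drops only the history
dependence.  Dropping the factor itself would inflate forces by τ/Δt
(~10⁶ at defaults) and break the integrator immediately.

Seeding: for *analysis* averages the damped value is seeded with the
first instantaneous coupling (no startup transient in the estimate).  For
*restrained* runs the default seeds at the target values
(`damped_init="targets"`), i.e. inside the flat bottom: instantaneous
couplings are kHz-scale while targets are Hz-scale, and seeding with the
first value was observed to launch a long, occasionally pole-trapping
startup transient.  Both behaviours are selectable everywhere.

Reported couplings are always plain means over the post-burn-in analysis
window; the damped average only drives forces.  Over long runs the time
mean of the damped average converges to the plain mean, so the two
reporting conventions agree when the restraint holds.

## Field-vector stochastic dynamics

The magnetic field is a rigid two-particle rotor: masses 15.035 u, bond
0.153 nm, friction γ = 2.4 ps⁻¹ (the value that optimises rotational
sampling for this rotor), T = 298 K, Δt = 0.002 ps, no centre-of-mass
motion removal, and the restraint as its only potential term.  The
integrator is an impulse-form Langevin leapfrog: one combined
deterministic-plus-stochastic kick with per-component force variance
2mγk_BT/Δt, a drift, SHAKE-style iterative projection of the bond back to
its length (relative tolerance 10⁻⁴, non-convergence raised as an
integration failure signalling unphysically large forces), and velocity
recomputation from the constrained positions.  Any fluctuation-dissipation
consistent leapfrog variant is acceptable here; this one validates against

* free rigid rotation (γ = T = 0): bond and angular momentum conserved to
  10⁻⁶ over 10³ steps,
* equipartition: kinetic temperature over 10⁶ steps within 3 % of 298 K
  using 5 degrees of freedom (6 Cartesian minus one constraint),
* velocity-variance of fresh Maxwell–Boltzmann draws within 5 %.

The inner loop exists twice: a readable numpy implementation
(`langevin_step`, the fallback paths) and a numba-compiled kernel
(`_kernels.py`) used by `simulate_mfv` and `run_mfv_block`, ~60× faster,
which is what makes 10⁷–10⁸-step runs interactive.  Both implement the
identical update; the kernel additionally accumulates kinetic energy and
the worst bond-length deviation so runs can report thermostat and
constraint quality.

Unbiased sampling converges as n^(−1/2): the replicate-RMS of ⟨D⟩/D^c is
≈ 0.019 at 10⁵ steps, crosses 10⁻² near 4×10⁵ steps, and reaches the
10⁻³ range needed for meaningful RDC work by ~2×10⁷ steps.  The measured
P₂ decorrelation time of the rotor is ≈ 0.18 ps (partly ballistic motion
under moderate friction), which sets these scales.

## The hybrid loop

Per molecule step: extract the bond vectors of the current frame; run
N_mfv restrained field-vector SD steps against them (state and damped
averages persist across blocks — warm start — unless cold restarts are
requested); fold the block's damped coupling averages into a second,
τ^msy-damped molecule-side average (the block average is the rotational
estimate for the current configuration); if K^msy > 0 convert the
force factors into per-atom forces on the coupling atoms by the chain
rule on the bond orientation, with the field-orientation samples of the
block held fixed, and apply them to the molecule integrator (or record
them for replayed trajectories).  With K^msy = 0 the molecule is
untouched and the loop computes rotationally sampled couplings for an
unrestrained trajectory.

Defaults follow the named reference combination K^mfv = 100 kJ mol⁻¹ Hz⁻²
and N_mfv = 100, with K^msy = 0.05 kJ mol⁻¹ Hz⁻² when molecule
restraining is on.  A single shared field vector serves all couplings.

The molecule-side energy/force pair
(`molecule_restraint_energy` / `molecule_restraint_forces`) is an exact
gradient pair for a frozen set of field-orientation samples; central
differences agree to 10⁻⁶ relative on random configurations.  During
runs the force factors come from the τ^msy-damped averages while the
geometric derivative comes from the current block — the same
current-configuration approximation as on the field side.

### Molecule sources

Full solvated molecular dynamics is outside this package's scope; three
stand-ins preserve the loop's structure:

* **replay** — stored frames (or a single fixed structure),
* **rigid diffusion** — rigid-body isotropic rotational Brownian motion
  with a prescribed axis-autocorrelation time; an optional alignment
  tensor attaches per-frame importance weights w = 1 + 5 eᵀA e (e the
  field direction in the molecule frame), an exact linear identity under
  which the weighted orientation average of P₂ equals the tensor's
  back-calculated reduced coupling (valid for tensor eigenvalues within
  ±0.2, enforced),
* **toy flexible molecule** — an elastic network (springs between all
  reference-structure pairs within 0.35 nm) integrated by Langevin
  dynamics with neighbour-count friction
  γ_i = γ_solv max(0, 1 − N_i^nb/N^nbref): γ_solv = 60 ps⁻¹ (methanol),
  N^nbref = 6 non-hydrogen neighbours within 0.3 nm, friction updated
  every 1 ps.

## Choice of τ and the strong-restraint regime

The two memory times are genuinely free parameters (the reference
parameter scans for them are not public).  The defaults are
τ^mfv = 5000 ps and τ^msy = 50 ps.  The reasoning:

* The restraining force scale is K ΔD^h (Δt/τ) |∂D/∂x| with
  |∂D/∂x| ≈ 3|D^c|/ℓ ≈ 9×10⁵ Hz/nm, so K/τ sets everything.  At the
  defaults the per-coupling force cap is ≈ 36 kJ mol⁻¹ nm⁻¹ — large
  enough to shape the orientation distribution within desk-scale runs
  (10⁷–10⁸ steps), small enough for robust constraint integration.
* Restrained convergence at the defaults: a 5×10⁷-step run against 35
  consistent targets reaches max |⟨D⟩ − D⁰| ≈ 0.5 Hz (rmsd ≈ 0.24 Hz),
  inside the 2 Hz flat bottom.
* This is a deliberately *strong* restraint regime.  Hz-precision plain
  sampling of kHz-scale couplings would need ~10⁹–10¹⁰ steps (that is the
  scale at which the reference simulations operate); at desk scale the
  restraint must instead concentrate the orientation distribution.  Two
  measurable signatures follow and should be monitored: the magic-angle
  ratio of orientation histograms rises above 1 when a small or
  inconsistent target set over-restrains the rotor, and the rotor's
  kinetic temperature rises above the thermostat (≈ 520 K at the
  defaults, ≈ 1400 K at τ^mfv = 2000 ps, back to ≈ 300 K at 20000 ps)
  because the restraining work outruns the Langevin dissipation.  The
  field vector is a sampling device rather than a physical particle, so
  this trades thermal fidelity of the *proposal* distribution for
  convergence; runs that need a near-thermal rotor should raise τ^mfv
  and the run length together (deviations at fixed length grow, e.g.
  ≈ 10 Hz at τ^mfv = 20000 ps and 5×10⁶ steps).

## Alignment-tensor baseline

The five tensor components are carried Saupe-style,
a = (A_zz, A_xx − A_yy, A_xy, A_xz, A_yz), normalised so that a pure
A_zz = 1 tensor predicts D = D^c P₂(cos θ_z) (pinned by a unit test);
serialized fits record the basis.  The fit minimises
Σ (D_k^c r(b̂_k)·a − D_k⁰)² by SVD; fewer than five couplings raise
unless a minimum-norm solution is requested, and the condition number of
the design matrix is reported.  The restrained-step force is the gradient
of ½K Σ(pred − target)² with the tensor held fixed at its per-structure
refit; because the tensor minimises the same quadratic, this equals the
total derivative (envelope theorem), which the finite-difference test
verifies with refitting enabled.  No tensor time-averaging is applied —
this is the standard instantaneous-refit baseline, not a reimplementation
of any specific molecular-dynamics code.

## Observables

* NOE distances: ⟨r⁻⁶⟩^(−1/6) over trajectory frames.  Violations use
  strict inequalities (a distance exactly at its bound does not violate),
  the >0.1 nm count uses the same margin convention, and the violation
  RMSD divides by the full bound-set size, satisfied bounds contributing
  zero — the conventions that reproduce the packaged tables' footers.
* ³J-couplings: Karplus J(θ) = a cos²θ + b cosθ + c with
  (6.4, −1.4, 1.9) Hz for H_N–H_C and (9.5, −1.6, 1.8) Hz for H_C–H_C
  dihedrals; deviation counts use a strict 2 Hz threshold.  The packaged
  ³J table carries two experimental columns; both assembly conventions
  (`ref24_preferred`, `ref45_only`) are implemented because the printed
  summary statistics are internally consistent only under a mixture:
  the unrestrained-simulation RMSD of 0.5 Hz and the annealed structure's
  deviation count of 5 reproduce under ref24-preferred, that structure's
  RMSD of 2.5 Hz under ref45-only.  Neither is silently preferred.
* Hydrogen bonds: d(H···A) < 0.25 nm and angle(D–H···A) > 135°, strict.
* Virtual hydrogens for united-atom carbons: ideal tetrahedral
  construction with C–H = 0.109 nm for CH and prochiral CH₂ (Re/Si
  assigned by signed volume, stable under rigid motion), and the methyl
  pseudoatom at the carbon with the 0.1 nm bound correction folded into
  the NOE bound itself.
* Orientation-angle diagnostics: θ histograms over [0°, 180°] (36 bins of
  5° by default) with a sin θ-corrected density normalised so that
  isotropic sampling is flat at 1.  The magic-angle ratio is the mean
  corrected density over [50°, 60°] ∪ [120°, 130°] divided by that over
  [85°, 95°]; uniform sampling gives 1.0 by construction, making the
  oversampling flag scale-free.  The exact windowing of the original
  diagnostic is not public; this normalised variant is a reinterpretation
  and the raw counts are also returned.

## Synthetic data

The toy helix is an idealised construction, not a real peptide: residues
on a regular helix carrying labelled N–H (0.100 nm), C_β–H_β and
C_α–H_α^Re/Si bonds (0.109 nm, the prochiral pair 0.178 nm apart at the
ideal tetrahedral angle), with each residue's carbonyl oxygen placed on
the extension of the i+2 amide N–H vector so the n−2 helical hydrogen
bonds satisfy the geometric criterion exactly at construction.  All
generators are seed-deterministic.  Passing tests on this geometry shows
the machinery is self-consistent — constants, restraining, fitting and
analysis agree with each other and with closed-form oracles — not that
any particular real molecule behaves this way; real data adds
conformational flexibility, experimental noise and assignment ambiguity
that only the noise parameters of the generators emulate.

The packaged tables (131 NOE bounds with two bound sets of 42 and 119,
21 ³J-couplings with two experimental columns, 39 RDCs with experimental
targets and several back-calculated columns) are fixtures of published
reference values; every footer statistic is recomputed by the generic
observable operations and audited (`hrsrdc audit-tables`, 19/19).  One
footer count in the source print (the annealed structure's >0.1 nm
violation count against the 42-bound set) contradicts its own per-row
values and accompanying text; the audit follows the per-row values
(largest violation on bound 31).

## Numerical choices and limitations

* Angles are degrees at interfaces, radians internally; coordinates nm
  everywhere, Å only at the PDB boundary.
* Junction points of the piecewise restraint belong to the inner regime;
  the Heaviside boundary value is irrelevant to the (continuous) energy.
* The constraint solver is the two-particle special case of SHAKE with a
  bounded iteration count; failure raises rather than silently degrading.
* Stochastic reproducibility: every run is bit-reproducible given its
  seed; the compiled kernels draw from numba's own generator seeded from
  the caller's stream (seeds kept below 2³¹).
* The hybrid loop's molecule stand-ins do not include nonbonded physics,
  solvent, pressure coupling or real force-field terms; conclusions about
  real peptides require coupling the loop to a proper simulation engine.
* Orientation distributions produced under desk-scale (strong) restraint
  are shaped by the restraint itself; they demonstrate the algorithm, not
  equilibrium Boltzmann sampling of a physical system.
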