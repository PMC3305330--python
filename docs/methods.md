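# Methods

## Model and assumptions

Membrane proteins are modelled as hard disks in the membrane plane. The
crowders are a discrete mixture of radii *r_i* with relative abundances
(normalised internally; any nonnegative rescaling describes the same
mixture), total number density *c* (nm⁻²), area fraction φ = cπ⟨r²⟩ and
relative radius variance δ² = (⟨r²⟩−⟨r⟩²)/⟨r⟩². The gating protein is a
disk that switches radius R_c → R_o; its internal energetics, lipid–protein
interactions and bilayer deformation are *not* modelled — in the
open-probability description they are lumped into a single bare gating
tension σ*₀. All energies are in k_BT (β ≡ 1) and lengths in nm, so
tensions carry units k_BT/nm² and k_BT/nm and temperature is not a free
parameter.

Key physical assumptions:

* **Hard-core exclusion only.** No membrane-mediated elastic or
  hydrophobic-mismatch interactions; proteins are effective cylinders that
  exclude lipids and proteins identically.
* **Incompressible lipids.** Lipid area per molecule is treated as fixed
  and the lipid count constant on gating time scales; in the
  constant-tension ensemble the total area therefore grows by exactly the
  channel's area change ΔA, which is what cancels the surface-tension term
  there.
* **Two-state gating.** The channel has exactly two conformations; the
  open probability is the Boltzmann sigmoid 1/(1+e^ΔG).
* **Moments suffice.** All closed-form results depend on the crowder
  distribution only through c, ⟨r⟩, ⟨r²⟩; continuous radius distributions
  are represented by finite discrete sampling at the caller's discretion.

## Tensions

The dilute ("ideal gas") estimate treats crowders as non-interacting:
σ_c = c (the 2D ideal-gas law) and τ_c = c⟨r⟩, the latter from the
exclusion annulus of width ⟨r⟩ around the channel; it vanishes with the
crowder size. Scaled-particle theory (SPT) for hard-disk mixtures
(Lebowitz-type equation of state) resums overlapping exclusion zones:

    sigma_c = c [ 1/(1-phi) + phi/((1+delta2)(1-phi)^2) ]
    tau_c   = c <r> / (1-phi)

The uniform-crowder row σ_c = c/(1−φ)², τ_c = cr/(1−φ) is the exact δ²=0
specialisation. Size variability lowers σ_c at fixed c and φ; with the
δ² ≈ 0.15–0.25 implied by measured transmembrane-helix-count distributions
the correction is ~10%, which is why the worked example sets δ² = 0. The
excess chemical potential of a test disk of radius R is

    mu_ex(R) = -ln(1-phi) + 2 pi c <r> R/(1-phi) + pi R^2 sigma_c

whose exponential exp(−μ_ex) is exactly the probability that a randomly
placed test disk overlaps nothing (the Widom identity; exact at R = 0,
where it equals 1−φ). The area integral of the equation of state at fixed
copy numbers n_i has the closed form used for ensemble bookkeeping:
with N = Σn_i, B = πΣn_i r_i², C = π(Σn_i r_i)²,
ΔF = −[N ln((A₂−B)/(A₁−B)) − C(1/(A₂−B) − 1/(A₁−B))]; its area derivative
reproduces −σ_c, which the tests check to 1e−6 relative by central
differences.

## Ensembles

Constant area: ΔG_crowd = σ_cΔA + τ_cΔC. Constant tension: the membrane
area adjusts so lipid area is conserved, the surface-tension contribution
cancels, and ΔG_crowd = τ_cΔC with loading-device term −σΔA (positive
applied tension favours the open state — the sign required for a
mechanosensitive channel). `constant_tension_decomposition_check` verifies
the cancellation non-perturbatively: it evaluates the stepwise route
(remove closed channel via μ_ex, expand the crowder fluid by ΔA via the
exact area integral, insert the open channel via μ_ex) and returns its
difference from τ_cΔC − σΔA. The channel's own translational-entropy
difference, O(ΔA/A), is excluded from the route, consistent with the
expansion order of the closed form; the residual then scales as 1/A
(≈1.4×10⁻³ k_BT at a cell-scale membrane of 10⁶ nm²) and is identically
zero without crowders.

The open-probability midpoint shift equals the constant-tension
gating-tension shift ΔG_crowd/ΔA algebraically; a property test asserts it
to machine precision.

## Crowding inputs

Three routes build a mixture: explicit radii+abundances; a uniform radius;
or a transmembrane-helix-count abundance table, with each n-helix protein
becoming a disk of area n times a per-helix footprint (default 1.4 nm²,
configurable), i.e. r = √(n·a/π). Under this r ∝ √n rule
δ² = ⟨n⟩/⟨√n⟩² − 1, independent of the footprint. Zero-helix rows are
rejected (not membrane-embedded). A protein:lipid mass ratio m with TM
mass fraction f maps to φ = fm/(fm+1) under equal mass density; the
physiological range m = 1–2.5, f = 0.5 gives φ ≈ 0.33–0.56. Construction
rejects φ ≥ 1 and logs a warning above φ = 0.78, where the hard-disk SPT
equation of state degrades on approach to close packing.

## Monte Carlo oracle

The closed-form SPT results are validated by an independent sampler that
shares no code with them: single-disk Metropolis displacement moves in a
periodic square box with minimum-image overlap tests (moves into overlap
rejected; symmetric proposals give detailed balance on the uniform
hard-disk measure), followed by Widom insertion of ghost disks. Periodic
boundaries remove the hard-wall edge effects that the analytic expansion
neglects; the hard-wall geometry survives only in the exact one-crowder
free-area formula (L−2r)² − π(R+r)², cross-checked against midpoint-rule
grid integration. Defaults: box side 40⟨r⟩, 500 equilibration sweeps with
the step half-width auto-tuned toward ~40% acceptance then frozen, 2000
sampling sweeps, snapshots every 10 sweeps, 2000 insertions per snapshot,
all randomness from a single seeded `numpy.random.Generator`. Start
configurations come from random sequential insertion (largest disks
first), which is rejected above φ = 0.7 where it jams. Standard errors are
computed over between-snapshot means, which respects within-snapshot
correlation; at R = 0 the trials are exactly iid Bernoulli(1−φ), and the
test suite uses the exact binomial standard error there.

The oracle tests run at reduced size — box 20⟨r⟩ (13–38 disks), 300
equilibration + 1200 sampling sweeps, snapshots every 12 sweeps —
chosen as the smallest runs whose Monte Carlo error sits comfortably
inside the 5% agreement band documented for SPT at φ ≤ 0.4; observed
agreement there is ≤ 2% at φ ∈ {0.1, 0.2, 0.3}, R ≤ ⟨r⟩. SPT is *not*
near-exact at high density: deviations beyond 5% should be expected above
φ ≈ 0.6 and are not asserted.

Finite-box note: the Widom comparison is made against SPT evaluated at the
*realised* density n/L² of the simulated box (n must be an integer), not
the nominal φ; at these box sizes the difference is up to ~2% in φ and
would otherwise dominate the error budget.

## Numerical choices

* Tensions and energies are exact closed forms in double precision;
  reported tables round energies to one decimal (k_BT) and tension shifts
  to two (k_BT/nm²), retaining full precision in adjacent columns.
* The open probability uses `scipy.special.expit` to avoid overflow at
  large |ΔG|; it saturates to exactly 0/1 beyond ~±37 k_BT, so strict
  monotonicity is only meaningful in the representable interior.
* Degenerate transitions (R_c = R_o) have ΔA = ΔC = 0; the gating-tension
  shift is then undefined and requesting it raises an error (the result
  record stores NaN).
* Mixture moments clip ⟨r²⟩−⟨r⟩² at zero against floating-point roundoff
  so δ² ≥ 0 always holds.

## Synthetic data

`generate_fixture` emits seeded crowder descriptions used by tests and
examples: a uniform-crowder config, a two-species mixture, and a synthetic
TM-helix abundance TSV whose expected abundance decays geometrically
(ratio 0.75) over 1–30 helices with lognormal (σ = 0.4) noise — mimicking
the qualitative shape of measured membrane-proteome helix distributions:
dominated by few-helix proteins, abundances spanning about an order of
magnitude. It does not emulate detection bias, protein-complex
aggregation, or non-circular cross-sections, so passing tests validate the
hard-disk pipeline, not those features of real proteomes.

## Known limitations

* SPT is approximate; accuracy degrades toward close packing
  (warning threshold φ = 0.78) and the package makes no attempt at
  higher-order equations of state.
* No NPT/constant-tension Monte Carlo — the oracle validates insertion
  free energies, not the ensemble Legendre transform, which is instead
  checked analytically by the decomposition residual.
* The hard-wall box entropy uses the (L−2r)² edge-band form, exact up to
  corner effects of the band; only entropy *differences* enter any
  downstream result and these are independent of both the discretization
  length b and the corner treatment.
* Crowding of cytoplasmic domains by bulk solution, sub-conductance
  states, and bilayer elastic energetics are out of scope.
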