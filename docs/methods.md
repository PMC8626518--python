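# Methods

This note documents the models implemented in `stabkin`, the defaults and
why they were chosen, what the synthetic fixtures emulate, and the known
limitations.

## Scope and data model

The engine starts *after* electronic structure: its inputs are
stationary-point descriptors (electronic energies, ZPEs, harmonic
frequencies, one imaginary TS frequency, rotational constants, symmetry
numbers, path degeneracies) for the wells and saddle points of a
multiwell network, plus a solvent (bath) block and a temperature grid.
Solvation effects are assumed to be embedded in the input energies (e.g.
computed with a continuum model); the engine makes no solvation
correction of its own.

Species come in two forms. Full rovibrational records support rate
computation; label-only stubs carrying relative energies (kcal/mol vs
the reactant) support validation, barrier bookkeeping and cross-scaffold
comparison against the embedded reference tables. Operations state which
form they need and fail loudly on the wrong one.

All unit conversions go through one pinned constants ledger
(CODATA 2018 defining constants; 1 Hartree = 627.5095 kcal/mol;
1 kcal/mol = 349.755 cm⁻¹) so every module agrees bit-for-bit.

## Thermochemistry (RRHO)

Partition functions are rigid-rotor harmonic-oscillator: vibrations
referenced to the zero-point level, classical external rotations
(linear, symmetric-top or asymmetric-top from 1–3 rotational constants,
divided by the symmetry number), electronic factor = spin multiplicity ×
optical isomers. No hindered-rotor or anharmonic corrections are applied
and frequencies are used unscaled by default (a global scale factor can
be applied by the caller). The translational factor uses the 1 atm
ideal-gas standard state; it cancels identically in the relative isomer
tables the tool reports, and a species without a declared mass simply
omits it (only valid for relative quantities, which is how it is used).
For isomer pairs Δ(pV) cancels, so ΔE°(T) = ΔH°(T) for every
well-to-well entry — a consistency check the suite asserts.

## State counting

Sums and densities of states use the Beyer–Swinehart direct count on a
uniform energy ladder: states binned by floor(E/grain), the zero-point
state in bin 0, each frequency rounded to the nearest ladder rung.
Default grain 10 cm⁻¹ and ceiling max(50 000 cm⁻¹, well above the
largest barrier), both configurable. External rotations are adiabatic
(not counted) by default; a classical-rotor convolution (1-D: ρ ∝
E^{-1/2}; 2-D: constant; 3-D: ρ ∝ E^{1/2}) is available where an active
K-rotor treatment is wanted. The count is pinned against brute-force
enumeration of occupation vectors for small systems and against the
zero-point-shifted classical limit (E + E_zpe)^s / (s! Π hcνᵢ) at high
energy.

## Eckart tunneling

Transmission through the asymmetric Eckart potential is evaluated in the
standard reduced variables αᵢ = 2πVᵢ/(hν‡) (log-cosh arithmetic keeps
deep-tunneling values finite), with the exothermicity floor
max(0, V₁ − V₂) below which the product channel is closed. The closed
form is *not* trusted from transcription: a Numerov scattering solver
integrates the Schrödinger equation through the same potential (length
scale fixed numerically from the imaginary-frequency curvature) and the
suite requires agreement to better than 10⁻³ in relative error across
seeded random barriers. The canonical correction
κ(T) = e^{V₁/kT}/(kT) ∫ P(E) e^{−E/kT} dE uses adaptive quadrature to
relative tolerance 10⁻⁸ with an upper limit 40 kT above the barrier.
Both canonical (κ multiplying k(T)) and microcanonical (transmission
convolved into G*) routes are provided; canonical is the default. Note
the strict E = 0 limit of the transmission is 0 (zero incident
momentum); tunneling is positive for any E > max(0, V₁ − V₂).

## Microcanonical rates and the master equation

k(E) = α G*(E − E₀)/(h N(E)) bin-wise, zero below E₀. A well with *no*
states anywhere an open TS sum exists is rejected as inconsistent data;
isolated empty bins of a sparse direct count simply carry no population.
Thermal averages evaluate Boltzmann weights at bin centers, which
removes the first-order bias of rounding state energies down onto the
ladder.

The energy-grained master equation uses the exponential-down transfer
kernel: down-collision rates out of each level normalized to the
Lennard-Jones collision frequency ω = π σ₁₂² Ω(2,2)* ⟨v_rel⟩ [M]
(combining rules σ₁₂ = (σ₁+σ₂)/2, ε₁₂ = √(ε₁ε₂); Neufeld-style analytic
fit for Ω(2,2)*, pinned against tabulated values), up-rates fixed by
detailed balance against the well's Boltzmann distribution. Because
detailed balance is imposed pairwise, the collision operator's
stationary state is exactly Boltzmann and the high-ω limit of the ME
rate is exactly the canonical (TST) rate — the suite verifies
convergence to 0.5 % at liquid-water collision frequency. The
phenomenological rates come from the least-negative eigenvalue of the
symmetrized transport–reaction matrix, with the eigenvector apportioning
the total loss among channels.

Defaults: ⟨ΔE⟩_down = 200 cm⁻¹, temperature-independent; bath number
density 3.34 × 10²² cm⁻³ (liquid water at 298.15 K, 0.997 g/cm³). At the
resulting ω ≈ 2.5 × 10¹³ s⁻¹ the ME is within a fraction of a percent of
the high-pressure limit for barriers of tens of kcal/mol, so the
production route for liquid-phase tables is HPL canonical TST with
canonical Eckart κ; the full ME is retained for verification and
fall-off studies. Reaction-path degeneracies default to 1 per channel
and are overridable per step.

## Network kinetics

For the sequential chain A ⇌ B ⇌ C ⇌ D ⇌ E the steady-state composite
rate constants add one reciprocal term per well:
1/k_obs,B = 1/k₁; 1/k_obs,C = 1/k₁ + k₋₁/(k₁k₂);
1/k_obs,D += k₋₁k₋₂/(k₁k₂k₃); 1/k_obs,E += k₋₁k₋₂k₋₃/(k₁k₂k₃k₄).
k_obs,B ≡ k₁ bit-exactly and the sequence telescopes monotonically; the
derivation treats the target well as a sink, so the numerical oracle
(matrix-exponential integration of the full linear system) truncates the
chain at the target well and compares production slopes in the
timescale-separation regime (intermediates relax much faster than the
entrance step feeds them). The shorter pathway through IN4 uses the same
formula pattern with three steps.

Half-lives use t½ = ln2 / Σ(exit rates), summing *all* exit channels of
a well (forward and reverse) and ignoring equilibrium back-population.
This convention is internally consistent with the embedded tables: e.g.
ln2 / 7.90 s ≈ 8.77 × 10⁻² s⁻¹ against a printed forward rate of
8.50 × 10⁻² s⁻¹, the remainder being the reverse channel.

Stability ranking orders compounds by ascending overall
product-formation rate (ties broken by the penultimate well's rate, then
by name): slower product formation = more chemically resistant.

## Synthetic fixtures

`make_two_pathway_network` builds the two-pathway graph (R, IN1–IN4, P; six
transition states) with seeded random rovibrational data and a
self-consistent relative-energy table shaped like the scaffold PESs
(high entrance barrier ~43 kcal/mol, deep second well, rate-determining
last step). It emulates the *structure* of real scaffold networks —
topology, barrier ordering, timescale separation — but not the actual
molecular frequencies, which live in supplementary material a user can
supply through the YAML network format. Passing tests on these fixtures
therefore demonstrate the correctness of the kinetics machinery, not
digit-level reproduction of any particular molecule's rate table; the
embedded printed tables cover the bookkeeping layer (barriers,
activation parameters, ratios, half-life conventions) exactly.

Two-route equivalence diagnostics snap fixture frequencies to grain
multiples so the grained and analytic partition functions describe the
same spectrum, and use moderate frequencies (80–900 cm⁻¹, 10 modes) so
the well's ladder is quasi-continuous at the barrier energy — the
regime the statistical k(E) expression assumes.

## Numerical choices

- Energy-ladder problem sizes in tests and the acceptance script:
  ~10⁴ bins (grain 10–20 cm⁻¹, ceiling 40 kT above the barrier for ME
  work, ~10⁵ cm⁻¹ for thermal averages).
- κ quadrature: scipy adaptive, relative tolerance 10⁻⁸, breakpoint at
  the barrier top.
- Numerov oracle: 6001 points over ±10 barrier length scales; reduced
  units ħ = μ = 1 (transmission depends only on E/V₁, V₂/V₁, V₁/hν‡).
- ME eigenproblem: restricted to populated bins, symmetrized with
  D = diag(√Boltzmann), solved with `eigh`.
- Overall-rate telescoping clamps one-ulp float rounding so the
  monotonicity identity holds exactly.
- Output dialect: uppercase scientific notation ("2.49E-19"), 3
  significant figures in reports, full precision internally; unicode
  minus signs and doubled exponent markers are normalized on input.

## Known limitations

- Harmonic oscillators only; no hindered rotors, no anharmonicity, no
  multidimensional (small/large-curvature) tunneling.
- 1-D (energy-only) master equation; no (E, J) resolution, no
  pressure-dependent fall-off fitting.
- The network topology is restricted to the two-pathway pattern and
  simple chains; no symbolic eigen-analysis of arbitrary graphs.
- Critical constants for LJ estimation are user inputs; no
  group-contribution estimator is included. The three scaffold solute LJ
  values (5.34 Å/519.88 K, 5.44 Å/580.79 K, 5.34 Å/553.67 K) and water
  (2.74 Å/506 K) ship as pinned presets.
- Liquid-phase standard-state conventions for absolute G are documented
  (1 atm ideal gas) but only relative quantities, where the choice
  cancels, are reported.
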