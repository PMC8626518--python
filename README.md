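# stabkin

RRKM/Eckart kinetics for multiwell–multichannel unimolecular reactions in
solution, aimed at ranking drug scaffolds by chemical resistance.

## The problem

Whether a drug molecule survives in solution depends on how fast it can
rearrange through intramolecular channels such as 1,4-hydrogen shifts.
For a five-membered heterocyclic scaffold (pyrrolone, furanone or
thiophenone core) the rearrangement proceeds through a multiwell network

```
(a)  R ⇌ IN1 ⇌ IN2 ⇌ IN3 ⇌ P
(b)  R ⇌ IN4 ⇌ IN3 ⇌ P
```

where R is the parent compound, IN1–IN4 are intermediates, P the aromatic
product, and each arrow is an elementary step over a transition state.
Given stationary-point quantum-chemistry descriptors (relative energies,
harmonic frequencies, rotational constants) for every well and saddle
point, `stabkin` computes the forward and reverse rate constants of every
step, the steady-state overall rate constants and half-lives over a
temperature grid, and ranks scaffolds by how slowly they form product —
the slower, the more chemically resistant.

## The model

* **Microcanonical rates** (RRKM):
  `k(E) = α G*(E − E₀) / (h N(E))` for `E ≥ E₀`, with `G*` the sum of
  states of the activated complex, `N` the density of states of the well
  (Beyer–Swinehart direct count), `E₀` the ZPE-corrected critical energy
  and `α` the reaction-path degeneracy.
* **Tunneling**: transmission through a one-dimensional asymmetric Eckart
  barrier parameterized by the forward/reverse barriers and the imaginary
  frequency, applied either canonically (κ(T) multiplying the thermal
  rate) or microcanonically (inside `G*`).  The closed form is validated
  against an independent Numerov scattering solver.
* **Thermal rates**: a one-dimensional energy-grained master equation
  with exponential-down collisional energy transfer (solvent as the third
  body, Lennard-Jones collision frequency), plus the high-pressure-limit
  canonical TST route `k(T) = α κ(T) (k_BT/h)(Q‡/Q) exp(−E₀/k_BT)`.
  At liquid-phase collision frequencies the two coincide; the HPL route
  is the production default.
* **Network kinetics**: steady-state overall rate constants
  `1/k_obs,B = 1/k₁`, `1/k_obs,C = 1/k₁ + k₋₁/(k₁k₂)`, … (each further
  well adds one reciprocal term), half-lives `t½ = ln2 / Σ k_exit`, and
  stability ranking by ascending product-formation rate.
* **Lennard-Jones parameters** from critical constants via the Tee
  correlations `σ/Å = 2.3647 (T_c/P_c)^{1/3}`, `ε/k = 0.7740 T_c`.

Reference tables for the three scaffolds (relative energies ΔE+ZPE, ΔE°,
ΔH°, ΔG°; per-channel rate constants; intermediate half-lives at three
levels of theory — CBS-QB3 and two M06-2X basis sets) ship as embedded
fixtures, so the bookkeeping layer works with no external data.

## Worked example

```python
from stabkin.fixtures import scaffold_network, reference_tables, FixtureSpec, make_two_pathway_network
from stabkin.network_model import barrier_height
from stabkin.network_kinetics import compare_rates, temperature_scan

net = scaffold_network("pyrrolone")
b = barrier_height(net, "TS2-N", "IN1-N", kind="E_plus_ZPE", level="A")
print(f"IN1-N -> IN2-N barrier (CBS-QB3): {b:.2f} kcal/mol")

t = reference_tables()
r = compare_rates(t["rates"][("furanone", "R-O->IN1-O", "A", "298.15")],
                  t["rates"][("pyrrolone", "R-N->IN1-N", "A", "298.15")])
print(f"furanone/pyrrolone entrance-rate ratio at 298.15 K: {r:.2e}")

toy = make_two_pathway_network(FixtureSpec(seed=1))
table = temperature_scan(toy, t_grid=[298.15, 360.0], level="toy")
for T, k1, ke in zip(table.temperatures, table.channels["R->IN1"], table.overall["P"]):
    print(f"T={T:6.2f} K  k(R->IN1)={k1:.2e} s^-1  k_obs(P)={ke:.2e} s^-1")
```

prints

```
IN1-N -> IN2-N barrier (CBS-QB3): 19.27 kcal/mol
furanone/pyrrolone entrance-rate ratio at 298.15 K: 4.38e-07
T=298.15 K  k(R->IN1)=3.08e-18 s^-1  k_obs(P)=1.41e-36 s^-1
T=360.00 K  k(R->IN1)=2.30e-13 s^-1  k_obs(P)=4.68e-29 s^-1
```

The 19.27 kcal/mol barrier is the second isomerization step of the
pyrrolone scaffold; the 4.4 × 10⁻⁷ ratio says the furanone scaffold
enters its rearrangement about two million times more slowly than the
pyrrolone one at room temperature (more chemically resistant).  The last
two lines run the full HPL/Eckart pipeline on a synthetic two-pathway
network: overall product formation is vanishingly slow and accelerates
with temperature, as expected for barriers of tens of kcal/mol.

A CLI mirrors the library: `stabkin validate|thermo|rates|overall|`
`halflife|rank|lj|fixtures` (see `stabkin --help`).  `stabkin fixtures`
materializes any fixture as a YAML network file you can edit to supply
your own frequencies and energies.

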