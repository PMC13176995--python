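# Methods

This note documents the models, conventions and numerical choices behind
`platkin`, and what its synthetic data can and cannot establish.

## Free-energy profiles

A profile is a set of labeled stationary points — minima (`MS…`),
transition states (`TS…`), and infinitely separated species — with Gibbs
energies stored **relative to one reference species set** (the intact
chloro complex plus free ligands) in kcal/mol, plus the elementary steps
connecting them. Absolute hartree-scale energies are converted at ingest
(627.5094740631 kcal/mol per hartree); nothing downstream ever sees an
absolute energy, which keeps every computed quantity invariant under a
common energy shift (a property test enforces this).

Thermochemical composition follows the usual continuum-solvation recipe:
gas-phase Born–Oppenheimer energy (electronic + nuclear repulsion), a
solvation free-energy/enthalpy contribution, harmonic thermal corrections,
and — for free energies only — the standard-state change from 1 atm to
1 mol/L, `RT·ln(RT/(1 atm)·1 mol/L)`. With exact CODATA-2018 constants this
is 1.894 kcal/mol at 298.15 K (displayed as 1.89) and 1.995 kcal/mol at
310.15 K. The term is a function of temperature, not a hard-coded constant.

Step arithmetic: a transition state's absolute energy is
`g(from) + ΔG‡_fwd`; the reverse barrier is that minus `g(to)`; and
`ΔG_step = ΔG‡_fwd − ΔG‡_rev` holds exactly by construction. For profiles
transcribed from published one-decimal values these identities only close
to ~0.1 kcal/mol (e.g. 4.5 + 24.8 − 11.2 = 18.1 against a printed reverse
barrier of 18.0), so the validator's default tolerance is **0.15 kcal/mol**;
exact synthetic profiles validate at 1e-9. The validator reports —
mismatched TS energies, negative reverse barriers, dangling transition
states, unreachable points — rather than raising, so a CLI `validate` run
can list every defect at once.

### Packaged profiles and transcription decisions

Twelve profiles ship as package data. Three transcription decisions are
flagged in metadata rather than silently applied:

* the aquation-path point `MS6'` of the GlcNS(6S) sulfate route is stored
  as **+12.2** kcal/mol although the source prints −12.1: the printed
  backward barrier (17.9) and the downstream values (−7.4 stabilization to
  a 4.8 product) are only mutually consistent with the positive value, so
  the sign is treated as a typo and the point carries a
  `sign_typo_corrected` flag with the printed value;
* the separated `H2O-PtN3` state is stored at 20.9 kcal/mol relative to the
  global reference although the source phrases it relative to `MS1`; the
  ambiguity is recorded on the point;
* the direct GlcNS(6S) sulfate route has no printed isolated-product
  energy; the profile ends at `MSd'` and says so in its metadata.

The explicit-water aquation variants (0/3/6 first-shell waters over the
continuum) are **separate profiles** tagged via `explicit_waters`, not
corrections applied at run time: the underlying explicit-solvation
derivation is not reproduced here, so the corrected energies are inputs.
Full hybrid-solvation networks for the saccharide pathways exist only in
unpublished supplementary tables; `builtin_profiles()` therefore carries
continuum values for those, and users holding the supplementary data can
load their own profiles through the same CSV/JSON formats.

## Transition-state theory

`k = (k_B·T/h)·exp(−ΔG‡/RT)` and `K_eq = exp(−ΔG/RT)` with CODATA-2018
`k_B` and `h`, `R = 1.98720425864e−3 kcal mol⁻¹ K⁻¹`, default temperature
298.15 K, all energies kcal/mol. The inverse map
`ΔG‡ = RT·ln((k_B·T/h)/k)` is exact (round-trip property tested to 1e-9
kcal/mol over [−10, 60]).

Two conventions adopted from the source material, documented because they
are easy to trip over:

* **Negative printed observables.** The quasi-equilibrium rate laws of the
  direct pathways are quoted with negative signs (−9.33 s⁻¹, −1.63×10⁻⁵
  s⁻¹), an artefact of the sign convention in the underlying derivation.
  The printed effective barriers (16.1, 24.0 kcal/mol) are exactly the
  inverse-Eyring images of the magnitudes, so `effective_barrier` takes
  magnitudes and rejects non-positive input.
* **Units of k_obs.** The pseudo-first-order product `k₁·[H₂O]` is reported
  numerically as a first-order constant ("s⁻¹ after absorbing [H₂O]");
  the source itself mixes L mol⁻¹ s⁻¹ and s⁻¹ for this quantity. Composite
  quasi-equilibrium constants are likewise reported on the 1 M standard
  state, where `K_pre·k₂ = eyring(ΔG_pre + ΔG‡₂)` — an identity the suite
  asserts to relative 1e-12.

Negative activation energies are allowed in `eyring_rate` because composite
effective barriers (downhill pre-association plus small step barrier) can
legitimately be negative.

## Microkinetics

`network_to_mass_action` turns a validated profile into reversible
mass-action reactions: TS-mediated steps get forward/reverse Eyring rates
(detailed balance then holds exactly, `k_f/k_r = K_eq(ΔG_step)`);
barrierless association/dissociation steps carry only a ΔG, so their
bimolecular direction receives a diffusion-controlled-order policy rate,
**k_assoc = 10⁹ M⁻¹ s⁻¹** by default, with the opposite direction fixed by
detailed balance. For the rare barrierless step that is unimolecular both
ways, the policy rate goes to the downhill direction so no constant ever
exceeds the policy scale. Equilibrium results are provably independent of
the policy; the acceptance suite verifies invariance to within relative
1e-4 over 10⁶–10¹⁰ M⁻¹ s⁻¹.

Water is clamped at 55.5 M (its concentration folded into effective rate
constants); chloride is a free species starting at 1 mM. The default
initial state reproduces the study conditions: 1 mM Pt complex, 5 mM
monosaccharide, 1 mM chloride.

**Integration.** Rate constants in these networks span ~20 orders of
magnitude, so the systems are stiff in the extreme. `simulate` uses
`scipy.integrate.solve_ivp` with an analytic Jacobian, relative tolerance
1e-9 and absolute tolerance 1e-15 M, on a log-spaced output grid (traces
run from millimolar to picomolar). BDF is tried first; if its iteration
matrix goes numerically singular at very large steps (h·k ≫ 1/ε), Radau
and LSODA are tried before failing with a diagnostic that includes the
rate-constant span. Negative concentrations beyond −1e-12 M trigger a
warning; smaller excursions are clipped to zero and counted in the
metadata, never silently.

**Equilibrium.** `equilibrium_state` integrates over expanding horizons and
then Newton-polishes the state in log-concentration space until every
reaction's net flux vanishes relative to its one-way fluxes (tolerance
1e-9), holding conserved totals at their initial values. When the
integrated state is outside the Newton basin (slow modes unrelaxed), the
polish is re-seeded from the log-linear detailed-balance solution; the
flux-residual check still decides convergence. The test oracle is
deliberately different machinery: it solves the K_eq equations under
conservation constraints (chemical-potential parametrization, no rate
constants), and for unimolecular networks a Boltzmann closed form;
implementation and oracle agree to ~1e-14 relative on every packaged
network.

Conserved moieties (Pt centre, saccharide, chloride) are declared as
species tags, checked reaction-by-reaction at build time and along every
trace (relative drift < 1e-6); untagged systems fall back to the left null
space of the stoichiometry matrix.

**Transient analysis.** `species_extremum` takes the grid argmax and
refines it with a local quadratic; monotone traces return their endpoint
with a flag. A caveat worth stating: at the published continuum-solvation
energies the aquation-driven two-path iduronate network shows *no* kinetic
overshoot — inter-branch exchange (reverse barriers 14.4/17.9 kcal/mol)
is many orders faster than the rate-limiting aquation supply, so the two
products remain mutually equilibrated throughout. The kinetic-product
transient that the study reports for its hybrid-solvation energies appears
here on the *direct* two-path network (sulfate adduct peaking near 10⁴ s),
and prominently on constructed low-barrier/high-ΔG toy networks used in
the tests.

## Benchmark statistics

MAD is the unweighted arithmetic mean of absolute deviations over the
stationary points shared by method and reference — the source does not
state a weighting, so the simplest estimator is used and documented.
Deviations are computed on relative energies, making all statistics
invariant under common shifts. Rankings sort ascending by overall MAD with
alphabetical, flagged tie-breaks; percent improvement is
`(MAD_worse/MAD_better − 1)·100`, displayed rounded half-up (117.6 → 118).
Since the per-point energies behind the published MADs are not
redistributable, the ranking and improvement ratio are exercised on the
published overall MADs, and the estimator itself is validated on synthetic
noisy methods where the expected MAD has the folded-normal closed form
`σ√(2/π)·exp(−b²/2σ²) + b·(1 − 2Φ(−b/σ))`.

## Synthetic data

`generate_network` draws backbone chains with optional branch-and-rejoin
detours: minima uniform over an energy range (default −10…15 kcal/mol,
bracketing the packaged profiles), each TS placed a barrier-range-uniform
amount (default 5…25 kcal/mol, the span of the published barriers) above
the higher endpoint, and a fraction of steps (default 0.3, matching the
packaged profiles' association/dissociation share) left barrierless. Both
directed barriers are non-negative and every cycle closes exactly because
energies are state functions — so generated profiles validate at 1e-9 by
construction, seeded and bit-reproducible.

What this emulates: thermodynamically consistent networks of the size and
energy scale of the real profiles, and method-energy families with
controlled bias/scatter. What it does not: correlated method errors across
stationary points, anharmonicity, conformational multiplicity, or any
structural realism — so passing tests demonstrate the correctness of the
bookkeeping, kinetics and statistics machinery, not the accuracy of any
electronic-structure method on real systems.

## Problem sizes

The default suite integrates every packaged network over 10⁴ s, checks
equilibrium against the oracle on all packaged networks plus 100 seeded
synthetic networks (≤ 6 species), validates 1000 generated networks, and
uses 10⁴-label Monte-Carlo sets for the folded-normal checks; the two-path
product-selectivity simulations run to 10⁹/10¹³ s on log grids. These
sizes keep the whole suite under a minute on one core while leaving every
statistical check at least 3σ-resolved.

## Known limitations

* No tunneling, transmission coefficients, diffusion-limit corrections or
  temperature-dependent barriers; rates are pure Eyring images.
* No activity/ionic-strength modeling beyond the explicit chloride pool;
  concentrations are treated as activities on the 1 M scale.
* `equilibrium_state` targets detailed-balanced networks (any network
  built from a single profile qualifies); driven systems with non-zero
  steady cycles would need a different steady-state notion and are out of
  scope.
* The packaged saccharide-pathway networks use continuum-solvation
  energies; conclusions that depend on hybrid-solvation values (absolute
  time scales of the published traces, in particular) are not reproducible
  from the packaged data and are checked as properties instead.
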