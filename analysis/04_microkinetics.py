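#!/usr/bin/env python
"""Microkinetic time courses of the two-path iduronate networks.

Builds mass-action systems from the merged carboxylate+sulfate profiles
(aquation-driven and direct routes) under the study's initial state
(1 mM chloro complex, 5 mM monosaccharide, 1 mM chloride, water clamped
at 55.5 M), integrates them, and reports product selectivity:

* at equilibrium the carboxylate adduct dominates the sulfate adduct by
  the Boltzmann factor of their 5.2 kcal/mol free-energy gap (~6500:1
  aquation route, ~7100:1 direct route);
* on the direct route the sulfate adduct is the kinetic product (its
  transition state lies 4.1 kcal/mol below the carboxylate one) and
  passes through an interior transient maximum before draining into the
  thermodynamic product.

Writes results/timecourse_{aquation,direct}.csv and
results/microkinetics_summary.csv.
"""
import pathlib

import pandas as pd

from platkin import microkin as mk
from platkin.profiles import merge_profiles
from platkin.synthetic import builtin_profiles

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

CO, SO = "IdoA(2S)-CO-PtN3", "IdoA(2S)-SO-PtN3"
profs = builtin_profiles()
summary = []

for route, parts, t_end in [
    ("aquation", ("idoa2s-co-aquation", "idoa2s-so-aquation"), 1e9),
    ("direct", ("idoa2s-co-direct", "idoa2s-so-direct"), 1e13),
]:
    network = merge_profiles(f"idoa2s-{route}-2path", *(profs[p] for p in parts))
    system = mk.network_to_mass_action(
        network, initial=mk.default_initial_concentrations(network))
    tc = mk.simulate(system, t_end=t_end, n_points=100)
    mk.write_timecourse_csv(tc, OUT / f"timecourse_{route}.csv")

    cons = mk.conservation_check(system, tc)
    assert cons["ok"].all(), cons
    eq = mk.equilibrium_state(system)
    ext = mk.species_extremum(tc, SO)
    summary.append({
        "route": route,
        "eq_carboxylate_M": eq[CO],
        "eq_sulfate_M": eq[SO],
        "selectivity_CO_over_SO": eq[CO] / eq[SO],
        "sulfate_transient_max": not ext.monotone,
        "sulfate_peak_time_s": ext.time,
        "max_conservation_drift": cons["max_rel_drift"].max(),
    })
    print(f"{route:9s} route: [CO adduct] = {eq[CO]:.3g} M, "
          f"[SO adduct] = {eq[SO]:.3g} M "
          f"(CO:SO = {eq[CO] / eq[SO]:.0f}:1)")
    if not ext.monotone:
        print(f"           sulfate adduct peaks at t = {ext.time:.3g} s "
              f"({ext.concentration:.3g} M) then decays: kinetic product")
    print(f"           conservation drift <= "
          f"{cons['max_rel_drift'].max():.2e} (Pt, sugar, Cl)")

pd.DataFrame(summary).to_csv(OUT / "microkinetics_summary.csv", index=False)
print(f"\nwrote time courses and {OUT / 'microkinetics_summary.csv'}")
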