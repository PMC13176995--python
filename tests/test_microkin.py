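"""Mass-action network assembly, stiff integration and trace analysis."""

import math

import numpy as np
import pytest

from helpers import boltzmann_equilibrium, keq_equilibrium
from platkin import microkin as mk
from platkin import tst
from platkin.constants import DEFAULT_CONSTANTS
from platkin.microkin import (
    AssocPolicy,
    MassActionSystem,
    Reaction,
    conservation_check,
    default_initial_concentrations,
    equilibrium_state,
    network_to_mass_action,
    parse_reaction_file,
    simulate,
    species_extremum,
    write_reaction_file,
    write_timecourse_csv,
    read_timecourse_csv,
)
from platkin.profiles import (
    ElementaryStep,
    ReactionProfile,
    StationaryPoint,
    merge_profiles,
    profile_from_dict,
    profile_to_dict,
    step_delta_g,
)

RT = DEFAULT_CONSTANTS.rt


def _ab_system(kf=1.0, kr=1.0, a0=1.0, b0=0.0):
    return MassActionSystem(
        species=["A", "B"],
        reactions=[Reaction({"A": 1}, {"B": 1}, kf, kr)],
        initial={"A": a0, "B": b0},
        tags={"A": {"M": 1}, "B": {"M": 1}})


class TestNetworkAssembly:
    def test_ts_steps_get_eyring_rates(self, profiles):
        prof = profiles["aquation-wat6"]
        system = network_to_mass_action(prof)
        rx = next(r for r in system.reactions if r.name == "MS1->MS2")
        assert rx.k_f == pytest.approx(tst.eyring_rate(18.98), rel=1e-12)
        assert rx.k_r == pytest.approx(tst.eyring_rate(21.56), rel=1e-9)

    def test_effective_aquation_rate_scale(self, profiles):
        """Composite chloride/water exchange constant at the 6-water
        hybrid-solvation barrier reproduces the ~2.6e-5 s^-1 scale."""
        prof = profiles["aquation-wat6"]
        system = network_to_mass_action(prof)
        assoc = next(r for r in system.reactions if r.name == "Cl-PtN3->MS1")
        exch = next(r for r in system.reactions if r.name == "MS1->MS2")
        # pre-association Keq on the 1 M standard-state scale; the study's
        # composite applies the Eyring map to the absolute TS energy, i.e.
        # Keq(pre) * k(step) without a solvent-concentration factor
        k_pre = assoc.k_f / assoc.k_r
        assert k_pre * exch.k_f == pytest.approx(tst.eyring_rate(23.71), rel=1e-9)
        assert k_pre * exch.k_f == pytest.approx(2.631e-5, rel=0.02)

    def test_symmetric_step_rates_equal(self):
        prof = ReactionProfile(
            name="sym", reference_label="A",
            points=[StationaryPoint("A", "minimum", 0.0),
                    StationaryPoint("TS", "transition_state", 12.0),
                    StationaryPoint("B", "minimum", 0.0)],
            steps=[ElementaryStep("A", "B", ts_point="TS", dg_forward=12.0)])
        system = network_to_mass_action(prof, fixed={})
        assert system.reactions[0].k_f == pytest.approx(system.reactions[0].k_r)

    def test_rate_ratio_is_keq_for_every_reaction(self, profiles):
        for prof in profiles.values():
            system = network_to_mass_action(prof)
            for rx, step in zip(system.reactions, prof.steps):
                keq = tst.equilibrium_constant(step_delta_g(prof, step))
                assert rx.k_f / rx.k_r == pytest.approx(keq, rel=1e-9), \
                    (prof.name, rx.name)

    def test_inconsistent_profile_refused_with_report(self, profiles):
        d = profile_to_dict(profiles["aquation"])
        for p in d["points"]:
            if p["label"] == "MS1":
                p["g_rel_kcal"] += 1.0
        with pytest.raises(ValueError, match="failed validation"):
            network_to_mass_action(profile_from_dict(d))

    def test_nonconserving_reaction_rejected(self):
        with pytest.raises(ValueError, match="does not conserve"):
            MassActionSystem(
                species=["A", "B"],
                reactions=[Reaction({"A": 1}, {"B": 2}, 1.0, 1.0)],
                tags={"A": {"M": 1}, "B": {"M": 1}})

    def test_study_condition_initial_state(self, profiles):
        init = default_initial_concentrations(profiles["idoa2s-co-aquation"])
        assert init["Cl-PtN3"] == 0.001
        assert init["IdoA(2S)"] == 0.005
        assert init["Cl-"] == 0.001
        assert "H2O" not in init


class TestSimulate:
    def test_symmetric_isomerization_halves(self):
        tc = simulate(_ab_system(), t_end=50.0)
        assert tc.trace("A")[-1] == pytest.approx(0.5, rel=1e-6)
        assert tc.trace("B")[-1] == pytest.approx(0.5, rel=1e-6)

    def test_irreversible_decay_closed_form(self):
        system = MassActionSystem(
            species=["A", "B"],
            reactions=[Reaction({"A": 1}, {"B": 1}, 0.1, 0.0)],
            initial={"A": 1.0})
        tc = simulate(system, t_end=10.0, times=[0.0, 5.0, 10.0])
        assert tc.trace("A")[-1] == pytest.approx(math.exp(-1.0), rel=1e-7)

    def test_equilibrium_ratio_from_free_energy(self):
        keq = tst.equilibrium_constant(-1.23)
        tc = simulate(_ab_system(kf=1.0, kr=1.0 / keq), t_end=100.0)
        assert tc.trace("B")[-1] / tc.trace("A")[-1] == pytest.approx(
            7.97, abs=0.01)

    def test_fixed_species_clamped(self):
        system = MassActionSystem(
            species=["A", "B", "W"],
            reactions=[Reaction({"A": 1, "W": 1}, {"B": 1}, 1.0, 1.0)],
            fixed={"W": 55.5}, initial={"A": 1.0})
        tc = simulate(system, t_end=1.0)
        assert np.all(tc.trace("W") == 55.5)
        # equilibrium: B/A = 55.5
        assert tc.trace("B")[-1] / tc.trace("A")[-1] == pytest.approx(
            55.5, rel=1e-6)

    def test_rate_doubling_rescales_time(self):
        times = np.linspace(0.0, 20.0, 50)[1:]
        base = simulate(_ab_system(kf=0.3, kr=0.1), t_end=20.0,
                        times=np.concatenate([[0.0], times]))
        fast = simulate(_ab_system(kf=0.6, kr=0.2), t_end=10.0,
                        times=np.concatenate([[0.0], times / 2]))
        assert np.allclose(base.conc, fast.conc, rtol=1e-8, atol=1e-12)

    def test_solver_failure_is_diagnostic(self):
        system = _ab_system()
        with pytest.raises(ValueError, match="t_end"):
            simulate(system, t_end=-1.0)

    def test_log_grid_and_metadata(self, profiles):
        system = network_to_mass_action(
            profiles["aquation-wat6"],
            initial=default_initial_concentrations(profiles["aquation-wat6"]))
        tc = simulate(system, t_end=1e4, n_points=80)
        assert np.all(np.diff(tc.times) > 0)
        assert tc.times[0] == 0.0 and tc.times[-1] == 1e4
        assert tc.metadata["system_hash"] == system.content_hash()
        assert np.all(tc.conc >= 0.0)


class TestEquilibriumState:
    def test_matches_long_time_integration_on_toys(self):
        for kf, kr in [(1.0, 1.0), (2.0, 0.5)]:
            system = _ab_system(kf=kf, kr=kr)
            eq = equilibrium_state(system)
            tc = simulate(system, t_end=200.0)
            assert eq["A"] == pytest.approx(tc.trace("A")[-1], rel=1e-6)
            assert eq["B"] == pytest.approx(tc.trace("B")[-1], rel=1e-6)

    def test_zero_conserved_group_stays_empty(self):
        system = MassActionSystem(
            species=["A", "B", "X", "Y"],
            reactions=[Reaction({"A": 1}, {"B": 1}, 1.0, 1.0),
                       Reaction({"X": 1}, {"Y": 1}, 1.0, 1.0)],
            initial={"A": 1.0},
            tags={"A": {"M": 1}, "B": {"M": 1}, "X": {"Q": 1}, "Y": {"Q": 1}})
        eq = equilibrium_state(system)
        assert eq["X"] == 0.0 and eq["Y"] == 0.0
        assert eq["A"] == pytest.approx(0.5, rel=1e-9)

    def test_competing_products_one_to_eight(self):
        """Two products whose free energies differ by RT ln 8 coexist in a
        1:8 equilibrium ratio."""
        ddg = RT * math.log(8.0)
        prof = ReactionProfile(
            name="comp", reference_label="A",
            points=[StationaryPoint("A", "minimum", 0.0),
                    StationaryPoint("TS1", "transition_state", 10.0),
                    StationaryPoint("P_os", "minimum", -1.0),
                    StationaryPoint("TS2", "transition_state", 11.0),
                    StationaryPoint("P_ns", "minimum", -1.0 - ddg)],
            steps=[ElementaryStep("A", "P_os", ts_point="TS1", dg_forward=10.0),
                   ElementaryStep("A", "P_ns", ts_point="TS2", dg_forward=11.0)],
            species_tags={s: {"M": 1} for s in ("A", "P_os", "P_ns")})
        eq = equilibrium_state(network_to_mass_action(
            prof, fixed={}, initial={"A": 0.006}))
        assert eq["P_ns"] / eq["P_os"] == pytest.approx(8.0, rel=1e-9)

    def test_agrees_with_keq_oracle_on_fixture(self, profiles):
        prof = profiles["glcns6s-os-aquation"]
        init = default_initial_concentrations(prof)
        eq = equilibrium_state(network_to_mass_action(prof, initial=init))
        oracle = keq_equilibrium(prof, init)
        for sp, ref in oracle.items():
            assert eq[sp] == pytest.approx(ref, rel=1e-6), sp


class TestTraceAnalysis:
    def test_sequential_chain_intermediate_maximum(self):
        """A -> B -> C with equal rates: [B] peaks at t = 1/k."""
        k = 0.01
        system = MassActionSystem(
            species=["A", "B", "C"],
            reactions=[Reaction({"A": 1}, {"B": 1}, k, 0.0),
                       Reaction({"B": 1}, {"C": 1}, k, 0.0)],
            initial={"A": 1.0})
        tc = simulate(system, t_end=1000.0,
                      times=np.linspace(0.0, 1000.0, 2001))
        ext = species_extremum(tc, "B")
        assert not ext.monotone
        assert ext.time == pytest.approx(1.0 / k, rel=0.02)
        assert ext.concentration == pytest.approx(math.exp(-1.0), rel=0.01)

    def test_monotone_trace_flagged(self):
        tc = simulate(_ab_system(), t_end=30.0)
        ext = species_extremum(tc, "B")
        assert ext.monotone
        assert ext.time == tc.times[-1]

    def test_unknown_species_rejected(self):
        tc = simulate(_ab_system(), t_end=1.0)
        with pytest.raises(KeyError):
            species_extremum(tc, "nope")

    def test_kinetic_product_overshoots_thermodynamic(self):
        """Low-barrier/high-dG vs high-barrier/low-dG competition: the
        kinetic product passes through an interior maximum and decays
        toward its small equilibrium share (dense-grid cross-check)."""
        prof = ReactionProfile(
            name="kin-thermo", reference_label="A",
            points=[StationaryPoint("A", "minimum", 0.0),
                    StationaryPoint("TSk", "transition_state", 15.0),
                    StationaryPoint("P_kin", "minimum", -1.0),
                    StationaryPoint("TSt", "transition_state", 18.0),
                    StationaryPoint("P_thermo", "minimum", -5.0)],
            steps=[ElementaryStep("A", "P_kin", ts_point="TSk", dg_forward=15.0),
                   ElementaryStep("A", "P_thermo", ts_point="TSt", dg_forward=18.0)],
            species_tags={s: {"M": 1} for s in ("A", "P_kin", "P_thermo")})
        system = network_to_mass_action(prof, fixed={}, initial={"A": 0.001})
        tc = simulate(system, t_end=1e3, n_points=400)
        ext = species_extremum(tc, "P_kin")
        assert not ext.monotone
        assert ext.concentration > 2.0 * tc.trace("P_kin")[-1]
        # dense linear grid around the peak confirms the refined location
        dense = simulate(system, t_end=2 * ext.time,
                         times=np.linspace(0, 2 * ext.time, 4001))
        i = int(np.argmax(dense.trace("P_kin")))
        assert ext.time == pytest.approx(dense.times[i], rel=0.05)
        # thermodynamic product wins in the end
        assert tc.trace("P_thermo")[-1] > 50 * tc.trace("P_kin")[-1]


class TestConservation:
    def test_fixture_run_drift_below_tolerance(self, profiles):
        prof = profiles["idoa2s-so-aquation"]
        system = network_to_mass_action(
            prof, initial=default_initial_concentrations(prof))
        tc = simulate(system, t_end=1e4)
        report = conservation_check(system, tc)
        assert set(report["group"]) == {"Pt", "Cl", "sugar"}
        assert report["ok"].all()
        assert (report["max_rel_drift"] < 1e-6).all()

    def test_untagged_system_uses_stoichiometric_invariants(self):
        system = MassActionSystem(
            species=["A", "B"],
            reactions=[Reaction({"A": 1}, {"B": 1}, 1.0, 1.0)],
            initial={"A": 1.0})
        tc = simulate(system, t_end=10.0)
        report = conservation_check(system, tc)
        assert len(report) == 1
        assert report["ok"].all()

    def test_empty_time_course_empty_report(self):
        system = _ab_system()
        tc = mk.TimeCourse(times=np.array([]), conc=np.zeros((2, 0)),
                           species=["A", "B"])
        assert conservation_check(system, tc).empty


class TestReactionFileFormat:
    def test_round_trip(self, tmp_path, profiles):
        prof = profiles["idoa2s-co-direct"]
        system = network_to_mass_action(
            prof, initial=default_initial_concentrations(prof))
        path = tmp_path / "network.rxn"
        write_reaction_file(system, path)
        back = parse_reaction_file(path)
        assert set(back.species) == set(system.species)
        assert back.fixed == system.fixed
        assert back.initial == system.initial
        assert back.tags == system.tags
        for rx0, rx1 in zip(system.reactions, back.reactions):
            assert rx1.reactants == rx0.reactants
            assert rx1.products == rx0.products
            assert rx1.k_f == rx0.k_f and rx1.k_r == rx0.k_r

    def test_parse_minimal_dialect(self, tmp_path):
        path = tmp_path / "sys.rxn"
        path.write_text(
            "# toy system\n"
            "A + B <=> C ; kf=1e9 ; kr=2.5\n"
            "FIX B 55.5\n"
            "INIT A 0.001\n"
            "TAG A M:1\nTAG C M:1\n")
        system = parse_reaction_file(path)
        assert system.reactions[0].reactants == {"A": 1, "B": 1}
        assert system.fixed == {"B": 55.5}
        assert system.tags["C"] == {"M": 1}

    def test_bad_line_reports_location(self, tmp_path):
        path = tmp_path / "bad.rxn"
        path.write_text("A -> B\n")
        with pytest.raises(ValueError, match="bad.rxn:1"):
            parse_reaction_file(path)

    def test_timecourse_csv_round_trip(self, tmp_path):
        tc = simulate(_ab_system(), t_end=5.0, n_points=40)
        path = tmp_path / "tc.csv"
        write_timecourse_csv(tc, path)
        back = read_timecourse_csv(path)
        assert back.species == tc.species
        assert np.allclose(back.times, tc.times)
        assert np.allclose(back.conc, tc.conc)
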