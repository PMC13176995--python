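"""Free-energy-profile data model and bookkeeping.

A :class:`ReactionProfile` is an ordered collection of stationary points
(minima, transition states, infinitely separated species) on a ligand
substitution free-energy surface, all referenced to one zero-energy
species set (here conventionally the intact chloro complex plus free
ligands), together with the elementary steps connecting them.

Energies are stored *relative* to the profile reference, in kcal/mol.
The module provides the thermochemical composition rules used to build
such profiles from electronic-structure output (Born-Oppenheimer energy
plus solvation and thermal corrections, with the 1 atm -> 1 mol/L
standard-state change), barrier arithmetic (absolute transition-state
energies, reverse barriers, step reaction free energies), and an
internal-consistency validator.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .constants import R_JOULE, ATM_PA, DEFAULT_CONSTANTS

__all__ = [
    "IncompleteThermochemistryError",
    "InconsistentProfileError",
    "ThermoComponents",
    "StationaryPoint",
    "ElementaryStep",
    "ReactionProfile",
    "ValidationIssue",
    "ValidationReport",
    "gibbs_in_solution",
    "enthalpy_in_solution",
    "standard_state_correction",
    "ts_absolute_energy",
    "reverse_barrier",
    "step_delta_g",
    "validate_profile",
    "merge_profiles",
    "read_profile_json",
    "write_profile_json",
    "read_profile_csv",
    "write_profile_csv",
]

#: Self-consistency tolerance (kcal/mol) for profiles transcribed from
#: one-decimal published values; rounding makes identities hold only to
#: ~0.1 kcal/mol (e.g. 4.5 + 24.8 - 11.2 = 18.1 against a printed 18.0).
PRINTED_TOL = 0.15

MINIMUM = "minimum"
TRANSITION_STATE = "transition_state"
SEPARATED = "separated_species"
_KINDS = (MINIMUM, TRANSITION_STATE, SEPARATED)


class IncompleteThermochemistryError(ValueError):
    """A thermochemical composition was requested with missing terms."""


class InconsistentProfileError(ValueError):
    """Barrier arithmetic contradicts the stored stationary-point energies."""


# ---------------------------------------------------------------------------
# thermochemical composition
# ---------------------------------------------------------------------------

@dataclass
class ThermoComponents:
    """Energy terms composing one stationary point, all in kcal/mol.

    ``e_bo`` is the gas-phase Born-Oppenheimer energy, the sum of the
    electronic energy ``e_el`` and nuclear repulsion ``v_nn``; either
    supply ``e_bo`` directly or both parts.  ``dg_solv``/``dh_solv`` are
    continuum-solvation contributions, ``g_n``/``h_n`` harmonic thermal
    corrections, and ``std_state`` the 1 atm -> 1 mol/L standard-state
    change (1.89 kcal/mol at 298.15 K).
    """

    e_bo: Optional[float] = None
    e_el: Optional[float] = None
    v_nn: Optional[float] = None
    dg_solv: Optional[float] = None
    g_n: Optional[float] = None
    h_n: Optional[float] = None
    dh_solv: Optional[float] = None
    std_state: float = 1.89

    def __post_init__(self) -> None:
        if self.std_state < 0:
            raise ValueError("std_state must be non-negative")
        if self.e_el is not None and self.v_nn is not None:
            composed = self.e_el + self.v_nn
            if self.e_bo is None:
                self.e_bo = composed
            elif abs(self.e_bo - composed) > 1e-9:
                raise ValueError(
                    f"e_bo={self.e_bo} inconsistent with e_el+v_nn={composed}"
                )


def _require(c: ThermoComponents, names: Iterable[str]) -> None:
    missing = [n for n in names if getattr(c, n) is None]
    if missing:
        raise IncompleteThermochemistryError(
            "incomplete thermochemistry: missing " + ", ".join(missing)
        )


def gibbs_in_solution(c: ThermoComponents) -> float:
    """Solution-phase Gibbs energy: E_BO + dG_solv + G_n + std_state."""
    _require(c, ("e_bo", "dg_solv", "g_n"))
    return c.e_bo + c.dg_solv + c.g_n + c.std_state


def enthalpy_in_solution(c: ThermoComponents) -> float:
    """Solution-phase enthalpy: E_BO + dH_solv + H_n (no standard-state term)."""
    _require(c, ("e_bo", "dh_solv", "h_n"))
    return c.e_bo + c.dh_solv + c.h_n


def standard_state_correction(temperature: float = 298.15) -> float:
    """Free-energy change (kcal/mol) of moving 1 atm gas to 1 mol/L solution.

    R*T*ln(V_m / (1 L/mol)) with V_m = R*T/(1 atm) the ideal-gas molar
    volume; 1.89 kcal/mol at 298.15 K.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    v_m_litre = R_JOULE * temperature / ATM_PA * 1e3
    return DEFAULT_CONSTANTS.r_gas * temperature * math.log(v_m_litre)


# ---------------------------------------------------------------------------
# stationary points, steps, profiles
# ---------------------------------------------------------------------------

@dataclass
class StationaryPoint:
    label: str
    kind: str
    g_rel: float
    explicit_waters: int = 0
    components: Optional[ThermoComponents] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stationary-point kind {self.kind!r}")
        if self.explicit_waters < 0:
            raise ValueError("explicit_waters must be >= 0")


@dataclass
class ElementaryStep:
    """A reversible transformation between two minima.

    ``ts_point`` is absent for barrierless association/dissociation steps
    (formation of encounter complexes, removal of a ligand to infinite
    separation), which carry only a reaction free energy given by their
    endpoints.  ``consumed``/``released`` are stoichiometric maps of free
    species entering/leaving in the forward direction (e.g. ``{"H2O": 1}``).
    """

    from_point: str
    to_point: str
    ts_point: Optional[str] = None
    dg_forward: Optional[float] = None
    consumed: Mapping[str, float] = field(default_factory=dict)
    released: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ts_point is not None:
            if self.dg_forward is None:
                raise ValueError(f"step {self.key} has a TS but no forward barrier")
            if self.dg_forward < 0:
                raise ValueError(f"step {self.key}: dg_forward must be >= 0")

    @property
    def key(self) -> str:
        return f"{self.from_point}->{self.to_point}"

    @property
    def barrierless(self) -> bool:
        return self.ts_point is None

    @property
    def molecularity(self) -> int:
        return 2 if self.consumed else 1


@dataclass
class ReactionProfile:
    name: str
    reference_label: str
    points: list[StationaryPoint] = field(default_factory=list)
    steps: list[ElementaryStep] = field(default_factory=list)
    temperature: float = 298.15
    species_tags: dict[str, dict[str, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate point labels: {sorted(dupes)}")
        self._index = {p.label: p for p in self.points}

    def point(self, label: str) -> StationaryPoint:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no stationary point labeled {label!r} in {self.name}")

    def g(self, label: str) -> float:
        """Relative Gibbs energy (kcal/mol) of a labeled point."""
        return self.point(label).g_rel

    @property
    def minima(self) -> list[StationaryPoint]:
        return [p for p in self.points if p.kind != TRANSITION_STATE]

    def step_between(self, from_point: str, to_point: str) -> ElementaryStep:
        for s in self.steps:
            if s.from_point == from_point and s.to_point == to_point:
                return s
        raise KeyError(f"no step {from_point}->{to_point} in {self.name}")


# ---------------------------------------------------------------------------
# barrier arithmetic
# ---------------------------------------------------------------------------

def ts_absolute_energy(profile: ReactionProfile, step: ElementaryStep) -> float:
    """Transition-state energy relative to the profile reference.

    Computed as g_rel(from_point) + forward barrier, i.e. the barrier is
    re-referenced from the preceding minimum to the global zero (the way
    "23.40 relative to the chloro complex" relates to a 28.32 step
    barrier from a -4.92 encounter complex).
    """
    if step.barrierless:
        raise InconsistentProfileError(f"step {step.key} has no transition state")
    return profile.g(step.from_point) + step.dg_forward


def reverse_barrier(
    profile: ReactionProfile, step: ElementaryStep, tol: float = PRINTED_TOL
) -> float:
    """Backward activation energy: TS absolute energy minus g_rel(to_point)."""
    rev = ts_absolute_energy(profile, step) - profile.g(step.to_point)
    if rev < -tol:
        raise InconsistentProfileError(
            f"inconsistent profile: step {step.key} has negative reverse "
            f"barrier {rev:.3f} kcal/mol"
        )
    return rev


def step_delta_g(profile: ReactionProfile, step: ElementaryStep) -> float:
    """Reaction free energy of one step: g_rel(to) - g_rel(from).

    For a TS-mediated step this equals forward minus reverse barrier.
    """
    return profile.g(step.to_point) - profile.g(step.from_point)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    kind: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def kinds(self) -> set[str]:
        return {i.kind for i in self.issues}

    def __str__(self) -> str:
        if self.ok:
            return "profile consistent"
        return "\n".join(str(i) for i in self.issues)


def validate_profile(profile: ReactionProfile, tol: float = PRINTED_TOL) -> ValidationReport:
    """Check a profile's internal consistency; report, never raise.

    Flags: missing step endpoints, TS-energy/barrier mismatches beyond
    ``tol``, negative reverse barriers, transition states not referenced
    by exactly one step, and minima unreachable from the reference.
    """
    issues: list[ValidationIssue] = []
    report = ValidationReport(issues)
    labels = {p.label for p in profile.points}

    if profile.reference_label not in labels and profile.points:
        issues.append(ValidationIssue(
            "missing_reference", profile.reference_label,
            "reference label is not a stationary point"))

    ts_refs: dict[str, int] = {
        p.label: 0 for p in profile.points if p.kind == TRANSITION_STATE
    }
    for s in profile.steps:
        missing = [l for l in (s.from_point, s.to_point) if l not in labels]
        if s.ts_point is not None and s.ts_point not in labels:
            missing.append(s.ts_point)
        if missing:
            issues.append(ValidationIssue(
                "missing_point", s.key, f"unknown labels {missing}"))
            continue
        if s.ts_point is not None:
            ts_refs[s.ts_point] = ts_refs.get(s.ts_point, 0) + 1
            ts_g = profile.g(s.ts_point)
            implied = profile.g(s.from_point) + s.dg_forward
            if abs(ts_g - implied) > tol:
                issues.append(ValidationIssue(
                    "barrier_mismatch", s.key,
                    f"TS energy {ts_g:.3f} != from + barrier {implied:.3f}"))
            rev = implied - profile.g(s.to_point)
            if rev < -tol:
                issues.append(ValidationIssue(
                    "negative_reverse_barrier", s.key,
                    f"reverse barrier {rev:.3f} kcal/mol"))
            # round-trip identity dG = dG_fwd - dG_rev, on stored TS energy
            ident = s.dg_forward - (ts_g - profile.g(s.to_point))
            if abs(step_delta_g(profile, s) - ident) > tol:
                issues.append(ValidationIssue(
                    "step_identity", s.key,
                    "step dG inconsistent with forward - reverse barriers"))

    for ts_label, n in ts_refs.items():
        if n != 1:
            issues.append(ValidationIssue(
                "ts_reference_count", ts_label,
                f"transition state referenced by {n} steps (expected 1)"))

    # connectivity: undirected reachability over steps, from the reference
    if profile.reference_label in labels:
        adjacency: dict[str, set[str]] = {l: set() for l in labels}
        for s in profile.steps:
            if s.from_point in labels and s.to_point in labels:
                adjacency[s.from_point].add(s.to_point)
                adjacency[s.to_point].add(s.from_point)
                if s.ts_point in labels:
                    adjacency[s.from_point].add(s.ts_point)
                    adjacency[s.ts_point].add(s.to_point)
        seen = {profile.reference_label}
        stack = [profile.reference_label]
        while stack:
            for nb in adjacency[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        for p in profile.points:
            if p.label not in seen:
                issues.append(ValidationIssue(
                    "unreachable", p.label,
                    "not connected to the reference through any step"))
    return report


def merge_profiles(name: str, *profiles: ReactionProfile) -> ReactionProfile:
    """Union of several profiles sharing a reference (e.g. two branches).

    Points with identical labels must agree in energy to 1e-9 kcal/mol;
    duplicate steps are kept once.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0].reference_label
    temp = profiles[0].temperature
    points: dict[str, StationaryPoint] = {}
    steps: dict[tuple, ElementaryStep] = {}
    tags: dict[str, dict[str, int]] = {}
    for pr in profiles:
        if pr.reference_label != ref:
            raise ValueError("profiles do not share a reference")
        for p in pr.points:
            if p.label in points:
                if abs(points[p.label].g_rel - p.g_rel) > 1e-9:
                    raise ValueError(
                        f"conflicting energies for shared point {p.label!r}")
            else:
                points[p.label] = p
        for s in pr.steps:
            steps.setdefault((s.from_point, s.to_point, s.ts_point), s)
        tags.update(pr.species_tags)
    return ReactionProfile(
        name=name, reference_label=ref, temperature=temp,
        points=list(points.values()), steps=list(steps.values()),
        species_tags=tags)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _species_to_str(m: Mapping[str, float]) -> str:
    return ";".join(
        f"{sp}:{int(n) if float(n).is_integer() else n}" for sp, n in m.items())


def _species_from_str(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in filter(None, (p.strip() for p in s.split(";"))):
        sp, _, n = part.partition(":")
        out[sp] = float(n) if n else 1.0
    return out


def profile_to_dict(profile: ReactionProfile) -> dict:
    return {
        "name": profile.name,
        "reference_label": profile.reference_label,
        "temperature": profile.temperature,
        "points": [
            {
                "label": p.label,
                "kind": p.kind,
                "g_rel_kcal": p.g_rel,
                "explicit_waters": p.explicit_waters,
                **({"meta": p.meta} if p.meta else {}),
            }
            for p in profile.points
        ],
        "steps": [
            {
                "from": s.from_point,
                "ts": s.ts_point,
                "to": s.to_point,
                "dg_forward_kcal": s.dg_forward,
                "consumed": _species_to_str(s.consumed),
                "released": _species_to_str(s.released),
            }
            for s in profile.steps
        ],
        "species_tags": profile.species_tags,
        "meta": profile.meta,
    }


def profile_from_dict(d: dict) -> ReactionProfile:
    points = [
        StationaryPoint(
            label=p["label"], kind=p["kind"], g_rel=float(p["g_rel_kcal"]),
            explicit_waters=int(p.get("explicit_waters", 0)),
            meta=p.get("meta", {}))
        for p in d["points"]
    ]
    steps = [
        ElementaryStep(
            from_point=s["from"], to_point=s["to"], ts_point=s.get("ts"),
            dg_forward=(None if s.get("dg_forward_kcal") is None
                        else float(s["dg_forward_kcal"])),
            consumed=_species_from_str(s.get("consumed", "")),
            released=_species_from_str(s.get("released", "")))
        for s in d["steps"]
    ]
    return ReactionProfile(
        name=d["name"], reference_label=d["reference_label"],
        temperature=float(d.get("temperature", 298.15)),
        points=points, steps=steps,
        species_tags={k: dict(v) for k, v in d.get("species_tags", {}).items()},
        meta=d.get("meta", {}))


def write_profile_json(profile: ReactionProfile, path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_dict(profile), fh, indent=1)
        fh.write("\n")


def read_profile_json(path) -> ReactionProfile:
    with open(path) as fh:
        return profile_from_dict(json.load(fh))


def write_profile_csv(profile: ReactionProfile, points_path, steps_path) -> None:
    """Two-file CSV export: points and steps.

    The CSV carries the per-point and per-step fields only; name,
    reference, temperature, tags and flags live in the JSON format.
    """
    with open(points_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "kind", "g_rel_kcal", "explicit_waters"])
        for p in profile.points:
            w.writerow([p.label, p.kind, repr(p.g_rel), p.explicit_waters])
    with open(steps_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "ts", "to", "dg_forward_kcal", "consumed", "released"])
        for s in profile.steps:
            w.writerow([
                s.from_point, s.ts_point or "", s.to_point,
                "" if s.dg_forward is None else repr(s.dg_forward),
                _species_to_str(s.consumed), _species_to_str(s.released)])


def read_profile_csv(points_path, steps_path, name: str | None = None,
                     reference_label: str | None = None,
                     temperature: float = 298.15) -> ReactionProfile:
    points: list[StationaryPoint] = []
    with open(points_path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(StationaryPoint(
                label=row["label"], kind=row["kind"],
                g_rel=float(row["g_rel_kcal"]),
                explicit_waters=int(row.get("explicit_waters") or 0)))
    steps: list[ElementaryStep] = []
    with open(steps_path, newline="") as fh:
        for row in csv.DictReader(fh):
            steps.append(ElementaryStep(
                from_point=row["from"], to_point=row["to"],
                ts_point=row["ts"] or None,
                dg_forward=float(row["dg_forward_kcal"]) if row["dg_forward_kcal"] else None,
                consumed=_species_from_str(row.get("consumed", "")),
                released=_species_from_str(row.get("released", ""))))
    if reference_label is None:
        # default: the first zero-energy separated/minimum point
        zero = [p for p in points if abs(p.g_rel) < 1e-12]
        reference_label = (zero[0] if zero else points[0]).label
    import os
    return ReactionProfile(
        name=name or os.path.splitext(os.path.basename(str(points_path)))[0],
        reference_label=reference_label, temperature=temperature,
        points=points, steps=steps)
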