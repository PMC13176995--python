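"""Synthetic reaction networks, noisy method-energy sets, and the
packaged literature free-energy profiles.

:func:`generate_network` draws thermodynamically consistent profiles
(state energies plus barriers obeying dG_step = dG_fwd - dG_rev, with
branch-and-rejoin cycles closing exactly because energies are state
functions).  :func:`perturb_method_energies` emulates the spread of DFT
functionals around a reference by adding method-specific bias and
Gaussian scatter, for which the expected MAD has the folded-normal
closed form.  :func:`builtin_profiles` loads the packaged substitution
profiles of the Pt(II) chloro complex with the two heparan-sulfate
monosaccharide models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .benchmark import MethodEnergySet
from .profiles import (
    MINIMUM,
    TRANSITION_STATE,
    ElementaryStep,
    ReactionProfile,
    StationaryPoint,
    profile_from_dict,
)

__all__ = [
    "NetworkSpec",
    "NoiseSpec",
    "generate_network",
    "perturb_method_energies",
    "expected_folded_normal_mad",
    "builtin_profiles",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a random, internally consistent reaction network.

    A backbone chain of ``n_minima`` minima (the first is the zero
    reference) is decorated with ``n_branches`` branch-and-rejoin
    detours of one intermediate minimum each.  Minima energies are drawn
    uniformly from ``energy_range``; each transition state sits
    ``barrier_range``-uniform above the higher endpoint, so both
    directed barriers are non-negative by construction.  A
    ``barrierless_fraction`` of steps is left without a TS.
    """

    n_minima: int = 5
    n_branches: int = 0
    energy_range: tuple[float, float] = (-10.0, 15.0)
    barrier_range: tuple[float, float] = (5.0, 25.0)
    barrierless_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minima < 2:
            raise ValueError("need at least two minima")
        if self.energy_range[0] > self.energy_range[1]:
            raise ValueError("empty energy range")
        if self.barrier_range[0] > self.barrier_range[1] or self.barrier_range[0] < 0:
            raise ValueError("barrier range must be non-negative and ordered")
        if not 0 <= self.barrierless_fraction <= 1:
            raise ValueError("barrierless_fraction must be in [0, 1]")
        if self.n_branches > 0 and self.n_minima < 3:
            raise ValueError("branches need a backbone of >= 3 minima")


def generate_network(spec: NetworkSpec) -> ReactionProfile:
    """Sample a consistent random profile; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.energy_range
    energies = [0.0] + list(rng.uniform(lo, hi, spec.n_minima - 1))
    labels = [f"M{i}" for i in range(spec.n_minima)]
    points = [
        StationaryPoint(l, MINIMUM if i else "separated_species", g)
        for i, (l, g) in enumerate(zip(labels, energies))
    ]
    steps: list[ElementaryStep] = []
    n_ts = 0

    def add_step(a: str, b: str) -> None:
        nonlocal n_ts
        g_a = next(p.g_rel for p in points if p.label == a)
        g_b = next(p.g_rel for p in points if p.label == b)
        if rng.uniform() < spec.barrierless_fraction:
            steps.append(ElementaryStep(from_point=a, to_point=b))
            return
        n_ts += 1
        ts_label = f"TS{n_ts}"
        extra = rng.uniform(*spec.barrier_range)
        ts_g = max(g_a, g_b) + extra
        points.append(StationaryPoint(ts_label, TRANSITION_STATE, ts_g))
        steps.append(ElementaryStep(
            from_point=a, to_point=b, ts_point=ts_label,
            dg_forward=ts_g - g_a))

    for a, b in zip(labels, labels[1:]):
        add_step(a, b)
    for k in range(spec.n_branches):
        i = int(rng.integers(0, spec.n_minima - 1))
        j = int(rng.integers(i + 1, spec.n_minima))
        mid = f"B{k}"
        points.append(StationaryPoint(mid, MINIMUM, float(rng.uniform(lo, hi))))
        add_step(labels[i], mid)
        add_step(mid, labels[j])

    tags = {p.label: {"M": 1} for p in points if p.kind != TRANSITION_STATE}
    return ReactionProfile(
        name=f"synthetic-{spec.seed}", reference_label=labels[0],
        points=points, steps=steps, species_tags=tags,
        meta={"spec": spec.__dict__.copy()})


@dataclass(frozen=True)
class NoiseSpec:
    """Per-method bias and Gaussian scatter (kcal/mol) around the reference."""

    biases: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for m, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"negative scatter sd for {m!r}")


def perturb_method_energies(
    profile: ReactionProfile | Mapping[str, float],
    noise: NoiseSpec,
    reference_name: str = "reference",
) -> tuple[MethodEnergySet, dict[str, MethodEnergySet]]:
    """Reference plus biased/noisy copies of a profile's energies.

    ``profile`` may be a :class:`ReactionProfile` or a plain
    label -> energy mapping.  Each method's energy for a label is
    ``exact + bias + N(0, sd)``, so the expected MAD against the
    reference is the folded-normal mean
    ``sd*sqrt(2/pi)*exp(-b^2/(2 sd^2)) + b*(1 - 2*Phi(-b/sd))``.
    """
    if isinstance(profile, ReactionProfile):
        exact = {p.label: p.g_rel for p in profile.points}
    else:
        exact = dict(profile)
    labels = list(exact)
    rng = np.random.default_rng(noise.seed)
    reference = MethodEnergySet(reference_name, dict(exact))
    methods: dict[str, MethodEnergySet] = {}
    names = sorted(set(noise.biases) | set(noise.sds))
    for m in names:
        b = noise.biases.get(m, 0.0)
        sd = noise.sds.get(m, 0.0)
        eps = rng.normal(0.0, sd, len(labels)) if sd > 0 else np.zeros(len(labels))
        methods[m] = MethodEnergySet(
            m, {l: exact[l] + b + e for l, e in zip(labels, eps)})
    return reference, methods


def expected_folded_normal_mad(bias: float, sd: float) -> float:
    """E|N(bias, sd)|, the asymptotic MAD of a biased noisy method."""
    from math import erf, exp, pi, sqrt
    if sd == 0:
        return abs(bias)
    phi = 0.5 * (1.0 + erf((-bias / sd) / sqrt(2.0)))
    return sd * sqrt(2.0 / pi) * exp(-bias**2 / (2 * sd**2)) + bias * (1 - 2 * phi)


# ---------------------------------------------------------------------------
# packaged literature profiles
# ---------------------------------------------------------------------------

def builtin_profiles() -> dict[str, ReactionProfile]:
    """The packaged substitution free-energy profiles.

    Twelve profiles, all referenced to the intact chloro complex plus
    free ligands at 298.15 K: the aquation step (one-decimal in-text
    values plus a two-decimal continuum-only set and its 3- and 6-water
    hybrid-solvation variants), the four aquation-driven saccharide
    substitution paths, and the four direct substitution paths.
    Transcription notes (sign-typo flags, reference ambiguities, missing
    printed values) ride along in each profile's ``meta``.
    """
    out: dict[str, ReactionProfile] = {}
    data_dir = resources.files("platkin").joinpath("data")
    for entry in sorted(data_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".json"):
            prof = profile_from_dict(json.loads(entry.read_text()))
            out[prof.name] = prof
    return out
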