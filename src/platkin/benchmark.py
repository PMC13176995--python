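"""Method-comparison statistics for stationary-point energy sets.

Compares per-point relative energies of electronic-structure methods
against a reference method (in the study, DLPNO-CCSD(T)): signed
deviations per stationary point, mean absolute deviations (MAD) overall
and grouped by reaction step, rankings, and percent-improvement ratios.

MAD is the unweighted arithmetic mean of absolute deviations over the
stationary points shared by both sets; since all energies are relative,
the statistics are invariant under a common additive shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MethodEnergySet",
    "DeviationReport",
    "RankResult",
    "deviations",
    "rank_methods",
    "improvement_pct",
    "format_improvement",
    "read_method_csv",
    "write_method_csv",
]


@dataclass
class MethodEnergySet:
    """Relative energies (kcal/mol) per stationary-point label for one method."""

    method: str
    energies: dict[str, float]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.energies:
            raise ValueError(f"method {self.method!r} has no energies")


@dataclass
class DeviationReport:
    method: str
    reference: str
    deviations: dict[str, float]          # method - reference, per label
    group_mad: dict[str, float]
    overall_mad: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"label": l, "deviation_kcal": d} for l, d in self.deviations.items()])


def deviations(method: MethodEnergySet, reference: MethodEnergySet) -> DeviationReport:
    """Signed per-label deviations and MADs of a method against a reference.

    Restricted to the labels both sets share; raises if the overlap is
    empty.
    """
    labels = [l for l in method.energies if l in reference.energies]
    if not labels:
        raise ValueError(
            f"no overlapping labels between {method.method!r} and "
            f"{reference.method!r}")
    devs = {l: method.energies[l] - reference.energies[l] for l in labels}
    groups: dict[str, list[float]] = {}
    group_of = {**reference.group_of, **method.group_of}
    for l, d in devs.items():
        g = group_of.get(l)
        if g is not None:
            groups.setdefault(g, []).append(abs(d))
    return DeviationReport(
        method=method.method,
        reference=reference.method,
        deviations=devs,
        group_mad={g: sum(v) / len(v) for g, v in sorted(groups.items())},
        overall_mad=sum(abs(d) for d in devs.values()) / len(devs),
        n=len(devs),
    )


@dataclass
class RankResult:
    order: list[str]                       # method names, best (lowest MAD) first
    mads: dict[str, float]
    ties: list[tuple[str, str]] = field(default_factory=list)


def rank_methods(reports: Sequence[DeviationReport]) -> RankResult:
    """Order methods by overall MAD ascending; ties alphabetical and flagged."""
    if not reports:
        raise ValueError("need at least one report")
    ranked = sorted(reports, key=lambda r: (r.overall_mad, r.method))
    ties = [
        (a.method, b.method)
        for a, b in zip(ranked, ranked[1:])
        if a.overall_mad == b.overall_mad
    ]
    return RankResult(
        order=[r.method for r in ranked],
        mads={r.method: r.overall_mad for r in ranked},
        ties=ties,
    )


def improvement_pct(mad_worse: float, mad_better: float) -> float:
    """Percent improvement of one MAD over another: (worse/better - 1)*100.

    An improvement above 100% means the deviation more than halved.
    """
    if mad_better <= 0:
        raise ValueError("mad_better must be positive")
    return (mad_worse / mad_better - 1.0) * 100.0


def format_improvement(pct: float) -> int:
    """Display rounding, half away from zero (117.6 -> 118)."""
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


# ---------------------------------------------------------------------------
# CSV format: method,label,group,energy_kcal
# ---------------------------------------------------------------------------

def read_method_csv(path) -> dict[str, MethodEnergySet]:
    df = pd.read_csv(path)
    out: dict[str, MethodEnergySet] = {}
    for m, sub in df.groupby("method", sort=False):
        energies = dict(zip(sub["label"], sub["energy_kcal"].astype(float)))
        group_of = {
            l: g for l, g in zip(sub["label"], sub.get("group", pd.Series(dtype=object)))
            if isinstance(g, str) and g
        }
        out[str(m)] = MethodEnergySet(str(m), energies, group_of)
    return out


def write_method_csv(sets: Mapping[str, MethodEnergySet] | Sequence[MethodEnergySet],
                     path) -> None:
    if isinstance(sets, Mapping):
        sets = list(sets.values())
    rows = [
        {"method": s.method, "label": l, "group": s.group_of.get(l, ""),
         "energy_kcal": e}
        for s in sets for l, e in s.energies.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
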