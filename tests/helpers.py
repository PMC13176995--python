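"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the equilibrium
oracle works from step equilibrium constants and conservation
constraints only (never from rate constants or ODE integration), and
the unimolecular oracle is a Boltzmann closed form.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import root

from platkin.constants import DEFAULT_CONSTANTS
from platkin.profiles import ReactionProfile, step_delta_g


def boltzmann_equilibrium(profile: ReactionProfile, total: float) -> dict[str, float]:
    """Closed-form equilibrium of a purely unimolecular network.

    Every state's concentration is proportional to exp(-G/RT); the
    proportionality constant comes from the conserved total.
    """
    consts = DEFAULT_CONSTANTS.at_temperature(profile.temperature)
    states = [p for p in profile.points if p.kind != "transition_state"]
    w = {p.label: math.exp(-p.g_rel / consts.rt) for p in states}
    z = sum(w.values())
    return {l: total * wi / z for l, wi in w.items()}


def keq_equilibrium(profile: ReactionProfile, initial: dict[str, float],
                    fixed: dict[str, float] | None = None) -> dict[str, float]:
    """Solve the mass-action equilibrium from Keq + conservation alone.

    Per step (with fixed-species activities folded in):
        sum_s nu_s ln c_s = ln Keq  =>  linear in ln c.
    The solution manifold is a particular solution plus the span of the
    conserved-moiety directions W (the left null space of the reaction
    stoichiometry); the remaining degrees of freedom are pinned by the
    nonlinear conservation equations W^T exp(ln c) = W^T c0, solved by a
    small root-find.
    """
    consts = DEFAULT_CONSTANTS.at_temperature(profile.temperature)
    if fixed is None:
        fixed = {"H2O": consts.water_conc}

    species: list[str] = [p.label for p in profile.points
                          if p.kind != "transition_state"]
    for s in profile.steps:
        for sp in list(s.consumed) + list(s.released):
            if sp not in fixed and sp not in species:
                species.append(sp)
    idx = {sp: i for i, sp in enumerate(species)}

    rows, rhs = [], []
    for s in profile.steps:
        nu = np.zeros(len(species))
        b = -step_delta_g(profile, s) / consts.rt  # ln Keq
        nu[idx[s.from_point]] -= 1
        nu[idx[s.to_point]] += 1
        for sp, n in s.consumed.items():
            if sp in fixed:
                b += n * math.log(fixed[sp])
            else:
                nu[idx[sp]] -= n
        for sp, n in s.released.items():
            if sp in fixed:
                b -= n * math.log(fixed[sp])
            else:
                nu[idx[sp]] += n
        rows.append(nu)
        rhs.append(b)
    A = np.array(rows)
    b = np.array(rhs)

    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(A @ p, b, atol=1e-8), "inconsistent Keq equations"
    W = null_space(A)                      # conserved directions
    c0 = np.array([initial.get(sp, 0.0) for sp in species])
    targets = W.T @ c0

    # start lambda so concentrations sit near the initial scale
    scale = max(c0.max(), 1e-12)
    lam0, *_ = np.linalg.lstsq(W, np.full(len(species), math.log(scale)) - p,
                               rcond=None)

    row_scale = np.maximum(np.abs(targets), 1e-3 * scale)

    def g(lam):
        logc = np.clip(p + W @ lam, -700, 700)
        return (W.T @ np.exp(logc) - targets) / row_scale

    rng = np.random.default_rng(0)
    sol = None
    for start in [lam0, np.zeros_like(lam0)] + [
            lam0 + rng.normal(0, 2, lam0.shape) for _ in range(6)]:
        sol = root(g, start, method="hybr", options={"xtol": 1e-14})
        if sol.success and np.max(np.abs(g(sol.x))) < 1e-9:
            break
    assert sol is not None and sol.success, (
        f"oracle root-find failed: {sol.message}")
    conc = np.exp(np.clip(p + W @ sol.x, -700, 700))
    out = dict(zip(species, conc.tolist()))
    out.update(fixed)
    return out
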