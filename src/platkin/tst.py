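"""Transition-state-theory engine.

Maps activation/reaction free energies to rate and equilibrium
constants and back:

    k    = (k_B T / h) exp(-dG_act / RT)          (Eyring)
    Keq  = exp(-dG / RT)
    dG_act = RT ln((k_B T / h) / k)               (inverse Eyring)

plus the two composite observables used for ligand substitution at a
square-planar Pt(II) centre:

* a pseudo-first-order aquation constant k_obs = k1 * [H2O], with the
  solvent concentration held at 55.5 M, and
* a quasi-equilibrium composite for direct substitution, where fast
  pre-association (equilibrium constant K_pre) precedes the slow bond
  substitution step: k_obs = K_pre * k2 = eyring(dG_pre + dG_act2).

Published observable rate constants quoted with a negative sign (an
artefact of the sign convention in the underlying rate-law derivation)
are interpreted as magnitudes: their printed effective barriers are the
inverse-Eyring images of the absolute values.  Pass ``abs(k)`` to
:func:`effective_barrier`.

Composite effective barriers may legitimately be negative (a downhill
pre-equilibrium can overcompensate the second step), so
:func:`eyring_rate` accepts negative arguments.
"""

from __future__ import annotations

import math

from .constants import DEFAULT_CONSTANTS, KineticConstants

__all__ = [
    "eyring_rate",
    "barrier_from_rate",
    "equilibrium_constant",
    "pseudo_first_order_kobs",
    "quasi_equilibrium_kobs",
    "effective_barrier",
]


def eyring_rate(dg_activation: float,
                consts: KineticConstants = DEFAULT_CONSTANTS) -> float:
    """Elementary rate constant (s^-1) for an activation free energy in kcal/mol."""
    if not math.isfinite(dg_activation):
        raise ValueError("activation free energy must be finite")
    return consts.kbt_over_h * math.exp(-dg_activation / consts.rt)


def barrier_from_rate(k: float,
                      consts: KineticConstants = DEFAULT_CONSTANTS) -> float:
    """Activation free energy (kcal/mol) whose Eyring rate equals ``k`` (s^-1).

    Exact inverse of :func:`eyring_rate`.
    """
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return consts.rt * math.log(consts.kbt_over_h / k)


def equilibrium_constant(dg_step: float,
                         consts: KineticConstants = DEFAULT_CONSTANTS) -> float:
    """Dimensionless equilibrium constant (1 M standard state) for a step dG."""
    if not math.isfinite(dg_step):
        raise ValueError("step free energy must be finite")
    return math.exp(-dg_step / consts.rt)


def pseudo_first_order_kobs(k1: float, conc: float) -> float:
    """Observable constant k1 * [X] for a reactant in large constant excess.

    For aquation X is the solvent itself ([H2O] = 55.5 M), so the
    bimolecular step collapses to a pseudo-first-order observable.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return k1 * conc


def quasi_equilibrium_kobs(dg_preassoc: float, dg_activation_step2: float,
                           consts: KineticConstants = DEFAULT_CONSTANTS) -> float:
    """Composite observable K_pre * k2 for fast pre-association + slow step.

    Algebraically identical to ``eyring_rate(dg_preassoc +
    dg_activation_step2)``; computed as the explicit product so the two
    factors remain inspectable.
    """
    return (equilibrium_constant(dg_preassoc, consts)
            * eyring_rate(dg_activation_step2, consts))


def effective_barrier(k_obs: float,
                      consts: KineticConstants = DEFAULT_CONSTANTS) -> float:
    """Effective activation free energy of an observable rate constant.

    Thin alias of :func:`barrier_from_rate`; pass magnitudes for rate
    constants printed with a sign.
    """
    return barrier_from_rate(k_obs, consts)
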