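"""Thermodynamic and regulatory scoring.

Free energies of reaction (actual and activity-effective), dissipation
rates and the entropy production rate (EPR), the adenylate energy charge,
and the calibre loss functions that decide when predicted concentrations
are in agreement with physiological targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicNetwork, ModelError
from .steadystate import SteadyStateSolution

__all__ = [
    "DissipationReport",
    "CalibreLoss",
    "reaction_free_energies",
    "dissipation_rates",
    "adenylate_energy_charge",
    "calibre_losses",
]


@dataclass
class DissipationReport:
    """Free-energy and energy dissipation rates at a steady state.

    dG/dt = -R_gT sum_j alpha_j (r_j - r_-j) ln(K_j Q_j^-1), with the
    Marcelin rates r_j = K_j Q_j^-1 and r_-j = K_j^-1 Q_j (dimensionless
    odds, unit timescale).  The entropy production rate is -dG/dt and is
    non-negative at any steady state.  dE/dt keeps only the K-dependent
    part, -R_gT sum_j alpha_j (r_j - r_-j) ln K_j: the rate of work
    available beyond maintaining the steady state.  Units: kJ mol^-1 per
    unit timescale.
    """

    dG_dt: float
    dE_dt: float
    entropy_production_rate: float
    per_reaction_dG_dt: np.ndarray
    per_reaction_dE_dt: np.ndarray
    forward_rates: np.ndarray
    reverse_rates: np.ndarray


@dataclass
class CalibreLoss:
    """Stopping and reward losses against target concentrations.

    L_i = ln(predicted_i / target_i) per variable metabolite; the stopping
    loss is L = sum_i max(L_i, 0) and the system is "in calibre" when every
    L_i <= 0 (with a small absolute slack for solver noise).  The reward
    loss Lambda = ln(sum_i predicted_i / target_i) weights the metabolites
    furthest out of calibre most heavily.
    """

    per_metabolite: np.ndarray
    stopping_loss: float
    rl_loss: float
    violating: np.ndarray  # indices into the variable species
    in_calibre: bool


def reaction_free_energies(
    solution: SteadyStateSolution, activities: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Actual and effective reaction free energies, kJ/mol.

    dG_j = -R_gT ln(K_j Q_j^-1).  The effective free energy folds the
    activity rheostat into the driving force,
    dG_j^eff = -R_gT ln(alpha_j K_j Q_j^-1) = dG_j - R_gT ln alpha_j,
    and moves toward zero as alpha_j decreases.  At alpha_j = 0 the
    effective value is undefined and returned as NaN.
    """
    alpha = solution.activities if activities is None else np.asarray(activities, float)
    dg = solution.delta_g.copy()
    with np.errstate(divide="ignore"):
        ln_alpha = np.where(alpha > 0, np.log(np.where(alpha > 0, alpha, 1.0)), np.nan)
    return dg, dg - solution.rt * ln_alpha


def dissipation_rates(
    solution: SteadyStateSolution, activities: np.ndarray | None = None
) -> DissipationReport:
    """Free-energy/energy dissipation rates and the EPR at a solution."""
    alpha = solution.activities if activities is None else np.asarray(activities, float)
    r_f, r_r = solution.forward_odds, solution.reverse_odds
    ln_odds = np.log(r_f)
    lnK = ln_odds + np.log(solution.reaction_quotients)
    net = alpha * (r_f - r_r)
    per_g = -solution.rt * net * ln_odds
    per_e = -solution.rt * net * lnK
    dg_dt = float(per_g.sum())
    de_dt = float(per_e.sum())
    return DissipationReport(
        dG_dt=dg_dt,
        dE_dt=de_dt,
        entropy_production_rate=-dg_dt,
        per_reaction_dG_dt=per_g,
        per_reaction_dE_dt=per_e,
        forward_rates=r_f,
        reverse_rates=r_r,
    )


def adenylate_energy_charge(atp: float, adp: float, amp: float = 0.0) -> float:
    """Energy charge of the adenylate pool, (ATP + ADP/2)/(ATP+ADP+AMP).

    A value in [0, 1]; treated throughout as an emergent readout of the
    boundary conditions, never as an objective.
    """
    pool = atp + adp + amp
    if atp < 0 or adp < 0 or amp < 0:
        raise ModelError("adenylate concentrations must be non-negative")
    if pool <= 0:
        raise ModelError("adenylate pool is empty")
    return (atp + 0.5 * adp) / pool


def calibre_losses(
    predicted: np.ndarray,
    targets: np.ndarray,
    *,
    slack: float = 1e-9,
) -> CalibreLoss:
    """Per-metabolite losses of predicted vs target variable concentrations.

    Both arrays cover the variable species only (boundary species are
    clamped and never targeted).  Predictions at or below target count as
    in calibre: the model tracks free metabolite pools while measured
    concentrations include enzyme-bound molecules.
    """
    pred = np.asarray(predicted, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    if pred.shape != tgt.shape:
        raise ModelError("predicted and target arrays differ in length")
    if np.any(pred <= 0):
        raise ModelError("predicted concentrations must be positive")
    if np.any(tgt <= 0):
        raise ModelError("target concentrations must be positive")
    L_i = np.log(pred / tgt)
    violating = np.flatnonzero(L_i > slack)
    L = float(np.sum(L_i[violating]))
    lam = float(np.log(np.sum(pred / tgt)))
    return CalibreLoss(
        per_metabolite=L_i,
        stopping_loss=L,
        rl_loss=lam,
        violating=violating,
        in_calibre=violating.size == 0,
    )


def energy_charge_from_state(
    network: MetabolicNetwork, concentrations: np.ndarray
) -> float:
    """Energy charge read off a full concentration vector (AMP absent -> 0)."""
    ids = network.metabolite_ids

    def get(mid: str) -> float:
        return concentrations[ids.index(mid)] if mid in ids else 0.0

    return adenylate_energy_charge(get("atp"), get("adp"), get("amp"))
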