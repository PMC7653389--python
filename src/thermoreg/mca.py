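"""Metabolic control analysis of activity regulation.

Concentration control coefficients C_{i,j} = d ln n_i / d ln alpha_j are
estimated by one-sided downward finite differences with a full steady-state
re-solve per perturbed activity (warm-started from the base solution).
The regulation loop repeatedly decrements the activity of the reaction
whose estimated loss reduction is largest until every predicted
concentration is at or below its target (in calibre), no reaction can
reduce the loss (stalled), or the network flux collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import CalibreLoss, calibre_losses, dissipation_rates
from .model import MetabolicNetwork, ModelError, SystemState, ThermoSpec
from .steadystate import SteadyStateSolution, solve_steady_state

__all__ = [
    "ControlMatrix",
    "RegulationTrace",
    "control_coefficients",
    "summed_influence",
    "loss_reduction",
    "run_mca_regulation",
]

MODES = ("unrestricted", "local")


@dataclass
class ControlMatrix:
    """Concentration control coefficients for the variable species.

    ``coefficients[i, j] = d ln n_i / d ln alpha_j`` (dimensionless,
    M_V x Z).  Boundary species are clamped, so their coefficients are
    identically zero (query via :meth:`coefficient`).  Columns that could
    not be probed (alpha_j = 0 or re-solve failure) are flagged in
    ``failed`` rather than silently zero-filled.
    """

    coefficients: np.ndarray
    base_activities: np.ndarray
    finite_difference_steps: np.ndarray
    variable_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    failed: tuple[str, ...] = ()

    def coefficient(self, met_id: str, rxn_id: str) -> float:
        j = self.reaction_ids.index(rxn_id)
        if met_id in self.variable_ids:
            return float(self.coefficients[self.variable_ids.index(met_id), j])
        return 0.0  # boundary species are fixed by definition

    def row_sums(self) -> np.ndarray:
        return self.coefficients.sum(axis=1)


@dataclass
class RegulationTrace:
    """Ordered record of a regulation run."""

    mode: str
    steps: list[dict] = field(default_factory=list)
    terminal_reason: str = ""
    activities: np.ndarray | None = None
    base_solution: SteadyStateSolution | None = None
    final_solution: SteadyStateSolution | None = None

    @property
    def regulated_reactions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for rec in self.steps:
            if rec["reaction_id"] is not None and rec["reaction_id"] not in seen:
                seen.append(rec["reaction_id"])
        return tuple(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=[
                "step",
                "reaction_id",
                "alpha_after",
                "L",
                "Lambda",
                "EPR",
                "dE_dt",
                "n_violating",
            ],
        )


def _resolve(
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    alpha: np.ndarray,
    warm: SteadyStateSolution | None,
    **solver_kwargs,
) -> SteadyStateSolution:
    init = (
        np.log(warm.concentrations[network.variable_mask]) if warm is not None else None
    )
    return solve_steady_state(
        network, thermo, state.with_activities(alpha), init=init, **solver_kwargs
    )


def control_coefficients(
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    *,
    rel_step: float = 0.01,
    base_solution: SteadyStateSolution | None = None,
    **solver_kwargs,
) -> ControlMatrix:
    """Finite-difference concentration control coefficients.

    Each active reaction j is probed downward by d alpha_j = rel_step *
    alpha_j (alpha may not exceed 1, so the difference is one-sided) and
    the steady state re-solved warm-started from the base solution.
    """
    if not 0 < rel_step < 1:
        raise ModelError("rel_step must lie in (0, 1)")
    alpha = state.activities.copy()
    base = base_solution or solve_steady_state(network, thermo, state, **solver_kwargs)
    if not base.converged:
        raise ModelError("control coefficients need a converged base solution")
    ln_base = np.log(base.concentrations[network.variable_mask])
    Z = network.n_reactions
    C = np.zeros((network.n_variable, Z))
    steps = np.zeros(Z)
    failed = []
    for j in range(Z):
        if alpha[j] <= 0:
            failed.append(network.reaction_ids[j])
            continue
        d_alpha = rel_step * alpha[j]
        pert = alpha.copy()
        pert[j] = alpha[j] - d_alpha
        sol = _resolve(network, thermo, state, pert, base, **solver_kwargs)
        if not sol.converged:
            failed.append(network.reaction_ids[j])
            continue
        steps[j] = d_alpha
        d_ln_alpha = np.log(pert[j]) - np.log(alpha[j])
        ln_pert = np.log(sol.concentrations[network.variable_mask])
        C[:, j] = (ln_pert - ln_base) / d_ln_alpha
    return ControlMatrix(
        coefficients=C,
        base_activities=alpha,
        finite_difference_steps=steps,
        variable_ids=network.variable_ids,
        reaction_ids=network.reaction_ids,
        failed=tuple(failed),
    )


def summed_influence(control: ControlMatrix, violating: np.ndarray) -> np.ndarray:
    """Per-reaction summed influence C_j = sum_{i in M'} max(C_{i,j}, 0).

    Activities are only ever reduced from 1.0, so only positive
    coefficients (where reducing activity reduces concentration) count.
    """
    violating = np.asarray(violating, dtype=int)
    if violating.size == 0:
        return np.zeros(len(control.reaction_ids))
    return np.maximum(control.coefficients[violating], 0.0).sum(axis=0)


def _immediate_products(
    network: MetabolicNetwork, base_solution: SteadyStateSolution
) -> list[np.ndarray]:
    """Variable-species indices of each reaction's products, taken in the
    net-flux direction of the unregulated base solution."""
    var_index = {m: i for i, m in enumerate(network.variable_ids)}
    out = []
    for j in range(network.n_reactions):
        sign = 1.0 if base_solution.net_fluxes[j] >= 0 else -1.0
        col = sign * network.stoich[:, j]
        prods = [
            var_index[m]
            for i, m in enumerate(network.metabolite_ids)
            if col[i] > 0 and m in var_index
        ]
        out.append(np.asarray(prods, dtype=int))
    return out


def loss_reduction(
    control: ControlMatrix,
    activities: np.ndarray,
    rel_step: float,
    violating: np.ndarray,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Estimated stopping-loss change per eligible reaction.

    dL_j = sum_{i in M'} -ln(1 - C_{i,j} * d alpha_j / alpha_j) with the
    relative step d alpha_j / alpha_j = rel_step.  Arguments driven to or
    past zero (C * step >= 1) are capped, yielding a large finite score.
    Ineligible or inactive reactions score -inf.
    """
    alpha = np.asarray(activities, float)
    Z = len(control.reaction_ids)
    out = np.full(Z, -np.inf)
    violating = np.asarray(violating, dtype=int)
    if eligible is None:
        eligible = np.ones(Z, dtype=bool)
    for j in range(Z):
        if not eligible[j] or alpha[j] <= 0:
            continue
        arg = 1.0 - control.coefficients[violating, j] * rel_step
        arg = np.maximum(arg, 1e-12)  # capped step for C*step >= 1
        out[j] = float(-np.log(arg).sum()) if violating.size else 0.0
    return out


def run_mca_regulation(
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    targets: np.ndarray,
    mode: str = "unrestricted",
    *,
    delta: float = 0.05,
    fd_step: float = 0.01,
    max_iter: int = 1000,
    collapse_ratio: float = 1e-6,
    refine: bool = True,
    slack: float = 1e-9,
    **solver_kwargs,
) -> RegulationTrace:
    """Iterative select-step-resolve regulation until in calibre.

    Per accepted step the selected activity is decremented multiplicatively,
    alpha <- alpha (1 - delta); the final step is refined by bisection so
    the stopping loss lands at zero without overshoot (minimal regulation).
    ``mode`` is "unrestricted" (any reaction may regulate any metabolite)
    or "local" (only reactions whose immediate products are out of
    calibre).  Terminal reasons: ``in_calibre``, ``stalled`` (no positive
    estimated loss reduction, or iteration cap) or ``flux_collapse``
    (max |J| below ``collapse_ratio`` times its unregulated value).
    """
    if mode not in MODES:
        raise ModelError(f"unknown mode {mode!r}; expected one of {MODES}")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (network.n_variable,):
        raise ModelError("targets must cover exactly the variable species")

    trace = RegulationTrace(mode=mode)
    alpha = state.activities.copy()
    sol = solve_steady_state(network, thermo, state.with_activities(alpha), **solver_kwargs)
    if not sol.converged:
        raise ModelError(
            "unregulated base solution did not converge: " + sol.null_direction_report
        )
    trace.base_solution = sol
    base_flux_scale = float(np.max(np.abs(sol.net_fluxes)))
    products = _immediate_products(network, sol)

    def record(step: int, rxn: str | None, loss: CalibreLoss, s: SteadyStateSolution):
        rep = dissipation_rates(s)
        trace.steps.append(
            {
                "step": step,
                "reaction_id": rxn,
                "alpha_after": None if rxn is None else float(alpha[network.reaction_index(rxn)]),
                "L": loss.stopping_loss,
                "Lambda": loss.rl_loss,
                "EPR": rep.entropy_production_rate,
                "dE_dt": rep.dE_dt,
                "n_violating": int(loss.violating.size),
            }
        )

    loss = calibre_losses(sol.concentrations[network.variable_mask], targets, slack=slack)
    record(0, None, loss, sol)
    last_action: tuple[int, float] | None = None  # (reaction index, alpha before step)

    for it in range(1, max_iter + 1):
        if loss.in_calibre:
            trace.terminal_reason = "in_calibre"
            break
        control = control_coefficients(
            network,
            thermo,
            state.with_activities(alpha),
            rel_step=fd_step,
            base_solution=sol,
            **solver_kwargs,
        )
        if mode == "local":
            viol = set(loss.violating.tolist())
            eligible = np.array(
                [bool(viol.intersection(p.tolist())) for p in products]
            )
        else:
            eligible = np.ones(network.n_reactions, dtype=bool)
        scores = loss_reduction(control, alpha, delta, loss.violating, eligible)
        if not np.any(scores > 0):
            trace.terminal_reason = "stalled"
            break
        j = int(np.argmax(scores))  # argmax; ties resolve to lowest index
        last_action = (j, float(alpha[j]))
        alpha[j] *= 1.0 - delta
        sol = _resolve(network, thermo, state, alpha, sol, **solver_kwargs)
        if not sol.converged:
            trace.terminal_reason = "stalled"
            record(it, network.reaction_ids[j], loss, sol)
            break
        loss = calibre_losses(
            sol.concentrations[network.variable_mask], targets, slack=slack
        )
        record(it, network.reaction_ids[j], loss, sol)
        if float(np.max(np.abs(sol.net_fluxes))) < collapse_ratio * base_flux_scale:
            trace.terminal_reason = "flux_collapse"
            break
    else:
        trace.terminal_reason = "stalled"

    if trace.terminal_reason == "in_calibre" and refine and last_action is not None:
        # bisect the last decrement so L lands at zero without overshoot
        j, a_hi = last_action
        a_lo = alpha[j]
        for _ in range(40):
            mid = 0.5 * (a_lo + a_hi)
            trial = alpha.copy()
            trial[j] = mid
            s_mid = _resolve(network, thermo, state, trial, sol, **solver_kwargs)
            l_mid = calibre_losses(
                s_mid.concentrations[network.variable_mask], targets, slack=slack
            )
            if l_mid.in_calibre:
                a_lo = mid
                sol, loss = s_mid, l_mid
            else:
                a_hi = mid
            if a_hi - a_lo < 1e-10:
                break
        alpha[j] = a_lo
        rid = network.reaction_ids[j]
        record(len(trace.steps), rid, loss, sol)

    trace.activities = alpha
    trace.final_solution = sol
    return trace
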