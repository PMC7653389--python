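"""Maximum path-entropy thermodynamic steady states.

The net rate of a reversible reaction is written thermodynamically
(Marcelin form) as the difference of its forward and reverse odds,

    J_j = alpha_j * (K_j Q_j^-1 - K_j^-1 Q_j),

with a common unit timescale for all reactions (c_j = 1).  At the steady
state all net driving forces are equal along linear segments and
proportional to stoichiometry at branches — the maximum path-entropy
solution.  The solver finds the variable-species concentrations that zero
``S_V @ J`` by damped least squares in log-concentration space, where the
problem is convex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model import MetabolicNetwork, ModelError, SystemState, ThermoSpec

__all__ = [
    "SteadyStateSolution",
    "RateConstants",
    "Trajectory",
    "thermodynamic_odds",
    "net_flux",
    "solve_steady_state",
    "back_calculate_rate_constants",
    "simulate_mass_action",
    "gated_steady_state",
]

# exponent clip guarding exp overflow far from the solution
_EXP_CLIP = 300.0


class SteadyStateError(RuntimeError):
    """Raised when the steady-state optimisation fails to converge."""


@dataclass
class SteadyStateSolution:
    """Converged (or best-effort) steady state of a network.

    ``residual_norm`` is the squared 2-norm of ``S_V @ J``; fluxes are in
    odds units per unit timescale.  Affinities A_j = R_g T ln(K_j/Q_j) are
    in kJ/mol and ``delta_g = -A``.
    """

    concentrations: np.ndarray          # all M species, molar
    activities: np.ndarray
    reaction_quotients: np.ndarray
    forward_odds: np.ndarray            # K_j / Q_j
    reverse_odds: np.ndarray            # Q_j / K_j
    net_fluxes: np.ndarray              # alpha * (forward - reverse)
    affinities: np.ndarray              # kJ/mol
    delta_g: np.ndarray                 # kJ/mol, = -affinities
    residual_norm: float                # ||S_V J||_2^2
    converged: bool
    rt: float                           # R_g T, kJ/mol
    null_direction_report: str = ""
    n_residual_evals: int = 0

    def variable_concentrations(self, network: MetabolicNetwork) -> np.ndarray:
        return self.concentrations[network.variable_mask]

    @property
    def mass_balance_inf_norm(self) -> float:
        return self._mass_balance_inf

    _mass_balance_inf: float = field(default=np.nan)


@dataclass
class RateConstants:
    """Forward/reverse mass-action rate constants back-calculated from a
    steady state; ``forward/reverse = K`` by construction.  Reactions too
    close to equilibrium (odds ~ 1) or with negligible flux carry NaN and
    are listed in ``skipped``.
    """

    forward: np.ndarray
    reverse: np.ndarray
    timescale_factor: float = 1.0
    skipped: tuple[str, ...] = ()


@dataclass
class Trajectory:
    times: np.ndarray
    concentrations: np.ndarray  # (n_times, M), molar; boundary rows constant
    success: bool
    message: str = ""


# ---------------------------------------------------------------------------


def thermodynamic_odds(
    state: SystemState, network: MetabolicNetwork, thermo: ThermoSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reaction quotients and forward/reverse thermodynamic odds.

    Q_j is built from signed stoichiometry over all species (boundary
    included) with molar activities; forward odds are K_j/Q_j and the
    reverse odds their exact reciprocal.
    """
    n = np.asarray(state.concentrations, dtype=float)
    if np.any(n <= 0):
        raise ModelError("concentrations must be positive to form odds")
    ln_q = network.stoich.T @ np.log(n)
    ln_fwd = np.log(thermo.equilibrium_constants) - ln_q
    Q = np.exp(ln_q)
    fwd = np.exp(np.clip(ln_fwd, -_EXP_CLIP, _EXP_CLIP))
    return Q, fwd, 1.0 / fwd


def net_flux(
    forward_odds: np.ndarray, reverse_odds: np.ndarray, activities: np.ndarray
) -> np.ndarray:
    """Activity-scaled Marcelin net flux J_j = alpha_j (K/Q - Q/K)."""
    alpha = np.asarray(activities, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise ModelError("activities must lie in [0, 1]")
    return alpha * (np.asarray(forward_odds) - np.asarray(reverse_odds))


def _solution_from_logn(
    x: np.ndarray,
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    residual_norm: float,
    converged: bool,
    report: str,
    nfev: int,
) -> SteadyStateSolution:
    n = state.concentrations.copy()
    n[network.variable_mask] = np.exp(x)
    full = SystemState(n, state.activities)
    Q, fwd, rev = thermodynamic_odds(full, network, thermo)
    J = net_flux(fwd, rev, state.activities)
    aff = thermo.rt * np.log(fwd)
    sol = SteadyStateSolution(
        concentrations=n,
        activities=state.activities.copy(),
        reaction_quotients=Q,
        forward_odds=fwd,
        reverse_odds=rev,
        net_fluxes=J,
        affinities=aff,
        delta_g=-aff,
        residual_norm=residual_norm,
        converged=converged,
        rt=thermo.rt,
        null_direction_report=report,
        n_residual_evals=nfev,
    )
    sol._mass_balance_inf = float(
        np.max(np.abs(network.stoich_variable @ J)) if J.size else 0.0
    )
    return sol


def solve_steady_state(
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    init: np.ndarray | None = None,
    *,
    tol: float = 1e-10,
    max_nfev: int = 10_000,
    n_multistart: int = 10,
    seed: int = 0,
) -> SteadyStateSolution:
    """Solve ``||S_V (alpha o (KQ^- - K^-Q))||_2^2 = 0`` for the variable
    log-concentrations.

    The optimisation runs over x = ln n_V (positivity built in; the
    residual is log-concave in x) with the analytic Jacobian
    ``-S_V diag(alpha_j (f_j + 1/f_j)) S_V^T``.  The default initial guess
    puts every variable species at 1 mM; on failure, up to ``n_multistart``
    seeded restarts perturb the start by +/-2 natural-log units.  The
    solution is converged when the squared residual norm falls below
    ``tol``.  Variable species not touched by any active reaction and flat
    directions of the Jacobian are described in ``null_direction_report``.
    """
    if np.any(state.boundary_concentrations(network) <= 0):
        raise ModelError("boundary concentrations must be fixed and positive")
    alpha = state.activities
    S_v = network.stoich_variable
    lnK = np.log(thermo.equilibrium_constants)
    ln_nb = np.log(state.concentrations[~network.variable_mask])
    S_b = network.stoich_boundary
    const = lnK - S_b.T @ ln_nb  # ln K - boundary part of ln Q

    untouched = [
        mid
        for row, mid in zip(S_v, network.variable_ids)
        if not np.any((row != 0) & (alpha > 0))
    ]

    def odds_terms(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.clip(const - S_v.T @ x, -_EXP_CLIP, _EXP_CLIP)
        e = np.exp(t)
        return e, 1.0 / e

    def residual(x: np.ndarray) -> np.ndarray:
        f, r = odds_terms(x)
        return S_v @ (alpha * (f - r))

    def jacobian(x: np.ndarray) -> np.ndarray:
        f, r = odds_terms(x)
        return -(S_v * (alpha * (f + r))) @ S_v.T

    # default start: the state's variable concentrations (1 mM unless the
    # caller warm-starts or the fixture chose another scale)
    x0 = (
        np.log(state.variable_concentrations(network))
        if init is None
        else np.asarray(init, float)
    )

    rng = np.random.default_rng(seed)
    best = None
    starts = [x0] + [
        x0 + rng.uniform(-2.0, 2.0, size=x0.size) for _ in range(n_multistart)
    ]
    nfev_total = 0
    for k, start in enumerate(starts):
        res = least_squares(
            residual,
            start,
            jac=jacobian,
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=max_nfev,
        )
        nfev_total += res.nfev
        sq = float(res.cost * 2.0)  # least_squares cost is 0.5 ||r||^2
        if best is None or sq < best[0]:
            best = (sq, res.x)
        if sq <= tol:
            break

    sq, x = best
    converged = sq <= tol
    report_bits = []
    if untouched:
        report_bits.append(
            "variable species untouched by any active reaction: "
            + ", ".join(untouched)
        )
    J_at_sol = jacobian(x)
    svals = np.linalg.svd(J_at_sol, compute_uv=False) if x.size else np.array([1.0])
    if x.size and svals[0] > 0 and svals[-1] < 1e-10 * svals[0]:
        n_flat = int(np.sum(svals < 1e-10 * svals[0]))
        report_bits.append(
            f"{n_flat} flat direction(s) in the residual Jacobian at the "
            "solution (degenerate/zero-flux subspace)"
        )
    report = "; ".join(report_bits)
    if not converged:
        report = (
            f"non-convergence after {len(starts)} start(s): best squared "
            f"residual {sq:.3e} > tol {tol:.1e}"
            + ("; " + report if report else "")
        )
    return _solution_from_logn(
        x, network, thermo, state, sq, converged, report, nfev_total
    )


# ---------------------------------------------------------------------------


def back_calculate_rate_constants(
    solution: SteadyStateSolution,
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    *,
    include_activities: bool = False,
    near_equilibrium_tol: float = 1e-6,
    flux_threshold: float = 0.0,
) -> RateConstants:
    """Recover mass-action rate constants that reproduce a steady state.

    k_j = J_j / (prod_i n_i^{nu_f} * (1 - K_j^-1 Q_j)) and k_-j = k_j/K_j.
    Near-equilibrium reactions (|1 - odds| < tol) leave k undefined; those
    and reactions with |J| at or below ``flux_threshold`` are skipped and
    reported.  With ``include_activities`` the current activity is folded
    into the rate constant (hard-wired regulation).
    """
    if not solution.converged:
        raise SteadyStateError("rate-constant back-calculation needs a converged solution")
    nu_f = network.forward_exponents
    n = solution.concentrations
    fwd_mono = np.exp(nu_f.T @ np.log(n))  # prod n^nu_f per reaction
    kf = np.full(network.n_reactions, np.nan)
    skipped = []
    for j, rid in enumerate(network.reaction_ids):
        if abs(1.0 - solution.forward_odds[j]) < near_equilibrium_tol:
            skipped.append(rid)
            continue
        if abs(solution.net_fluxes[j]) <= flux_threshold:
            skipped.append(rid)
            continue
        denom = fwd_mono[j] * (1.0 - solution.reverse_odds[j])
        if include_activities:
            if solution.activities[j] == 0:
                skipped.append(rid)
                continue
            denom *= solution.activities[j]
        kf[j] = solution.net_fluxes[j] / denom
    kr = kf / thermo.equilibrium_constants
    return RateConstants(kf, kr, 1.0, tuple(skipped))


def _mass_action_flux(
    log_n: np.ndarray,
    network: MetabolicNetwork,
    rates: RateConstants,
    gating: np.ndarray,
) -> np.ndarray:
    nu_f, nu_r = network.forward_exponents, network.reverse_exponents
    kf = np.nan_to_num(rates.forward)
    kr = np.nan_to_num(rates.reverse)
    F = kf * np.exp(np.clip(nu_f.T @ log_n, -_EXP_CLIP, _EXP_CLIP))
    R = kr * np.exp(np.clip(nu_r.T @ log_n, -_EXP_CLIP, _EXP_CLIP))
    return gating * (F - R)


def simulate_mass_action(
    network: MetabolicNetwork,
    rate_constants: RateConstants,
    state: SystemState,
    duration: float,
    *,
    gating: np.ndarray | None = None,
    n_points: int = 100,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate mass-action kinetics of the variable species.

    Boundary species are clamped; optional ``gating`` factors scale both
    forward and reverse rates (the gated-kinetics control).
    """
    g = np.ones(network.n_reactions) if gating is None else np.asarray(gating, float)
    mask = network.variable_mask
    S_v = network.stoich_variable
    n_full = state.concentrations.copy()

    def rhs(_t, nv):
        log_n = np.log(np.maximum(n_full, 1e-300))
        log_n[mask] = np.log(np.maximum(nv, 1e-300))
        return S_v @ _mass_action_flux(log_n, network, rate_constants, g)

    sol = solve_ivp(
        rhs,
        (0.0, duration),
        state.variable_concentrations(network),
        method="LSODA",
        t_eval=np.linspace(0.0, duration, n_points),
        rtol=rtol,
        atol=atol,
    )
    conc = np.tile(n_full, (len(sol.t), 1))
    conc[:, mask] = sol.y.T
    msg = sol.message if not sol.success else ""
    if not sol.success:
        msg = f"integration stopped at t={sol.t[-1] if len(sol.t) else 0:.3g}: {sol.message}"
    return Trajectory(sol.t, conc, bool(sol.success), msg)


def gated_steady_state(
    network: MetabolicNetwork,
    rate_constants: RateConstants,
    gating_factors: np.ndarray,
    state: SystemState,
    thermo: ThermoSpec,
    *,
    tol: float = 1e-10,
    max_nfev: int = 10_000,
) -> SteadyStateSolution:
    """Steady state of gated mass-action kinetics.

    Gating scales forward and reverse rate constants identically
    (dn_B/dt = g k_1 n_A - g k_-1 n_B), so the thermodynamic odds computed
    from the gated rates are algebraically independent of the gating
    factor — the negative control against the activity-coefficient
    (rheostat) mechanism.
    """
    g = np.asarray(gating_factors, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ModelError("gating factors must lie in [0, 1]")
    mask = network.variable_mask
    S_v = network.stoich_variable
    nu_f, nu_r = network.forward_exponents, network.reverse_exponents
    n_full = state.concentrations.copy()
    log_nb = np.log(n_full)

    def full_log(x):
        log_n = log_nb.copy()
        log_n[mask] = x
        return log_n

    def residual(x):
        return S_v @ _mass_action_flux(full_log(x), network, rate_constants, g)

    def jacobian(x):
        log_n = full_log(x)
        kf = np.nan_to_num(rate_constants.forward)
        kr = np.nan_to_num(rate_constants.reverse)
        F = g * kf * np.exp(np.clip(nu_f.T @ log_n, -_EXP_CLIP, _EXP_CLIP))
        R = g * kr * np.exp(np.clip(nu_r.T @ log_n, -_EXP_CLIP, _EXP_CLIP))
        nu_f_v, nu_r_v = nu_f[mask], nu_r[mask]
        return S_v @ (F[:, None] * nu_f_v.T - R[:, None] * nu_r_v.T)

    x0 = np.log(state.variable_concentrations(network))
    res = least_squares(
        residual, x0, jac=jacobian, method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
    )
    sq = float(res.cost * 2.0)
    gated_state = SystemState(n_full, np.ones(network.n_reactions))
    n_sol = n_full.copy()
    n_sol[mask] = np.exp(res.x)
    gated_state = SystemState(n_sol, np.ones(network.n_reactions))
    Q, fwd, rev = thermodynamic_odds(gated_state, network, thermo)
    log_n = full_log(res.x)
    J = _mass_action_flux(log_n, network, rate_constants, g)
    aff = thermo.rt * np.log(fwd)
    sol = SteadyStateSolution(
        concentrations=n_sol,
        activities=g.copy(),
        reaction_quotients=Q,
        forward_odds=fwd,
        reverse_odds=rev,
        net_fluxes=J,
        affinities=aff,
        delta_g=-aff,
        residual_norm=sq,
        converged=sq <= tol,
        rt=thermo.rt,
        null_direction_report="" if sq <= tol else
        f"gated steady state: best squared residual {sq:.3e} > tol {tol:.1e}",
        n_residual_evals=res.nfev,
    )
    sol._mass_balance_inf = float(np.max(np.abs(S_v @ J))) if J.size else 0.0
    return sol
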