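"""Synthetic scenario generators.

Every stage of the pipeline (solve -> MCA -> RL) is testable without any
external thermodynamic database or metabolomics download: favourable
equilibrium-constant sets are generated from synthetic per-metabolite
standard chemical potentials, and target-concentration sets are derived
from unregulated predictions so that regulation is actually required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    MetabolicNetwork,
    ModelError,
    SystemState,
    ThermoSpec,
    build_ecoli_pathway,
    generate_toy_pathway,
    write_model,
    write_targets,
    write_thermo,
)
from .steadystate import SteadyStateSolution

__all__ = [
    "ScenarioSpec",
    "generate_synthetic_thermo",
    "generate_targets",
    "make_scenario",
    "write_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A reproducible end-to-end scenario: network + thermo + targets."""

    name: str
    network: MetabolicNetwork
    state: SystemState
    thermo: ThermoSpec
    targets: np.ndarray  # molar, variable species
    seed: int


def generate_synthetic_thermo(
    network: MetabolicNetwork,
    overall_favourability: float,
    seed: int = 0,
    *,
    split: str = "random",
    temperature: float = 298.15,
) -> ThermoSpec:
    """Synthetic equilibrium constants with a prescribed total drive.

    Per-reaction standard free-energy drops are sampled uniformly from
    [1, 10] kJ/mol (``split="random"``) or taken equal (``split="even"``),
    fitted by per-metabolite standard chemical potentials (least squares on
    S^T mu = dG°') so that the resulting K set is path-independent on
    branched and cyclic topologies, and rescaled so the drops realised by
    the fit sum to ``overall_favourability`` (kJ/mol; equal to the
    source-to-sink standard drop on a linear chain).  Zero favourability
    yields all K = 1.  Deterministic per seed.
    """
    if overall_favourability < 0:
        raise ModelError("overall favourability must be non-negative (kJ/mol)")
    Z = network.n_reactions
    rng = np.random.default_rng(seed)
    if split == "even":
        drops = np.ones(Z)
    elif split == "random":
        drops = rng.uniform(1.0, 10.0, size=Z)
    else:
        raise ModelError(f"unknown split {split!r}; expected 'random' or 'even'")
    # fit potentials: dG°' = S^T mu, target dG°' = -drops
    mu, *_ = np.linalg.lstsq(network.stoich.T, -drops, rcond=None)
    realised = -(network.stoich.T @ mu)
    total = float(realised.sum())
    if overall_favourability == 0.0:
        return ThermoSpec.from_potentials(
            network, np.zeros(network.n_metabolites), temperature
        )
    if total <= 1e-9:
        raise ModelError(
            "infeasible favourability request: the sampled drops lie (almost) "
            "entirely in the cycle space of this topology"
        )
    mu *= overall_favourability / total
    return ThermoSpec.from_potentials(network, mu, temperature)


def generate_targets(
    network: MetabolicNetwork,
    solution: SteadyStateSolution,
    fraction: float = 1.0,
    subset: tuple[str, ...] | None = None,
    default_mM: float = 1.0,
) -> np.ndarray:
    """Targets (molar, variable species) as a fraction of the unregulated
    prediction.

    For metabolites in ``subset`` (all variable species when None) the
    target is ``fraction`` times the predicted concentration — any
    fraction below 1 guarantees the violating set is non-empty at the
    start.  An empty subset leaves every target at the ``default_mM``
    fallback used for unmeasured metabolites.
    """
    if not 0 < fraction <= 1:
        raise ModelError("fraction must lie in (0, 1]")
    if not solution.converged:
        raise ModelError("targets need a converged unregulated solution")
    predicted = solution.concentrations[network.variable_mask]
    targets = np.full(network.n_variable, default_mM * 1e-3)
    ids = network.variable_ids
    chosen = ids if subset is None else tuple(subset)
    unknown = [m for m in chosen if m not in ids]
    if unknown:
        raise ModelError(f"subset names non-variable metabolites: {unknown}")
    for m in chosen:
        i = ids.index(m)
        targets[i] = fraction * predicted[i]
    return targets


def _toy_chain(seed: int) -> tuple[MetabolicNetwork, SystemState, ThermoSpec]:
    return generate_toy_pathway("chain", 2, (1.0, 1.0), (4.0, 1.0))


def _toy_branch(seed: int) -> tuple[MetabolicNetwork, SystemState, ThermoSpec]:
    network, state, _ = generate_toy_pathway("branch", 3, None, (4.0, 1.0, 1.0))
    thermo = generate_synthetic_thermo(network, 3 * 2.479, seed)
    return network, state, thermo


def _glyc_tca(seed: int) -> tuple[MetabolicNetwork, SystemState, ThermoSpec]:
    network, state = build_ecoli_pathway("glycolysis_tca", "high_nad_low_nadp")
    thermo = generate_synthetic_thermo(network, 260.0, seed)
    return network, state, thermo


SCENARIOS = {
    "toy-chain": _toy_chain,
    "branch": _toy_branch,
    "glyc-tca-synthetic": _glyc_tca,
}


def make_scenario(name: str, seed: int = 0, target_fraction: float = 0.75) -> ScenarioSpec:
    """Build a shipped scenario with targets derived from the unregulated
    solution (fraction < 1 so regulation is required)."""
    from .steadystate import solve_steady_state

    if name not in SCENARIOS:
        raise ModelError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")
    network, state, thermo = SCENARIOS[name](seed)
    sol = solve_steady_state(network, thermo, state, seed=seed)
    targets = generate_targets(network, sol, fraction=target_fraction)
    return ScenarioSpec(name, network, state, thermo, targets, seed)


def write_scenario(spec: ScenarioSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write model.json, thermo.tsv and targets.tsv for a scenario."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": out / "model.json",
        "thermo": out / "thermo.tsv",
        "targets": out / "targets.tsv",
    }
    write_model(paths["model"], spec.network, spec.state)
    write_thermo(paths["thermo"], spec.network, spec.thermo)
    write_targets(
        paths["targets"],
        {
            m: t * 1e3
            for m, t in zip(spec.network.variable_ids, spec.targets)
        },
    )
    return paths
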