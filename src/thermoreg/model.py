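"""Stoichiometric networks with a fixed/variable species partition.

A metabolic network is an M x Z signed stoichiometric matrix ``S`` whose
rows (metabolites) are split into a variable block ``S_V`` (species whose
steady-state concentrations are solved for) and a boundary block ``S_B``
(species clamped at fixed concentrations to impose non-equilibrium driving:
nutrients, wastes and cofactor pools).  Concentrations are held internally
in molar against a 1 M standard state; file interfaces use mM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelError",
    "MetabolicNetwork",
    "SystemState",
    "ThermoSpec",
    "GAS_CONSTANT_KJ",
    "build_network",
    "build_ecoli_pathway",
    "generate_toy_pathway",
    "load_model",
    "write_model",
    "load_thermo",
    "write_thermo",
    "load_targets",
    "write_targets",
]

#: molar gas constant, kJ mol^-1 K^-1
GAS_CONSTANT_KJ = 8.31446261815324e-3


class ModelError(ValueError):
    """Raised for inconsistent network, thermodynamic or file input."""


@dataclass(frozen=True)
class MetabolicNetwork:
    """Reaction stoichiometry with a variable/boundary metabolite partition.

    Attributes
    ----------
    reaction_ids : ordered reaction identifiers (length Z).
    metabolite_ids : ordered metabolite identifiers (length M).
    stoich : (M, Z) signed stoichiometric coefficients gamma_{i,j};
        negative entries are substrates of the forward direction,
        positive entries products.
    variable_mask : boolean (M,) — True for species solved at steady
        state, False for clamped boundary species.
    """

    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    stoich: np.ndarray
    variable_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich", np.asarray(self.stoich, dtype=float))
        object.__setattr__(
            self, "variable_mask", np.asarray(self.variable_mask, dtype=bool)
        )
        if self.stoich.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ModelError(
                f"stoichiometry shape {self.stoich.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x "
                f"{len(self.reaction_ids)} reactions"
            )
        if self.variable_mask.shape != (len(self.metabolite_ids),):
            raise ModelError("variable_mask length does not match metabolites")

    # -- sizes ---------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_variable(self) -> int:
        return int(self.variable_mask.sum())

    @property
    def n_boundary(self) -> int:
        return self.n_metabolites - self.n_variable

    # -- matrix blocks -------------------------------------------------
    @property
    def stoich_variable(self) -> np.ndarray:
        """S_V, the (M_V, Z) rows of S for variable species."""
        return self.stoich[self.variable_mask]

    @property
    def stoich_boundary(self) -> np.ndarray:
        """S_B, the (M_B, Z) rows of S for boundary species."""
        return self.stoich[~self.variable_mask]

    @property
    def forward_exponents(self) -> np.ndarray:
        """nu_{i,j} for the forward direction (unsigned substrate counts)."""
        return np.maximum(-self.stoich, 0.0)

    @property
    def reverse_exponents(self) -> np.ndarray:
        """nu_{i,j} for the reverse direction (unsigned product counts)."""
        return np.maximum(self.stoich, 0.0)

    @property
    def variable_ids(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.metabolite_ids)[self.variable_mask])

    @property
    def boundary_ids(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.metabolite_ids)[~self.variable_mask])

    def metabolite_index(self, met_id: str) -> int:
        return self.metabolite_ids.index(met_id)

    def reaction_index(self, rxn_id: str) -> int:
        return self.reaction_ids.index(rxn_id)


@dataclass
class SystemState:
    """Concentrations (molar, all M species) and per-reaction activities.

    Activities alpha_j in [0, 1] act as rheostats on the net thermodynamic
    driving force of each reaction: 1.0 means no regulation, 0.0 complete
    inhibition.  Boundary concentrations are never mutated by solvers.
    """

    concentrations: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ModelError("all concentrations must be positive")
        if np.any((self.activities < 0) | (self.activities > 1)):
            raise ModelError("activities must lie in [0, 1]")

    def copy(self) -> "SystemState":
        return SystemState(self.concentrations.copy(), self.activities.copy())

    def with_activities(self, activities: np.ndarray) -> "SystemState":
        return SystemState(self.concentrations.copy(), np.asarray(activities, float))

    def variable_concentrations(self, network: MetabolicNetwork) -> np.ndarray:
        return self.concentrations[network.variable_mask]

    def boundary_concentrations(self, network: MetabolicNetwork) -> np.ndarray:
        return self.concentrations[~network.variable_mask]


@dataclass(frozen=True)
class ThermoSpec:
    """Per-reaction equilibrium constants at a stated temperature.

    ``K_j`` are dimensionless against a 1 M standard state.  When built
    from standard transformed reaction free energies (kJ/mol),
    ``K_j = exp(-dG°'_j / R_g T)``.  Optional per-metabolite standard
    chemical potentials ``mu°_i`` (kJ/mol) allow equilibrium checks against
    the Boltzmann distribution n_i ∝ exp(-mu°_i / R_g T).
    """

    equilibrium_constants: np.ndarray
    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KJ
    standard_potentials: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "equilibrium_constants",
            np.asarray(self.equilibrium_constants, dtype=float),
        )
        if np.any(self.equilibrium_constants <= 0):
            raise ModelError("equilibrium constants must be positive")
        if self.standard_potentials is not None:
            object.__setattr__(
                self,
                "standard_potentials",
                np.asarray(self.standard_potentials, dtype=float),
            )

    @property
    def rt(self) -> float:
        """R_g T in kJ/mol."""
        return self.gas_constant * self.temperature

    @property
    def delta_g_standard(self) -> np.ndarray:
        """Standard transformed reaction free energies, kJ/mol."""
        return -self.rt * np.log(self.equilibrium_constants)

    @classmethod
    def from_delta_g(
        cls,
        delta_g_kj_mol: Iterable[float],
        temperature: float = 298.15,
        standard_potentials: np.ndarray | None = None,
    ) -> "ThermoSpec":
        dg = np.asarray(list(delta_g_kj_mol), dtype=float)
        rt = GAS_CONSTANT_KJ * temperature
        return cls(np.exp(-dg / rt), temperature, GAS_CONSTANT_KJ, standard_potentials)

    @classmethod
    def from_potentials(
        cls,
        network: MetabolicNetwork,
        potentials_kj_mol: np.ndarray,
        temperature: float = 298.15,
    ) -> "ThermoSpec":
        """Build K from per-metabolite standard chemical potentials.

        dG°'_j = sum_i gamma_{i,j} mu°_i; path-independence (Wegscheider
        consistency) on cyclic topologies is automatic.
        """
        mu = np.asarray(potentials_kj_mol, dtype=float)
        dg = network.stoich.T @ mu
        return cls.from_delta_g(dg, temperature, standard_potentials=mu)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(
    reaction_specs: Sequence[tuple[str, Mapping[str, float]]],
    metabolite_specs: Sequence[tuple[str, bool, float | None]],
    *,
    activities: np.ndarray | None = None,
    check_determined: bool = True,
) -> tuple[MetabolicNetwork, SystemState]:
    """Assemble a network and its initial state from explicit specs.

    Parameters
    ----------
    reaction_specs : ordered (reaction id, {metabolite id: signed coeff}).
    metabolite_specs : ordered (metabolite id, fixed flag, concentration in
        mM).  Fixed species must carry a positive concentration; variable
        species default to 1.0 mM when None.
    check_determined : when True (default), raise if M_V > Z — the
        steady-state system is then underdetermined.  Closed-system
        fixtures (equilibrium studies) may pass False.
    """
    rxn_ids = [r for r, _ in reaction_specs]
    met_ids = [m for m, _, _ in metabolite_specs]
    if len(set(rxn_ids)) != len(rxn_ids):
        raise ModelError("duplicate reaction id")
    if len(set(met_ids)) != len(met_ids):
        raise ModelError("duplicate metabolite id")
    met_index = {m: i for i, m in enumerate(met_ids)}

    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, (rid, coeffs) in enumerate(reaction_specs):
        if not coeffs or all(c == 0 for c in coeffs.values()):
            raise ModelError(f"reaction {rid!r} has no nonzero coefficient")
        for met, c in coeffs.items():
            if met not in met_index:
                raise ModelError(f"reaction {rid!r} references unknown metabolite {met!r}")
            S[met_index[met], j] = c

    variable = np.array([not fixed for _, fixed, _ in metabolite_specs])
    conc_molar = np.empty(len(met_ids))
    for i, (mid, fixed, conc_mM) in enumerate(metabolite_specs):
        if fixed:
            if conc_mM is None or conc_mM <= 0:
                raise ModelError(
                    f"fixed metabolite {mid!r} requires a positive concentration"
                )
            conc_molar[i] = conc_mM * 1e-3
        else:
            conc_molar[i] = (conc_mM if conc_mM is not None else 1.0) * 1e-3
            if conc_molar[i] <= 0:
                raise ModelError(f"metabolite {mid!r} has non-positive concentration")

    n_var, n_rxn = int(variable.sum()), len(rxn_ids)
    if check_determined and n_var > n_rxn:
        raise ModelError(
            f"underdetermined network: {n_var} variable metabolites exceed "
            f"{n_rxn} reactions (M_V <= Z required for a unique steady state)"
        )
    network = MetabolicNetwork(tuple(rxn_ids), tuple(met_ids), S, variable)
    if activities is None:
        activities = np.ones(n_rxn)
    state = SystemState(conc_molar, np.asarray(activities, float))
    return network, state


# ---------------------------------------------------------------------------
# E. coli central-metabolism builders
# ---------------------------------------------------------------------------

# Boundary concentrations (mM): glucose-fed exponential growth, fixed pools
# that keep the whole system out of equilibrium.  Water is an explicit
# boundary species at 55.5 M; supplied dG°' must use the matching convention.
_BOUNDARY_MM = {
    "glc__D": 1.0,
    "glu__L": 9.6e-2,
    "gln__L": 3.81,
    "adp": 5.6e-1,
    "atp": 9.6,
    "pi": 20.0,
    "nadh": 8.3e-2,
    "nad": 2.6,
    "h2o": 55.5e3,
    "co2": 0.1,
    "coa": 1.4,
}

# Completion of the boundary set to the documented 20 species: the
# NADP/NADPH pair used by the oxidative PPP, the quinone pool reduced by
# succinate dehydrogenase, and a mitochondrial-compartment pool (NAD_m,
# CoA_m, CO2_m, H2O_m) implied by the explicit pyruvate transporter PYRt2m.
_NADH_MM = 8.3e-2
_NAD_OVER_NADH = 31.3
_BOUNDARY_EXTRA_MM = {
    "q8": 1.0,
    "q8h2": 1.0,
    "nad_m": 2.6,
    "nadh_m": _NADH_MM,
    "co2_m": 0.1,
    "h2o_m": 55.5e3,
    "coa_m": 1.4,
}

_GLYCOLYSIS = [
    ("HEX1", {"glc__D": -1, "atp": -1, "g6p": 1, "adp": 1}),
    ("PGI", {"g6p": -1, "f6p": 1}),
    ("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}),
    ("FBA", {"fdp": -1, "dhap": 1, "g3p": 1}),
    ("TPI", {"dhap": -1, "g3p": 1}),
    ("GAPD", {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "nadh": 1}),
    ("PGK", {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}),
    ("PGM", {"3pg": -1, "2pg": 1}),
    ("ENO", {"2pg": -1, "pep": 1, "h2o": 1}),
    ("PYK", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}),
    # pure translocation between pools; K = 1 unless a dG°' is supplied
    ("PYRt2m", {"pyr": -1, "pyr_m": 1}),
    ("PDH", {"pyr_m": -1, "coa": -1, "nad_m": -1, "accoa": 1, "co2_m": 1, "nadh_m": 1}),
]

_PPP = [
    ("G6PDH", {"g6p": -1, "nadp": -1, "6pgl": 1, "nadph": 1}),
    ("PGL", {"6pgl": -1, "h2o": -1, "6pgc": 1}),
    ("GND", {"6pgc": -1, "nadp": -1, "ru5p__D": 1, "co2": 1, "nadph": 1}),
    ("RPI", {"ru5p__D": -1, "r5p": 1}),
    ("RPE", {"ru5p__D": -1, "xu5p__D": 1}),
    ("TKT1", {"xu5p__D": -1, "r5p": -1, "s7p": 1, "g3p": 1}),
    ("TALA", {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}),
    ("TKT2", {"xu5p__D": -1, "e4p": -1, "f6p": 1, "g3p": 1}),
]

_TCA = [
    ("CSM", {"accoa": -1, "oaa": -1, "h2o_m": -1, "cit": 1, "coa_m": 1}),
    ("ACONT", {"cit": -1, "icit": 1}),
    ("ICDH", {"icit": -1, "nad_m": -1, "akg": 1, "co2_m": 1, "nadh_m": 1}),
    ("AKGD", {"akg": -1, "coa_m": -1, "nad_m": -1, "succoa": 1, "co2_m": 1, "nadh_m": 1}),
    ("SUCOAS", {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "atp": 1, "coa_m": 1}),
    ("SUCD", {"succ": -1, "q8": -1, "fum": 1, "q8h2": 1}),
    ("FUM", {"fum": -1, "h2o_m": -1, "mal__L": 1}),
    ("MDH", {"mal__L": -1, "nad_m": -1, "oaa": 1, "nadh_m": 1}),
]

# NADH-dependent glutamine:2-oxoglutarate amidotransferase; maintains a
# defined species count in the TCA cycle by coupling 2-oxoglutarate to the
# fixed glutamate/glutamine pools.
_GOGAT = ("GOGAT", {"akg": -1, "gln__L": -1, "nadh_m": -1, "glu__L": 2, "nad_m": 1})

# Gluconeogenic direction; glucose 6-phosphatase is folded into the fixed
# G6P product pool so the pathway keeps its canonical 10-reaction roster
# while retaining PC and FBP.
_GLUCONEOGENESIS = [
    ("PC", {"pyr": -1, "atp": -1, "co2": -1, "oaa": 1, "adp": 1, "pi": 1}),
    ("PPCK", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}),
    ("ENO_r", {"pep": -1, "h2o": -1, "2pg": 1}),
    ("PGM_r", {"2pg": -1, "3pg": 1}),
    ("PGK_r", {"3pg": -1, "atp": -1, "13dpg": 1, "adp": 1}),
    ("GAPD_r", {"13dpg": -1, "nadh": -1, "g3p": 1, "nad": 1, "pi": 1}),
    ("TPI_r", {"g3p": -1, "dhap": 1}),
    ("FBA_r", {"dhap": -1, "g3p": -1, "fdp": 1}),
    ("FBP", {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}),
    ("PGI", {"f6p": -1, "g6p": 1}),
]

ECOLI_PATHWAYS = ("gluconeogenesis", "glycolysis_tca", "glycolysis_ppp_tca")
ECOLI_CONDITIONS = ("high_nad_low_nadp", "high_nad_high_nadp")


def build_ecoli_pathway(
    name: str,
    condition: str = "high_nad_low_nadp",
    pfk_off: bool = False,
) -> tuple[MetabolicNetwork, SystemState]:
    """Assemble one of the three central-metabolism models.

    ``condition`` sets the clamped NADP+/NADPH ratio: 0.02 (low, favouring
    glycolytic flux) or 31.3 (high, matching the NAD+/NADH ratio and
    favouring PPP flux).  ``pfk_off`` pins alpha_PFK = 0 so flux must be
    channelled through the pentose phosphate pathway.
    """
    if name not in ECOLI_PATHWAYS:
        raise ModelError(f"unknown pathway {name!r}; expected one of {ECOLI_PATHWAYS}")
    if condition not in ECOLI_CONDITIONS:
        raise ModelError(
            f"unknown condition {condition!r}; expected one of {ECOLI_CONDITIONS}"
        )

    if name == "gluconeogenesis":
        reactions = list(_GLUCONEOGENESIS)
    elif name == "glycolysis_tca":
        reactions = list(_GLYCOLYSIS) + list(_TCA) + [_GOGAT]
    else:
        reactions = list(_GLYCOLYSIS) + list(_PPP) + list(_TCA) + [_GOGAT]

    boundary_mM = dict(_BOUNDARY_MM)
    boundary_mM.update(_BOUNDARY_EXTRA_MM)
    # NADPH clamped at the NADH level; NADP+ follows the condition ratio
    # (only the ratio is constrained by the study conditions).
    ratio = 0.02 if condition == "high_nad_low_nadp" else _NAD_OVER_NADH
    boundary_mM["nadph"] = _NADH_MM
    boundary_mM["nadp"] = ratio * _NADH_MM
    if name == "gluconeogenesis":
        boundary_mM = dict(_BOUNDARY_MM)
        boundary_mM["pyr"] = 1.0   # gluconeogenic carbon source
        boundary_mM["g6p"] = 1.0   # fixed product pool (G6Pase sink)

    used = []
    seen = set()
    for _, coeffs in reactions:
        for met in coeffs:
            if met not in seen:
                seen.add(met)
                used.append(met)
    met_specs = []
    for met in used:
        if met in boundary_mM:
            met_specs.append((met, True, boundary_mM[met]))
        else:
            met_specs.append((met, False, 1.0))

    network, state = build_network(reactions, met_specs)
    if pfk_off:
        if "PFK" not in network.reaction_ids:
            raise ModelError(f"pathway {name!r} has no PFK reaction to switch off")
        state.activities[network.reaction_index("PFK")] = 0.0
    return network, state


# ---------------------------------------------------------------------------
# toy fixtures with closed-form solutions
# ---------------------------------------------------------------------------

def generate_toy_pathway(
    topology: str,
    length: int = 2,
    K_values: Sequence[float] | None = None,
    boundary_values: Sequence[float] | None = None,
) -> tuple[MetabolicNetwork, SystemState, ThermoSpec]:
    """Deterministic toy networks used as solver oracles.

    ``chain``: X0 <=> X1 <=> ... <=> X_L with both ends fixed; length 2
    with K=(1,1) and boundaries (4,1) is the canonical closed-form case
    (the intermediate solves to 2 with flux 1.5).
    ``branch``: X0 -> HUB, then HUB -> each of (length-1) fixed sinks.
    ``cycle``: 8 reactions over 7 cyclic intermediates with a fixed feed,
    a fixed waste and one internal bypass (M_V < Z, as in a TCA-like loop).

    Boundary/K values are in the same concentration units (treated as molar
    internally against a unit standard state).
    """
    if length < 1:
        raise ModelError("length must be >= 1")
    if topology == "chain":
        n_rxn = length
        species = [f"X{i}" for i in range(length + 1)]
        reactions = [
            (f"R{j + 1}", {species[j]: -1, species[j + 1]: 1}) for j in range(length)
        ]
        boundary = boundary_values if boundary_values is not None else (4.0, 1.0)
        if len(boundary) != 2:
            raise ModelError("chain boundary_values must be (source, sink)")
        fixed = {species[0]: boundary[0], species[-1]: boundary[1]}
    elif topology == "branch":
        n_sinks = max(length - 1, 2)
        n_rxn = 1 + n_sinks
        species = ["X0", "HUB"] + [f"SINK{k}" for k in range(n_sinks)]
        reactions = [("R1", {"X0": -1, "HUB": 1})] + [
            (f"R{k + 2}", {"HUB": -1, f"SINK{k}": 1}) for k in range(n_sinks)
        ]
        boundary = (
            boundary_values if boundary_values is not None else (4.0,) + (1.0,) * n_sinks
        )
        if len(boundary) != 1 + n_sinks:
            raise ModelError("branch boundary_values must be (source, sink...)")
        fixed = {"X0": boundary[0]}
        fixed.update({f"SINK{k}": boundary[k + 1] for k in range(n_sinks)})
    elif topology == "cycle":
        # feed: S + C7 -> C1; ring C1 -> ... -> C7; exit C2 -> C3 + W;
        # bypass C3 -> C5.  Eight reactions, seven intermediates.
        n_rxn = 8
        species = ["S", "W"] + [f"C{i}" for i in range(1, 8)]
        reactions = [
            ("FEED", {"S": -1, "C7": -1, "C1": 1}),
            ("R12", {"C1": -1, "C2": 1}),
            ("R23", {"C2": -1, "C3": 1, "W": 1}),
            ("R34", {"C3": -1, "C4": 1}),
            ("R45", {"C4": -1, "C5": 1}),
            ("R56", {"C5": -1, "C6": 1}),
            ("R67", {"C6": -1, "C7": 1}),
            ("BYPASS", {"C3": -1, "C5": 1}),
        ]
        boundary = boundary_values if boundary_values is not None else (4.0, 1.0)
        if len(boundary) != 2:
            raise ModelError("cycle boundary_values must be (feed, waste)")
        fixed = {"S": boundary[0], "W": boundary[1]}
    else:
        raise ModelError(f"unknown topology {topology!r}")

    if K_values is None:
        K_values = np.ones(n_rxn)
    K_values = np.asarray(K_values, dtype=float)
    if K_values.shape != (n_rxn,):
        raise ModelError(f"{topology} of this size needs {n_rxn} K values")
    if np.any(K_values <= 0):
        raise ModelError("equilibrium constants must be positive")
    if any(v <= 0 for v in fixed.values()):
        raise ModelError("boundary concentrations must be positive")

    met_specs = [
        (m, m in fixed, fixed.get(m, 1.0) * 1e3)  # *1e3: specs are in mM units
        for m in species
    ]
    network, state = build_network(reactions, met_specs)
    thermo = ThermoSpec(K_values)
    return network, state, thermo


# ---------------------------------------------------------------------------
# file I/O (model JSON, thermo/targets TSV; concentrations in mM)
# ---------------------------------------------------------------------------

def write_model(
    path: str | Path, network: MetabolicNetwork, state: SystemState
) -> None:
    doc = {
        "reactions": [
            {
                "id": rid,
                "stoichiometry": {
                    met: network.stoich[i, j]
                    for i, met in enumerate(network.metabolite_ids)
                    if network.stoich[i, j] != 0
                },
            }
            for j, rid in enumerate(network.reaction_ids)
        ],
        "metabolites": [
            {
                "id": mid,
                "fixed": bool(not network.variable_mask[i]),
                "concentration_mM": state.concentrations[i] * 1e3,
            }
            for i, mid in enumerate(network.metabolite_ids)
        ],
        "activities": {
            rid: state.activities[j] for j, rid in enumerate(network.reaction_ids)
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> tuple[MetabolicNetwork, SystemState]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"model file {path}: invalid JSON ({exc})") from exc
    for key in ("reactions", "metabolites"):
        if key not in doc:
            raise ModelError(f"model file {path}: missing top-level field {key!r}")
    reaction_specs = []
    for entry in doc["reactions"]:
        if "id" not in entry or "stoichiometry" not in entry:
            raise ModelError(
                f"model file {path}: reaction entry needs 'id' and 'stoichiometry'"
            )
        reaction_specs.append((entry["id"], entry["stoichiometry"]))
    met_specs = []
    for entry in doc["metabolites"]:
        if "id" not in entry or "fixed" not in entry:
            raise ModelError(
                f"model file {path}: metabolite entry needs 'id' and 'fixed'"
            )
        met_specs.append(
            (entry["id"], bool(entry["fixed"]), entry.get("concentration_mM"))
        )
    network, state = build_network(reaction_specs, met_specs)
    if "activities" in doc:
        alpha = np.ones(network.n_reactions)
        for rid, a in doc["activities"].items():
            alpha[network.reaction_index(rid)] = a
        state = state.with_activities(alpha)
    return network, state


def write_thermo(path: str | Path, network: MetabolicNetwork, thermo: ThermoSpec) -> None:
    pd.DataFrame(
        {
            "reaction_id": network.reaction_ids,
            "K": thermo.equilibrium_constants,
            "delta_g_prime_kj_mol": thermo.delta_g_standard,
        }
    ).to_csv(path, sep="\t", index=False)


def load_thermo(
    path: str | Path, network: MetabolicNetwork, temperature: float = 298.15
) -> ThermoSpec:
    """Read a TSV with columns reaction_id and K and/or delta_g_prime_kj_mol.

    If both are present they must agree to 1e-6 relative.
    """
    df = pd.read_csv(path, sep="\t")
    if "reaction_id" not in df.columns:
        raise ModelError(f"thermo file {path}: missing 'reaction_id' column")
    has_k = "K" in df.columns
    has_dg = "delta_g_prime_kj_mol" in df.columns
    if not has_k and not has_dg:
        raise ModelError(
            f"thermo file {path}: need a 'K' or 'delta_g_prime_kj_mol' column"
        )
    df = df.set_index("reaction_id")
    missing = [r for r in network.reaction_ids if r not in df.index]
    if missing:
        raise ModelError(f"thermo file {path}: missing reactions {missing}")
    rt = GAS_CONSTANT_KJ * temperature
    if has_k:
        K = df.loc[list(network.reaction_ids), "K"].to_numpy(float)
        if np.any(K <= 0):
            raise ModelError(f"thermo file {path}: K must be positive")
    if has_dg:
        dg = df.loc[list(network.reaction_ids), "delta_g_prime_kj_mol"].to_numpy(float)
        K_dg = np.exp(-dg / rt)
    if has_k and has_dg:
        rel = np.abs(K - K_dg) / K
        if np.any(rel > 1e-6):
            worst = network.reaction_ids[int(np.argmax(rel))]
            raise ModelError(
                f"thermo file {path}: K and delta_g_prime disagree beyond 1e-6 "
                f"relative (worst: {worst})"
            )
    return ThermoSpec(K if has_k else K_dg, temperature)


def write_targets(path: str | Path, targets_mM: Mapping[str, float]) -> None:
    pd.DataFrame(
        {"metabolite_id": list(targets_mM), "concentration_mM": list(targets_mM.values())}
    ).to_csv(path, sep="\t", index=False)


def load_targets(
    path: str | Path, network: MetabolicNetwork, default_mM: float = 1.0
) -> np.ndarray:
    """Target concentrations (molar) for the variable species.

    Metabolites absent from the file default to ``default_mM`` (1.0 mM, the
    assumption for unmeasured metabolites).  Boundary species are never
    targeted.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("metabolite_id", "concentration_mM"):
        if col not in df.columns:
            raise ModelError(f"targets file {path}: missing column {col!r}")
    given = dict(zip(df["metabolite_id"], df["concentration_mM"]))
    if any(v <= 0 for v in given.values()):
        raise ModelError(f"targets file {path}: targets must be positive")
    return np.array(
        [given.get(m, default_mM) * 1e-3 for m in network.variable_ids], dtype=float
    )


def default_targets(network: MetabolicNetwork, default_mM: float = 1.0) -> np.ndarray:
    """Uniform default target (molar) for every variable species."""
    return np.full(network.n_variable, default_mM * 1e-3)
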