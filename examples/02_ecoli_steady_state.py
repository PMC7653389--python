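"""Unregulated steady state of the glycolysis-TCA model.

Synthetic favourable equilibrium constants stand in for database-derived
reaction energetics; the stoichiometric structure of the solution does not
depend on the individual K values.  One hexose splits into two trioses at
FBA, so lower glycolysis and the TCA cycle carry twice the molar flux of
upper glycolysis — and, at the max-path-entropy steady state, twice the
thermodynamic odds (a dG offset of -R_gT ln 2).
"""

import numpy as np

import thermoreg as tr

net, state = tr.build_ecoli_pathway("glycolysis_tca")
thermo = tr.generate_synthetic_thermo(net, 260.0, seed=1)
sol = tr.solve_steady_state(net, thermo, state)
print("converged:", sol.converged, " max |S_V J|:", f"{sol.mass_balance_inf_norm:.2e}")

idx = {r: i for i, r in enumerate(net.reaction_ids)}
print(f"{'reaction':8s} {'flux':>10s} {'odds':>10s} {'dG kJ/mol':>10s}")
for r in ("HEX1", "PGI", "PFK", "FBA", "TPI", "GAPD", "PYK", "PDH", "CSM", "MDH"):
    j = idx[r]
    print(
        f"{r:8s} {sol.net_fluxes[j]:10.2f} {sol.forward_odds[j]:10.2f} "
        f"{sol.delta_g[j]:10.3f}"
    )
ratio = sol.forward_odds[idx["GAPD"]] / sol.forward_odds[idx["PGI"]]
print(f"lower/upper odds ratio = {ratio:.4f} (stoichiometric factor of two)")
print(
    "dG(GAPD) - dG(PGI) =",
    round(sol.delta_g[idx["GAPD"]] - sol.delta_g[idx["PGI"]], 4),
    "kJ/mol; -R_gT ln 2 =",
    round(-tr.GAS_CONSTANT_KJ * 298.15 * np.log(2), 4),
)
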