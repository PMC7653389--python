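"""Train an n-step SARSA agent to regulate the toy chain.

The agent starts unregulated each episode, reduces one activity by 0.05
per step, and is rewarded by scaled reductions of Lambda plus the entropy
production rate when it reaches calibre (all concentrations at or below
target).  With annealed exploration the mean episode reward rises, and the
best terminal state dissipates nearly as fast as the (continuous) MCA
optimum.
"""

import numpy as np

import thermoreg as tr

net, state, thermo = tr.generate_toy_pathway("chain", 2, (1.0, 1.0), (4.0, 1.0))
targets = np.array([1.5])  # 0.75 x the unregulated prediction of 2.0

res = tr.train_agent(tr.RLConfig(episodes=150, seed=3), net, thermo, state, targets)
print("episodes:", len(res.episode_rewards), " terminal states:", len(res.terminal_states))
print(f"mean reward, first 50 episodes: {np.mean(res.episode_rewards[:50]):.3f}")
print(f"mean reward, last 50 episodes:  {np.mean(res.episode_rewards[-50:]):.3f}")

best = res.best_terminal
print("best scheme activities:", best["activities"], " EPR:", round(best["EPR"], 4))

mca = tr.run_mca_regulation(net, thermo, state, targets)
mca_epr = tr.dissipation_rates(mca.final_solution).entropy_production_rate
print(f"max terminal EPR {res.max_terminal_epr:.4f} vs MCA EPR {mca_epr:.4f} "
      f"({100 * res.max_terminal_epr / mca_epr:.1f}% of the continuous optimum)")
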