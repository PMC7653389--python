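"""Reinforcement-learning search for regulation schemes.

Regulation is cast as a Markov decision process: states are the activity
vectors alpha in [0, 1]^Z (on a finite lattice, since each action reduces
one activity by a fixed step), actions pick the reaction to regulate, and
transitions are deterministic (each action triggers a steady-state
re-solve).  Intermediate rewards are scaled reductions of the loss
Lambda = ln(sum_i n~_i / n_i); reaching calibre (L = 0) additionally pays
the entropy production rate of the terminal state, so among schemes that
control concentrations the agent prefers those that dissipate fastest.
Learning uses on-policy n-step SARSA with an epsilon-greedy policy and a
small single-hidden-layer tanh network as state-value approximator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import calibre_losses, dissipation_rates
from .model import MetabolicNetwork, ModelError, SystemState, ThermoSpec
from .steadystate import SteadyStateSolution, solve_steady_state

__all__ = [
    "RLConfig",
    "AgentResult",
    "SweepResult",
    "RegulationEnvironment",
    "ValueNetwork",
    "environment_step",
    "epsilon_greedy_action",
    "train_agent",
    "agent_sweep",
]


@dataclass(frozen=True)
class RLConfig:
    """Hyperparameters of one SARSA agent.

    ``epsilon_initial`` defaults to 0.5 for networks of up to 12 reactions
    and 0.2 for larger ones; it is divided by ``anneal_divisor`` every
    ``anneal_every`` episodes.  ``reward_scale`` (eta) defaults to
    Lambda(s0)/10 so intermediate rewards are O(1).  ``action_step`` is
    the fixed activity decrement, placing states on a lattice.
    """

    n_step: int = 4
    learning_rate: float = 1e-4
    discount: float = 0.9
    epsilon_initial: float | None = None
    anneal_every: int = 25
    anneal_divisor: float = 2.0
    reward_scale: float | None = None
    action_step: float = 0.05
    episodes: int = 350
    agents_per_setting: int = 10
    hidden_width: int = 64
    max_episode_steps: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_step < 1 or self.episodes < 1:
            raise ModelError("n_step and episodes must be positive")
        if not 0 <= self.discount <= 1:
            raise ModelError("discount must lie in [0, 1]")
        if self.epsilon_initial is not None and not 0 < self.epsilon_initial <= 1:
            raise ModelError("epsilon_initial must lie in (0, 1]")
        if not 0 < self.action_step <= 1:
            raise ModelError("action_step must lie in (0, 1]")
        if self.reward_scale is not None and self.reward_scale <= 0:
            raise ModelError("reward_scale must be positive")


@dataclass
class AgentResult:
    """Outcome of training one agent."""

    config: RLConfig
    episode_rewards: list[float]
    episode_steps: list[int]
    terminal_states: list[dict]  # {activities, L, Lambda, EPR, dE_dt, episode, reward}
    value_network: "ValueNetwork"
    episode_reward_traces: list[list[float]] = field(default_factory=list)
    aborted: bool = False
    abort_reason: str = ""

    @property
    def score(self) -> float:
        """Cumulative episode reward averaged over the last 50 terminal states."""
        rewards = [t["reward"] for t in self.terminal_states[-50:]]
        return float(np.mean(rewards)) if rewards else -np.inf

    @property
    def max_terminal_epr(self) -> float:
        """Largest EPR in the terminal-state population found in training."""
        eprs = [t["EPR"] for t in self.terminal_states]
        return float(max(eprs)) if eprs else float("nan")

    @property
    def best_terminal(self) -> dict | None:
        if not self.terminal_states:
            return None
        return max(self.terminal_states, key=lambda t: t["reward"])


@dataclass
class SweepResult:
    agents: list[AgentResult]
    best_agent: AgentResult
    best_scheme: dict  # best terminal state of the best agent


class ValueNetwork:
    """Single-hidden-layer tanh network V: [0,1]^Z -> R, trained by SGD on
    the squared n-step return error."""

    def __init__(self, n_inputs: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_inputs)
        self.W1 = rng.normal(0.0, scale, size=(hidden, n_inputs))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.b2 = 0.0

    def value(self, x: np.ndarray) -> float:
        h = np.tanh(self.W1 @ x + self.b1)
        return float(self.W2 @ h + self.b2)

    def update(self, x: np.ndarray, target: float, lr: float) -> float:
        """One SGD step on (V(x) - target)^2; returns the new prediction error."""
        h = np.tanh(self.W1 @ x + self.b1)
        v = float(self.W2 @ h + self.b2)
        err = v - target
        grad_out = 2.0 * err
        dW2 = grad_out * h
        db2 = grad_out
        dh = grad_out * self.W2 * (1.0 - h * h)
        self.W1 -= lr * np.outer(dh, x)
        self.b1 -= lr * dh
        self.W2 -= lr * dW2
        self.b2 -= lr * db2
        return err

    def finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.W1))
            and np.all(np.isfinite(self.W2))
            and np.all(np.isfinite(self.b1))
            and np.isfinite(self.b2)
        )


class RegulationEnvironment:
    """Deterministic MDP over the activity lattice.

    Transitions re-solve the steady state; because states live on a finite
    lattice and transitions are deterministic, solutions and losses are
    cached by quantised activity vector.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        thermo: ThermoSpec,
        state: SystemState,
        targets: np.ndarray,
        action_step: float = 0.05,
        reward_scale: float | None = None,
        **solver_kwargs,
    ):
        self.network = network
        self.thermo = thermo
        self.state = state
        self.targets = np.asarray(targets, dtype=float)
        if self.targets.shape != (network.n_variable,):
            raise ModelError("targets must cover exactly the variable species")
        self.action_step = action_step
        self.solver_kwargs = solver_kwargs
        self._cache: dict[tuple[int, ...], tuple[SteadyStateSolution, float, float, float]] = {}
        self.initial_activities = state.activities.copy()
        sol0, L0, lam0, _ = self.evaluate(self.initial_activities)
        if not sol0.converged:
            raise ModelError("unregulated base solution did not converge")
        self.reward_scale = (
            reward_scale
            if reward_scale is not None
            else max(abs(lam0) / 10.0, 1e-6)
        )

    def key(self, alpha: np.ndarray) -> tuple[int, ...]:
        return tuple(np.round(np.asarray(alpha) / self.action_step).astype(int))

    def evaluate(
        self, alpha: np.ndarray
    ) -> tuple[SteadyStateSolution, float, float, float]:
        """(solution, L, Lambda, EPR) at an activity vector, cached."""
        k = self.key(alpha)
        hit = self._cache.get(k)
        if hit is not None:
            return hit
        sol = solve_steady_state(
            self.network,
            self.thermo,
            self.state.with_activities(alpha),
            **self.solver_kwargs,
        )
        loss = calibre_losses(
            sol.concentrations[self.network.variable_mask], self.targets
        )
        epr = dissipation_rates(sol).entropy_production_rate
        out = (sol, loss.stopping_loss, loss.rl_loss, epr)
        self._cache[k] = out
        return out

    def legal_actions(self, alpha: np.ndarray) -> np.ndarray:
        """Actions are masked once an activity cannot absorb a full step."""
        return np.flatnonzero(np.asarray(alpha) >= self.action_step - 1e-12)

    def step(
        self, alpha: np.ndarray, action: int
    ) -> tuple[np.ndarray, float, bool, dict]:
        """Apply one activity decrement and return (s', reward, terminal, info).

        reward = (Lambda(s) - Lambda(s'))/eta, plus EPR(s') when the move
        reaches calibre (L(s') = 0, the terminal condition).
        """
        alpha = np.asarray(alpha, dtype=float)
        if alpha[action] < self.action_step - 1e-12:
            raise ModelError(
                f"action {action} is masked: activity {alpha[action]:.3f} < step"
            )
        sol, _L, lam, _ = self.evaluate(alpha)
        if not sol.converged:
            raise ModelError("episode aborted: steady state failed to converge")
        nxt = alpha.copy()
        nxt[action] = max(nxt[action] - self.action_step, 0.0)
        sol2, L2, lam2, epr2 = self.evaluate(nxt)
        if not sol2.converged:
            return nxt, 0.0, False, {"solver_failure": True}
        terminal = L2 == 0.0
        reward = (lam - lam2) / self.reward_scale
        if terminal:
            reward += epr2
        info = {"L": L2, "Lambda": lam2, "EPR": epr2, "solver_failure": False}
        return nxt, float(reward), bool(terminal), info


def environment_step(
    alpha: np.ndarray,
    action: int,
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    targets: np.ndarray,
    *,
    action_step: float = 0.05,
    reward_scale: float | None = None,
    **solver_kwargs,
) -> tuple[np.ndarray, float, bool]:
    """Single functional environment transition (convenience wrapper)."""
    env = RegulationEnvironment(
        network, thermo, state, targets, action_step, reward_scale, **solver_kwargs
    )
    nxt, reward, terminal, _ = env.step(alpha, action)
    return nxt, reward, terminal


def epsilon_greedy_action(
    value_network: ValueNetwork,
    alpha: np.ndarray,
    env: RegulationEnvironment,
    epsilon: float,
    rng: np.random.Generator,
    discount: float,
) -> int | None:
    """Pick an action: greedy one-step lookahead argmax_a R(s,a,s') + g V(s')
    with probability 1-eps, else a uniform draw among unmasked actions.

    Returns None when every action is masked (episode exhausted).
    """
    legal = env.legal_actions(alpha)
    if legal.size == 0:
        return None
    if rng.uniform() < epsilon:
        return int(rng.choice(legal))
    best, best_val = None, -np.inf
    for a in legal:
        nxt, reward, terminal, info = env.step(alpha, int(a))
        if info.get("solver_failure"):
            continue
        val = reward if terminal else reward + discount * value_network.value(nxt)
        if val > best_val:  # ties resolve to the lowest reaction index
            best, best_val = int(a), val
    if best is None:
        return int(rng.choice(legal))
    return best


def train_agent(
    config: RLConfig,
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    targets: np.ndarray,
    env: RegulationEnvironment | None = None,
    **solver_kwargs,
) -> AgentResult:
    """Train one n-step SARSA agent.

    Every episode starts from the supplied activity vector (all 1.0 unless
    a reaction is pinned off).  The value network is updated online with
    n-step returns truncated at terminals.  Divergent (non-finite) value
    estimates abort training with a diagnostic.
    """
    if env is None:
        env = RegulationEnvironment(
            network,
            thermo,
            state,
            targets,
            config.action_step,
            config.reward_scale,
            **solver_kwargs,
        )
    Z = network.n_reactions
    eps0 = config.epsilon_initial if config.epsilon_initial is not None else (
        0.5 if Z <= 12 else 0.2
    )
    max_steps = (
        config.max_episode_steps
        if config.max_episode_steps is not None
        else int(np.ceil(Z / config.action_step))
    )
    rng = np.random.default_rng(config.seed)
    vnet = ValueNetwork(Z, config.hidden_width, rng)
    gamma = config.discount

    result = AgentResult(
        config=config,
        episode_rewards=[],
        episode_steps=[],
        terminal_states=[],
        value_network=vnet,
    )

    for episode in range(config.episodes):
        eps = eps0 / config.anneal_divisor ** (episode // config.anneal_every)
        alpha = env.initial_activities.copy()
        _, L0, lam0, epr0 = env.evaluate(alpha)
        if L0 == 0.0:
            # degenerate episode: already in calibre at step 0
            result.episode_rewards.append(epr0)
            result.episode_steps.append(0)
            result.episode_reward_traces.append([epr0])
            result.terminal_states.append(
                {
                    "activities": alpha.copy(),
                    "L": L0,
                    "Lambda": lam0,
                    "EPR": epr0,
                    "dE_dt": dissipation_rates(env.evaluate(alpha)[0]).dE_dt,
                    "episode": episode,
                    "reward": epr0,
                }
            )
            continue

        states = [alpha.copy()]
        rewards = [0.0]  # rewards[t] = reward received entering states[t]
        T = np.inf
        t = 0
        total = 0.0
        terminal_info: dict | None = None
        while True:
            if t < T:
                action = epsilon_greedy_action(vnet, states[t], env, eps, rng, gamma)
                if action is None or t >= max_steps:
                    T = t  # exhausted: truncate with no terminal bonus
                else:
                    nxt, r, terminal, info = env.step(states[t], action)
                    if info.get("solver_failure"):
                        result.aborted = True
                        result.abort_reason = "steady-state solver failure mid-episode"
                        T = t
                    else:
                        states.append(nxt)
                        rewards.append(r)
                        total += r
                        if terminal:
                            T = t + 1
                            terminal_info = dict(info)
            tau = t - config.n_step + 1
            if tau >= 0:
                upper = int(min(tau + config.n_step, T))
                G = sum(
                    gamma ** (i - tau - 1) * rewards[i]
                    for i in range(tau + 1, upper + 1)
                )
                if tau + config.n_step < T:
                    G += gamma**config.n_step * vnet.value(states[tau + config.n_step])
                vnet.update(states[tau], G, config.learning_rate)
                if not vnet.finite():
                    result.aborted = True
                    result.abort_reason = "value network diverged (non-finite weights)"
                    return result
            if tau >= T - 1:
                break
            t += 1

        result.episode_rewards.append(total)
        result.episode_steps.append(len(states) - 1)
        result.episode_reward_traces.append(rewards[1:])
        if terminal_info is not None:
            final = states[-1]
            sol_f, Lf, lamf, eprf = env.evaluate(final)
            result.terminal_states.append(
                {
                    "activities": final.copy(),
                    "L": Lf,
                    "Lambda": lamf,
                    "EPR": eprf,
                    "dE_dt": dissipation_rates(sol_f).dE_dt,
                    "episode": episode,
                    "reward": total,
                }
            )
    return result


def agent_sweep(
    network: MetabolicNetwork,
    thermo: ThermoSpec,
    state: SystemState,
    targets: np.ndarray,
    base_config: RLConfig | None = None,
    *,
    n_values: tuple[int, ...] = (2, 4, 6, 8, 10, 12),
    learning_rates: tuple[float, ...] = (1e-4, 1e-5, 1e-6),
    agents_per_setting: int | None = None,
    **solver_kwargs,
) -> SweepResult:
    """Grid sweep over n-step horizon and learning rate.

    ``agents_per_setting`` independent seeded agents are trained per grid
    point (default 10, i.e. 180 runs on the default grid); the returned
    best scheme belongs to the agent with the largest cumulative reward
    averaged over its last 50 terminal states.
    """
    base = base_config or RLConfig()
    n_agents = agents_per_setting or base.agents_per_setting
    env = RegulationEnvironment(
        network, thermo, state, targets, base.action_step, base.reward_scale,
        **solver_kwargs,
    )
    seed_seq = np.random.SeedSequence(base.seed)
    agents: list[AgentResult] = []
    n_settings = len(n_values) * len(learning_rates)
    child_seeds = seed_seq.generate_state(n_settings * n_agents) % (2**31 - 1)
    idx = 0
    for n in n_values:
        for lr in learning_rates:
            for _ in range(n_agents):
                cfg = replace(
                    base, n_step=n, learning_rate=lr, seed=int(child_seeds[idx])
                )
                idx += 1
                agents.append(
                    train_agent(cfg, network, thermo, state, targets, env=env)
                )
    scored = [a for a in agents if a.terminal_states]
    if not scored:
        raise ModelError(
            "no agent reached a terminal state: system uncontrollable under "
            "these RL settings"
        )
    best = max(scored, key=lambda a: a.score)
    return SweepResult(agents=agents, best_agent=best, best_scheme=best.best_terminal)
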