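"""The sender model: a per-round decision loop over memory, trust, and rules.

Each round the agent processes the counterparts one at a time, in an order
sampled by a Boltzmann draw over cumulative payoffs (uniform at round 1).
For each counterpart it blends stored instances into a predicted return
fraction (0.5 prior before any experience), classifies the counterpart's
trust regime, selects increase / decrease / hold from the utility table for
the (regime, predicted-return-bin) context, and adjusts its previous
allocation under the remaining-endowment constraint.

After the round settles, the agent encodes the observed return fractions as
instances, updates the trust accumulators (net-outcome update for
counterparts it interacted with, discount for the rest), computes the
round's total reward according to its variant, and reinforces every rule
that fired.

Lesioned variants: ``trust_only`` freezes the trust-invest accumulator (no
trust-necessity regime), ``no_trust`` freezes both accumulators and reduces
the reward to the sender's own payoff plus the endowment kept.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ClockError, NoExperienceError
from .game import ConfederateSpec, GameConfig, GameLog, RoundRecord, default_specs, run_game
from .memory import MemoryStore, recency_bin, return_bin
from .procedural import UtilityTable, apply_action, predicted_return_bin, select_rule
from .trust import (
    Regime,
    TrustParams,
    TrustState,
    classify_regime,
    compute_reward,
    discount_on_unavailability,
    update_on_outcome,
)

__all__ = ["ModelVariant", "CognitiveAgent", "ModelRuns", "run_model_game"]


class ModelVariant(str, enum.Enum):
    FULL = "full"
    TRUST_ONLY = "trust_only"  # trust-invest accumulator lesioned
    NO_TRUST = "no_trust"      # both accumulators lesioned


@dataclass
class TraceRow:
    round: int
    counterpart: int
    trust: float
    invest: float
    regime: str


class CognitiveAgent:
    """Stateful sender agent for one game."""

    def __init__(
        self,
        config: GameConfig,
        trust_params: TrustParams | None = None,
        memory: MemoryStore | None = None,
        utilities: UtilityTable | None = None,
        variant: ModelVariant = ModelVariant.FULL,
    ) -> None:
        self.config = config
        self.params = trust_params or TrustParams()
        self.memory = memory or MemoryStore()
        self.utilities = utilities or UtilityTable()
        self.variant = ModelVariant(variant)
        n = config.n_confederates
        self.trust_state = TrustState.initial(n, self.params)
        self.cumulative_payoff = np.zeros(n)
        self.last_allocations = np.zeros(n, dtype=int)
        self.last_return_frac: list[float | None] = [None] * n
        self.last_interaction_round: list[int | None] = [None] * n
        self._fired: list[tuple[tuple[str, str], str]] = []
        self._pending_round: int | None = None
        self.trace: list[TraceRow] = []

    # ------------------------------------------------------------------ decide

    def _prior_prediction(self) -> float:
        # 0.5 before any experience, nudged by dispositional (initial) trust.
        return float(np.clip(0.5 + 0.1 * self.params.initial_trust, 0.0, 1.0))

    def predicted_return(self, counterpart: int, round_index: int) -> float:
        context = self._memory_context(counterpart, round_index)
        try:
            return self.memory.blended_prediction(counterpart, context, round_index)
        except NoExperienceError:
            return self._prior_prediction()

    def _memory_context(self, counterpart: int, round_index: int) -> tuple[str, str]:
        last = self.last_interaction_round[counterpart]
        since = None if last is None else round_index - last
        return (return_bin(self.last_return_frac[counterpart]), recency_bin(since))

    def _regime(self, counterpart: int) -> Regime:
        # Lesions freeze the accumulators at their initial values, so the
        # frozen state classifies to the same regime every round.
        return classify_regime(self.trust_state, counterpart, self.params)

    def _processing_order(self, rng: np.random.Generator) -> list[int]:
        """Sequential sampling without replacement, Boltzmann over cumulative
        payoff (normalized by the endowment; temperature = selection noise)."""
        n = len(self.cumulative_payoff)
        temp = self.utilities.noise
        scores = [p / self.config.endowment for p in self.cumulative_payoff]
        remaining = list(range(n))
        order: list[int] = []
        while remaining:
            top = max(scores[i] for i in remaining)
            weights = [math.exp((scores[i] - top) / temp) for i in remaining]
            u = rng.random() * math.fsum(weights)
            acc = 0.0
            pick = len(remaining) - 1
            for j, w in enumerate(weights):
                acc += w
                if u <= acc:
                    pick = j
                    break
            order.append(remaining.pop(pick))
        return order

    def decide_allocations(self, round_index: int, rng: np.random.Generator) -> list[int]:
        """Choose this round's allocations; records the fired rules for credit
        assignment at feedback time."""
        self._fired = []
        allocations = np.zeros(self.config.n_confederates, dtype=int)
        remaining = self.config.endowment
        for c in self._processing_order(rng):
            pred = self.predicted_return(c, round_index)
            context = (self._regime(c).value, predicted_return_bin(pred, self.config.multiplier))
            action = select_rule(self.utilities, context, rng)
            self._fired.append((context, action))
            alloc = apply_action(action, int(self.last_allocations[c]), remaining, self.utilities.step)
            allocations[c] = alloc
            remaining -= alloc
        self._pending_round = round_index
        return [int(a) for a in allocations]

    # ----------------------------------------------------------------- observe

    def observe_feedback(self, record: RoundRecord) -> None:
        """Learn from a settled round: encode instances, update accumulators,
        deliver the total reward to every fired rule, update payoffs."""
        if self._pending_round is not None and record.round != self._pending_round:
            raise ClockError(
                f"feedback for round {record.round}, expected {self._pending_round}"
            )
        self._apply_trust_and_memory(record)
        reward = self._round_reward(record) / self.config.endowment
        for context, action in self._fired:
            self.utilities.update(context, action, reward)
        self._fired = []
        self._finalize_round(record)

    def yoked_update(self, record: RoundRecord) -> None:
        """Observe a round the agent did not decide (a participant's logged
        decisions and payoffs): memory and accumulator updates only, no
        reward delivery.  Used for latent-state inference."""
        self._apply_trust_and_memory(record)
        self._finalize_round(record)

    def _finalize_round(self, record: RoundRecord) -> None:
        for c in range(self.config.n_confederates):
            self.cumulative_payoff[c] += record.returned[c]
            if self._interacted(record, c):
                self.last_return_frac[c] = record.returned[c] / record.given[c]
                self.last_interaction_round[c] = record.round
        self.last_allocations = np.array(record.allocations, dtype=int)
        self._pending_round = None
        self._record_trace(record.round)

    @staticmethod
    def _interacted(record: RoundRecord, c: int) -> bool:
        return record.availability[c] and record.allocations[c] > 0

    def _apply_trust_and_memory(self, record: RoundRecord) -> None:
        # Predictions must be taken before any of this round's encodings land
        # in memory: they are the expectations the agent held when it decided.
        preds = [
            self.predicted_return(c, record.round)
            for c in range(self.config.n_confederates)
        ]
        for c in range(self.config.n_confederates):
            if self._interacted(record, c):
                # context at decision time, before this round's observation
                context = self._memory_context(c, record.round)
                self.memory.encode_instance(
                    c, context, record.returned[c] / record.given[c], record.round
                )
                if self.variant is not ModelVariant.NO_TRUST:
                    invest_before = self.trust_state.invest[c]
                    update_on_outcome(
                        self.trust_state,
                        c,
                        record.allocations[c],
                        record.returned[c],
                        self.config.endowment,
                        self.params,
                        expected=preds[c] * record.given[c],
                    )
                    if self.variant is ModelVariant.TRUST_ONLY:
                        self.trust_state.invest[c] = invest_before  # lesioned
            else:
                if self.variant is not ModelVariant.NO_TRUST:
                    attempted = 0.0
                    if not record.availability[c] and record.allocations[c] > 0:
                        attempted = record.allocations[c] / self.config.endowment
                    invest_before = self.trust_state.invest[c]
                    discount_on_unavailability(
                        self.trust_state, c, self.params, attempted_frac=attempted
                    )
                    if self.variant is ModelVariant.TRUST_ONLY:
                        self.trust_state.invest[c] = invest_before  # lesioned

    def _round_reward(self, record: RoundRecord) -> float:
        """Total round reward in points: endowment kept plus refunds plus the
        regime-dependent reward summed over every counterpart.

        Own payoff is the sender's net from the interaction (returned minus
        allocated; zero when no interaction took place, since refunds are
        credited with the endowment), other payoff is the counterpart's gain
        (given minus returned).  The distrust penalty charges the allocation
        whether or not the counterpart turned out to be available."""
        total = float(record.kept + record.refunded)
        for c in range(self.config.n_confederates):
            interacted = self._interacted(record, c)
            own = record.returned[c] - record.allocations[c] if interacted else 0
            other = record.given[c] - record.returned[c]
            if self.variant is ModelVariant.NO_TRUST:
                total += own
            else:
                total += compute_reward(
                    self._regime(c), own, other, record.allocations[c], kept=0.0
                )
        return total

    def _record_trace(self, round_index: int) -> None:
        for c in range(self.config.n_confederates):
            self.trace.append(
                TraceRow(
                    round=round_index,
                    counterpart=c,
                    trust=float(self.trust_state.trust[c]),
                    invest=float(self.trust_state.invest[c]),
                    regime=self._regime(c).value,
                )
            )


# ---------------------------------------------------------------- simulation


@dataclass
class ModelRuns:
    """Output of a batch of independent model games."""

    variant: ModelVariant
    logs: list[GameLog]
    mean_curves: np.ndarray  # (n_rounds, n_confederates)
    agents: list[CognitiveAgent] = field(default_factory=list)


def run_model_game(
    variant: ModelVariant | str,
    trust_params: TrustParams | None = None,
    config: GameConfig | None = None,
    specs: Sequence[ConfederateSpec] | None = None,
    n_runs: int = 1,
    seed: int = 0,
    utility_kwargs: dict | None = None,
    memory_kwargs: dict | None = None,
    keep_agents: bool = False,
) -> ModelRuns:
    """Run ``n_runs`` independent seeded games of the model and average the
    allocation curves across runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    variant = ModelVariant(variant)
    config = config or GameConfig()
    specs = specs or default_specs(config)
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    logs: list[GameLog] = []
    agents: list[CognitiveAgent] = []
    total = np.zeros((config.n_rounds, config.n_confederates))
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        agent = CognitiveAgent(
            config,
            trust_params=trust_params,
            utilities=UtilityTable(**(utility_kwargs or {})),
            memory=MemoryStore(**(memory_kwargs or {})),
            variant=variant,
        )

        def policy(round_index: int, history: list[RoundRecord]) -> list[int]:
            if history:
                agent.observe_feedback(history[-1])
            return agent.decide_allocations(round_index, rng)

        log = run_game(policy, config, specs, rng)
        agent.observe_feedback(log.records[-1])
        logs.append(log)
        total += log.allocation_matrix()
        if keep_agents:
            agents.append(agent)
    return ModelRuns(
        variant=variant, logs=logs, mean_curves=total / n_runs, agents=agents
    )
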