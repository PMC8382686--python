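"""Utility-learned selection among allocation-adjustment rules.

The sender's procedural repertoire is a fixed set of three actions per
context — increase, decrease, or hold the previous allocation to a
counterpart by a fixed step.  A context is (trust regime, predicted-return
bin).  Each (context, action) pair carries a utility updated by the standard
difference-learning rule ``U += alpha * (R - U)`` with the round's total
reward, and actions are sampled from a Boltzmann distribution over utilities
with temperature ``s`` (the noise parameter).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ACTIONS",
    "UtilityTable",
    "update_utility",
    "select_rule",
    "apply_action",
    "boltzmann_probs",
    "predicted_return_bin",
]

ACTIONS: tuple[str, ...] = ("increase", "decrease", "hold")

ContextKey = tuple[str, str]  # (regime label, predicted-return bin)


def predicted_return_bin(predicted_frac: float, multiplier: int) -> str:
    """Bin the predicted points-back-per-point-allocated ratio.

    ratio = predicted return fraction x multiplier: below ~1x the allocation
    ("<1x"), about break-even ("~1x"), or profitable (">1x").
    """
    ratio = predicted_frac * multiplier
    if ratio < 0.9:
        return "<1x"
    if ratio <= 1.1:
        return "~1x"
    return ">1x"


def update_utility(utility: float, reward: float, alpha: float) -> float:
    """One difference-learning step: U + alpha * (R - U)."""
    return utility + alpha * (reward - utility)


def boltzmann_probs(utilities: np.ndarray, temperature: float) -> np.ndarray:
    """Numerically stable softmax of utilities / temperature."""
    z = np.asarray(utilities, dtype=float) / temperature
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


@dataclass
class UtilityTable:
    """Context -> per-action utilities, plus the learning parameters.

    alpha — learning rate in (0, 1]; noise — Boltzmann temperature s > 0;
    step — points added or removed per adjustment (default 4, i.e. 10% of
    the default endowment).
    """

    alpha: float = 0.2
    noise: float = 0.5
    step: int = 4
    table: dict[ContextKey, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.noise <= 0:
            raise ValueError("selection noise must be positive")
        if self.step < 1:
            raise ValueError("step size must be >= 1")

    def utilities(self, context: ContextKey) -> dict[str, float]:
        """Utilities for a context; unseen contexts initialize all actions to 0."""
        return self.table.setdefault(context, {a: 0.0 for a in ACTIONS})

    def update(self, context: ContextKey, action: str, reward: float) -> None:
        utils = self.utilities(context)
        utils[action] = update_utility(utils[action], reward, self.alpha)

    # --- JSON dump/load ------------------------------------------------------

    def dump_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "noise": self.noise,
            "step": self.step,
            "table": [
                {"context": list(ctx), "utilities": utils}
                for ctx, utils in self.table.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "UtilityTable":
        payload = json.loads(Path(path).read_text())
        table = cls(
            alpha=payload["alpha"], noise=payload["noise"], step=payload["step"]
        )
        for entry in payload["table"]:
            table.table[tuple(entry["context"])] = dict(entry["utilities"])
        return table


def select_rule(
    table: UtilityTable, context: ContextKey, rng: np.random.Generator
) -> str:
    """Sample an action from the Boltzmann distribution over the context's
    utilities.  As the temperature goes to 0 the max-utility action is chosen
    with probability approaching 1."""
    utils = table.utilities(context)
    # inverse-CDF sampling with plain floats; this sits on the simulator's
    # innermost loop and numpy overhead dominates at this size
    top = max(utils.values())
    weights = [math.exp((utils[a] - top) / table.noise) for a in ACTIONS]
    u = rng.random() * math.fsum(weights)
    acc = 0.0
    for action, w in zip(ACTIONS, weights):
        acc += w
        if u <= acc:
            return action
    return ACTIONS[-1]


def apply_action(
    action: str, previous_allocation: int, remaining_endowment: int, step: int
) -> int:
    """Apply an adjustment: increase (+step), decrease (-step) or hold, clipped
    to [0, remaining_endowment]."""
    if previous_allocation < 0:
        raise ValueError("previous allocation must be non-negative")
    if action == "increase":
        new = previous_allocation + step
    elif action == "decrease":
        new = previous_allocation - step
    elif action == "hold":
        new = previous_allocation
    else:
        raise ValueError(f"unknown action {action!r}")
    return max(0, min(new, remaining_endowment))
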