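"""Round mechanics of the multi-arm trust game (MATG).

One sender splits a fixed per-round endowment between itself and several
receivers ("confederates").  A confederate that is available this round is
given the allocated points times a multiplier and returns a share of the
multiplied amount; points allocated to an unavailable confederate are
refunded to the sender.  Confederates play a scripted two-phase
trustworthiness strategy: a generous deterministic return (75% of the
multiplied amount, i.e. three times the allocation) up to the switch round,
then a break-even stochastic return with mean 25% of the multiplied amount
(equal, in expectation, to the allocation itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import InvalidAllocationError, LogValidationError

__all__ = [
    "GameConfig",
    "ConfederateSpec",
    "RoundRecord",
    "GameLog",
    "default_specs",
    "availability_draw",
    "multiplied_amount",
    "confederate_return",
    "settle_round",
    "run_game",
    "round_half_up",
]


class GameConfig(BaseModel):
    """All fixed constants of the paradigm.

    Defaults are the study conditions: a 40-point endowment, a 4x
    multiplier, 120 rounds with the strategy switch after round 70,
    75% deterministic returns in phase 1, 25% mean returns in phase 2,
    and availability schedules of every round / every 3 / every 6 rounds
    on average.
    """

    model_config = ConfigDict(frozen=True)

    endowment: int = Field(default=40, gt=0)
    multiplier: int = Field(default=4, ge=1)
    n_rounds: int = Field(default=120, ge=1)
    switch_round: int = Field(default=70, ge=1)
    phase1_return_frac: float = Field(default=0.75, ge=0.0, le=1.0)
    phase2_return_frac: float = Field(default=0.25, ge=0.0, le=1.0)
    schedules: tuple[int, ...] = (1, 3, 6)
    condition_label: str = "animacy"  # metadata only; no behavioral effect
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GameConfig":
        if not (1 <= self.switch_round <= self.n_rounds):
            raise ValueError(
                f"switch_round must lie in [1, n_rounds]; got {self.switch_round} "
                f"with n_rounds={self.n_rounds}"
            )
        if any(p < 1 for p in self.schedules):
            raise ValueError("every schedule period must be >= 1")
        if not self.schedules:
            raise ValueError("at least one confederate schedule is required")
        return self

    @property
    def n_confederates(self) -> int:
        return len(self.schedules)


@dataclass(frozen=True)
class ConfederateSpec:
    """A scripted receiver: availability schedule plus per-phase return policy."""

    id: int
    schedule_period: int
    phase1_return_frac: float = 0.75
    phase2_return_frac: float = 0.25
    phase2_stochastic: bool = True

    def __post_init__(self) -> None:
        if self.schedule_period < 1:
            raise ValueError("schedule_period must be >= 1")


def default_specs(config: GameConfig) -> tuple[ConfederateSpec, ...]:
    """One confederate per schedule period in ``config.schedules``."""
    return tuple(
        ConfederateSpec(
            id=i,
            schedule_period=p,
            phase1_return_frac=config.phase1_return_frac,
            phase2_return_frac=config.phase2_return_frac,
        )
        for i, p in enumerate(config.schedules)
    )


@dataclass(frozen=True)
class RoundRecord:
    """Complete ledger of a single round.

    Invariants (checked by :meth:`validate`):
    kept + sum(allocations) == endowment; given_i = multiplier * allocations_i
    when available else 0; 0 <= returned_i <= given_i; refunded = sum of
    allocations to unavailable confederates; sender_total = kept + refunded +
    sum(returned); confederate_totals_i = given_i - returned_i.
    """

    round: int
    allocations: tuple[int, ...]
    kept: int
    availability: tuple[bool, ...]
    given: tuple[int, ...]
    returned: tuple[int, ...]
    refunded: int
    sender_total: int
    confederate_totals: tuple[int, ...]

    def validate(self, config: GameConfig) -> None:
        r = self.round
        if self.kept + sum(self.allocations) != config.endowment:
            raise LogValidationError(
                f"round {r}: kept + allocations must equal the endowment "
                f"({self.kept} + {sum(self.allocations)} != {config.endowment})"
            )
        if any(a < 0 for a in self.allocations):
            raise LogValidationError(f"round {r}: negative allocation")
        expect_refund = sum(
            a for a, av in zip(self.allocations, self.availability) if not av
        )
        if self.refunded != expect_refund:
            raise LogValidationError(
                f"round {r}: refunded must equal allocations to unavailable "
                f"confederates ({self.refunded} != {expect_refund})"
            )
        for i, (a, av, g, ret) in enumerate(
            zip(self.allocations, self.availability, self.given, self.returned)
        ):
            want_g = config.multiplier * a if av else 0
            if g != want_g:
                raise LogValidationError(
                    f"round {r}: given[{i}] must be multiplier x allocation when "
                    f"available else 0 ({g} != {want_g})"
                )
            if not (0 <= ret <= g):
                raise LogValidationError(
                    f"round {r}: returned[{i}] outside [0, given] ({ret} vs {g})"
                )
            if self.confederate_totals[i] != g - ret:
                raise LogValidationError(
                    f"round {r}: confederate_totals[{i}] must be given - returned"
                )
        want_total = self.kept + self.refunded + sum(self.returned)
        if self.sender_total != want_total:
            raise LogValidationError(
                f"round {r}: sender_total must be kept + refunded + returns "
                f"({self.sender_total} != {want_total})"
            )


@dataclass
class GameLog:
    """An entire game: configuration plus one :class:`RoundRecord` per round."""

    config: GameConfig
    records: list[RoundRecord] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.records) != self.config.n_rounds:
            raise LogValidationError(
                f"log has {len(self.records)} records, expected {self.config.n_rounds}"
            )
        for i, rec in enumerate(self.records, start=1):
            if rec.round != i:
                raise LogValidationError(
                    f"records must be numbered consecutively from 1; "
                    f"position {i} holds round {rec.round}"
                )
            rec.validate(self.config)

    def allocation_matrix(self) -> np.ndarray:
        """(n_rounds, n_confederates) integer array of allocations."""
        return np.array([rec.allocations for rec in self.records], dtype=float)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (points are indivisible)."""
    return int(math.floor(x + 0.5))


def availability_draw(spec: ConfederateSpec, rng: np.random.Generator) -> bool:
    """Draw this round's availability: period 1 is always available, period p > 1
    is an independent Bernoulli with probability 1/p (available every p rounds
    on average, unpredictable on any given round)."""
    if spec.schedule_period == 1:
        return True
    return bool(rng.random() < 1.0 / spec.schedule_period)


def multiplied_amount(allocation: int, config: GameConfig) -> int:
    """Points a receiver is given: the allocation times the multiplier."""
    if allocation < 0 or allocation > config.endowment:
        raise InvalidAllocationError(
            f"allocation {allocation} outside [0, {config.endowment}]"
        )
    return config.multiplier * allocation


def confederate_return(
    given: int,
    round_index: int,
    spec: ConfederateSpec,
    config: GameConfig,
    rng: np.random.Generator,
) -> int:
    """Points the confederate sends back.

    Phase 1 (round <= switch_round): deterministic, 75% of the multiplied
    amount (rounded half-up), i.e. three times the allocation at the default
    multiplier.  Phase 2: an integer draw from Binomial(given, 0.25), bounded
    in [0, given] with mean exactly 25% of the multiplied amount — in
    expectation the sender gets back what it allocated.
    """
    if given < 0:
        raise InvalidAllocationError(f"given must be non-negative, got {given}")
    if round_index <= config.switch_round:
        return round_half_up(spec.phase1_return_frac * given)
    if spec.phase2_stochastic:
        return int(rng.binomial(given, spec.phase2_return_frac))
    return round_half_up(spec.phase2_return_frac * given)


def settle_round(
    allocations: Sequence[int],
    round_index: int,
    config: GameConfig,
    specs: Sequence[ConfederateSpec],
    rng: np.random.Generator,
) -> RoundRecord:
    """Resolve one round: draw availability, deliver multiplied amounts,
    collect returns and refunds, and fill every ledger field."""
    allocations = tuple(int(a) for a in allocations)
    if len(allocations) != len(specs):
        raise InvalidAllocationError(
            f"{len(allocations)} allocations for {len(specs)} confederates"
        )
    if any(a < 0 for a in allocations):
        raise InvalidAllocationError(f"round {round_index}: negative allocation")
    if sum(allocations) > config.endowment:
        raise InvalidAllocationError(
            f"round {round_index}: allocations sum to {sum(allocations)} "
            f"> endowment {config.endowment}"
        )
    availability = tuple(availability_draw(spec, rng) for spec in specs)
    given = []
    returned = []
    refunded = 0
    for a, av, spec in zip(allocations, availability, specs):
        if av:
            g = multiplied_amount(a, config)
            given.append(g)
            returned.append(confederate_return(g, round_index, spec, config, rng))
        else:
            given.append(0)
            returned.append(0)
            refunded += a
    kept = config.endowment - sum(allocations)
    record = RoundRecord(
        round=round_index,
        allocations=allocations,
        kept=kept,
        availability=availability,
        given=tuple(given),
        returned=tuple(returned),
        refunded=refunded,
        sender_total=kept + refunded + sum(returned),
        confederate_totals=tuple(g - r for g, r in zip(given, returned)),
    )
    record.validate(config)
    return record


Policy = Callable[[int, list[RoundRecord]], Sequence[int]]


def run_game(
    policy: Policy,
    config: GameConfig,
    specs: Sequence[ConfederateSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> GameLog:
    """Play a full game with a sender policy ``policy(round, history) -> allocations``.

    Same seed and same deterministic policy give a bit-identical log.
    """
    if specs is None:
        specs = default_specs(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[RoundRecord] = []
    for round_index in range(1, config.n_rounds + 1):
        allocations = policy(round_index, records)
        try:
            record = settle_round(allocations, round_index, config, specs, rng)
        except InvalidAllocationError as err:
            raise InvalidAllocationError(f"policy failed at round {round_index}: {err}") from err
        records.append(record)
    return GameLog(config=config, records=records)
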