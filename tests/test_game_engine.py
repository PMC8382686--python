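"""Round mechanics: multiplication, returns, settlement, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matg import (
    ConfederateSpec,
    GameConfig,
    availability_draw,
    confederate_return,
    default_specs,
    multiplied_amount,
    run_game,
    settle_round,
)
from matg.exceptions import InvalidAllocationError


class TestAvailability:
    def test_period_one_always_available(self, rng):
        spec = ConfederateSpec(id=0, schedule_period=1)
        assert all(availability_draw(spec, rng) for _ in range(1000))

    @pytest.mark.parametrize("period", [3, 6])
    def test_long_run_rate_matches_schedule(self, period):
        spec = ConfederateSpec(id=0, schedule_period=period)
        rng = np.random.default_rng(7)
        draws = sum(availability_draw(spec, rng) for _ in range(100_000))
        assert draws / 100_000 == pytest.approx(1 / period, abs=0.01)

    def test_same_seed_same_sequence(self):
        spec = ConfederateSpec(id=0, schedule_period=3)
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        assert [availability_draw(spec, r1) for _ in range(200)] == [
            availability_draw(spec, r2) for _ in range(200)
        ]


class TestMultiplication:
    @pytest.mark.parametrize("allocation,expected", [(4, 16), (0, 0), (10, 40)])
    def test_worked_examples(self, config, allocation, expected):
        assert multiplied_amount(allocation, config) == expected

    @pytest.mark.parametrize("bad", [-1, 41])
    def test_out_of_range_allocation_rejected(self, config, bad):
        with pytest.raises(InvalidAllocationError):
            multiplied_amount(bad, config)


class TestConfederateReturn:
    def test_phase1_returns_three_times_allocation(self, config, specs, rng):
        # 75% of the multiplied amount = 3x the allocation
        assert confederate_return(16, 10, specs[0], config, rng) == 12

    def test_zero_given_returns_zero(self, config, specs, rng):
        assert confederate_return(0, 5, specs[0], config, rng) == 0
        assert confederate_return(0, 100, specs[0], config, rng) == 0

    def test_phase2_mean_is_quarter_of_given(self, config, specs):
        rng = np.random.default_rng(11)
        draws = [confederate_return(40, 80, specs[0], config, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(10.0, abs=0.3)

    def test_phase2_support_bounded(self, config, specs):
        rng = np.random.default_rng(2)
        draws = [confederate_return(16, 99, specs[1], config, rng) for _ in range(2000)]
        assert min(draws) >= 0 and max(draws) <= 16


class TestSettleRound:
    def _always_available(self, config):
        return tuple(
            ConfederateSpec(id=i, schedule_period=1) for i in range(3)
        )

    def test_phase1_hand_trace(self, config, rng):
        rec = settle_round((4, 0, 0), 5, config, self._always_available(config), rng)
        assert rec.kept == 36
        assert rec.given == (16, 0, 0)
        assert rec.returned == (12, 0, 0)
        assert rec.sender_total == 48

    def test_unavailable_confederate_refunds_allocation(self, config):
        specs = (
            ConfederateSpec(id=0, schedule_period=1),
            ConfederateSpec(id=1, schedule_period=10**9),  # effectively never
            ConfederateSpec(id=2, schedule_period=1),
        )
        rec = settle_round((0, 5, 0), 3, config, specs, np.random.default_rng(0))
        assert rec.refunded == 5
        assert rec.sender_total == 40

    def test_no_interaction_keeps_endowment(self, config, specs, rng):
        rec = settle_round((0, 0, 0), 1, config, specs, rng)
        assert rec.sender_total == 40

    def test_over_endowment_rejected(self, config, specs, rng):
        with pytest.raises(InvalidAllocationError):
            settle_round((20, 20, 20), 1, config, specs, rng)

    @settings(max_examples=50, deadline=None)
    @given(
        allocs=st.lists(st.integers(0, 13), min_size=3, max_size=3),
        round_index=st.integers(1, 120),
        seed=st.integers(0, 10_000),
    )
    def test_conservation_and_invariants(self, allocs, round_index, seed):
        config = GameConfig()
        rec = settle_round(
            allocs, round_index, config, default_specs(config),
            np.random.default_rng(seed),
        )
        rec.validate(config)  # all RoundRecord invariants
        assert rec.kept + sum(rec.allocations) == config.endowment
        assert rec.sender_total == rec.kept + rec.refunded + sum(rec.returned)


class TestRunGame:
    def test_zero_policy_yields_full_endowment_every_round(self, config, specs):
        log = run_game(lambda r, h: (0, 0, 0), config, specs, np.random.default_rng(0))
        assert len(log.records) == 120
        assert all(rec.sender_total == 40 for rec in log.records)

    def test_phase1_constant_policy_profit_identity(self, config, specs):
        log = run_game(lambda r, h: (10, 0, 0), config, specs, np.random.default_rng(0))
        for rec in log.records[:70]:
            # 30 kept + 10*3 returned by the always-available confederate
            assert rec.sender_total == 60

    def test_phase2_break_even_on_average(self, config, specs):
        log = run_game(lambda r, h: (10, 0, 0), config, specs, np.random.default_rng(5))
        diffs = [rec.returned[0] - rec.allocations[0] for rec in log.records[70:]]
        # neutral strategy: zero expected profit per interaction
        assert abs(np.mean(diffs)) < 2.0

    def test_seeded_replay_is_bit_identical(self, config, specs):
        policy = lambda r, h: (8, 4, 2)
        log1 = run_game(policy, config, specs, np.random.default_rng(42))
        log2 = run_game(policy, config, specs, np.random.default_rng(42))
        assert log1.records == log2.records

    def test_invalid_policy_error_names_round(self, config, specs):
        def bad_policy(r, h):
            return (50, 0, 0) if r == 9 else (0, 0, 0)

        with pytest.raises(InvalidAllocationError, match="round 9"):
            run_game(bad_policy, config, specs, np.random.default_rng(0))
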