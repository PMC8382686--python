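"""Trust and trust-invest accumulators, regime classification, and rewards.

Each counterpart has two accumulators.  The *trust* accumulator integrates
normalized net outcomes of interactions (what came back minus what was sent,
as a fraction of the endowment) and is discounted by a fixed amount delta on
every round without an interaction — trust decays in the absence of evidence.
The *trust-invest* accumulator indexes trust necessity: it rises while
interactions fail to pay off and decays geometrically otherwise.

The pair defines three mutually exclusive regimes:

* trust           — trust accumulator above its threshold;
* trust necessity — trust at/below threshold but trust-invest above its
                    threshold (low trust, but motivation to develop it);
* distrust        — both at/below threshold.

The per-counterpart reward depends on the regime: in trust it is the joint
payoff of sender and counterpart, in distrust a penalty equal to the points
allocated, in trust necessity the counterpart's own gain (rewarding
investment in the relationship).  On top of the per-counterpart rewards the
sender is rewarded for the endowment it kept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import MatgError

__all__ = [
    "TrustParams",
    "TrustState",
    "Regime",
    "classify_regime",
    "update_on_outcome",
    "discount_on_unavailability",
    "compute_reward",
]


# Below this level a decayed trust-invest accumulator counts as fully drained.
INVEST_FLOOR = 1e-3


class Regime(str, enum.Enum):
    TRUST = "trust"
    DISTRUST = "distrust"
    TRUST_NECESSITY = "trust_necessity"


class TrustParams(BaseModel):
    """Parameters of the accumulator dynamics.

    eta    — learning gain on the normalized net outcome (trust update);
    delta  — trust discount applied per non-interacting round;
    kappa  — trust-invest gain / decay factor;
    initial_trust — starting value of every trust accumulator (the only
    free-parameter stand-in for dispositional trust).
    """

    model_config = ConfigDict(frozen=True)

    trust_threshold: float = 0.0
    invest_threshold: float = 0.0
    eta: float = Field(default=1.0, gt=0)
    delta: float = Field(default=0.1, ge=0)
    kappa: float = Field(default=0.5, gt=0)
    initial_trust: float = 0.0


@dataclass
class TrustState:
    """Per-counterpart trust and trust-invest accumulators."""

    trust: np.ndarray
    invest: np.ndarray

    @classmethod
    def initial(cls, n_counterparts: int, params: TrustParams) -> "TrustState":
        return cls(
            trust=np.full(n_counterparts, params.initial_trust, dtype=float),
            invest=np.zeros(n_counterparts, dtype=float),
        )

    def copy(self) -> "TrustState":
        return TrustState(trust=self.trust.copy(), invest=self.invest.copy())


def classify_regime(state: TrustState, counterpart: int, params: TrustParams) -> Regime:
    """Total, mutually exclusive classification of a counterpart's regime."""
    if state.trust[counterpart] > params.trust_threshold:
        return Regime.TRUST
    if state.invest[counterpart] > params.invest_threshold:
        return Regime.TRUST_NECESSITY
    return Regime.DISTRUST


def update_on_outcome(
    state: TrustState,
    counterpart: int,
    allocated: int,
    returned: int,
    endowment: int,
    params: TrustParams,
    expected: float | None = None,
) -> TrustState:
    """Update both accumulators after an interaction (counterpart available).

    Trust moves in one of two modes.  At or below threshold (repair mode)
    it integrates the normalized net outcome,

        trust += eta * (returned - allocated) / endowment,

    so evidence of profitable reciprocation rebuilds trust.  Above threshold
    (maintenance mode) it moves by the normalized prediction error,

        trust += eta * (returned - expected) / endowment,

    where ``expected`` is the return the sender anticipated (default: the
    allocation, i.e. break-even; the cognitive agent passes its blended
    prediction times the amount given).  Anticipated generosity therefore
    stops inflating trust once it is established, while a shift in
    trustworthiness produces large negative surprises that pull trust down
    immediately.

    The trust-invest accumulator indexes unmet need to interact.  It rises
    only on thwarted investment attempts (see
    :func:`discount_on_unavailability`).  A served attempt relieves the
    need: a profitable interaction drains it gently by the factor
    (1 - kappa) (trust is forming, some urgency remains), while an
    unprofitable one resolves it outright (the necessity-driven investment
    was tried and did not pay — the accumulator resets and the regime falls
    back to distrust).  This makes trust necessity a transient state.

    The state is updated in place and returned.
    """
    if allocated < 0:
        raise MatgError("allocated must be non-negative")
    if expected is None:
        expected = float(allocated)
    net = returned - allocated
    if allocated > 0:
        if state.trust[counterpart] > params.trust_threshold:
            evidence = returned - expected
        else:
            evidence = float(net)
        state.trust[counterpart] += params.eta * evidence / endowment
        if net > 0:
            state.invest[counterpart] *= 1.0 - params.kappa
        else:
            state.invest[counterpart] = 0.0
    else:
        state.invest[counterpart] *= 1.0 - params.kappa
    if state.invest[counterpart] < INVEST_FLOOR:
        # geometric decay never reaches the threshold exactly; snap drained
        # investment need to zero
        state.invest[counterpart] = 0.0
    return state


def discount_on_unavailability(
    state: TrustState,
    counterpart: int,
    params: TrustParams,
    attempted_frac: float = 0.0,
) -> TrustState:
    """Round without an interaction: discount trust by delta.

    ``attempted_frac`` is the fraction of the endowment the sender allocated
    to a counterpart that turned out to be unavailable (the points were
    refunded).  Such a thwarted attempt, while trust is at or below
    threshold, feeds the trust-invest accumulator by kappa * attempted_frac —
    unmet need to interact is what builds trust necessity.  With the default
    ``attempted_frac=0`` trust-invest is unchanged.  Updated in place and
    returned.
    """
    state.trust[counterpart] -= params.delta
    if attempted_frac > 0 and state.trust[counterpart] <= params.trust_threshold:
        state.invest[counterpart] += params.kappa * attempted_frac
    return state


def compute_reward(
    regime: Regime,
    own_payoff: float,
    other_payoff: float,
    allocated: int,
    kept: float,
    params: TrustParams | None = None,
) -> float:
    """Reward contributed by one counterpart, plus the endowment-kept reward.

    trust           -> own_payoff + other_payoff (joint payoff)
    distrust        -> -allocated (penalty for allocating at all)
    trust necessity -> other_payoff (counterpart's gain)
    """
    if regime is Regime.TRUST:
        r = own_payoff + other_payoff
    elif regime is Regime.DISTRUST:
        r = -float(allocated)
    elif regime is Regime.TRUST_NECESSITY:
        r = other_payoff
    else:  # pragma: no cover - enum is closed
        raise MatgError(f"unknown regime {regime!r}")
    return r + kept
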