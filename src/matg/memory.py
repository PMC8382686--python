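"""Episodic instance memory with recency/frequency activation and blending.

Each interaction with a counterpart is stored as an instance chunk holding the
observed return fraction together with a discretized one-step sequence context
(the previously observed return bin and how long ago the last interaction
was).  Retrieval strength follows the base-level learning equation
``A = ln sum_j (now - t_j)^(-d)`` over the chunk's encoding times, so chunks
gain strength with frequency and lose it with recency of disuse.  A point
prediction of the next return is the Boltzmann-weighted (temperature tau)
average of candidate chunk values — "blending".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ClockError, NoExperienceError, RetrievalFailureError

__all__ = [
    "InstanceChunk",
    "MemoryStore",
    "activation",
    "return_bin",
    "recency_bin",
    "VALUE_BIN_WIDTH",
]

# Chunks whose values fall in the same 0.05-wide bin are treated as re-encodings
# of the same instance rather than new chunks.
VALUE_BIN_WIDTH = 0.05

# Discretization of the sequence context.
RETURN_BINS = ("none", "low", "neutral", "high")
RECENCY_BINS = ("1", "2-3", "4+")


def return_bin(frac: float | None) -> str:
    """Bin a previously observed return fraction: none / low (<0.4) /
    neutral (0.4-0.6) / high (>0.6)."""
    if frac is None:
        return "none"
    if frac < 0.4:
        return "low"
    if frac <= 0.6:
        return "neutral"
    return "high"


def recency_bin(rounds_since: int | None) -> str:
    """Bin rounds since the last interaction: 1 / 2-3 / 4+ (never seen -> 4+)."""
    if rounds_since is None or rounds_since >= 4:
        return "4+"
    if rounds_since <= 1:
        return "1"
    return "2-3"


Context = tuple[str, str]  # (previous return bin, rounds-since-interaction bin)


@dataclass
class InstanceChunk:
    """One remembered kind of interaction outcome with a counterpart."""

    counterpart: int
    context: Context
    value: float  # observed return as a fraction of the amount given
    encodings: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"chunk value must lie in [0, 1], got {self.value}")


def activation(chunk: InstanceChunk, now: int, d: float) -> float:
    """Base-level activation ``ln sum_j (now - t_j)^(-d)`` at round ``now``."""
    if not chunk.encodings:
        raise RetrievalFailureError("chunk has no encodings")
    if now <= max(chunk.encodings):
        raise ClockError(f"now={now} must exceed the last encoding time")
    return math.log(sum((now - t) ** (-d) for t in chunk.encodings))


def _value_key(value: float) -> int:
    return int(round(value / VALUE_BIN_WIDTH))


@dataclass
class MemoryStore:
    """Collection of instance chunks with decay ``d`` and blending temperature ``tau``."""

    d: float = 0.5
    tau: float = 0.25
    _chunks: dict[tuple[int, Context, int], InstanceChunk] = field(default_factory=dict)
    _by_counterpart: dict[int, list[InstanceChunk]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d <= 0 or self.tau <= 0:
            raise ValueError("decay d and temperature tau must be positive")

    @property
    def chunks(self) -> list[InstanceChunk]:
        return list(self._chunks.values())

    def encode_instance(
        self, counterpart: int, context: Context, value: float, round_index: int
    ) -> None:
        """Store an observation.  A chunk with the same counterpart, context and
        value bin is strengthened (the round is appended to its encodings);
        otherwise a new chunk is created.  The store's clock is non-decreasing
        (several counterparts may be encoded in the same round) and each
        chunk's encoding times are strictly increasing."""
        last = self._last_encoding()
        if last is not None and round_index < last:
            raise ClockError(
                f"encoding round {round_index} precedes latest encoding {last}"
            )
        value = _value_key(value) * VALUE_BIN_WIDTH
        key = (counterpart, context, _value_key(value))
        chunk = self._chunks.get(key)
        if chunk is None:
            chunk = InstanceChunk(counterpart, context, value, [round_index])
            self._chunks[key] = chunk
            self._by_counterpart.setdefault(counterpart, []).append(chunk)
        else:
            if round_index <= chunk.encodings[-1]:
                raise ClockError(
                    f"round {round_index} not after chunk's last encoding "
                    f"{chunk.encodings[-1]}"
                )
            chunk.encodings.append(round_index)

    def _last_encoding(self) -> int | None:
        latest = None
        for chunk in self._chunks.values():
            if latest is None or chunk.encodings[-1] > latest:
                latest = chunk.encodings[-1]
        return latest

    def blended_prediction(self, counterpart: int, context: Context, now: int) -> float:
        """Activation-weighted average return fraction for a counterpart.

        Candidates are the chunks matching (counterpart, context); if none
        match the context, all chunks for the counterpart are used.  Weights
        are proportional to exp(A_i / tau), so the result is a convex
        combination of candidate values.
        """
        chunks = self._by_counterpart.get(counterpart)
        if not chunks:
            raise NoExperienceError(f"no instances stored for counterpart {counterpart}")
        candidates = [c for c in chunks if c.context == context]
        if not candidates:
            candidates = chunks
        scaled = [activation(c, now, self.d) / self.tau for c in candidates]
        top = max(scaled)
        weights = [math.exp(a - top) for a in scaled]  # stable softmax
        total = math.fsum(weights)
        return math.fsum(w * c.value for w, c in zip(weights, candidates)) / total

    # --- JSONL dump/load for inspection and fixtures -------------------------

    def dump_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chunk in self._chunks.values():
                fh.write(
                    json.dumps(
                        {
                            "counterpart": chunk.counterpart,
                            "context": list(chunk.context),
                            "value": chunk.value,
                            "encodings": chunk.encodings,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def load_jsonl(cls, path: str | Path, d: float = 0.5, tau: float = 0.25) -> "MemoryStore":
        store = cls(d=d, tau=tau)
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                context = tuple(rec["context"])
                chunk = InstanceChunk(rec["counterpart"], context, rec["value"], list(rec["encodings"]))
                key = (chunk.counterpart, context, _value_key(chunk.value))
                store._chunks[key] = chunk
                store._by_counterpart.setdefault(chunk.counterpart, []).append(chunk)
        return store
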