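"""Readers and writers: game logs as CSV, configs as JSON, run manifests.

The log dialect is one row per round x confederate with the sender columns
repeated: ``round, confederate_id, allocation, available, given, returned,
kept, refunded, sender_total``.  Reads re-validate every round-record
invariant and name the offending round on failure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .exceptions import MatgError
from .game import GameConfig, GameLog, RoundRecord
from .trust import TrustParams

__all__ = [
    "LOG_COLUMNS",
    "write_game_log",
    "read_game_log",
    "load_config",
    "save_config",
    "write_mean_curves",
    "read_mean_curves",
    "RunManifest",
]

LOG_COLUMNS = [
    "round",
    "confederate_id",
    "allocation",
    "available",
    "given",
    "returned",
    "kept",
    "refunded",
    "sender_total",
]


class ParseError(MatgError):
    """Malformed log or config file."""


def write_game_log(log: GameLog, path: str | Path) -> None:
    rows = []
    for rec in log.records:
        for c in range(len(rec.allocations)):
            rows.append(
                {
                    "round": rec.round,
                    "confederate_id": c,
                    "allocation": rec.allocations[c],
                    "available": int(rec.availability[c]),
                    "given": rec.given[c],
                    "returned": rec.returned[c],
                    "kept": rec.kept,
                    "refunded": rec.refunded,
                    "sender_total": rec.sender_total,
                }
            )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def read_game_log(path: str | Path, config: GameConfig | None = None) -> GameLog:
    """Read a CSV log and re-validate every invariant.

    If no config is given, one is inferred with default constants and
    n_rounds taken from the file.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as err:
        raise ParseError(f"cannot parse game log {path}: {err}") from err
    missing = [c for c in LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"game log {path} is missing column(s): {', '.join(missing)}")
    if frame.empty:
        raise ParseError(f"game log {path} contains no rounds")
    n_rounds = int(frame["round"].max())
    n_conf = frame["confederate_id"].nunique()
    if config is None:
        config = GameConfig(
            n_rounds=n_rounds,
            switch_round=min(70, n_rounds),
            schedules=tuple([1, 3, 6][:n_conf]) if n_conf <= 3 else tuple([1] * n_conf),
        )
    records = []
    for round_index, group in frame.sort_values(["round", "confederate_id"]).groupby(
        "round", sort=True
    ):
        rec = RoundRecord(
            round=int(round_index),
            allocations=tuple(int(a) for a in group["allocation"]),
            kept=int(group["kept"].iloc[0]),
            availability=tuple(bool(a) for a in group["available"]),
            given=tuple(int(g) for g in group["given"]),
            returned=tuple(int(r) for r in group["returned"]),
            refunded=int(group["refunded"].iloc[0]),
            sender_total=int(group["sender_total"].iloc[0]),
            confederate_totals=tuple(
                int(g) - int(r) for g, r in zip(group["given"], group["returned"])
            ),
        )
        records.append(rec)
    log = GameLog(config=config, records=records)
    log.validate()  # raises LogValidationError naming round and rule
    return log


def load_config(path: str | Path) -> tuple[GameConfig, TrustParams]:
    """Load a JSON configuration; unspecified fields take the paradigm
    defaults.  Trust parameters may be nested under a ``trust`` key."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"config {path} is not valid JSON: {err}") from err
    if not isinstance(payload, dict):
        raise ParseError(f"config {path} must contain a JSON object")
    trust_payload = payload.pop("trust", {})
    try:
        config = GameConfig(**payload)
        params = TrustParams(**trust_payload)
    except ValidationError as err:
        raise ParseError(f"config {path} failed validation: {err}") from err
    return config, params


def save_config(config: GameConfig, path: str | Path, params: TrustParams | None = None) -> None:
    payload = config.model_dump()
    if params is not None:
        payload["trust"] = params.model_dump()
    Path(path).write_text(json.dumps(payload, indent=2))


def write_mean_curves(curves: np.ndarray, path: str | Path) -> None:
    """Tidy CSV of mean allocation curves: round, confederate_id, mean_allocation."""
    n_rounds, n_conf = curves.shape
    rows = [
        {"round": r + 1, "confederate_id": c, "mean_allocation": curves[r, c]}
        for r in range(n_rounds)
        for c in range(n_conf)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mean_curves(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path)
    for col in ("round", "confederate_id", "mean_allocation"):
        if col not in frame.columns:
            raise ParseError(f"mean-curve file {path} is missing column {col!r}")
    pivot = frame.pivot(index="round", columns="confederate_id", values="mean_allocation")
    return pivot.sort_index().to_numpy(dtype=float)


@dataclass
class RunManifest:
    """Reproducibility record written before any run output."""

    config_hash: str
    seed: int
    variant: str
    package_version: str
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def hash_config(config: GameConfig, params: TrustParams | None = None) -> str:
        payload = config.model_dump()
        if params is not None:
            payload["trust"] = params.model_dump()
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "variant": self.variant,
                    "package_version": self.package_version,
                    "outputs": self.outputs,
                },
                indent=2,
            )
        )
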