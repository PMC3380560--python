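"""Session file formats, run configuration and result serialization.

Trial logs are plain CSV, one row per completed trial, with the header
``session_id,trial,block,pL,pR,choice,reward``.  Choices are "L"/"R",
rewards 0/1, reward probabilities decimals (not percent), and trial/block
indices 1-based.  Cohort manifests and fit/CV results are JSON.  Every
artifact written by the pipeline embeds (directly or via a sidecar
``*.meta.json``) the configuration hash and seeds that produced it.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import models
from .task import DEFAULT_N_BLOCKS, Session, Setting, Trial

__all__ = [
    "SESSION_HEADER",
    "read_sessions",
    "write_sessions",
    "read_manifest",
    "write_manifest",
    "RunConfig",
    "config_hash",
    "write_json",
]

logger = logging.getLogger("bayesq")

SESSION_HEADER = ["session_id", "trial", "block", "pL", "pR", "choice", "reward"]

_PROB_LEVELS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


def _format_prob(p: float) -> str:
    return f"{p:.6f}"


def _parse_prob(text: str, line: int) -> float:
    try:
        v = float(text)
    except ValueError:
        raise ValueError(f"line {line}: invalid reward probability {text!r}") from None
    for level in _PROB_LEVELS:
        if math.isclose(v, level, abs_tol=1e-4):
            return level
    raise ValueError(f"line {line}: reward probability {text!r} is not one of 0, 1/3, 2/3, 1")


def write_sessions(sessions: list[Session], path: str | Path) -> None:
    """Write a session collection as CSV; byte-identical across runs for
    identical inputs."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SESSION_HEADER)
        for s in sessions:
            for t in s.trials:
                writer.writerow(
                    [
                        s.session_id,
                        t.index,
                        t.block,
                        _format_prob(t.setting.pL),
                        _format_prob(t.setting.pR),
                        "L" if t.choice == models.LEFT else "R",
                        t.reward,
                    ]
                )


def read_sessions(
    path: str | Path, validate: bool = False, min_blocks: int = 7
) -> list[Session]:
    """Read a session CSV, reporting malformed rows with line numbers.

    With ``validate=True`` every session is additionally checked against
    the structural task invariants (block lengths, setting coverage, no
    consecutive repeats, at least ``min_blocks`` blocks).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {SESSION_HEADER}") from None
        if header != SESSION_HEADER:
            raise ValueError(f"{path}: bad header {header!r}, expected {SESSION_HEADER}")
        by_id: dict[str, list[Trial]] = {}
        order: list[str] = []
        for line, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SESSION_HEADER):
                raise ValueError(f"line {line}: expected {len(SESSION_HEADER)} fields, got {len(row)}")
            sid, trial_s, block_s, pl_s, pr_s, choice_s, reward_s = row
            try:
                trial = int(trial_s)
                block = int(block_s)
            except ValueError:
                raise ValueError(f"line {line}: non-integer trial or block index") from None
            if choice_s not in ("L", "R"):
                raise ValueError(f"line {line}: unknown choice label {choice_s!r} (expected L or R)")
            if reward_s not in ("0", "1"):
                raise ValueError(f"line {line}: reward must be 0 or 1, got {reward_s!r}")
            setting = Setting(_parse_prob(pl_s, line), _parse_prob(pr_s, line))
            trials = by_id.setdefault(sid, [])
            if sid not in order:
                order.append(sid)
            expected = len(trials) + 1
            if trial != expected:
                raise ValueError(
                    f"line {line}: non-consecutive trial index {trial} for session {sid!r}"
                    f" (expected {expected})"
                )
            if trials and block < trials[-1].block:
                raise ValueError(f"line {line}: block index decreases for session {sid!r}")
            trials.append(
                Trial(
                    index=trial,
                    block=block,
                    setting=setting,
                    choice=models.LEFT if choice_s == "L" else models.RIGHT,
                    reward=int(reward_s),
                )
            )
    if not order:
        logger.warning("%s: valid header but no trial rows; returning empty collection", path)
    sessions = [Session(trials=by_id[sid], session_id=sid) for sid in order]
    if validate:
        for s in sessions:
            s.validate(min_blocks=min_blocks)
    return sessions


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _default_rat_specs() -> list[dict]:
    from .task import DEFAULT_AGENT_PARAMS, DEFAULT_AGENT_VARIANT

    return [
        {
            "rat_id": f"rat{i}",
            "variant": DEFAULT_AGENT_VARIANT,
            "params": asdict(DEFAULT_AGENT_PARAMS),
            "n_sessions": 26,
        }
        for i in range(5)
    ]


@dataclass
class RunConfig:
    """Seeds, cohort specification and pipeline options for a full run.

    All seeds are explicit integers; the config round-trips losslessly
    through YAML/JSON and its canonical hash is embedded in every output.
    """

    master_seed: int = 0
    optimizer_seed: int = 0
    split_seed: int = 0
    variants: list[str] = field(default_factory=lambda: ["FQ", "asymmetricBQ", "asymmetricBQ_phi0"])
    rat_specs: list[dict] = field(default_factory=_default_rat_specs)
    n_blocks: int = DEFAULT_N_BLOCKS
    max_trials: int = 5000
    n_starts: int = 10
    alpha_level: float = 0.01
    out_dir: str = "bayesq_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json(payload: dict, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a result JSON, embedding the config hash and seeds if given."""
    out = dict(payload)
    if config is not None:
        out["meta"] = {
            "config_hash": config_hash(config),
            "master_seed": config.master_seed,
            "optimizer_seed": config.optimizer_seed,
            "split_seed": config.split_seed,
        }
    Path(path).write_text(json.dumps(_jsonable(out), indent=1, sort_keys=True) + "\n")
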