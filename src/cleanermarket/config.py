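"""Run configuration: YAML loading, validation and defaults.

A run config has four sections — ``environment``, ``learner``, ``run`` and
``output`` — mirroring the library objects.  A minimal config only needs a
regime and a model; the standard defaults (Q=10, C_p=2, alpha=0.1, bins of
40 trials, 100 replicates) are applied on load.  Unknown keys are rejected
with the offending field named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .environments import EnvironmentConfig
from .learners import LearnerParams

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


_ENV_KEYS = {
    "regime",
    "p_v",
    "p_r",
    "p_0",
    "pair_mix",
    "reward_visitor",
    "reward_resident",
}
_LEARNER_KEYS = {"model", "q", "c_p", "alpha"}
_RUN_KEYS = {"n_trials", "n_reps", "seed", "bin_size", "window"}
_OUTPUT_KEYS = {"directory", "formats"}
_SECTIONS = {"environment", "learner", "run", "output"}


@dataclass
class RunConfig:
    """Validated bundle of environment, learner and run settings."""

    environment: EnvironmentConfig
    learner: LearnerParams
    n_trials: int = 2000
    n_reps: int = 100
    seed: int = 1
    bin_size: int = 40
    window: int = 200
    out_dir: Path = Path("out")
    formats: tuple[str, ...] = ("csv", "json", "dot")


def _reject_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _build(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    # accept flattened top-level keys alongside explicit sections
    env_d = dict(data.pop("environment", {}) or {})
    lrn_d = dict(data.pop("learner", {}) or {})
    run_d = dict(data.pop("run", {}) or {})
    out_d = dict(data.pop("output", {}) or {})
    for k in list(data):
        if k in _ENV_KEYS:
            env_d.setdefault(k, data.pop(k))
        elif k in _LEARNER_KEYS:
            lrn_d.setdefault(k, data.pop(k))
        elif k in _RUN_KEYS:
            run_d.setdefault(k, data.pop(k))
        elif k in _OUTPUT_KEYS:
            out_d.setdefault(k, data.pop(k))
    if data:
        raise ConfigError(
            f"unknown top-level key(s): {sorted(data)}; "
            f"sections are {sorted(_SECTIONS)}"
        )
    _reject_unknown("environment", env_d, _ENV_KEYS)
    _reject_unknown("learner", lrn_d, _LEARNER_KEYS)
    _reject_unknown("run", run_d, _RUN_KEYS)
    _reject_unknown("output", out_d, _OUTPUT_KEYS)

    if "regime" not in env_d:
        raise ConfigError("environment.regime is required")
    regime = env_d.pop("regime")
    if "pair_mix" in env_d:
        pm = env_d["pair_mix"]
        if isinstance(pm, dict):
            try:
                pm = (pm["rv"], pm["rr"], pm["vv"])
            except KeyError as e:
                raise ConfigError(f"pair_mix needs keys rv/rr/vv, missing {e}")
        env_d["pair_mix"] = tuple(float(p) for p in pm)
    if regime == "two_choice":
        env_d.setdefault("reward_visitor", 2.0)
        env_d.setdefault("reward_resident", 1.0)
    try:
        env = EnvironmentConfig(regime=regime, **env_d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"environment: {e}") from e

    if "model" not in lrn_d:
        raise ConfigError("learner.model is required")
    try:
        learner = LearnerParams(
            model=lrn_d["model"],
            Q=int(lrn_d.get("q", 10)),
            C_p=float(lrn_d.get("c_p", 2.0)),
            alpha=float(lrn_d.get("alpha", 0.1)),
        )
    except (TypeError, ValueError) as e:
        raise ConfigError(f"learner: {e}") from e

    formats = out_d.get("formats", ("csv", "json", "dot"))
    if isinstance(formats, str):
        formats = (formats,)
    return RunConfig(
        environment=env,
        learner=learner,
        n_trials=int(run_d.get("n_trials", 2000)),
        n_reps=int(run_d.get("n_reps", 100)),
        seed=int(run_d.get("seed", 1)),
        bin_size=int(run_d.get("bin_size", 40)),
        window=int(run_d.get("window", 200)),
        out_dir=Path(out_d.get("directory", "out")),
        formats=tuple(formats),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if data is None:
        raise ConfigError(f"config file {path} is empty")
    return _build(data)
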