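"""Simulated client environments and serving dynamics.

Four regimes fill a two-spot arena each trial:

* ``two_choice`` — the basic quantitative choice task: two clients offering
  2 and 1 food units, both ephemeral, only the chosen one is consumed; an
  empty trial follows each feeding trial.
* ``lab_market`` — the laboratory market problem: every feeding trial is a
  mixed visitor-resident pair, with an empty trial after each feeding trial.
* ``lab_complex`` — the laboratory complex market: feeding trials draw a
  pair from a mix of visitor-resident / resident-resident / visitor-visitor
  presentations (default 0.5 / 0.25 / 0.25), empty trial interleaved.
* ``natural`` — each spot filled by an independent draw with probabilities
  P_V (visitor), P_R (resident), P_0 (empty); no forced empty trials.

The serving dynamics capture the ephemeral-reward structure: a visitor
leaves if not served first, a resident waits and is served second.
"""

from __future__ import annotations

from dataclasses import dataclass

from .learners import Action

__all__ = [
    "REGIMES",
    "VISITOR",
    "RESIDENT",
    "EMPTY",
    "EnvironmentConfig",
    "ArenaState",
    "StepOutcome",
    "sample_arena",
    "resolve_step",
    "rv_pair_frequency",
]

REGIMES = ("two_choice", "lab_market", "natural", "lab_complex")

VISITOR = "visitor"
RESIDENT = "resident"
EMPTY = "empty"

_SPOTS = (VISITOR, RESIDENT, EMPTY)


@dataclass(frozen=True)
class ArenaState:
    """Occupancy of the two spots for one trial (positions carry no meaning)."""

    spot1: str
    spot2: str

    def __post_init__(self) -> None:
        for s in (self.spot1, self.spot2):
            if s not in _SPOTS:
                raise ValueError(f"invalid spot content {s!r}")

    @property
    def n_visitors(self) -> int:
        return (self.spot1 == VISITOR) + (self.spot2 == VISITOR)

    @property
    def n_residents(self) -> int:
        return (self.spot1 == RESIDENT) + (self.spot2 == RESIDENT)

    @property
    def n_clients(self) -> int:
        return self.n_visitors + self.n_residents

    @property
    def is_empty(self) -> bool:
        return self.n_clients == 0

    @property
    def is_mixed(self) -> bool:
        return self.n_visitors == 1 and self.n_residents == 1


@dataclass(frozen=True)
class EnvironmentConfig:
    """Regime plus its client probabilities and reward map.

    For the natural regime, P_V + P_R + P_0 must equal 1; the two derived
    ecological axes are ``visitor_frequency`` = P_V/(P_V+P_R) and
    ``density`` = 1 - P_0.
    """

    regime: str
    p_v: float = 0.0
    p_r: float = 0.0
    p_0: float = 1.0
    pair_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # rv, rr, vv
    reward_visitor: float = 1.0
    reward_resident: float = 1.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if self.regime == "natural":
            for name, p in (("p_v", self.p_v), ("p_r", self.p_r), ("p_0", self.p_0)):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name} must lie in [0, 1], got {p}")
            if abs(self.p_v + self.p_r + self.p_0 - 1.0) > 1e-9:
                raise ValueError("p_v + p_r + p_0 must equal 1")
        if self.regime == "lab_complex":
            if len(self.pair_mix) != 3 or any(p < 0 for p in self.pair_mix):
                raise ValueError("pair_mix needs 3 nonnegative entries (rv, rr, vv)")
            if abs(sum(self.pair_mix) - 1.0) > 1e-9:
                raise ValueError("pair_mix must sum to 1")
        if self.reward_visitor < 0 or self.reward_resident < 0:
            raise ValueError("rewards must be nonnegative")

    # -- derived quantities -----------------------------------------------

    @property
    def forced_empty_after_feeding(self) -> bool:
        """Laboratory protocols interleave an empty trial after feeding."""
        return self.regime != "natural"

    @property
    def both_ephemeral(self) -> bool:
        """Only in the basic two-choice task does the unchosen client always leave."""
        return self.regime == "two_choice"

    @property
    def visitor_frequency(self) -> float:
        tot = self.p_v + self.p_r
        return self.p_v / tot if tot > 0 else 0.0

    @property
    def density(self) -> float:
        return 1.0 - self.p_0

    def reward(self, client: str) -> float:
        return self.reward_visitor if client == "V" else self.reward_resident

    # -- factories ---------------------------------------------------------

    @classmethod
    def lab_market(cls) -> "EnvironmentConfig":
        return cls(regime="lab_market")

    @classmethod
    def lab_complex(
        cls, pair_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    ) -> "EnvironmentConfig":
        return cls(regime="lab_complex", pair_mix=pair_mix)

    @classmethod
    def two_choice(cls) -> "EnvironmentConfig":
        return cls(regime="two_choice", reward_visitor=2.0, reward_resident=1.0)

    @classmethod
    def natural(cls, p_v: float, p_r: float, p_0: float) -> "EnvironmentConfig":
        return cls(regime="natural", p_v=p_v, p_r=p_r, p_0=p_0)

    @classmethod
    def natural_from_ecology(
        cls, visitor_frequency: float, density: float
    ) -> "EnvironmentConfig":
        """Build a natural regime from the two ecological axes."""
        p_v = visitor_frequency * density
        p_r = (1.0 - visitor_frequency) * density
        return cls(regime="natural", p_v=p_v, p_r=p_r, p_0=1.0 - density)


@dataclass(frozen=True)
class StepOutcome:
    """Resolution of one action: perceived (element, reward) pairs in order,
    which clients departed unserved, and whether an RV execution left a
    pending second-step credit for the next trial."""

    perceived: tuple[tuple[str, float], ...]
    departed: tuple[str, ...] = ()
    pending_rv: bool = False

    @property
    def food(self) -> float:
        return sum(r for _, r in self.perceived)


def sample_arena(config: EnvironmentConfig, rng, force_empty: bool = False) -> ArenaState:
    """Draw the arena occupancy for one trial.

    ``force_empty`` marks the interleaved empty trial of the laboratory
    protocols (the engine raises it after every feeding trial there).
    """
    if force_empty:
        return ArenaState(EMPTY, EMPTY)
    regime = config.regime
    if regime in ("lab_market", "two_choice"):
        return ArenaState(VISITOR, RESIDENT)
    if regime == "lab_complex":
        u = rng.random()
        rv, rr, _ = config.pair_mix
        if u < rv:
            return ArenaState(VISITOR, RESIDENT)
        if u < rv + rr:
            return ArenaState(RESIDENT, RESIDENT)
        return ArenaState(VISITOR, VISITOR)
    # natural: two independent draws per spot
    spots = []
    for _ in range(2):
        u = rng.random()
        if u < config.p_v:
            spots.append(VISITOR)
        elif u < config.p_v + config.p_r:
            spots.append(RESIDENT)
        else:
            spots.append(EMPTY)
    return ArenaState(spots[0], spots[1])


def resolve_step(
    config: EnvironmentConfig, arena: ArenaState, action: Action, rng=None
) -> StepOutcome:
    """Resolve an action against the arena into perceived states and rewards.

    A visitor not served first leaves; a waiting resident is served second
    (except in the two-choice task, where no second approach is allowed).
    Executing the VR chunk consumes both clients as one perceived element
    worth both rewards; executing RV serves the resident now (the visitor
    leaves) and leaves the chunk's second food unit to the first client
    served on the *next* trial — that part is the engine's bookkeeping, so
    here only the immediate outcome and a ``pending_rv`` flag are returned.
    """
    rw_v = config.reward_visitor
    rw_r = config.reward_resident
    nv, nr = arena.n_visitors, arena.n_residents

    if action.kind == "wait":
        if not arena.is_empty:
            raise ValueError("cannot wait with clients present")
        return StepOutcome((("X", 0.0),))

    if action.kind == "execute_chunk":
        if not arena.is_mixed:
            raise ValueError("chunk execution needs one visitor and one resident")
        if action.target == "VR":
            return StepOutcome((("VR", rw_v + rw_r),))
        if action.target == "RV":
            return StepOutcome(
                (("RV", rw_r),), departed=(VISITOR,), pending_rv=True
            )
        raise ValueError(f"unknown chunk action {action.target!r}")

    if action.kind != "serve":
        raise ValueError(f"unknown action kind {action.kind!r}")

    chosen = action.target
    if chosen == "V" and nv == 0 or chosen == "R" and nr == 0:
        raise ValueError(f"no {chosen} client present to serve")

    if arena.n_clients == 1:
        return StepOutcome(((chosen, config.reward(chosen)),))

    if config.both_ephemeral:
        other = VISITOR if chosen == "R" else RESIDENT
        return StepOutcome(((chosen, config.reward(chosen)),), departed=(other,))

    if chosen == "V":
        if nr >= 1:  # mixed pair: the waiting resident is served second
            return StepOutcome((("V", rw_v), ("R", rw_r)))
        return StepOutcome((("V", rw_v),), departed=(VISITOR,))  # v+v pair
    # chosen == "R"
    if nr == 2:  # r+r pair: the second resident waits and is served too
        return StepOutcome((("R", rw_r), ("R", rw_r)))
    return StepOutcome((("R", rw_r),), departed=(VISITOR,))  # mixed pair


def rv_pair_frequency(config: EnvironmentConfig) -> float:
    """Analytic probability that a natural-regime trial presents a mixed
    visitor-resident pair: 2 * P_V * P_R (a feature of the environment, not
    a simulated quantity)."""
    if config.regime != "natural":
        raise ValueError("rv_pair_frequency is defined for the natural regime")
    return 2.0 * config.p_v * config.p_r
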