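"""The four decision policies over the shared graph representation.

* ``linear_operator`` — a Rescorla-Wagner-style benchmark tracking one
  exponentially smoothed value per basic state; no graph structure is used
  for decisions.
* ``core`` — first-order associative learning: soft-max choice on the
  normalised values f = F/U of the two client states.
* ``extended_credit`` — the core model plus one-step-backward credit
  (chaining-like): a rewarding state also raises the value of the state
  perceived immediately before it.
* ``chunking`` — the core model plus chunk creation: an ordered pair of
  basic states co-occurring significantly more often than chance (by more
  than ``C_p`` binomial standard deviations) becomes a new decision element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .representation import (
    BASIC_LABELS,
    AssociativeGraph,
    ElementId,
    softmax_binary,
)

__all__ = [
    "MODELS",
    "LearnerParams",
    "LinearOperatorState",
    "ChunkEvent",
    "Action",
    "Learner",
    "linear_operator_update",
    "extended_credit_assign",
    "chunk_formation_test",
    "chunk_threshold",
    "maybe_create_chunks",
    "choose_action",
]

MODELS = ("linear_operator", "core", "extended_credit", "chunking")


@dataclass(frozen=True)
class LearnerParams:
    """Model choice and its parameters.

    Q is the prior threshold (occurrences before F may rise above zero, and
    minimum pair count before chunk testing); C_p >= 0 is the chunking
    avoidance parameter; alpha in (0, 1] is the linear-operator learning
    rate.  Q=10, C_p=2 and alpha=0.1 are the defaults used throughout.
    """

    model: str
    Q: int = 10
    C_p: float = 2.0
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.Q < 0 or int(self.Q) != self.Q:
            raise ValueError("Q must be a nonnegative integer (0 disables the prior)")
        if self.C_p < 0:
            raise ValueError("C_p must be nonnegative")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class LinearOperatorState:
    """Tracked values f(i) of the linear operator learner."""

    values: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BASIC_LABELS}
    )
    alpha: float = 0.1


@dataclass(frozen=True)
class ChunkEvent:
    """A chunk-creation event: which chunk, when, and at what evidence."""

    chunk: ElementId
    trial_index: int
    W_at_creation: int
    threshold_at_creation: float


@dataclass(frozen=True)
class Action:
    """What the cleaner does on a trial.

    ``serve`` targets a basic client state; ``execute_chunk`` runs a
    two-step sequence (only the chunking model, only when both client types
    are present); ``wait`` is the empty-arena response.
    """

    kind: str  # "serve" | "execute_chunk" | "wait"
    target: str | None = None


def linear_operator_update(
    state: LinearOperatorState, element: str, reward: float
) -> LinearOperatorState:
    """f(i) <- (1 - alpha) * f(i) + alpha * reward, in place."""
    if element not in state.values:
        raise KeyError(f"untracked state {element!r}")
    a = state.alpha
    state.values[element] = (1.0 - a) * state.values[element] + a * reward
    return state


def extended_credit_assign(
    graph: AssociativeGraph,
    prev: str | None,
    current: str,
    reward: float,
    Q: int,
) -> AssociativeGraph:
    """Credit ``current`` with its reward and extend it one step back.

    The current element receives the ordinary choice-outcome update.  If the
    reward is positive and a preceding element exists, that element's F also
    grows by the reward — behind its own already-accumulated Q gate, without
    touching its U.  X neither donates nor receives extended credit (its
    reward is always zero and it is never a decision option).
    """
    graph.record_choice_outcome(current, reward, Q)
    if reward > 0 and prev is not None and prev != "X":
        graph._check(prev)
        if graph.U.get(prev, 0) > Q:
            graph.F[prev] = graph.F.get(prev, 0.0) + reward
    return graph


def chunk_threshold(graph: AssociativeGraph, pair: tuple[str, str], C_p: float) -> float:
    """Right-hand side of the chunk test: M*Pi*Pj + C_p * binomial sd.

    P(k) are observed element frequencies O(k)/sum(O); the standard
    deviation is sqrt(M * Pi*Pj * (1 - Pi*Pj)).
    """
    pi = graph.frequency(pair[0])
    pj = graph.frequency(pair[1])
    pp = pi * pj
    return graph.M * pp + C_p * math.sqrt(graph.M * pp * (1.0 - pp))


def chunk_formation_test(
    graph: AssociativeGraph, pair: tuple[str, str], C_p: float, Q: int
) -> bool:
    """Should the ordered pair become a chunk?

    True iff W(pair) >= Q (minimal sample size for the inference) and
    W(pair) exceeds its chance expectation by more than C_p binomial
    standard deviations.  Only pairs of basic states may be chunked.
    """
    a, b = pair
    for lbl in pair:
        e = graph.elements.get(lbl)
        if e is None:
            raise KeyError(f"unknown element {lbl!r}")
        if e.is_chunk:
            raise ValueError("chunks are pairs of basic elements only")
    w = graph.W.get((a, b), 0)
    if w < Q or graph.M == 0:
        return False
    return w > chunk_threshold(graph, pair, C_p)


def maybe_create_chunks(
    graph: AssociativeGraph,
    last_pair: tuple[str, str],
    params: LearnerParams,
    trial: int,
) -> ChunkEvent | None:
    """Run the chunk test on the just-updated pair; create the chunk if due.

    A no-op when the chunk already exists or either member is itself a
    chunk.  The new element starts with zero U/F/O; W counts are kept.
    """
    a, b = last_pair
    if a not in BASIC_LABELS or b not in BASIC_LABELS:
        return None
    if (a + b) in graph.elements:
        return None
    if not chunk_formation_test(graph, last_pair, params.C_p, params.Q):
        return None
    elem = graph.add_chunk(a, b)
    return ChunkEvent(
        chunk=elem,
        trial_index=trial,
        W_at_creation=graph.W.get((a, b), 0),
        threshold_at_creation=chunk_threshold(graph, last_pair, params.C_p),
    )


class Learner:
    """A decision policy bundled with its mutable learning state.

    The engine drives the per-trial updates; this class supplies the value
    readout and the model-specific option set for the soft-max choice.
    """

    def __init__(self, params: LearnerParams) -> None:
        self.params = params
        self.graph = AssociativeGraph()
        self.linear: LinearOperatorState | None = (
            LinearOperatorState(alpha=params.alpha)
            if params.model == "linear_operator"
            else None
        )

    def value(self, label: str) -> float:
        if self.linear is not None:
            return self.linear.values.get(label, 0.0)
        return self.graph.normalized_value(label)

    def mixed_pair_options(self) -> tuple[Action, Action]:
        """The (visitor-side, resident-side) options for a mixed pair.

        The chunking model substitutes chunk executions for plain servings
        as soon as the relevant chunks exist; once a chunk covers a client
        type, serving that type's first element alone is no longer offered.
        """
        if self.params.model == "chunking":
            has_vr = self.graph.has_element("VR")
            has_rv = self.graph.has_element("RV")
            v_opt = (
                Action("execute_chunk", "VR") if has_vr else Action("serve", "V")
            )
            r_opt = (
                Action("execute_chunk", "RV") if has_rv else Action("serve", "R")
            )
            return v_opt, r_opt
        return Action("serve", "V"), Action("serve", "R")


def choose_action(learner: Learner, arena, rng) -> Action:
    """Pick the trial's action for an arena state.

    Empty arena: wait.  Single client: serve it.  Same-type pair: serve that
    type (the two positions are interchangeable).  Mixed pair: binary
    soft-max over the learner's option set, on the options' values.
    """
    nv = arena.n_visitors
    nr = arena.n_residents
    if nv + nr == 0:
        return Action("wait")
    if nv + nr == 1 or nv == 2 or nr == 2:
        return Action("serve", "V" if nv else "R")
    v_opt, r_opt = learner.mixed_pair_options()
    f_v = learner.value(v_opt.target)
    f_r = learner.value(r_opt.target)
    p = softmax_binary(f_v, f_r)
    return v_opt if rng.random() < p else r_opt
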