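"""Weighted directed graph internal representation.

The learner's memory is a directed graph over *elements*: the three basic
behavioural states ``V`` (serving a visitor client), ``R`` (serving a
resident client) and ``X`` (waiting at an empty arena), plus any *chunk*
elements created later (ordered pairs of basic states such as ``VR``).

Four count stores are attached to the graph:

``W``
    edge weights — how often element ``j`` was perceived right after ``i``;
``U``
    node weights — how often each element was chosen/perceived as an action
    outcome;
``F``
    node values — food units accumulated from choosing the element, gated by
    the prior threshold ``Q`` (the first ``Q`` servings never raise ``F``);
``O``
    perceived-occurrence counts, used for the element frequency estimates
    that feed the chunk-formation significance test.

All counts only ever increase: there is no decay or forgetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BASIC_LABELS",
    "ElementId",
    "AssociativeGraph",
    "softmax_binary",
]

#: The three basic behavioural states available from the start.
BASIC_LABELS = ("V", "R", "X")


@dataclass(frozen=True)
class ElementId:
    """Identity of a graph element: a basic state or an ordered-pair chunk.

    Chunks are always pairs of *basic* labels (``components``); chunks of
    chunks do not exist.
    """

    kind: str  # "basic" | "chunk"
    label: str
    components: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind == "basic":
            if self.components is not None:
                raise ValueError("basic elements have no components")
        elif self.kind == "chunk":
            if (
                self.components is None
                or len(self.components) != 2
                or any(c not in BASIC_LABELS for c in self.components)
            ):
                raise ValueError(
                    "a chunk's components must be exactly two basic labels"
                )
        else:
            raise ValueError(f"unknown element kind: {self.kind!r}")

    @classmethod
    def basic(cls, label: str) -> "ElementId":
        return cls("basic", label)

    @classmethod
    def chunk(cls, first: str, second: str) -> "ElementId":
        return cls("chunk", first + second, (first, second))

    @property
    def is_chunk(self) -> bool:
        return self.kind == "chunk"


def softmax_binary(f_i: float, f_j: float) -> float:
    """Probability of picking the first of two options under soft-max choice.

    ``pi_i = 1 / (1 + exp(-(f_i - f_j)))``; the complement is the second
    option's probability.  Saturates smoothly for large differences.
    """
    d = f_i - f_j
    if d >= 0.0:
        return 1.0 / (1.0 + math.exp(-d))
    e = math.exp(d)
    return e / (1.0 + e)


class AssociativeGraph:
    """Mutable element graph with transition, choice and value counts.

    Attributes mirror the model's bookkeeping: ``W`` maps ordered label
    pairs to transition counts, ``U``/``F``/``O`` map labels to choice
    counts, accumulated food and perceived occurrences, ``M`` is the total
    number of recorded transitions and ``n_obs`` the total number of
    perceived elements (the stream length).
    """

    __slots__ = ("elements", "W", "U", "F", "O", "M", "n_obs")

    def __init__(self, basics: tuple[str, ...] = BASIC_LABELS) -> None:
        self.elements: dict[str, ElementId] = {
            b: ElementId.basic(b) for b in basics
        }
        self.W: dict[tuple[str, str], int] = {}
        self.U: dict[str, int] = {}
        self.F: dict[str, float] = {}
        self.O: dict[str, int] = {}
        self.M: int = 0
        self.n_obs: int = 0

    # -- structure ---------------------------------------------------------

    def add_chunk(self, first: str, second: str) -> ElementId:
        """Add the chunk element for the ordered pair (first, second).

        The new element starts with zero U/F/O; existing W counts for the
        constituent pair are left untouched.
        """
        elem = ElementId.chunk(first, second)
        if elem.label in self.elements:
            raise ValueError(f"element {elem.label!r} already exists")
        self.elements[elem.label] = elem
        return elem

    def has_element(self, label: str) -> bool:
        return label in self.elements

    def _check(self, label: str) -> None:
        if label not in self.elements:
            raise KeyError(
                f"unknown element {label!r}: corrupted perception stream"
            )

    # -- update rules ------------------------------------------------------

    def record_transition(self, prev: str | None, nxt: str) -> None:
        """Record that ``nxt`` was perceived right after ``prev``.

        Increments ``W(prev, nxt)``, ``M`` and ``O(nxt)``.  At the start of
        the stream (``prev is None``) only the occurrence of ``nxt`` is
        counted.
        """
        self._check(nxt)
        if prev is not None:
            self._check(prev)
            key = (prev, nxt)
            self.W[key] = self.W.get(key, 0) + 1
            self.M += 1
        self.O[nxt] = self.O.get(nxt, 0) + 1
        self.n_obs += 1

    def record_choice_outcome(self, element: str, reward: float, Q: int) -> None:
        """Credit a chosen element with its food reward, behind the Q prior.

        ``U`` is incremented first; ``F`` then grows by ``reward`` only once
        the post-increment ``U`` exceeds ``Q`` (with Q=10, from the 11th
        serving on).
        """
        self._check(element)
        if reward < 0:
            raise ValueError("reward must be nonnegative")
        u = self.U.get(element, 0) + 1
        self.U[element] = u
        if u > Q:
            self.F[element] = self.F.get(element, 0.0) + reward

    # -- readouts ----------------------------------------------------------

    def normalized_value(self, element: str) -> float:
        """Average payoff f = F/U of an element; 0 for a never-chosen one."""
        u = self.U.get(element, 0)
        if u == 0:
            return 0.0
        return self.F.get(element, 0.0) / u

    def frequency(self, element: str) -> float:
        """Observed frequency P(element) = O(element) / total observations."""
        if self.n_obs == 0:
            return 0.0
        return self.O.get(element, 0) / self.n_obs

    def final_values(self) -> dict[str, float]:
        """Normalised value f for every element currently in the graph."""
        return {lbl: self.normalized_value(lbl) for lbl in self.elements}

    # -- export ------------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "element": lbl,
                "kind": e.kind,
                "U": self.U.get(lbl, 0),
                "F": self.F.get(lbl, 0.0),
                "O": self.O.get(lbl, 0),
                "f": self.normalized_value(lbl),
            }
            for lbl, e in self.elements.items()
        ]
        return pd.DataFrame(rows, columns=["element", "kind", "U", "F", "O", "f"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "W": w} for (a, b), w in self.W.items()
        ]
        return pd.DataFrame(rows, columns=["from", "to", "W"])

    def to_networkx(self):
        """The representation as a ``networkx.DiGraph`` (weights on edges)."""
        import networkx as nx

        g = nx.DiGraph()
        for lbl, e in self.elements.items():
            g.add_node(
                lbl,
                kind=e.kind,
                U=self.U.get(lbl, 0),
                F=self.F.get(lbl, 0.0),
                O=self.O.get(lbl, 0),
                f=self.normalized_value(lbl),
            )
        for (a, b), w in self.W.items():
            g.add_edge(a, b, W=w)
        return g

    def to_dot(self) -> str:
        """GraphViz DOT snapshot (node size ~ value, edge label = W)."""
        lines = ["digraph representation {", "  rankdir=LR;"]
        for lbl, e in self.elements.items():
            shape = "ellipse" if e.kind == "basic" else "box"
            f = self.normalized_value(lbl)
            lines.append(
                f'  "{lbl}" [shape={shape}, label="{lbl}\\nf={f:.2f} '
                f'U={self.U.get(lbl, 0)}"];'
            )
        for (a, b), w in sorted(self.W.items()):
            lines.append(f'  "{a}" -> "{b}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
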