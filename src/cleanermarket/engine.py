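"""Trial loop coupling learner and environment, plus replicate aggregation.

``run_simulation`` executes the discrete-trial loop: sample the arena,
choose an action, resolve the serving dynamics, then update the learner
(transition counts over the perceived-state stream, choice/value credit,
and — for the chunking model — the chunk-formation test on the pair just
observed).  The inner loop inlines the representation update rules for
speed; the test suite replays recorded streams through the public
:mod:`cleanermarket.representation` operations to pin both paths to the
same semantics.

Preference is always measured as the proportion of visitor-first choices
among mixed (one visitor + one resident) encounters; executing the VR chunk
counts as visitor-first, serving R or executing RV as resident-first.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .environments import EMPTY, RESIDENT, VISITOR, EnvironmentConfig
from .learners import ChunkEvent, LearnerParams
from .representation import BASIC_LABELS, AssociativeGraph, ElementId

__all__ = [
    "TrialRecord",
    "SimulationResult",
    "ReplicateSummary",
    "run_simulation",
    "preference_series",
    "final_preference",
    "run_replicates",
]


@dataclass(frozen=True)
class TrialRecord:
    """One trial's log row."""

    index: int
    spot1: str
    spot2: str
    action_kind: str
    action_target: str | None
    perceived: tuple[str, ...]
    food: float
    mixed_encounter: bool
    visitor_first: bool | None  # defined only for mixed encounters


@dataclass
class SimulationResult:
    """Full log of one simulation run.

    ``mixed`` and ``visitor_first`` are per-trial boolean arrays kept even
    when detailed trial records are switched off, so preference series can
    always be computed.
    """

    trials: list[TrialRecord]
    chunk_events: list[ChunkEvent]
    final_graph: AssociativeGraph
    seed: int
    n_trials: int
    mixed: np.ndarray
    visitor_first: np.ndarray
    final_values: dict[str, float]
    total_food: float
    model: str

    def chunk_labels(self) -> tuple[str, ...]:
        return tuple(e.chunk.label for e in self.chunk_events)


_LAB_REGIMES = ("two_choice", "lab_market", "lab_complex")


def run_simulation(
    env: EnvironmentConfig,
    params: LearnerParams,
    n_trials: int,
    seed: int,
    record: bool = True,
) -> SimulationResult:
    """Run ``n_trials`` trials of one learner in one environment.

    ``n_trials`` counts *all* trials, including the empty trials that the
    laboratory protocols interleave after each feeding trial (so 1,000
    feeding trials of a lab regime are ``n_trials=2000``).  With
    ``record=False`` only the aggregate arrays are kept, which the
    parameter sweeps rely on.  Identical (configs, seed) give bit-identical
    results.
    """
    rng = random.Random(seed)
    rnd = rng.random
    exp = math.exp
    sqrt = math.sqrt

    model = params.model
    is_chunking = model == "chunking"
    is_extended = model == "extended_credit"
    is_linear = model == "linear_operator"
    Q = params.Q
    Cp = params.C_p
    alpha = params.alpha

    graph = AssociativeGraph()
    elements = graph.elements
    W = graph.W
    U = graph.U
    F = graph.F
    O = graph.O
    lin_vals = {b: 0.0 for b in BASIC_LABELS} if is_linear else None

    regime = env.regime
    natural = regime == "natural"
    two_choice = regime == "two_choice"
    lab_complex = regime == "lab_complex"
    rw_v = env.reward_visitor
    rw_r = env.reward_resident
    p_v = env.p_v
    p_vr = env.p_v + env.p_r
    mix_rv, mix_rr, _ = env.pair_mix

    m_total = 0
    n_obs = 0
    prev: str | None = None
    forced_empty = False
    pending: str | None = None  # chunk label owed next-trial credit
    pending_next: str | None = None
    chunked: set[tuple[str, str]] = set()
    chunk_events: list[ChunkEvent] = []
    trials: list[TrialRecord] = []
    mixed_arr = bytearray(n_trials)
    vf_arr = bytearray(n_trials)
    total_food = 0.0
    BAS = BASIC_LABELS

    for t in range(n_trials):
        pending = pending_next
        pending_next = None

        # --- arena occupancy -------------------------------------------
        if forced_empty:
            forced_empty = False
            nv = nr = 0
            s1 = s2 = EMPTY
        elif natural:
            u = rnd()
            s1 = VISITOR if u < p_v else (RESIDENT if u < p_vr else EMPTY)
            u = rnd()
            s2 = VISITOR if u < p_v else (RESIDENT if u < p_vr else EMPTY)
            nv = (s1 == VISITOR) + (s2 == VISITOR)
            nr = (s1 == RESIDENT) + (s2 == RESIDENT)
        elif lab_complex:
            u = rnd()
            if u < mix_rv:
                nv, nr, s1, s2 = 1, 1, VISITOR, RESIDENT
            elif u < mix_rv + mix_rr:
                nv, nr, s1, s2 = 0, 2, RESIDENT, RESIDENT
            else:
                nv, nr, s1, s2 = 2, 0, VISITOR, VISITOR
        else:  # lab_market, two_choice: always one visitor and one resident
            nv, nr, s1, s2 = 1, 1, VISITOR, RESIDENT

        # --- choose an action and resolve the serving dynamics ---------
        mixed = False
        vfirst = False
        if nv + nr == 0:
            perceived = (("X", 0.0),)
            act_kind, act_target = "wait", None
        elif nv + nr == 1:
            if nv:
                perceived = (("V", rw_v),)
                act_target = "V"
            else:
                perceived = (("R", rw_r),)
                act_target = "R"
            act_kind = "serve"
        elif nr == 2:
            # same-type pair: pick either resident; the other waits and is
            # also served (positions are interchangeable)
            perceived = (("R", rw_r), ("R", rw_r))
            act_kind, act_target = "serve", "R"
        elif nv == 2:
            perceived = (("V", rw_v),)  # the unchosen visitor leaves
            act_kind, act_target = "serve", "V"
        else:
            mixed = True
            if is_chunking:
                has_vr = "VR" in elements
                has_rv = "RV" in elements
            else:
                has_vr = has_rv = False
            if is_linear:
                f_v = lin_vals["V"]
                f_r = lin_vals["R"]
            else:
                lv = "VR" if has_vr else "V"
                lr = "RV" if has_rv else "R"
                uv = U.get(lv, 0)
                f_v = F.get(lv, 0.0) / uv if uv else 0.0
                ur = U.get(lr, 0)
                f_r = F.get(lr, 0.0) / ur if ur else 0.0
            d = f_v - f_r
            p1 = 1.0 / (1.0 + exp(-d)) if d > -500.0 else 0.0
            pick_v = rnd() < p1
            if two_choice:
                # both ephemeral: only the chosen client is consumed
                if pick_v:
                    perceived = (("V", rw_v),)
                    act_kind, act_target, vfirst = "serve", "V", True
                else:
                    perceived = (("R", rw_r),)
                    act_kind, act_target = "serve", "R"
            elif pick_v:
                vfirst = True
                if has_vr:
                    perceived = (("VR", rw_v + rw_r),)
                    act_kind, act_target = "execute_chunk", "VR"
                else:
                    perceived = (("V", rw_v), ("R", rw_r))
                    act_kind, act_target = "serve", "V"
            else:
                if has_rv:
                    perceived = (("RV", rw_r),)
                    act_kind, act_target = "execute_chunk", "RV"
                    pending_next = "RV"
                else:
                    perceived = (("R", rw_r),)
                    act_kind, act_target = "serve", "R"

        if not natural and nv + nr > 0:
            forced_empty = True  # lab protocols: empty trial after feeding

        # --- learner updates over the perceived stream ------------------
        food = 0.0
        for lbl, rwd in perceived:
            food += rwd
            # occurrence + transition bookkeeping
            o = O.get(lbl, 0) + 1
            O[lbl] = o
            n_obs += 1
            credit_prev = prev
            if prev is not None:
                key = (prev, lbl)
                w = W.get(key, 0) + 1
                W[key] = w
                m_total += 1
                if (
                    is_chunking
                    and w >= Q
                    and key not in chunked
                    and prev in BAS
                    and lbl in BAS
                ):
                    pp = (O[prev] / n_obs) * (o / n_obs)
                    thresh = m_total * pp + Cp * sqrt(
                        m_total * pp * (1.0 - pp)
                    )
                    if w > thresh:
                        clabel = prev + lbl
                        elements[clabel] = ElementId("chunk", clabel, key)
                        chunked.add(key)
                        chunk_events.append(
                            ChunkEvent(elements[clabel], t, w, thresh)
                        )
            prev = lbl

            # choice/value credit
            if is_linear:
                lin_vals[lbl] = (1.0 - alpha) * lin_vals[lbl] + alpha * rwd
            elif pending is not None and rwd > 0.0 and lbl != "X":
                # the first food unit of this trial repays the RV chunk
                # executed on the previous trial
                if lbl in BAS:
                    if U.get(pending, 0) > Q:
                        F[pending] = F.get(pending, 0.0) + rwd
                    # the serving client's own U/F are not updated
                else:
                    # next trial's action is itself a chunk execution: the
                    # pending chunk takes the first constituent's reward,
                    # the executed chunk keeps the remainder
                    comp0 = elements[lbl].components[0]
                    first_unit = rw_v if comp0 == "V" else rw_r
                    if U.get(pending, 0) > Q:
                        F[pending] = F.get(pending, 0.0) + first_unit
                    u = U.get(lbl, 0) + 1
                    U[lbl] = u
                    if u > Q:
                        F[lbl] = F.get(lbl, 0.0) + (rwd - first_unit)
                pending = None
            else:
                u = U.get(lbl, 0) + 1
                U[lbl] = u
                if u > Q:
                    F[lbl] = F.get(lbl, 0.0) + rwd
                if (
                    is_extended
                    and rwd > 0.0
                    and credit_prev is not None
                    and credit_prev != "X"
                ):
                    if U.get(credit_prev, 0) > Q:
                        F[credit_prev] = F.get(credit_prev, 0.0) + rwd

        total_food += food
        mixed_arr[t] = mixed
        vf_arr[t] = vfirst
        if record:
            trials.append(
                TrialRecord(
                    index=t,
                    spot1=s1,
                    spot2=s2,
                    action_kind=act_kind,
                    action_target=act_target,
                    perceived=tuple(lbl for lbl, _ in perceived),
                    food=food,
                    mixed_encounter=mixed,
                    visitor_first=vfirst if mixed else None,
                )
            )

    graph.M = m_total
    graph.n_obs = n_obs
    if is_linear:
        final_values = dict(lin_vals)
    else:
        final_values = graph.final_values()
    return SimulationResult(
        trials=trials,
        chunk_events=chunk_events,
        final_graph=graph,
        seed=seed,
        n_trials=n_trials,
        mixed=np.frombuffer(bytes(mixed_arr), dtype=np.uint8).astype(bool),
        visitor_first=np.frombuffer(bytes(vf_arr), dtype=np.uint8).astype(bool),
        final_values=final_values,
        total_food=total_food,
        model=model,
    )


def preference_series(
    result: SimulationResult, bin_size: int = 40
) -> list[tuple[int, float]]:
    """Visitor preference per consecutive bin of trials.

    For each bin, preference = visitor-first count / mixed-encounter count;
    NaN marks bins without any mixed encounter.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out: list[tuple[int, float]] = []
    mixed = result.mixed
    vf = result.visitor_first
    n = result.n_trials
    for b, start in enumerate(range(0, n, bin_size)):
        sl = slice(start, min(start + bin_size, n))
        m = int(mixed[sl].sum())
        out.append((b, float(vf[sl].sum()) / m if m else math.nan))
    return out


def preference_counts(
    result: SimulationResult, window: int = 200
) -> tuple[int, int]:
    """(visitor-first, mixed-encounter) counts in the last ``window`` trials.

    Exposed so that callers pooling several replicates can weight each by
    its actual number of encounters instead of averaging ratios.
    """
    if window > result.n_trials:
        raise ValueError("window exceeds the number of trials")
    return (
        int(result.visitor_first[-window:].sum()),
        int(result.mixed[-window:].sum()),
    )


def final_preference(result: SimulationResult, window: int = 200) -> float:
    """Preference over mixed encounters in the last ``window`` trials
    (NaN if that window contains none)."""
    if window > result.n_trials:
        raise ValueError("window exceeds the number of trials")
    mixed = result.mixed[-window:]
    m = int(mixed.sum())
    if m == 0:
        return math.nan
    return float(result.visitor_first[-window:].sum()) / m


@dataclass
class ReplicateSummary:
    """Aggregate of seeded replicate simulations of one condition."""

    n_reps: int
    base_seed: int
    bin_size: int
    window: int
    bin_index: np.ndarray
    bin_mean: np.ndarray
    bin_sem: np.ndarray
    final_preferences: np.ndarray
    final_values: list[dict[str, float]] = field(repr=False)
    chunk_created: dict[str, int] = field(default_factory=dict)
    chunk_labels_per_rep: list[tuple[str, ...]] = field(
        default_factory=list, repr=False
    )

    def preference_mean(self) -> float:
        """Mean final preference over replicates with mixed encounters."""
        return float(np.nanmean(self.final_preferences))

    def mean_final_value(self, label: str) -> float:
        """Replicate-mean final f(label), over replicates where the element
        exists (relevant for chunks, which not every replicate creates)."""
        vals = [fv[label] for fv in self.final_values if label in fv]
        if not vals:
            return math.nan
        return float(np.mean(vals))

    def chunk_fraction(self, label: str) -> float:
        """Fraction of replicates in which the chunk was created."""
        return self.chunk_created.get(label, 0) / self.n_reps


def run_replicates(
    env: EnvironmentConfig,
    params: LearnerParams,
    n_trials: int,
    n_reps: int = 100,
    base_seed: int = 0,
    bin_size: int = 40,
    window: int = 200,
    record: bool = False,
) -> ReplicateSummary:
    """Run ``n_reps`` seeded replicates (seeds ``base_seed + i``) and
    aggregate: per-bin preference mean and standard error of the mean,
    final preferences and final normalised values per replicate, and the
    count of replicates creating each chunk."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_bins = (n_trials + bin_size - 1) // bin_size
    bins = np.full((n_reps, n_bins), np.nan)
    finals = np.full(n_reps, np.nan)
    final_values: list[dict[str, float]] = []
    chunk_created: dict[str, int] = {}
    labels_per_rep: list[tuple[str, ...]] = []
    for i in range(n_reps):
        res = run_simulation(env, params, n_trials, base_seed + i, record=record)
        for b, p in preference_series(res, bin_size):
            bins[i, b] = p
        finals[i] = final_preference(res, window)
        final_values.append(res.final_values)
        labels = res.chunk_labels()
        labels_per_rep.append(labels)
        for lbl in set(labels):
            chunk_created[lbl] = chunk_created.get(lbl, 0) + 1
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(bins, axis=0)
        counts = np.sum(~np.isnan(bins), axis=0)
        sd = np.nanstd(bins, axis=0, ddof=1) if n_reps > 1 else np.zeros(n_bins)
        sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
    return ReplicateSummary(
        n_reps=n_reps,
        base_seed=base_seed,
        bin_size=bin_size,
        window=window,
        bin_index=np.arange(n_bins),
        bin_mean=mean,
        bin_sem=sem,
        final_preferences=finals,
        final_values=final_values,
        chunk_created=chunk_created,
        chunk_labels_per_rep=labels_per_rep,
    )
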