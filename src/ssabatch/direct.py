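"""Exact SSA, Gillespie's direct method: one realization at a time.

Each step draws two uniforms r1, r2 from (0, 1]; the waiting time is
tau = ln(1/r1) / a_total and the fired channel is the smallest m with
sum_{i<m} a_i < r2 * a_total <= sum_{i<=m} a_i.  Counts are updated through
the reaction's CRS row, time and the step counter advance, and the full state
is recorded (every step by default) until a step or time horizon is reached
or the system absorbs (a_total == 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import CRSStoichiometry, ModelSpec, ReactionSpec, crs_from_model, require_valid

__all__ = [
    "RNGStream",
    "SimState",
    "TimeCourse",
    "propensity",
    "propensity_vector",
    "total_propensity",
    "reaction_time",
    "select_reaction",
    "fire_reaction",
    "run_trajectory",
]

_BLOCK = 4096  # uniforms drawn per refill; does not change the draw sequence


class RNGStream:
    """Seeded uniform-(0, 1] stream with independent per-realization substreams.

    Mersenne Twister (MT19937) seeded through a SeedSequence keyed by
    ``(seed, stream)``: identical keys reproduce the identical sequence, and
    distinct stream indices give statistically independent substreams.
    Uniforms are ``1 - U[0, 1)`` so the open-at-zero guarantee holds and
    ``ln(1/r)`` never overflows.
    """

    def __init__(self, seed: int, stream: int = 0):
        self.seed = int(seed)
        self.stream = int(stream)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(self.stream,))
        self._gen = np.random.Generator(np.random.MT19937(ss))
        self._buf = np.empty(0)
        self._pos = 0

    def uniform(self) -> float:
        """Next uniform in (0, 1]."""
        if self._pos >= len(self._buf):
            self._buf = 1.0 - self._gen.random(_BLOCK)
            self._pos = 0
        u = self._buf[self._pos]
        self._pos += 1
        return float(u)

    def uniforms(self, k: int) -> np.ndarray:
        """Next k uniforms in (0, 1], in draw order."""
        return np.array([self.uniform() for _ in range(k)])


@dataclass(frozen=True)
class SimState:
    """Counts, cumulative time, and fired-step counter of one realization."""

    counts: np.ndarray
    t: float = 0.0
    step: int = 0

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))


@dataclass(frozen=True)
class TimeCourse:
    """Per-step record of one realization: (step, time, counts) rows.

    ``counts`` has one row per record; row 0 is the initial state.
    ``absorbed`` flags early termination at a_total == 0.  ``cadence`` k
    means every k-th step was recorded (plus the initial state and, on
    absorption, the final state).
    """

    steps: np.ndarray
    times: np.ndarray
    counts: np.ndarray
    species: tuple[str, ...]
    absorbed: bool = False
    cadence: int = 1

    def __post_init__(self):
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=np.int64))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=np.float64))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))

    @property
    def n_records(self) -> int:
        return len(self.steps)

    def final_state(self) -> SimState:
        return SimState(self.counts[-1], float(self.times[-1]), int(self.steps[-1]))


def propensity(reaction: ReactionSpec, counts: np.ndarray, combinatorial: bool = True) -> float:
    """Mass-action propensity of one channel at the given counts.

    order 0 -> c; order 1 -> c*x; heterodimer -> c*x1*x2; homodimer ->
    c*x*(x-1)/2 (number of distinct pairs).  ``combinatorial=False`` switches
    the homodimer form to c*x**2.
    """
    c = reaction.rate_constant
    r = reaction.reactants
    if not r:
        return c
    if len(r) == 1:
        s, k = r[0]
        x = float(counts[s])
        if k == 1:
            return c * x
        if k == 2:
            return c * x * (x - 1.0) / 2.0 if combinatorial else c * x * x
    elif len(r) == 2:
        (s1, k1), (s2, k2) = r
        if k1 == 1 and k2 == 1:
            return c * float(counts[s1]) * float(counts[s2])
    raise ValueError(f"reaction {reaction.id!r}: order {reaction.order} > 2 unsupported")


def propensity_vector(model: ModelSpec, counts: np.ndarray, combinatorial: bool = True) -> np.ndarray:
    return np.array([propensity(r, counts, combinatorial) for r in model.reactions])


def total_propensity(a) -> float:
    """Sum of propensities, compensated (fsum) so long vectors stay exact."""
    return math.fsum(a)


def reaction_time(a_total: float, r1: float) -> float:
    """tau = ln(1/r1) / a_total, the exponential waiting time."""
    if a_total <= 0.0:
        raise ValueError("a_total must be positive (absorbing state)")
    return math.log(1.0 / r1) / a_total


def select_reaction(a, r2: float, a_total: float | None = None) -> int:
    """Smallest index m with cumulative propensity >= r2 * a_total.

    Linear cumulative scan (the direct method); satisfies the double
    inequality sum_{i<m} a_i < r2*a_total <= sum_{i<=m} a_i.
    """
    if a_total is None:
        a_total = total_propensity(a)
    if a_total <= 0.0:
        raise ValueError("cannot select a reaction when a_total == 0")
    threshold = r2 * a_total
    cum = 0.0
    last = 0
    for i, ai in enumerate(a):
        cum += ai
        if ai > 0.0:
            last = i
            if threshold <= cum:
                return i
    return last  # r2 == 1 with float round-down: last nonzero channel


def fire_reaction(state: SimState, crs: CRSStoichiometry, m: int, tau: float) -> SimState:
    """Apply CRS row m to the counts; advance time by tau and step by 1."""
    counts = state.counts.copy()
    idx, delta = crs.row(m)
    counts[idx] += delta
    if (counts[idx] < 0).any():
        raise RuntimeError(
            f"reaction {m} drove a count negative (propensity bug upstream)"
        )
    return SimState(counts, state.t + tau, state.step + 1)


def _reaction_tables(model: ModelSpec, crs: CRSStoichiometry, combinatorial: bool):
    """Precompute per-reaction dispatch tuples for the inner loop.

    kind: 0 = zeroth order, 1 = unimolecular, 2 = heterodimer, 3 = homodimer.
    """
    kinds = []
    for r in model.reactions:
        c = r.rate_constant
        if not r.reactants:
            kinds.append((0, -1, -1, c))
        elif len(r.reactants) == 1:
            s, k = r.reactants[0]
            if k == 1:
                kinds.append((1, s, -1, c))
            else:
                kinds.append((3, s, -1, c))
        else:
            (s1, _), (s2, _) = r.reactants
            kinds.append((2, s1, s2, c))
    rows = [
        [(int(s), int(d)) for s, d in zip(*crs.row(j))] for j in range(crs.n)
    ]
    return kinds, rows


def run_trajectory(
    model: ModelSpec,
    crs: CRSStoichiometry | None = None,
    rng: RNGStream | None = None,
    *,
    seed: int | None = None,
    stream: int = 0,
    max_steps: int | None = None,
    max_time: float | None = None,
    cadence: int = 1,
    combinatorial: bool = True,
) -> TimeCourse:
    """Run one realization of the direct method and record its time course.

    Exactly two uniforms (r1 then r2) are consumed per fired step, so a
    trajectory is fully determined by (seed, stream) and the stop criterion.
    Stops at whichever of ``max_steps`` / ``max_time`` triggers first (the
    time check happens after firing, so the last record may lie past
    ``max_time``); a_total == 0 terminates early with ``absorbed=True``.
    """
    require_valid(model)
    if max_steps is None and max_time is None:
        raise ValueError("need a stop criterion: max_steps and/or max_time")
    if cadence < 1:
        raise ValueError("cadence must be >= 1")
    if crs is None:
        crs = crs_from_model(model)
    if rng is None:
        if seed is None:
            raise ValueError("provide rng or seed")
        rng = RNGStream(seed, stream)

    m_sp = model.m_species
    counts = [int(x) for x in model.initial_counts]
    kinds, rows = _reaction_tables(model, crs, combinatorial)
    fsum = math.fsum
    log = math.log
    uniform = rng.uniform

    cap = (max_steps // cadence + 2) if max_steps is not None else 1024
    rec_steps = np.empty(cap, dtype=np.int64)
    rec_times = np.empty(cap, dtype=np.float64)
    rec_counts = np.empty((cap, m_sp), dtype=np.int64)
    n_rec = 0

    def record(step, t):
        nonlocal n_rec, cap, rec_steps, rec_times, rec_counts
        if n_rec == cap:
            cap *= 2
            rec_steps = np.resize(rec_steps, cap)
            rec_times = np.resize(rec_times, cap)
            rec_counts = np.resize(rec_counts, (cap, m_sp))
        rec_steps[n_rec] = step
        rec_times[n_rec] = t
        rec_counts[n_rec] = counts
        n_rec += 1

    t = 0.0
    step = 0
    absorbed = False
    record(0, 0.0)
    while True:
        if max_steps is not None and step >= max_steps:
            break
        if max_time is not None and t >= max_time:
            break
        a = [0.0] * len(kinds)
        for j, (kind, s1, s2, c) in enumerate(kinds):
            if kind == 1:
                a[j] = c * counts[s1]
            elif kind == 2:
                a[j] = c * counts[s1] * counts[s2]
            elif kind == 3:
                x = counts[s1]
                a[j] = c * x * (x - 1) * 0.5 if combinatorial else c * x * x
            else:
                a[j] = c
        a_total = fsum(a)
        if a_total <= 0.0:
            absorbed = True
            if step % cadence != 0:
                record(step, t)  # final state, even off-cadence
            break
        r1 = uniform()
        r2 = uniform()
        t += log(1.0 / r1) / a_total
        threshold = r2 * a_total
        cum = 0.0
        m = 0
        for j, aj in enumerate(a):
            cum += aj
            if aj > 0.0:
                m = j
                if threshold <= cum:
                    break
        for s, d in rows[m]:
            counts[s] += d
            if counts[s] < 0:
                raise RuntimeError(
                    f"reaction {m} drove species {s} negative (propensity bug)"
                )
        step += 1
        if step % cadence == 0:
            record(step, t)

    if n_rec == 0 or rec_steps[n_rec - 1] != step:
        record(step, t)
    return TimeCourse(
        steps=rec_steps[:n_rec].copy(),
        times=rec_times[:n_rec].copy(),
        counts=rec_counts[:n_rec].copy(),
        species=model.species,
        absorbed=absorbed,
        cadence=cadence,
    )
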