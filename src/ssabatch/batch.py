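"""Coarse-grained ensemble execution.

N independent realizations of one model, realization r driven by the
substream (seed, r).  The ensemble is split into chunks by a
:class:`StreamPlan`; a background writer thread drains finished chunks so
simulation of chunk k+1 overlaps the writing of chunk k, while the output —
ordered by realization id, then step — stays byte-identical to a sequential
single-chunk run.  Ensemble state snapshots use the species-major layout
(for each species, the N realization values contiguous).
"""

from __future__ import annotations

import hashlib
import json
import queue
import threading
from dataclasses import dataclass

import numpy as np

from .direct import RNGStream, SimState, TimeCourse, run_trajectory
from .model import ModelSpec, crs_from_model, require_valid
from .sinks import MemorySink, SinkWriteError

__all__ = [
    "StreamPlan",
    "BatchState",
    "init_batch",
    "simulate_batch_state",
    "ensemble_layout_check",
    "run_batch",
    "overlap_stream",
    "model_digest",
]


@dataclass(frozen=True)
class StreamPlan:
    """Split of the ensemble into n_ways contiguous chunks."""

    n_ways: int = 1

    def __post_init__(self):
        if self.n_ways < 1:
            raise ValueError("n_ways must be >= 1")

    def chunk_ranges(self, n_realizations: int) -> list[tuple[int, int]]:
        """Contiguous [lo, hi) ranges partitioning [0, N), near-equal sizes."""
        bounds = np.linspace(0, n_realizations, self.n_ways + 1).astype(int)
        return [
            (int(bounds[i]), int(bounds[i + 1]))
            for i in range(self.n_ways)
            if bounds[i + 1] > bounds[i]
        ]


@dataclass
class BatchState:
    """Ensemble state, species-major: counts[s, r] is species s in realization r."""

    counts: np.ndarray  # (m_species, N)
    t: np.ndarray  # (N,)
    step: np.ndarray  # (N,)
    active: np.ndarray  # (N,) bool

    @property
    def n_realizations(self) -> int:
        return self.counts.shape[1]

    def slice_state(self, r: int) -> SimState:
        return SimState(self.counts[:, r].copy(), float(self.t[r]), int(self.step[r]))


def init_batch(model: ModelSpec, n_realizations: int) -> BatchState:
    require_valid(model)
    init = np.asarray(model.initial_counts, dtype=np.int64)
    return BatchState(
        counts=np.repeat(init[:, None], n_realizations, axis=1),
        t=np.zeros(n_realizations),
        step=np.zeros(n_realizations, dtype=np.int64),
        active=np.ones(n_realizations, dtype=bool),
    )


def simulate_batch_state(
    model: ModelSpec, n_realizations: int, seed: int, n_steps: int
) -> BatchState:
    """Advance every realization n_steps (substream r per realization) and
    pack the final states species-major."""
    crs = crs_from_model(model)
    batch = init_batch(model, n_realizations)
    for r in range(n_realizations):
        tc = run_trajectory(
            model, crs, RNGStream(seed, r), max_steps=n_steps, cadence=max(n_steps, 1)
        )
        final = tc.final_state()
        batch.counts[:, r] = final.counts
        batch.t[r] = final.t
        batch.step[r] = final.step
        batch.active[r] = not tc.absorbed
    return batch


def ensemble_layout_check(
    batch: BatchState, reference_states: list[SimState] | None = None
) -> dict:
    """Verify the species-major layout contract.

    Checks that the counts array is species-major and C-contiguous
    (realization index fastest-varying) and, when reference per-realization
    states are given, that slicing realization r out of the batch reproduces
    them exactly.
    """
    report: dict = {
        "n_realizations": batch.n_realizations,
        "m_species": batch.counts.shape[0],
        "species_major": batch.counts.ndim == 2,
        "c_contiguous": bool(batch.counts.flags["C_CONTIGUOUS"]),
        "realization_stride_elements": batch.counts.strides[1] // batch.counts.itemsize,
        "mismatches": [],
    }
    if reference_states is not None:
        for r, ref in enumerate(reference_states):
            got = batch.slice_state(r)
            if (
                not np.array_equal(got.counts, ref.counts)
                or got.t != ref.t
                or got.step != ref.step
            ):
                report["mismatches"].append(r)
    report["ok"] = (
        report["species_major"]
        and report["c_contiguous"]
        and report["realization_stride_elements"] == 1
        and not report["mismatches"]
    )
    return report


def model_digest(model: ModelSpec) -> str:
    """Stable content hash of a model, for reproducibility manifests."""
    payload = {
        "species": list(model.species),
        "initial_counts": list(model.initial_counts),
        "reactions": [
            {
                "id": r.id,
                "c": r.rate_constant,
                "reactants": [list(x) for x in r.reactants],
                "products": [list(x) for x in r.products],
            }
            for r in model.reactions
        ],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_batch(
    model: ModelSpec,
    n_realizations: int,
    seed: int,
    *,
    max_steps: int | None = None,
    max_time: float | None = None,
    cadence: int = 1,
    plan: StreamPlan | None = None,
    sink=None,
    combinatorial: bool = True,
) -> dict:
    """Run the ensemble and deliver all trajectories to the sink.

    Realization r uses RNGStream(seed, r), so results are bitwise independent
    of the number of chunks and of writer scheduling.  Returns the run
    manifest.  A sink failure aborts with :class:`SinkWriteError` carrying a
    partial-output manifest.
    """
    require_valid(model)
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    crs = crs_from_model(model)
    plan = plan or StreamPlan(1)
    sink = sink if sink is not None else MemorySink()

    manifest = {
        "model_digest": model_digest(model),
        "seed": seed,
        "n_realizations": n_realizations,
        "max_steps": max_steps,
        "max_time": max_time,
        "cadence": cadence,
        "n_ways": plan.n_ways,
        "combinatorial": combinatorial,
    }
    sink.open(model.species, manifest)

    written: list[int] = []
    write_error: list[Exception] = []
    done = object()
    # maxsize 1: at most one finished chunk queued, so simulation runs at
    # most one chunk ahead of writing -- the overlap contract without
    # unbounded memory growth.
    q: queue.Queue = queue.Queue(maxsize=1)

    def writer():
        while True:
            item = q.get()
            if item is done:
                return
            for r, tc in item:
                if not write_error:
                    try:
                        sink.write(r, tc)
                        written.append(r)
                    except Exception as exc:  # noqa: BLE001 - reported via manifest
                        write_error.append(exc)

    thread = threading.Thread(target=writer, name="ssabatch-writer", daemon=True)
    thread.start()
    try:
        for lo, hi in plan.chunk_ranges(n_realizations):
            chunk = [
                (
                    r,
                    run_trajectory(
                        model,
                        crs,
                        RNGStream(seed, r),
                        max_steps=max_steps,
                        max_time=max_time,
                        cadence=cadence,
                        combinatorial=combinatorial,
                    ),
                )
                for r in range(lo, hi)
            ]
            q.put(chunk)
            if write_error:
                break
    finally:
        q.put(done)
        thread.join()

    if write_error:
        partial = dict(manifest)
        partial["realizations_written"] = len(written)
        partial["aborted"] = True
        try:
            partial.update(sink.close())
        except Exception:
            pass
        raise SinkWriteError(f"sink write failed: {write_error[0]}", partial)

    manifest.update(sink.close())
    manifest["aborted"] = False
    return manifest


def overlap_stream(chunks, sink, species=(), manifest: dict | None = None) -> dict:
    """Assemble completed chunks into the sink, ordered by realization id.

    ``chunks`` is an iterable of lists of (realization_id, TimeCourse); they
    may arrive in any completion order.  Output equals the sequential-write
    oracle: realization id ascending.
    """
    sink.open(species, manifest or {})
    records: list[tuple[int, TimeCourse]] = []
    for chunk in chunks:
        records.extend(chunk)
    ids = [r for r, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate realization ids across chunks")
    for r, tc in sorted(records, key=lambda x: x[0]):
        sink.write(r, tc)
    out = sink.close()
    out["realizations_written"] = len(records)
    return out
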