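"""Result sinks: where recorded time courses go.

All sinks receive whole trajectories ordered by realization id and promise
that the bytes on disk are independent of how the ensemble was chunked or
buffered.  CSV output is written through a :class:`RecordBuffer` that stages
rows and flushes them in blocks; buffered and unbuffered output are
byte-identical, the buffer only batches I/O.
"""

from __future__ import annotations

import gzip
import json
import os
from typing import IO

import h5py
import numpy as np

from .direct import TimeCourse

__all__ = [
    "RecordBuffer",
    "MemorySink",
    "CSVDirSink",
    "GzipCSVSink",
    "HDF5Sink",
    "SinkWriteError",
    "make_sink",
]


class SinkWriteError(RuntimeError):
    """A sink failed mid-run; ``manifest`` describes what was written."""

    def __init__(self, message: str, manifest: dict):
        super().__init__(message)
        self.manifest = manifest


class RecordBuffer:
    """Stages formatted records and flushes them to a stream in blocks.

    ``capacity`` is the number of records held before a flush.  Concatenated
    flushed output equals what unbuffered writes would produce.
    """

    def __init__(self, stream: IO[bytes], capacity: int = 1024):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._stream = stream
        self._staged: list[bytes] = []
        self.flushes = 0

    def stage(self, record: bytes) -> None:
        self._staged.append(record)
        if len(self._staged) >= self.capacity:
            self.flush()

    def flush(self) -> None:
        if self._staged:
            self._stream.write(b"".join(self._staged))
            self._staged.clear()
            self.flushes += 1


def _format_rows(tc: TimeCourse, prefix: str = "") -> list[bytes]:
    rows = []
    for i in range(tc.n_records):
        cells = ",".join(str(int(x)) for x in tc.counts[i])
        rows.append(f"{prefix}{int(tc.steps[i])},{float(tc.times[i])!r},{cells}\n".encode())
    return rows


class MemorySink:
    """Keeps trajectories in a dict keyed by realization id."""

    def __init__(self):
        self.trajectories: dict[int, TimeCourse] = {}
        self.species: tuple[str, ...] = ()

    def open(self, species, manifest) -> None:
        self.species = tuple(species)
        self.trajectories.clear()

    def write(self, realization: int, tc: TimeCourse) -> None:
        self.trajectories[realization] = tc

    def close(self) -> dict:
        return {
            "sink": "memory",
            "realizations_written": len(self.trajectories),
        }


class CSVDirSink:
    """One CSV per realization (``traj_<id>.csv``: step, time, species...)."""

    def __init__(self, directory: str | os.PathLike, buffer_capacity: int = 1024):
        self.directory = os.fspath(directory)
        self.buffer_capacity = buffer_capacity
        self._header = b""
        self._written = 0

    def open(self, species, manifest) -> None:
        os.makedirs(self.directory, exist_ok=True)
        self._header = ("step,time," + ",".join(species) + "\n").encode()
        self._written = 0

    def write(self, realization: int, tc: TimeCourse) -> None:
        path = os.path.join(self.directory, f"traj_{realization:06d}.csv")
        with open(path, "wb") as fh:
            buf = RecordBuffer(fh, self.buffer_capacity)
            buf.stage(self._header)
            for row in _format_rows(tc):
                buf.stage(row)
            buf.flush()
        self._written += 1

    def close(self) -> dict:
        return {
            "sink": "csv-dir",
            "directory": self.directory,
            "realizations_written": self._written,
        }


class GzipCSVSink:
    """Single streaming gzip CSV with a leading realization column.

    The gzip header is written with mtime=0 and no filename so identical
    ensembles produce identical bytes.
    """

    def __init__(self, path: str | os.PathLike, buffer_capacity: int = 1024):
        self.path = os.fspath(path)
        self.buffer_capacity = buffer_capacity
        self._gz: gzip.GzipFile | None = None
        self._buf: RecordBuffer | None = None
        self._written = 0

    def open(self, species, manifest) -> None:
        raw = open(self.path, "wb")
        self._gz = gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
        self._buf = RecordBuffer(self._gz, self.buffer_capacity)
        self._buf.stage(("realization,step,time," + ",".join(species) + "\n").encode())
        self._written = 0

    def write(self, realization: int, tc: TimeCourse) -> None:
        assert self._buf is not None
        for row in _format_rows(tc, prefix=f"{realization},"):
            self._buf.stage(row)
        self._written += 1

    def close(self) -> dict:
        if self._gz is not None:
            assert self._buf is not None
            self._buf.flush()
            raw = self._gz.fileobj
            self._gz.close()
            raw.close()
            self._gz = None
        return {
            "sink": "gzip-csv",
            "path": self.path,
            "realizations_written": self._written,
        }


class HDF5Sink:
    """One HDF5 container: /trajectories/r<id> groups plus a JSON manifest."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._file: h5py.File | None = None
        self._written = 0

    def open(self, species, manifest) -> None:
        self._file = h5py.File(self.path, "w")
        self._file.attrs["species"] = json.dumps(list(species))
        self._file.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        self._file.create_group("trajectories")
        self._written = 0

    def write(self, realization: int, tc: TimeCourse) -> None:
        assert self._file is not None
        g = self._file["trajectories"].create_group(f"r{realization:06d}")
        g.create_dataset("steps", data=tc.steps)
        g.create_dataset("times", data=tc.times)
        g.create_dataset("counts", data=tc.counts.astype(np.int32))
        g.attrs["absorbed"] = bool(tc.absorbed)
        g.attrs["cadence"] = int(tc.cadence)
        self._written += 1

    def close(self) -> dict:
        if self._file is not None:
            self._file.close()
            self._file = None
        return {
            "sink": "hdf5",
            "path": self.path,
            "realizations_written": self._written,
        }


def make_sink(spec: str, buffer_capacity: int = 1024):
    """Build a sink from ``kind:path`` (csv-dir, gzip-csv, hdf5, memory)."""
    kind, _, path = spec.partition(":")
    if kind == "memory":
        return MemorySink()
    if not path:
        raise ValueError(f"sink spec {spec!r} needs a path (kind:path)")
    if kind == "csv-dir":
        return CSVDirSink(path, buffer_capacity)
    if kind == "gzip-csv":
        return GzipCSVSink(path, buffer_capacity)
    if kind == "hdf5":
        return HDF5Sink(path)
    raise ValueError(f"unknown sink kind {kind!r}")
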