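"""Redundant 24:64 switch-matrix model, configuration logs and demultiplexing.

The on-paddle multiplexer routes 24 bidirectional lead conductors ("inputs")
to 64 outputs, of which the first 60 are electrode contacts.  Each output
block owns >= 4 candidate input switches, so up to three broken conductors
can be tolerated while still rastering the whole array.  Recordings are made
on the 24 inputs; the time-stamped configuration log says which electrode
each input was wired to, allowing the multiplexed recording to be split into
a sparse electrode-indexed matrix with an explicit validity mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MuxConfigError",
    "SwitchMatrix",
    "MuxConfigLog",
    "DemuxedRecording",
    "default_switch_matrix",
    "validate_config",
    "reachability_under_faults",
    "demultiplex",
    "multiplex",
]

N_ELECTRODES = 60


class MuxConfigError(ValueError):
    """Raised for switch requests the matrix cannot realize."""


@dataclass(frozen=True)
class SwitchMatrix:
    """Candidate input sets per output and basic matrix dimensions."""

    n_inputs: int = 24
    n_outputs: int = 64
    blocks: tuple[frozenset[int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.blocks) != self.n_outputs:
            raise ValueError("one candidate block per output required")
        for o, blk in enumerate(self.blocks):
            if len(blk) < 4:
                raise ValueError(f"output {o} has fewer than 4 candidate inputs")
            if any(i < 0 or i >= self.n_inputs for i in blk):
                raise ValueError(f"output {o} references unknown inputs")


def default_switch_matrix(n_inputs: int = 24, n_outputs: int = 64) -> SwitchMatrix:
    """Round-robin candidate assignment: output ``o`` may use inputs
    ``{o, o+1, o+2, o+3} mod n_inputs``.

    The proprietary assignment is unpublished; this pattern satisfies the
    4-way redundancy and lets a raster of all outputs survive any 3 broken
    conductors.
    """
    blocks = tuple(
        frozenset((o + k) % n_inputs for k in range(4)) for o in range(n_outputs)
    )
    return SwitchMatrix(n_inputs, n_outputs, blocks)


def validate_config(
    matrix: SwitchMatrix, requested: set[tuple[int, int]] | frozenset[tuple[int, int]]
) -> frozenset[tuple[int, int]]:
    """Validate a set of ``(input, output)`` switch closures.

    A request is accepted iff every switch exists in its output's candidate
    block and no output is driven by two inputs at once.  One input fanning
    out to several outputs is legal (anodic ties).
    """
    closed = frozenset((int(i), int(o)) for i, o in requested)
    driven: dict[int, int] = {}
    for i, o in sorted(closed):
        if not (0 <= i < matrix.n_inputs and 0 <= o < matrix.n_outputs):
            raise MuxConfigError(f"switch ({i}, {o}) references unknown lines")
        if i not in matrix.blocks[o]:
            raise MuxConfigError(f"input {i} is not a candidate for output {o}")
        if o in driven:
            raise MuxConfigError(f"output {o} driven by inputs {driven[o]} and {i}")
        driven[o] = i
    return closed


def reachability_under_faults(
    matrix: SwitchMatrix, broken_conductors: set[int] | frozenset[int]
) -> tuple[np.ndarray, dict[str, int]]:
    """Which outputs remain reachable when some input conductors are broken.

    Returns a boolean flag per output and a summary with reachable /
    unreachable counts.
    """
    broken = frozenset(int(b) for b in broken_conductors)
    if any(b < 0 or b >= matrix.n_inputs for b in broken):
        raise ValueError("broken set references unknown inputs")
    flags = np.array([bool(blk - broken) for blk in matrix.blocks])
    summary = {
        "n_reachable": int(flags.sum()),
        "n_unreachable": int((~flags).sum()),
        "n_broken": len(broken),
    }
    return flags, summary


@dataclass(frozen=True)
class MuxConfigLog:
    """Ordered ``(timestamp, closed-switch set)`` entries.

    Timestamps are 0-based sample indices; each entry's configuration holds
    over the half-open span up to the next entry.  The first entry must be
    at or before the start of the recording.
    """

    entries: tuple[tuple[int, frozenset[tuple[int, int]]], ...] = field(default=())

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("log timestamps must be strictly increasing")

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for t, closed in self.entries:
                fh.write(json.dumps({"t": int(t), "closed": sorted(map(list, closed))}) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "MuxConfigLog":
        entries = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                entries.append((int(rec["t"]), frozenset((int(i), int(o)) for i, o in rec["closed"])))
        return cls(tuple(entries))


@dataclass
class DemuxedRecording:
    """Electrode-indexed sparse recording: data plus validity mask.

    A sample is valid for an electrode iff some input was routed to it at
    that sample; unrouted spans are masked, not zero.
    """

    data: np.ndarray  # (n_electrodes, n_samples)
    mask: np.ndarray  # bool, same shape

    @property
    def valid_fraction(self) -> np.ndarray:
        return self.mask.mean(axis=1)


def _segments(log: MuxConfigLog, n_samples: int):
    ts = [t for t, _ in log.entries]
    if not ts:
        raise ValueError("empty configuration log")
    if ts[0] > 0:
        raise ValueError("first log entry must be at or before recording start")
    if any(t > n_samples for t in ts):
        raise ValueError("log timestamp beyond recording length")
    bounds = ts + [n_samples]
    for (t, closed), end in zip(log.entries, bounds[1:]):
        yield max(t, 0), end, closed


def demultiplex(
    recording: np.ndarray,
    log: MuxConfigLog,
    matrix: SwitchMatrix | None = None,
    n_electrodes: int = N_ELECTRODES,
) -> DemuxedRecording:
    """Split a multiplexed ``(n_inputs, n)`` recording into electrode rows.

    Each log entry is validated against the matrix; within its span, the
    samples of an input routed to electrode ``o`` (< ``n_electrodes``) are
    copied into row ``o``.  Outputs beyond the electrode count exist in the
    matrix but carry no tissue contact and are ignored.
    """
    matrix = matrix or default_switch_matrix()
    rec = np.asarray(recording, dtype=float)
    if rec.ndim != 2 or rec.shape[0] != matrix.n_inputs:
        raise ValueError(f"recording must be ({matrix.n_inputs}, n)")
    n = rec.shape[1]
    data = np.zeros((n_electrodes, n))
    mask = np.zeros((n_electrodes, n), dtype=bool)
    for start, end, closed in _segments(log, n):
        validate_config(matrix, closed)
        for i, o in closed:
            if o < n_electrodes:
                data[o, start:end] = rec[i, start:end]
                mask[o, start:end] = True
    return DemuxedRecording(data, mask)


def multiplex(
    truth: np.ndarray,
    log: MuxConfigLog,
    matrix: SwitchMatrix | None = None,
) -> np.ndarray:
    """Route electrode-frame signals onto the 24 input conductors.

    Inverse of :func:`demultiplex` for recording-style (injective
    input -> electrode) configurations; used to build synthetic multiplexed
    recordings.  An input wired to several outputs would superpose signals
    and is rejected here.
    """
    matrix = matrix or default_switch_matrix()
    truth = np.asarray(truth, dtype=float)
    n = truth.shape[1]
    rec = np.zeros((matrix.n_inputs, n))
    for start, end, closed in _segments(log, n):
        validate_config(matrix, closed)
        used: set[int] = set()
        for i, o in closed:
            if i in used:
                raise MuxConfigError(f"input {i} fans out; recording route must be injective")
            used.add(i)
            if o < truth.shape[0]:
                rec[i, start:end] = truth[o, start:end]
    return rec
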