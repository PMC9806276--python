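"""Serial frame protocol for the valve controller, plus actuation limits.

Wire format (one frame per camera per video frame)::

    [0xAA] [n_valves] [payload: ceil(n/8) bytes, LSB-first] [checksum]

Bit 0 of payload byte 0 is valve 0 (leftmost nozzle).  The checksum is the
XOR of the ``n_valves`` byte and every payload byte.  The decoder reports
distinct error codes and a consuming controller holds the previous valve
state for up to 3 bad frames before failing safe to all-closed.

Solenoid valves have a maximum complete open/close cycling frequency
(10 Hz for the reference hardware) and small weeds need a base opening
time, so the raw per-frame requests are post-processed into a rate-limited
:class:`ValveTimeline` that only ever extends or merges open intervals —
sprayed coverage is always a superset of what was requested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

from .grille import DecisionVector

START_BYTE = 0xAA


class ProtocolError(ValueError):
    pass


class DecodeError(enum.Enum):
    BAD_START = "bad_start_byte"
    BAD_LENGTH = "length_mismatch"
    BAD_CHECKSUM = "checksum_failure"


def encode_frame(v: DecisionVector | Sequence[int]) -> bytes:
    """Serialize a decision vector into one wire frame.

    Frame length is ``3 + ceil(n/8)`` bytes for ``1 <= n <= 255`` valves.
    """
    bits = tuple(v)
    n = len(bits)
    if n == 0:
        raise ProtocolError("cannot encode an empty decision vector")
    if n > 255:
        raise ProtocolError(f"at most 255 valves per frame, got {n}")
    payload = bytearray(math.ceil(n / 8))
    for i, b in enumerate(bits):
        if b:
            payload[i // 8] |= 1 << (i % 8)
    checksum = n
    for byte in payload:
        checksum ^= byte
    return bytes([START_BYTE, n, *payload, checksum])


def decode_frame(frame: bytes) -> tuple[DecisionVector | None, DecodeError | None]:
    """Parse one wire frame; returns (vector, None) or (None, error code)."""
    if len(frame) < 1 or frame[0] != START_BYTE:
        return None, DecodeError.BAD_START
    if len(frame) < 3:
        return None, DecodeError.BAD_LENGTH
    n = frame[1]
    if n == 0 or len(frame) != 3 + math.ceil(n / 8):
        return None, DecodeError.BAD_LENGTH
    payload = frame[2:-1]
    checksum = n
    for byte in payload:
        checksum ^= byte
    if checksum != frame[-1]:
        return None, DecodeError.BAD_CHECKSUM
    bits = tuple((payload[i // 8] >> (i % 8)) & 1 for i in range(n))
    return DecisionVector(bits), None


class FrameConsumer:
    """Fail-safe frame consumer emulating the valve controller.

    On a decode error the previous valve state is held for up to
    ``hold_frames`` consecutive bad frames, then the state falls back to
    all-closed.
    """

    def __init__(self, n_valves: int, hold_frames: int = 3) -> None:
        self.n_valves = n_valves
        self.hold_frames = hold_frames
        self._bad_streak = 0
        self.state = DecisionVector((0,) * n_valves)

    def feed(self, frame: bytes) -> DecisionVector:
        vector, err = decode_frame(frame)
        if err is None:
            assert vector is not None
            self._bad_streak = 0
            self.state = vector
        else:
            self._bad_streak += 1
            if self._bad_streak > self.hold_frames:
                self.state = DecisionVector((0,) * self.n_valves)
        return self.state


@dataclass
class ValveTimeline:
    """Per-valve open intervals ``[t_open, t_close)`` in seconds."""

    intervals: list[list[tuple[float, float]]] = field(default_factory=list)

    @property
    def n_valves(self) -> int:
        return len(self.intervals)

    def is_open(self, valve: int, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals[valve])

    def cycles_per_second(self, valve: int) -> float:
        """Worst-case number of open-interval starts in any 1 s sliding window."""
        starts = [a for a, _ in self.intervals[valve]]
        if not starts:
            return 0.0
        worst = 1
        for i, s in enumerate(starts):
            j = i
            while j + 1 < len(starts) and starts[j + 1] < s + 1.0:
                j += 1
            worst = max(worst, j - i + 1)
        return float(worst)


def _frames_to_intervals(column: Sequence[int], dt: float) -> list[tuple[float, float]]:
    """Merge consecutive 1-frames into raw open intervals."""
    out: list[tuple[float, float]] = []
    start = None
    for k, bit in enumerate(column):
        if bit and start is None:
            start = k * dt
        elif not bit and start is not None:
            out.append((start, k * dt))
            start = None
    if start is not None:
        out.append((start, len(column) * dt))
    return out


def apply_rate_limit(requests: Sequence[DecisionVector | Sequence[int]], fps: float,
                     max_freq: float = 10.0, min_open_s: float = 0.1) -> ValveTimeline:
    """Turn per-frame open requests into a hardware-feasible valve timeline.

    Each frame holds its request for ``1/fps`` seconds.  Per valve:

    1. consecutive open frames merge into raw open intervals;
    2. every interval is extended to last at least ``min_open_s``;
    3. intervals whose open edges would cycle faster than ``max_freq``
       complete cycles per second are merged (the valve stays open through
       the short gap).

    Closing is never advanced, so coverage is a superset of the request.
    """
    if max_freq <= 0:
        raise ProtocolError("max_freq must be positive")
    if fps <= 0:
        raise ProtocolError("fps must be positive")
    if not requests:
        return ValveTimeline([])
    n_valves = len(requests[0])
    dt = 1.0 / fps
    min_period = 1.0 / max_freq
    timeline = ValveTimeline([[] for _ in range(n_valves)])
    for valve in range(n_valves):
        column = [int(tuple(v)[valve]) for v in requests]
        raw = _frames_to_intervals(column, dt)
        extended = [(a, max(b, a + min_open_s)) for a, b in raw]
        merged: list[tuple[float, float]] = []
        for a, b in extended:
            if merged and (a < merged[-1][1] or a - merged[-1][0] < min_period):
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        timeline.intervals[valve] = merged
    return timeline
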