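"""Simulated event camera (DVS) and spike encoders.

A dynamic vision sensor emits per-pixel polarized address events when the
intensity change since the last event at that pixel crosses a threshold,
instead of transmitting frames.  Here intensity is linear in [0, 1], each
pixel keeps a reference intensity that resets to the current value whenever
it emits, and at most one event per pixel is emitted per frame.

Two encoders turn events into network input:

* reaching — one visual neuron per pixel (polarity ignored) plus one axis
  feature neuron per row and per column that fires for every event in its
  row/column, so each event yields exactly three input spikes;
* lane following — the 128x32 sensor is tiled into non-overlapping 8x8
  windows, one neuron each, firing at a rate proportional to the event count
  in its window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityFrame",
    "AddressEvent",
    "dvs_frame_diff",
    "DVSSimulator",
    "encode_reaching_spikes",
    "encode_lane_rates",
    "events_to_csv",
]

ON = 1
OFF = -1


@dataclass
class IntensityFrame:
    """A rendered grayscale frame; ``pixels[row, col]`` in [0, 1]."""

    pixels: np.ndarray
    t: float = 0.0

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class AddressEvent:
    """One polarized event; 0-based pixel coordinates, origin top-left."""

    x: int
    y: int
    polarity: int  # ON (+1) or OFF (-1)
    t: float = 0.0


def dvs_frame_diff(prev, curr, threshold: float, t: float = 0.0) -> list[AddressEvent]:
    """Events between a reference frame and the current frame.

    Emits one ON event where ``curr - prev > threshold``, one OFF event where
    ``prev - curr > threshold``.  ``prev`` acts as the per-pixel reference
    memory; callers maintaining sensor state should reset the reference to
    ``curr`` at exactly the emitting pixels (see :class:`DVSSimulator`).
    """
    p = prev.pixels if isinstance(prev, IntensityFrame) else np.asarray(prev)
    c = curr.pixels if isinstance(curr, IntensityFrame) else np.asarray(curr)
    if p.shape != c.shape:
        raise ValueError(f"frame shape mismatch: {p.shape} vs {c.shape}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = c - p
    events: list[AddressEvent] = []
    for pol, mask in ((ON, diff > threshold), (OFF, diff < -threshold)):
        rows, cols = np.nonzero(mask)
        events.extend(AddressEvent(x=int(x), y=int(y), polarity=pol, t=t)
                      for y, x in zip(rows, cols))
    return events


class DVSSimulator:
    """Stateful sensor: per-pixel reference memory across an arbitrary frame stream.

    The reference is initialized from the first frame (no burst of spurious
    events at startup) and reset to the current intensity only at pixels that
    emitted, so slow drifts accumulate until they cross the threshold.
    """

    def __init__(self, shape: tuple[int, int], threshold: float):
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        self.threshold = threshold
        self.reference = np.zeros(shape)
        self._primed = False

    def step(self, frame, t: float = 0.0) -> list[AddressEvent]:
        pixels = frame.pixels if isinstance(frame, IntensityFrame) else np.asarray(frame)
        if not self._primed:
            self.reference = pixels.copy()
            self._primed = True
            return []
        events = dvs_frame_diff(self.reference, pixels, self.threshold, t=t)
        for ev in events:
            self.reference[ev.y, ev.x] = pixels[ev.y, ev.x]
        return events

    def step_masks(self, pixels: np.ndarray) -> np.ndarray:
        """Vectorized variant returning the boolean event mask (polarity merged)."""
        if not self._primed:
            self.reference = pixels.copy()
            self._primed = True
            return np.zeros(pixels.shape, dtype=bool)
        mask = np.abs(pixels - self.reference) > self.threshold
        self.reference[mask] = pixels[mask]
        return mask


def encode_reaching_spikes(events: list[AddressEvent], pixels: int = 16) -> np.ndarray:
    """Per-input-neuron spike counts for the reaching encoder.

    Input ordering: ``pixels*pixels`` visual neurons (row-major), then
    ``pixels`` row-axis neurons, then ``pixels`` column-axis neurons.  Each
    event (polarity ignored) spikes its pixel's visual neuron, its row-axis
    neuron and its column-axis neuron; axis neurons therefore fire once per
    event in the row/column they cover and may spike several times per step.
    """
    counts = np.zeros(pixels * pixels + 2 * pixels, dtype=np.int64)
    for ev in events:
        if not (0 <= ev.x < pixels and 0 <= ev.y < pixels):
            raise ValueError(f"event at ({ev.x}, {ev.y}) outside {pixels}x{pixels} sensor")
        counts[ev.y * pixels + ev.x] += 1
        counts[pixels * pixels + ev.y] += 1  # row-axis neuron
        counts[pixels * pixels + pixels + ev.x] += 1  # column-axis neuron
    return counts


def encode_lane_rates(events: list[AddressEvent], gain: float, width: int = 128,
                      height: int = 32, window: int = 8, rho_max: float = 500.0) -> np.ndarray:
    """Per-neuron firing rates (Hz) for the windowed lane encoder.

    The ``width x height`` sensor is tiled into non-overlapping
    ``window x window`` blocks, one neuron per block (row-major over blocks);
    each neuron's rate is ``gain`` times the event count in its block, capped
    at ``rho_max``.
    """
    nx, ny = width // window, height // window
    counts = np.zeros((ny, nx), dtype=np.int64)
    for ev in events:
        if not (0 <= ev.x < width and 0 <= ev.y < height):
            raise ValueError(f"event at ({ev.x}, {ev.y}) outside {width}x{height} sensor")
        counts[ev.y // window, ev.x // window] += 1
    return np.minimum(gain * counts.ravel().astype(float), rho_max)


def events_to_csv(events: list[AddressEvent]) -> str:
    """Serialize events as a simple AER text stream (t, x, y, polarity)."""
    lines = ["t,x,y,polarity"]
    lines += [f"{ev.t},{ev.x},{ev.y},{ev.polarity}" for ev in events]
    return "\n".join(lines) + "\n"
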