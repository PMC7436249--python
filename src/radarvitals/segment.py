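"""Direction-based segmentation of a demodulated displacement record.

Back-and-forth body motion violates the constant-velocity assumption the
RBM canceller relies on, so a long record is cut into contiguous parts
within which the body moves in a single direction. The direction at each
sample is the sign of a moving-average-smoothed derivative — smoothing
over about a second suppresses the mm-scale vital ripple so that only the
cm-scale trend decides the sign. Runs shorter than ``min_duration`` are
merged into their neighbour (hysteresis against spurious flips), and runs
longer than ``max_duration`` are split into near-equal pieces so every
part is short enough for the short-window rate estimator (3-5 s windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import DisplacementTrace

__all__ = ["Segment", "SegmentationConfig", "segment_by_direction"]


@dataclass(frozen=True)
class Segment:
    """A contiguous, single-direction part of the record.

    Indices are 1-based inclusive; ``duration = (end - start) * dt``.
    """

    start_index: int
    end_index: int
    direction: int  # +1 moving away from the radar, -1 toward it
    duration: float  # s

    def slice(self) -> slice:
        """0-based slice covering the segment's samples."""
        return slice(self.start_index - 1, self.end_index)


@dataclass(frozen=True)
class SegmentationConfig:
    smooth_window: float = 1.0  # s, moving-average width for the derivative
    min_duration: float = 2.0  # s, shorter runs are merged away
    max_duration: float = 3.5  # s, longer runs are split

    def __post_init__(self) -> None:
        if not (0 < self.min_duration <= self.max_duration):
            raise ValueError(
                f"need 0 < min_duration <= max_duration, got "
                f"({self.min_duration}, {self.max_duration})"
            )
        if self.smooth_window <= 0:
            raise ValueError(f"smooth_window must be positive, got {self.smooth_window}")


def _smoothed_derivative(x: np.ndarray, fs: float, smooth_window: float) -> np.ndarray:
    d = np.gradient(x) * fs
    w = max(1, int(round(smooth_window * fs)))
    if w % 2 == 0:
        w += 1  # odd kernel keeps the smoother symmetric under time reversal
    if w > 1:
        pad = w // 2
        d = np.convolve(np.pad(d, pad, mode="edge"), np.ones(w) / w, mode="valid")
    return d


def _sign_runs(signs: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of constant sign as 0-based (start, end) inclusive pairs."""
    change = np.nonzero(np.diff(signs))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(signs) - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def segment_by_direction(
    trace: DisplacementTrace, cfg: SegmentationConfig | None = None
) -> list[Segment]:
    """Split a record into contiguous single-direction segments.

    Segments tile the record exactly (no gaps or overlaps); each segment's
    direction is the majority sign of the smoothed derivative over it.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    fs = trace.fs
    dt = 1.0 / fs
    n = len(trace)
    if n < cfg.min_duration * fs:
        raise ValueError(
            f"record of {n / fs:.2f} s is shorter than min_duration={cfg.min_duration} s"
        )

    d = _smoothed_derivative(trace.samples, fs, cfg.smooth_window)
    signs = np.sign(d).astype(int)
    # propagate the last decisive sign through flat stretches
    nz = np.nonzero(signs)[0]
    if nz.size == 0:
        signs[:] = 1
    else:
        signs[: nz[0]] = signs[nz[0]]
        for i in range(1, n):
            if signs[i] == 0:
                signs[i] = signs[i - 1]

    runs = _sign_runs(signs)

    # hysteresis: absorb runs shorter than min_duration into a neighbour
    min_samples = cfg.min_duration * fs
    merged = True
    while merged and len(runs) > 1:
        merged = False
        for j, (a, b) in enumerate(runs):
            if (b - a) < min_samples - 1:
                if j > 0:
                    pa, _ = runs[j - 1]
                    runs[j - 1 : j + 1] = [(pa, b)]
                else:
                    _, nb = runs[1]
                    runs[0:2] = [(a, nb)]
                merged = True
                break

    # cap run length for the short-window estimator
    max_samples = max(1, int(round(cfg.max_duration * fs)))
    capped: list[tuple[int, int]] = []
    for a, b in runs:
        length = b - a + 1
        pieces = max(1, int(np.ceil(length / max_samples)))
        bounds = np.linspace(a, b + 1, pieces + 1).round().astype(int)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            capped.append((int(lo), int(hi) - 1))

    segments = []
    for a, b in capped:
        seg_sign = int(np.sign(np.sum(np.sign(d[a : b + 1]))))
        if seg_sign == 0:
            seg_sign = 1
        segments.append(
            Segment(
                start_index=a + 1,
                end_index=b + 1,
                direction=seg_sign,
                duration=(b - a) * dt,
            )
        )
    return segments
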