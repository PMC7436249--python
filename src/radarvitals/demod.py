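"""Extended DACM phase demodulation of quadrature baseband.

The differentiate-and-cross-multiply (DACM) algorithm accumulates the
discrete derivative of ``atan2(Q, I)`` through the cross-product form

    phi(n) = sum_{m=2..n} [ I(m) dQ(m) - dI(m) Q(m) ] / (I(m)^2 + Q(m)^2),

which avoids explicit phase unwrapping as long as per-sample phase
increments stay well below pi. The recovered phase is *relative*: the
constant offset 4*pi*d0/lambda + phi is invisible, so phi(1) := 0 and the
displacement estimate is relative to the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import BasebandFrame, DisplacementTrace, RadarConfig, TimeBase

__all__ = ["PhaseTrace", "dacm_phase", "phase_to_displacement"]

#: Samples with I^2 + Q^2 below this are numerically dead and rejected.
ENVELOPE_FLOOR = 1e-12


@dataclass(frozen=True)
class PhaseTrace:
    """Accumulated relative phase phi(n) in radians; phi(1) = 0."""

    phi: np.ndarray
    timebase: TimeBase

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        if len(phi) != self.timebase.n_samples:
            raise ValueError("phase length does not match timebase")
        if not np.all(np.isfinite(phi)):
            raise ValueError("phase samples must be finite")
        if phi[0] != 0.0:
            raise ValueError("relative phase must start at 0")


def dacm_phase(frame: BasebandFrame, envelope_floor: float = ENVELOPE_FLOOR) -> PhaseTrace:
    """Accumulate the relative Doppler phase from an I/Q frame.

    Raises a ``ValueError`` naming the first 1-based sample index whose
    envelope I^2 + Q^2 falls below ``envelope_floor``.
    """
    I = frame.I
    Q = frame.Q
    if len(I) < 2:
        raise ValueError("DACM needs at least 2 samples")
    env = I**2 + Q**2
    dead = np.nonzero(env < envelope_floor)[0]
    if dead.size:
        raise ValueError(
            f"degenerate baseband sample at index {dead[0] + 1}: "
            f"I^2+Q^2 = {env[dead[0]]:.3e} < {envelope_floor:.1e}"
        )
    # increments for m = 2..N (0-based slice [1:])
    incr = (I[1:] * np.diff(Q) - np.diff(I) * Q[1:]) / env[1:]
    phi = np.concatenate(([0.0], np.cumsum(incr)))
    return PhaseTrace(phi, frame.timebase)


def phase_to_displacement(
    phase: PhaseTrace, cfg: RadarConfig, offset: float = 0.0
) -> DisplacementTrace:
    """Scale phase to line-of-sight displacement: x_hat = phi * lambda / (4 pi).

    ``offset`` (mm) is an optional reporting shift, e.g. -d0 to express the
    trace as distance change from the nominal range; absolute range itself
    is unobservable from relative phase, so the default keeps x_hat(1) = 0.
    """
    lam = cfg.wavelength
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    x = phase.phi * lam / (4.0 * np.pi) + offset
    return DisplacementTrace(x, phase.timebase)
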