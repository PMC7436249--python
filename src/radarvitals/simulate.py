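"""Synthetic chest-wall motion and quadrature baseband generation.

A continuous-wave Doppler radar observes the superposition of three
displacements of the subject's torso along the radar line of sight:

* respiration, modelled as ``m_r * sin(2*pi*f_r*t)`` (mm-scale, < 0.6 Hz),
* heartbeat, modelled as ``m_h * sin(2*pi*f_h*t)`` (sub-mm, 0.8-3 Hz),
* bulk body movement at a constant velocity ``v`` whose sign encodes whether
  the subject moves away from (+) or toward (-) the radar.

The total displacement phase-modulates the reflected carrier; after
quadrature down-conversion the baseband pair is

    I(n) = cos(theta_n),  Q(n) = sin(theta_n),
    theta_n = 4*pi*d0/lambda + 4*pi*x(t_n)/lambda + phi,

with ``lambda`` the carrier wavelength, ``d0`` the nominal subject-radar
distance and ``phi`` a constant residual phase (short-range range
correlation makes oscillator phase noise negligible, so the residual is
treated as constant).

All displacements are in millimetres, time in seconds, rates in Hz.
Sample indexing is 1-based with ``t_1 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_MM_S",
    "RadarConfig",
    "MotionParams",
    "TimeBase",
    "DisplacementTrace",
    "BasebandFrame",
    "synth_motion",
    "synth_back_and_forth",
    "synth_baseband",
    "write_baseband_csv",
    "read_baseband_csv",
]

#: Speed of light in mm/s (displacements and wavelengths are kept in mm).
SPEED_OF_LIGHT_MM_S = 2.99792458e11


@dataclass(frozen=True)
class RadarConfig:
    """Radar front-end parameters.

    Parameters
    ----------
    carrier_freq : float
        Transmit carrier frequency in Hz (e.g. 10e9 for a 10 GHz sensor).
    fs : float
        Baseband sampling rate in Hz.
    d0 : float
        Nominal subject-radar distance in mm. Contributes only a constant
        phase offset; it cannot be recovered from relative phase.
    residual_phase : float
        Constant residual phase ``phi`` in radians.
    """

    carrier_freq: float
    fs: float
    d0: float = 0.0
    residual_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_freq <= 0:
            raise ValueError(f"carrier_freq must be positive, got {self.carrier_freq}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.d0 < 0:
            raise ValueError(f"d0 must be non-negative, got {self.d0}")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in mm, ``lambda = c / f``."""
        return SPEED_OF_LIGHT_MM_S / self.carrier_freq


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the three-component chest-wall motion model.

    ``direction_sign`` is +1 when the body moves away from the radar and
    -1 when it moves toward it. ``phi_r``/``phi_h`` are the initial phases
    of the two oscillations relative to the window start; 0 gives the pure
    sine convention, pi/2 makes the component even (cosine-like) in the
    window, which is the phasing under which the cosine-projection
    spectrum attains its maximum at the component frequency.
    """

    m_r: float = 3.0  # respiration amplitude, mm
    f_r: float = 0.4  # respiration rate, Hz
    m_h: float = 1.0  # heartbeat amplitude, mm
    f_h: float = 1.3  # heartbeat rate, Hz
    v: float = 30.0  # bulk body velocity, mm/s
    direction_sign: int = +1
    phi_r: float = 0.0  # respiration initial phase, rad
    phi_h: float = 0.0  # heartbeat initial phase, rad

    def __post_init__(self) -> None:
        if self.m_r < 0 or self.m_h < 0:
            raise ValueError("amplitudes m_r, m_h must be non-negative")
        if self.f_r <= 0 or self.f_h <= 0:
            raise ValueError("frequencies f_r, f_h must be positive")
        if self.direction_sign not in (+1, -1):
            raise ValueError(f"direction_sign must be +1 or -1, got {self.direction_sign}")


@dataclass(frozen=True)
class TimeBase:
    """Uniform 1-based sample grid: ``t_n = (n - 1) * dt`` for n = 1..N."""

    n_samples: int
    fs: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"need at least 2 samples, got {self.n_samples}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class DisplacementTrace:
    """A displacement series in mm on a shared timebase.

    Holds either ground-truth motion x(t) or a demodulated estimate x_hat(n).
    """

    samples: np.ndarray
    timebase: TimeBase

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or len(samples) != self.timebase.n_samples:
            raise ValueError(
                f"samples length {samples.shape} does not match timebase "
                f"N={self.timebase.n_samples}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("displacement samples must be finite")

    @property
    def fs(self) -> float:
        return self.timebase.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BasebandFrame:
    """Paired I/Q baseband samples on a shared timebase."""

    I: np.ndarray
    Q: np.ndarray
    timebase: TimeBase

    def __post_init__(self) -> None:
        I = np.asarray(self.I, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "Q", Q)
        if len(I) != len(Q) or len(I) != self.timebase.n_samples:
            raise ValueError(
                f"I ({len(I)}) and Q ({len(Q)}) must both match timebase "
                f"N={self.timebase.n_samples}"
            )

    @property
    def fs(self) -> float:
        return self.timebase.fs

    def __len__(self) -> int:
        return len(self.I)


def synth_motion(params: MotionParams, tb: TimeBase) -> DisplacementTrace:
    """Generate the three-component ground-truth displacement.

    x(t) = m_r sin(2 pi f_r t) + m_h sin(2 pi f_h t) + s * v * t,

    with s = ``direction_sign``. Frequencies at or above the Nyquist rate
    are rejected since the sampled sinusoid would alias.
    """
    nyquist = tb.fs / 2.0
    if params.f_r >= nyquist or params.f_h >= nyquist:
        raise ValueError(
            f"f_r={params.f_r} Hz and f_h={params.f_h} Hz must be below "
            f"the Nyquist frequency fs/2 = {nyquist} Hz"
        )
    t = tb.t
    x = (
        params.m_r * np.sin(2.0 * np.pi * params.f_r * t + params.phi_r)
        + params.m_h * np.sin(2.0 * np.pi * params.f_h * t + params.phi_h)
        + params.direction_sign * params.v * t
    )
    return DisplacementTrace(x, tb)


def synth_back_and_forth(
    params: MotionParams, tb: TimeBase, turn_interval: float
) -> DisplacementTrace:
    """Vitals riding a triangle-wave bulk motion that reverses direction.

    The bulk velocity is ``direction_sign * v`` for the first
    ``turn_interval`` seconds, then flips sign every ``turn_interval``
    seconds; the bulk displacement is its continuous integral (a triangle
    wave). The vital oscillations run continuously across turns. Models a
    subject pacing back and forth in front of the radar.
    """
    if turn_interval <= 0:
        raise ValueError(f"turn_interval must be positive, got {turn_interval}")
    nyquist = tb.fs / 2.0
    if params.f_r >= nyquist or params.f_h >= nyquist:
        raise ValueError("vital frequencies must be below the Nyquist frequency")
    t = tb.t
    phase = (t / turn_interval) % 2.0  # 0..2 sawtooth, one turn per interval
    tri = turn_interval * np.where(phase < 1.0, phase, 2.0 - phase)
    x = (
        params.m_r * np.sin(2.0 * np.pi * params.f_r * t + params.phi_r)
        + params.m_h * np.sin(2.0 * np.pi * params.f_h * t + params.phi_h)
        + params.direction_sign * params.v * tri
    )
    return DisplacementTrace(x, tb)


def synth_baseband(
    truth: DisplacementTrace,
    cfg: RadarConfig,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> BasebandFrame:
    """Phase-modulate a displacement trace into a quadrature baseband pair.

    theta(n) = 4 pi d0 / lambda + 4 pi x(n) / lambda + phi;
    I = cos(theta) + eps_I, Q = sin(theta) + eps_Q.

    ``noise_sd`` adds i.i.d. zero-mean Gaussian noise to each channel; the
    default 0 gives the exact unit-circle pair (I^2 + Q^2 = 1). Noise draws
    are reproducible through ``rng`` (a Generator or an integer seed).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if abs(truth.fs - cfg.fs) > 1e-9 * cfg.fs:
        raise ValueError(
            f"displacement fs={truth.fs} Hz does not match radar fs={cfg.fs} Hz"
        )
    lam = cfg.wavelength
    theta = 4.0 * np.pi * cfg.d0 / lam + 4.0 * np.pi * truth.samples / lam + cfg.residual_phase
    I = np.cos(theta)
    Q = np.sin(theta)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        I = I + gen.normal(0.0, noise_sd, size=len(I))
        Q = Q + gen.normal(0.0, noise_sd, size=len(Q))
    return BasebandFrame(I, Q, truth.timebase)


def write_baseband_csv(path, frame: BasebandFrame, cfg: RadarConfig | None = None) -> None:
    """Write a frame as ``t,I,Q`` CSV; radar settings go in ``#`` header lines."""
    import pandas as pd

    df = pd.DataFrame({"t": frame.timebase.t, "I": frame.I, "Q": frame.Q})
    with open(path, "w") as fh:
        fh.write(f"# fs={frame.fs}\n")
        if cfg is not None:
            fh.write(f"# carrier_freq={cfg.carrier_freq}\n")
            fh.write(f"# d0={cfg.d0}\n")
        df.to_csv(fh, index=False)


def read_baseband_csv(path) -> tuple[BasebandFrame, dict]:
    """Read a ``t,I,Q`` CSV written by :func:`write_baseband_csv`.

    Returns the frame and a dict of the ``# key=value`` header metadata.
    The sampling rate comes from the header if present, otherwise from the
    median spacing of the ``t`` column.
    """
    import pandas as pd

    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh)
        except Exception as exc:  # surface pandas' line info verbatim
            raise ValueError(f"malformed baseband CSV {path}: {exc}") from exc
    for col in ("t", "I", "Q"):
        if col not in df.columns:
            raise ValueError(f"baseband CSV {path} missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line_no = int(bad[0]) + 2 + len(meta)  # 1-based, after header lines
            raise ValueError(f"non-numeric value in column {col!r} near line {line_no}")
    fs = meta.get("fs")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    tb = TimeBase(len(df), fs)
    return BasebandFrame(df["I"].to_numpy(), df["Q"].to_numpy(), tb), meta
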