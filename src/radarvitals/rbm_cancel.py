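"""Random-body-movement cancellation: polynomial reference + LMS ANC.

Bulk torso motion (cm-scale, roughly constant velocity over a short
window) buries the mm-scale vital-sign oscillations in the demodulated
displacement. Cancellation proceeds in two steps:

1. A low-order polynomial in the sample index is least-squares fitted to
   the displacement trace; the fitted curve x_f(n) approximates the body
   motion but not the faster vital oscillations.
2. An LMS adaptive filter, driven by x_f(n) as its reference, produces
   y(n) = w^T x_f-window(n), and the residual z(n) = x_hat(n) - y(n) is the
   vital-sign estimate. Weights update as w <- w + 2*mu*x_f(n)*z(n) and the
   record is re-swept until the pass-level mean of z^2 stops decreasing.

The reference is normalized to unit RMS before adaptation so that a single
step size is stable across displacement amplitudes (normalized-LMS style);
reported weights are rescaled back to original reference units, and y and
z are in the original mm units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .simulate import DisplacementTrace

__all__ = [
    "PolyFitModel",
    "ANCConfig",
    "ANCResult",
    "fit_polynomial",
    "lms_anc",
    "cancel_rbm",
]


@dataclass(frozen=True)
class PolyFitModel:
    """Least-squares polynomial model of a displacement trace.

    ``coeffs`` are the coefficients in the numerically conditioned basis
    (sample index mapped affinely onto [-1, 1]); ``fitted`` holds the
    basis-independent fitted values in original coordinates. ``mse`` is the
    mean squared misfit (mm^2).
    """

    order: int
    coeffs: np.ndarray
    mse: float
    fitted: DisplacementTrace


@dataclass(frozen=True)
class ANCConfig:
    """LMS adaptive-noise-canceller settings.

    mu : step size, acting on the unit-RMS-normalized reference. The
        default is small enough that the filter converges to the Wiener
        (minimum mean-square) gain over repeated passes instead of
        tracking the vital oscillations within a pass; tracking would
        cancel part of the signal the residual is meant to keep.
    taps : FIR filter length in samples. The reference is already a
        polynomial approximation of the body motion, so a single adaptive
        gain suffices by default; longer filters are supported.
    passes : maximum number of sweeps over the record; adaptation stops
        earlier once the pass-level mean of z^2 stops improving by more
        than ``tol`` (relative).
    """

    mu: float = 1e-4
    taps: int = 1
    passes: int = 200
    tol: float = 1e-6
    w_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.taps < 1:
            raise ValueError(f"taps must be >= 1, got {self.taps}")
        if self.passes < 1:
            raise ValueError(f"passes must be >= 1, got {self.passes}")


@dataclass(frozen=True)
class ANCResult:
    """Outcome of an ANC run.

    z = desired - y sample-exactly; z is the vital-sign estimate.
    ``w_final`` is expressed in original reference units (a perfectly
    cancelling single tap reads 1.0); ``mse_trajectory`` records the
    adaptation-time mean of z^2 per pass.
    """

    y: DisplacementTrace
    z: DisplacementTrace
    w_final: np.ndarray
    mse_trajectory: np.ndarray
    reference: DisplacementTrace
    passes_used: int = field(default=0)


def fit_polynomial(trace: DisplacementTrace, order: int) -> PolyFitModel:
    """Fit an ``order``-degree polynomial in the sample index to a trace.

    The index variable is centered/rescaled to [-1, 1] internally for
    conditioning (a raw 1..N index basis is numerically hostile at
    N = 500, order 5); fitted values are reported in original coordinates.
    """
    if order < 0:
        raise ValueError(f"order must be non-negative, got {order}")
    n = len(trace)
    if n <= order:
        raise ValueError(f"need more samples ({n}) than the order ({order}) to fit")
    idx = np.arange(1, n + 1, dtype=float)
    poly = Polynomial.fit(idx, trace.samples, deg=order)
    fitted = poly(idx)
    mse = float(np.mean((fitted - trace.samples) ** 2))
    return PolyFitModel(
        order=order,
        coeffs=poly.coef.copy(),
        mse=mse,
        fitted=DisplacementTrace(fitted, trace.timebase),
    )


def _lagged_window(ref: np.ndarray, n: int, taps: int) -> np.ndarray:
    """Reference window [ref(n), ref(n-1), ..., ref(n-taps+1)], zero-padded."""
    lo = n - taps + 1
    if lo >= 0:
        return ref[n::-1][:taps]
    w = np.zeros(taps)
    w[: n + 1] = ref[n::-1]
    return w


def lms_anc(
    desired: DisplacementTrace,
    reference: DisplacementTrace,
    cfg: ANCConfig | None = None,
) -> ANCResult:
    """Run LMS adaptive noise cancellation of ``reference`` from ``desired``.

    Sweeps the record up to ``cfg.passes`` times with weights carried over
    between sweeps, stopping once the pass-level mean of the adaptation
    residual z^2 no longer decreases by more than ``cfg.tol`` (relative).
    The returned y is the frozen-weight filtering of the reference after
    adaptation ends, and z = desired - y exactly.
    """
    if cfg is None:
        cfg = ANCConfig()
    d = desired.samples
    ref = reference.samples
    if len(d) != len(ref):
        raise ValueError(f"desired ({len(d)}) and reference ({len(ref)}) lengths differ")
    n = len(d)
    taps = cfg.taps

    rms = float(np.sqrt(np.mean(ref**2)))
    scale = 1.0 / rms if rms > 0 else 1.0
    x = ref * scale

    if cfg.mu * taps * np.mean(x**2) >= 1.0:
        warnings.warn(
            f"mu={cfg.mu} with taps={taps} is at or beyond the LMS stability "
            "bound for the normalized reference power; adaptation may diverge",
            RuntimeWarning,
            stacklevel=2,
        )

    w = np.zeros(taps) if cfg.w_init is None else np.asarray(cfg.w_init, dtype=float).copy()
    if len(w) != taps:
        raise ValueError(f"w_init length {len(w)} does not match taps={taps}")

    mse_traj: list[float] = []
    passes_used = 0
    for _ in range(cfg.passes):
        sq_sum = 0.0
        # overflow on a diverging run is detected explicitly below
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(n):
                xi = _lagged_window(x, i, taps)
                yi = float(w @ xi)
                zi = d[i] - yi
                w = w + 2.0 * cfg.mu * xi * zi
                sq_sum += zi * zi
        if not np.all(np.isfinite(w)):
            raise FloatingPointError(
                f"LMS weights diverged to non-finite values (mu={cfg.mu}); "
                "reduce the step size"
            )
        passes_used += 1
        mse_p = sq_sum / n
        mse_traj.append(mse_p)
        if len(mse_traj) >= 2:
            prev = mse_traj[-2]
            if prev - mse_p <= cfg.tol * max(prev, 1e-300):
                break

    # frozen-weight output with the converged filter
    y = np.array([float(w @ _lagged_window(x, i, taps)) for i in range(n)])
    z = d - y
    return ANCResult(
        y=DisplacementTrace(y, desired.timebase),
        z=DisplacementTrace(z, desired.timebase),
        w_final=w * scale,
        mse_trajectory=np.asarray(mse_traj),
        reference=reference,
        passes_used=passes_used,
    )


def cancel_rbm(
    trace: DisplacementTrace,
    order: int = 3,
    cfg: ANCConfig | None = None,
) -> ANCResult:
    """Remove body movement from a displacement trace.

    Fits an ``order``-degree polynomial reference to the trace, then
    adaptively cancels it; the residual z carries the vital signs.
    """
    model = fit_polynomial(trace, order)
    return lms_anc(desired=trace, reference=model.fitted, cfg=cfg)
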