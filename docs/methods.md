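# Methods

## Signal model and assumptions

A continuous-wave radar at carrier frequency f (default 10 GHz,
λ = c/f ≈ 29.98 mm) illuminates a subject at nominal range d₀. The
line-of-sight chest displacement is modelled as two sinusoids plus a
constant-velocity bulk drift,

    x(t) = m_r sin(2π f_r t + φ_r) + m_h sin(2π f_h t + φ_h) ± v t,

with defaults m_r = 3 mm, f_r = 0.4 Hz (respiration), m_h = 1 mm,
f_h = 1.3 Hz (heartbeat), v = 30 mm/s, sampled at fs = 100 Hz for 5 s
(L = 500). The quadrature baseband is the noiseless unit-amplitude pair
I = cos θ, Q = sin θ with θ = 4π(d₀ + x)/λ + φ; the residual phase φ is
treated as constant (short-range range correlation suppresses oscillator
phase noise). Optional additive Gaussian I/Q noise (seeded, default off)
supports robustness experiments; it is an extension of the model, not part
of it.

Assumptions inherited from the model: the bulk velocity is constant within
an analysis window (segmentation enforces this approximately for real
records); the vital amplitudes are stationary over the window; I/Q are
balanced and DC-free (instrument calibration is out of scope).

## Demodulation

The DACM accumulator sums the per-sample increments
(I·ΔQ − ΔI·Q)/(I² + Q²), which for unit-circle data equals sin(Δθ) at each
step. The phase is therefore recovered with a cubic-in-step bias,
Δθ − sin Δθ ≈ Δθ³/6 per sample. At v = 30 mm/s and fs = 100 Hz
(Δθ ≈ 0.13 rad) the bias accumulates to ≈ 0.25 mm over 5 s; it is smooth
(velocity-dependent) and is absorbed almost entirely by the polynomial
reference in the cancellation stage, so the rate estimates are unaffected.
The recovered phase is relative (φ(1) := 0): the constant 4π d₀/λ + φ and
hence absolute range are unobservable. Samples whose envelope I² + Q²
falls below 10⁻¹² are rejected as numerically dead rather than propagated.

## Body-movement cancellation

A degree-Y polynomial in the sample index (default Y = 3) is least-squares
fitted to x̂ as the canceller's reference. The fit is computed in an index
basis affinely mapped to [−1, 1]; a raw 1..N Vandermonde basis at N = 500,
Y = 5 is badly conditioned, and fitted values are basis-independent.

The LMS canceller defaults are a **single tap** and **μ = 10⁻⁴** on a
unit-RMS-normalized reference, with up to 200 passes and a relative
stopping tolerance of 10⁻⁶ on the pass-level mean of z². Rationale:

* The reference is already a fitted approximation of the body motion, so
  the Wiener solution is a gain of ~1; one tap realizes it exactly and
  adds no spurious degrees of freedom.
* With a large step size (e.g. μ = 10⁻² on this strongly autocorrelated
  reference) the filter partially *tracks* the vital oscillations within a
  pass — the adaptation-time mean square error then falls below the
  least-squares residual floor precisely because part of the signal of
  interest is being cancelled, and the residual spectrum shifts by ~1%.
  The small default step converges to the minimum-mean-square (Wiener)
  gain instead, which is what the stopping rule is meant to find.
* Multi-tap filters and other step sizes remain available via `ANCConfig`.

z = desired − y holds sample-exactly by construction, with y the
frozen-weight filtering of the reference after adaptation ends.

## Spectral estimation and its phase sensitivity

The cosine projection X[k] = 2 Σ z(n) cos(2πkn/M) equals twice the real
part of the M-point zero-padded DFT and is computed that way (M a power of
two, default 2¹⁷; grid spacing fs/M ≈ 7.6·10⁻⁴ Hz). Its implicit even
extension about n = 0 doubles the effective window, so its main lobe is
roughly half as wide as the FFT magnitude lobe — the property that
motivates its use on short windows. Peaks are picked on |X[k]|, ties
toward the lower frequency.

The projection is **phase-sensitive**: for a tone that is odd (sine-
phased) about the window start, X has a null at the tone frequency and
twin lobes ±0.08 Hz away (at 2 cycles/window); only an even
(cosine-phased) component peaks at its own frequency. The canonical
simulation fixture therefore phases both vitals as cosines (φ_r = φ_h =
π/2) — the phasing under which the estimator is meaningful and under which
the whole-pipeline demonstration reproduces single peaks at the reference
rates. For real records the window phase is arbitrary, which is the
dominant error source of short-window RR estimates (see Limitations).

Even with favourable phasing, a finite rectangular window biases the peak
of a 2-cycle tone by a few 10⁻³ Hz (interference from the
negative-frequency image); the bias shrinks quadratically with window
length and is far below 1% in all default configurations, but it exceeds
one fs/M grid step at L = 500 — fine-grid zero padding removes grid error,
not windowing bias.

The heartbeat band is pre-filtered with a zero-phase elliptic high-pass
(stopband edge 0.7 Hz, passband edge 0.9 Hz; 20 dB/0.5 dB per pass, hence
≥ 40 dB stopband attenuation and ≤ 1 dB passband ripple after
forward–backward application; signal-extension padding handles the
transients). The elliptic family meets the narrow 0.2 Hz transition with
the lowest order (4). The respiration band is 0.05–0.6 Hz — the lower edge
keeps residual drift leakage at DC out of the argmax — and the heartbeat
band is 0.8–3 Hz.

Rates are only asserted when the band peak maps to a component amplitude
(peak/L for the cosine projection, 2·peak/L for the FFT) of at least
0.05 mm; below that the band is flagged as holding no vital signal. Real
chest motion is 0.2–10 mm and the demodulation noise floor is ~µm, so the
floor separates the two regimes by orders of magnitude. (A peak-to-band-
median rule was rejected: the FFT main lobe fills most of the respiration
band at L = 500, and a vitals-free ramp's smooth demodulation-bias
residual still shows band peak/median ratios above 3.)

## Segmentation

Direction is the sign of the displacement derivative smoothed by a 1 s
moving average — long enough that a ≥ 20 mm/s trend dominates the ≤ 16
mm/s peak vital-ripple velocity, so breathing alone cannot flip the sign.
Runs shorter than 2 s are merged into their neighbour (hysteresis); runs
longer than 3.5 s are split into near-equal pieces, targeting ~3 s parts
for the short-window estimator. Segments tile the record exactly; each
part's direction is the majority sign of its smoothed derivative. The
boundary localization error is bounded by roughly half the smoothing
window on clean turns.

## Synthetic data: what it does and does not emulate

The generator reproduces the stated study conditions exactly (amplitudes,
rates, velocity, fs, L) plus a triangle-wave variant (default: four 3.2 s
single-direction parts) for segmentation studies. It does not emulate:
amplitude/rate variability within a window, harmonic content of real
breathing, I/Q imbalance or DC offsets, thermal/phase noise (beyond the
optional Gaussian I/Q term), arm motion, or multiple reflectors. Passing
tests on these fixtures therefore demonstrate correctness of the
*algorithms* under the model's assumptions, not field performance on human
subjects.

## Numerical choices

* Time origin t₁ = 0, 1-based sample indexing; displacements in mm,
  rates in Hz.
* M restricted to powers of two; transform lengths below L are rejected.
* LMS stability warning when μ·taps·(normalized reference power) ≥ 1;
  non-finite weights raise instead of propagating.
* Error percentages are computed at full precision and rounded only for
  display.
* All randomness (baseband noise) flows through an explicit seed; default
  runs are fully deterministic and reports embed the resolved
  configuration.
* Problem sizes in the test-suite and acceptance runs are the study's own
  (L = 500, M = 2¹⁷, 12.8 s segmented records); nothing is scaled up
  beyond them.

## Known limitations

* **Short-window RR accuracy is phase-limited.** On ~3 s segments a 0.4 Hz
  respiration completes ~1.3 cycles at arbitrary phase; cosine-projection
  RR errors of tens of percent arise on unfavourably phased segments (the
  segmented demo shows this), and HR (≥ 4 cycles per window) is much more
  robust. This is a property of the estimator, not an implementation
  artifact.
* Fit orders 4–5 over a 5 s window absorb a visible fraction of the
  2-cycle respiration and displace its residual peak; orders 1–3 behave
  well on the canonical fixture, and order 3 is the default.
* The DACM cubic-step bias grows with bulk velocity; at ≫ 50 mm/s or lower
  fs the smooth-bias assumption (absorbed by the fit) starts to erode.
* Only polynomial references are provided; strongly non-polynomial motion
  (speed changes within a part) degrades cancellation.
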