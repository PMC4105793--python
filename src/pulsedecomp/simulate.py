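"""Forward model of the five-component arterial pressure pulse.

The decomposition model holds that the peripheral pressure pulse is a
superposition of the primary left-ventricular ejection pulse (P1), two
reflections from central reflection sites — the renal site (P2, the
"second systolic" pulse) and the iliac site (P3, the "diastolic" pulse) —
and, when the ejection time is short enough to resolve them, up to two
re-reflection harmonics (P4, P5) trailing P3 at the P2–P3 spacing.  All
five components share the temporal width of the ejection pulse; peripheral
resistance elongates every component on its tail end, which is what raises
the effective P2 amplitude above P1 in typical pulses.

Two physiological couplings drive blood-pressure tracking and are inverted
here to produce annotated synthetic data:

* the P2/P1 amplitude ratio (``P2P1``) rises linearly with systolic
  pressure (the renal-junction impedance mismatch grows with pressure);
* the P1→P3 arrival delay (``T13``) rises linearly with pulse pressure
  (differential wave speeds along the aorta).

:func:`synthesize_peripheral_stream` builds a continuous first-derivative
sensor stream in which every beat's P2 amplitude and P3 arrival time are
set so that the *measured* P2P1 and T13 (by the exact amplitude and timing
conventions of the detector in :mod:`pulsedecomp.detect`) equal the values
implied by the requested per-beat pressures under a given linear coupling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .convert import ConversionModel
from .detect import P2_AVERAGING_MS
from .errors import InvalidParameterError
from .signal import WaveformStream

logger = logging.getLogger(__name__)

#: Physiological bounds enforced on per-beat coupling targets.
P2P1_RANGE = (1e-3, 1.5)
T13_RANGE_MS = (180.0, 450.0)

#: Default digitization rate of the sensing hardware (Hz).
DEFAULT_FS = 500.0

#: Fraction of the ejection time spent on the systolic upstroke of the
#: component kernel.  The arterial upstroke is much faster than the decay;
#: the asymmetry is also what keeps overlapping components identifiable in
#: the second-derivative spectrum.
KERNEL_RISE_FRACTION = 0.2


@dataclass
class ComponentSpec:
    """Morphology of one synthetic beat's component-pulse superposition.

    Parameters
    ----------
    lvet_ms
        Left-ventricular ejection time: the duration of the primary pulse
        and, by the model's assumption, of every reflected component.
    t12_ms, t13_ms
        Arrival delays of the renal (P2) and iliac (P3) reflections behind
        P1.  Typical physiology: 70–140 ms and 180–450 ms respectively.
    r_renal, r_iliac
        Reflection coefficients of the two sites (resting values reported
        around 0.17 and 0.30–0.40).
    n_harmonics
        Number of re-reflection harmonics past P3 (0, 1 or 2), spaced by
        ``t13_ms - t12_ms`` and attenuated by ``r_renal * r_iliac`` per
        round trip.
    tail_tau_ms
        Time constant of the causal exponential tail elongation applied to
        every component (peripheral-resistance effect).
    amplitude_mmHg
        P1 peak pressure above the diastolic floor.
    rise_fraction
        Fraction of the ejection time spent on the kernel's upstroke.
    """

    lvet_ms: float = 300.0
    t12_ms: float = 100.0
    t13_ms: float = 280.0
    r_renal: float = 0.17
    r_iliac: float = 0.35
    n_harmonics: int = 0
    tail_tau_ms: float = 30.0
    amplitude_mmHg: float = 30.0
    rise_fraction: float = KERNEL_RISE_FRACTION

    def __post_init__(self) -> None:
        if not self.lvet_ms > 0:
            raise InvalidParameterError("lvet_ms must be positive")
        if not (0 < self.t12_ms < self.t13_ms):
            raise InvalidParameterError("require 0 < t12_ms < t13_ms")
        if not (0 <= self.r_renal <= 1 and 0 <= self.r_iliac <= 1):
            raise InvalidParameterError("reflection coefficients must lie in [0, 1]")
        if self.n_harmonics not in (0, 1, 2):
            raise InvalidParameterError("n_harmonics must be 0, 1 or 2")
        if self.tail_tau_ms < 0:
            raise InvalidParameterError("tail_tau_ms must be >= 0")
        if not self.amplitude_mmHg > 0:
            raise InvalidParameterError("amplitude_mmHg must be positive")
        if not (0 < self.rise_fraction < 1):
            raise InvalidParameterError("rise_fraction must lie in (0, 1)")

    def component_offsets_ms(self) -> list[float]:
        """Start offsets of the component kernels relative to beat onset."""
        spacing = self.t13_ms - self.t12_ms
        offsets = [0.0, self.t12_ms, self.t13_ms]
        for k in range(1, self.n_harmonics + 1):
            offsets.append(self.t13_ms + k * spacing)
        return offsets

    def component_coefficients(self) -> list[float]:
        """Amplitude coefficients relative to P1 for each component.

        Each re-reflection harmonic is attenuated by one additional factor
        of ``r_renal * r_iliac`` (one extra round trip between the sites).
        """
        coeffs = [1.0, self.r_renal, self.r_iliac]
        for k in range(1, self.n_harmonics + 1):
            coeffs.append(coeffs[-1] * self.r_renal * self.r_iliac)
        return coeffs


@dataclass
class BeatTrainSpec:
    """A synthetic beat train with per-beat ground-truth pressures.

    The ``coupling`` pair of :class:`~pulsedecomp.convert.ConversionModel`
    objects is applied *in inverse* to turn the requested systole and
    pulse-pressure series into per-beat P2P1 and T13 targets.
    """

    n_beats: int
    mean_ibi_ms: float
    ibi_sd_ms: float
    systole_series: np.ndarray
    diastole_series: np.ndarray
    coupling: tuple[ConversionModel, ConversionModel]
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.systole_series = np.broadcast_to(
            np.asarray(self.systole_series, dtype=float), (self.n_beats,)
        ).copy()
        self.diastole_series = np.broadcast_to(
            np.asarray(self.diastole_series, dtype=float), (self.n_beats,)
        ).copy()
        if self.n_beats < 1:
            raise InvalidParameterError("n_beats must be >= 1")
        if not np.all(self.systole_series > self.diastole_series):
            raise InvalidParameterError("systole must exceed diastole on every beat")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        model_s, model_p = self.coupling
        if model_s.parameter != "p2p1" or model_p.parameter != "t13":
            raise InvalidParameterError(
                "coupling must be (p2p1->systole model, t13->pulse-pressure model)"
            )


def component_kernel(
    duration_ms: float,
    sampling_rate: float = DEFAULT_FS,
    rise_fraction: float = KERNEL_RISE_FRACTION,
) -> np.ndarray:
    """Unit-amplitude component-pulse kernel.

    An asymmetric raised-cosine lobe: a half-cosine rise over
    ``rise_fraction`` of the duration and a half-cosine fall over the rest,
    zero at both ends with a single interior maximum of exactly 1.  The
    fast-rise/slow-fall asymmetry mimics the arterial ejection pulse and
    ensures that partially overlapping components of equal width remain
    distinguishable in the second-derivative spectrum (two symmetric
    raised cosines of equal width sum to a *single* cosine over their
    overlap, which would make the decomposition unidentifiable).
    """
    if not duration_ms > 0 or not sampling_rate > 0:
        raise InvalidParameterError("duration and sampling rate must be positive")
    if not (0 < rise_fraction < 1):
        raise InvalidParameterError("rise_fraction must lie in (0, 1)")
    n = int(round(duration_ms * sampling_rate / 1000.0))
    n = max(n, 3)
    t = np.arange(n) / (n - 1)  # 0 .. 1 inclusive
    k = np.empty(n)
    rise = t < rise_fraction
    k[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / rise_fraction))
    fall = 0.5 * (1.0 + np.cos(np.pi * (t[~rise] - rise_fraction) / (1.0 - rise_fraction)))
    # squaring the falling half-lobe makes the pulse land on zero with
    # vanishing curvature, like the exponential diastolic decay of real
    # pulses; a hard curvature step at the support end would bleed spurious
    # features into the second-derivative spectrum of later components.
    k[~rise] = fall * fall
    return k / k.max()  # peak exactly 1 on the sample grid


def make_component_pulse(
    duration_ms: float,
    amplitude: float,
    sampling_rate: float = DEFAULT_FS,
) -> WaveformStream:
    """A single smooth unimodal component pulse as an envelope stream.

    The pulse spans ``round(duration_ms * fs / 1000)`` samples, is zero at
    both ends and peaks at exactly ``amplitude``.  The same kernel shape is
    reused for all five components of a synthetic beat.
    """
    k = component_kernel(duration_ms, sampling_rate)
    return WaveformStream(samples=amplitude * k, sampling_rate=sampling_rate, kind="envelope")


def _tail_filter(x: np.ndarray, tau_ms: float, sampling_rate: float) -> np.ndarray:
    """Causal exponential tail elongation (unit DC gain); identity at tau=0."""
    if tau_ms <= 0:
        return x
    import scipy.signal as sps

    alpha = 1.0 - np.exp(-1000.0 / (tau_ms * sampling_rate))
    return sps.lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def _elongated_kernel(spec: ComponentSpec, sampling_rate: float) -> tuple[np.ndarray, int]:
    """Tail-elongated component kernel and its detection-convention offset.

    The returned index is the *arrival mark* of an isolated component
    under the detector's measurement chain (first difference, central
    difference, 20-point smoothing, curvature-trough search), so that
    ground-truth component times and detected times share one convention.
    """
    k = component_kernel(spec.lvet_ms, sampling_rate, spec.rise_fraction)
    if spec.tail_tau_ms > 0:
        tail = int(round(5.0 * spec.tail_tau_ms * sampling_rate / 1000.0))
        k = _tail_filter(np.concatenate([k, np.zeros(tail)]), spec.tail_tau_ms, sampling_rate)
    return k, _detection_offset(k, sampling_rate)


def _detection_offset(kernel: np.ndarray, sampling_rate: float) -> int:
    """Curvature-trough index of an isolated component, detector chain."""
    from .signal import SMOOTH_WINDOW, smooth_array

    pad = 4 * SMOOTH_WINDOW
    env = np.concatenate([np.zeros(pad), kernel, np.zeros(pad)])
    d1 = np.diff(env, prepend=0.0) * sampling_rate
    d2 = np.gradient(d1, 1.0 / sampling_rate)
    d2s = smooth_array(d2, SMOOTH_WINDOW)
    return int(np.argmin(d2s)) - pad


def synthesize_central_pulse(
    spec: ComponentSpec,
    sampling_rate: float = DEFAULT_FS,
    window_ms: float | None = None,
):
    """Noise-free central pressure pulse plus its ground-truth annotation.

    Returns ``(stream, truth)`` where ``stream`` is the envelope of the
    full superposition over one beat window and ``truth`` is a
    :class:`~pulsedecomp.detect.ComponentSet` holding the true component
    times (kernel peaks, ms from window start), the envelope amplitudes at
    those times, and the P2P1/T13 values by the detector's measurement
    conventions (50 ms averaging for P2, onset baseline).

    Components whose support extends beyond the window are truncated with
    a logged warning.
    """
    from .detect import ComponentSet

    kernel, mark_idx = _elongated_kernel(spec, sampling_rate)
    offsets_ms = spec.component_offsets_ms()
    coeffs = spec.component_coefficients()

    auto_window = offsets_ms[-1] + spec.lvet_ms + 5.0 * spec.tail_tau_ms
    win_ms = auto_window if window_ms is None else window_ms
    n = int(round(win_ms * sampling_rate / 1000.0))
    if n < 2:
        raise InvalidParameterError("window too short for a single sample pulse")

    env = np.zeros(n)
    truncated = False
    for off_ms, c in zip(offsets_ms, coeffs):
        i0 = int(round(off_ms * sampling_rate / 1000.0))
        i1 = i0 + kernel.size
        if i0 >= n:
            truncated = True
            continue
        if i1 > n:
            truncated = True
        seg = kernel[: max(0, min(i1, n) - i0)]
        env[i0 : i0 + seg.size] += spec.amplitude_mmHg * c * seg
    if truncated:
        logger.warning("component pulses truncated at the %.0f ms beat window", win_ms)

    dt_ms = 1000.0 / sampling_rate
    times_idx = [int(round(o * sampling_rate / 1000.0)) + mark_idx for o in offsets_ms]
    times_ms = [i * dt_ms for i in times_idx]

    def env_at(i: int) -> float:
        return float(env[i]) if 0 <= i < n else 0.0

    half = int(round(P2_AVERAGING_MS / 2.0 * sampling_rate / 1000.0))
    i2 = times_idx[1]
    a2_window = env[max(0, i2 - half) : min(n, i2 + half + 1)]
    a1 = env_at(times_idx[0])
    a2 = float(np.mean(a2_window)) if a2_window.size else 0.0

    truth = ComponentSet(
        t1_ms=times_ms[0],
        t2_ms=times_ms[1],
        t3_ms=times_ms[2],
        t4_ms=times_ms[3] if len(times_ms) > 3 else None,
        t5_ms=times_ms[4] if len(times_ms) > 4 else None,
        a1=a1,
        a2=a2,
        a3=env_at(times_idx[2]),
        p2p1=a2 / a1 if a1 > 0 else np.nan,
        t13_ms=times_ms[2] - times_ms[0],
        p1_merged=False,
    )
    stream = WaveformStream(samples=env, sampling_rate=sampling_rate, kind="envelope")
    return stream, truth


def _solve_beat(
    buffer_seg: np.ndarray,
    kernel: np.ndarray,
    mark_idx: int,
    spec: ComponentSpec,
    t13_idx: int,
    rho: float,
    pp: float,
    sampling_rate: float,
) -> tuple[np.ndarray, int]:
    """Solve P1/P2 amplitudes so the beat realizes P2P1=rho and peak=pp.

    ``buffer_seg`` holds the spill-over from earlier beats across this
    beat's construction window (long enough to contain all new components).
    Returns the combined new-component contribution to add to the buffer,
    plus the P1 peak index within the window.

    The measurement conventions mirror the detector exactly: amplitudes
    are referenced to the envelope value at beat onset, P2 uses the 50 ms
    centered average, and the beat peak above onset defines pulse
    pressure.  Both constraints are linear in the unknown amplitudes once
    the peak location is fixed, so a short fixed-point iteration on the
    peak location solves the 2x2 system exactly.
    """
    n = buffer_seg.size
    t12_idx = int(round(spec.t12_ms * sampling_rate / 1000.0))
    spacing_idx = t13_idx - t12_idx

    def placed(offset_idx: int) -> np.ndarray:
        out = np.zeros(n)
        seg = kernel[: max(0, min(offset_idx + kernel.size, n) - offset_idx)]
        if offset_idx < n and seg.size:
            out[offset_idx : offset_idx + seg.size] = seg
        return out

    # fixed-shape part G (P1 + P3 + harmonics, unit P1 amplitude) and the
    # free P2 kernel K2
    g = placed(0)
    k3 = placed(t13_idx)
    g = g + spec.r_iliac * k3
    coeff = spec.r_iliac
    for h in range(1, spec.n_harmonics + 1):
        coeff *= spec.r_renal * spec.r_iliac
        g = g + coeff * placed(t13_idx + h * spacing_idx)
    k2 = placed(t12_idx)

    i1 = mark_idx
    half = int(round(P2_AVERAGING_MS / 2.0 * sampling_rate / 1000.0))
    i2 = t12_idx + mark_idx
    w0, w1 = max(0, i2 - half), min(n, i2 + half + 1)

    c0 = buffer_seg[0]
    s_t1 = buffer_seg[i1] if i1 < n else 0.0
    s_w = float(np.mean(buffer_seg[w0:w1])) if w1 > w0 else 0.0
    g_t1 = g[i1] if i1 < n else 0.0
    g_w = float(np.mean(g[w0:w1])) if w1 > w0 else 0.0
    k2_t1 = k2[i1] if i1 < n else 0.0
    k2_w = float(np.mean(k2[w0:w1])) if w1 > w0 else 0.0

    # peak location: iterate argmax of the composed beat
    i_pk = i2  # initial guess: the P2 region (P2P1 >= ~1 in typical pulses)
    amp_a = spec.amplitude_mmHg
    amp_b = rho * amp_a
    for _ in range(25):
        # ratio constraint:  (s_w - c0) + A g_w + B k2_w = rho [(s_t1 - c0) + A g_t1 + B k2_t1]
        # peak constraint:   (s_pk - c0) + A g_pk + B k2_pk = pp
        s_pk = buffer_seg[i_pk]
        row1 = (g_w - rho * g_t1, k2_w - rho * k2_t1)
        rhs1 = rho * (s_t1 - c0) - (s_w - c0)
        row2 = (g[i_pk], k2[i_pk])
        rhs2 = pp - (s_pk - c0)
        det = row1[0] * row2[1] - row1[1] * row2[0]
        if abs(det) < 1e-12:
            break
        amp_a = (rhs1 * row2[1] - row1[1] * rhs2) / det
        amp_b = (row1[0] * rhs2 - rhs1 * row2[0]) / det
        beat = buffer_seg + amp_a * g + amp_b * k2
        new_pk = int(np.argmax(beat))
        if new_pk == i_pk:
            break
        i_pk = new_pk

    if amp_a <= 0 or amp_b < 0:
        warnings.warn("beat amplitude solve produced non-physical amplitudes; clamped")
        amp_a = max(amp_a, 1e-6)
        amp_b = max(amp_b, 0.0)
    return amp_a * g + amp_b * k2, i1


def synthesize_peripheral_stream(
    train: BeatTrainSpec,
    spec: ComponentSpec | None = None,
    sampling_rate: float = DEFAULT_FS,
):
    """Continuous first-derivative sensor stream for a whole beat train.

    Per beat the coupling models are inverted — ``P2P1 = (systole -
    offset_s) / gain_s`` and ``T13 = (PP - offset_p) / gain_p`` — and the
    beat's P2 amplitude and P3 arrival are set accordingly; targets
    falling outside the physiological ranges are clamped (per-beat flag in
    the returned table).  Component tails spill naturally into following
    beats.  Gaussian sensor noise of ``train.noise_sd`` (stream units) is
    added to the derivative stream.

    The emitted stream is the first difference of the internally
    constructed envelope scaled by the sampling rate, so cumulative-sum
    integration reproduces the envelope exactly (before noise).

    Returns ``(stream, truth)``: the d1 :class:`WaveformStream` and a
    per-beat ground-truth :class:`pandas.DataFrame` with columns
    ``onset_s, ibi_ms, systole, diastole, pulse_pressure, p2p1, t13_ms,
    clamped``.
    """
    if spec is None:
        spec = ComponentSpec()
    rng = np.random.default_rng(train.seed)

    model_s, model_p = train.coupling
    ibis_ms = rng.normal(train.mean_ibi_ms, train.ibi_sd_ms, train.n_beats)
    ibis_ms = np.clip(ibis_ms, 400.0, None)
    ibi_idx = np.round(ibis_ms * sampling_rate / 1000.0).astype(int)
    onsets = np.concatenate([[0], np.cumsum(ibi_idx[:-1])])
    n_total = int(onsets[-1] + ibi_idx[-1])

    kernel, mark_idx = _elongated_kernel(spec, sampling_rate)
    env = np.zeros(n_total + kernel.size + n_total // 10 + 8)

    records = []
    n_clamped = 0
    dt_ms = 1000.0 / sampling_rate
    for b in range(train.n_beats):
        systole = train.systole_series[b]
        pp_req = train.systole_series[b] - train.diastole_series[b]

        rho = model_s.invert(systole)
        t13_ms = model_p.invert(pp_req)
        clamped = False
        if not (P2P1_RANGE[0] <= rho <= P2P1_RANGE[1]):
            rho = float(np.clip(rho, *P2P1_RANGE))
            clamped = True
        if not (T13_RANGE_MS[0] <= t13_ms <= T13_RANGE_MS[1]):
            t13_ms = float(np.clip(t13_ms, *T13_RANGE_MS))
            clamped = True
        n_clamped += clamped

        t13_idx = int(round(t13_ms * sampling_rate / 1000.0))
        t13_real_ms = t13_idx * dt_ms
        # realized pressures are re-derived from the (possibly clamped,
        # sample-quantized) parameters so that truth and coupling agree
        sys_real = model_s.apply(rho)
        pp_real = model_p.apply(t13_real_ms)

        o = onsets[b]
        win = kernel.size + t13_idx + (spec.n_harmonics + 1) * kernel.size
        win = min(win, env.size - o)
        contrib, _ = _solve_beat(
            env[o : o + win], kernel, mark_idx, spec, t13_idx, rho, pp_real, sampling_rate
        )
        env[o : o + win] += contrib

        records.append(
            {
                "onset_s": o / sampling_rate,
                "ibi_ms": ibi_idx[b] * dt_ms,
                "systole": sys_real,
                "diastole": sys_real - pp_real,
                "pulse_pressure": pp_real,
                "p2p1": rho,
                "t13_ms": t13_real_ms,
                "clamped": bool(clamped),
            }
        )

    if n_clamped:
        warnings.warn(f"{n_clamped} beats had coupling targets clamped to physiological ranges")

    env = env[:n_total]
    d1 = np.diff(env, prepend=0.0) * sampling_rate
    if train.noise_sd > 0:
        d1 = d1 + rng.normal(0.0, train.noise_sd, d1.size)

    stream = WaveformStream(samples=d1, sampling_rate=sampling_rate, kind="d1")
    truth = pd.DataFrame.from_records(records)
    truth.attrs["n_clamped"] = n_clamped
    return stream, truth


def reference_noise_sd(
    train: BeatTrainSpec,
    spec: ComponentSpec | None = None,
    sampling_rate: float = DEFAULT_FS,
    fraction: float = 0.02,
) -> float:
    """Noise SD equal to ``fraction`` of the clean stream's peak amplitude.

    Convenience for expressing sensor noise relative to pulse amplitude on
    the derivative stream: synthesizes the train noise-free and returns
    ``fraction * max|d1|``.
    """
    clean = BeatTrainSpec(
        n_beats=train.n_beats,
        mean_ibi_ms=train.mean_ibi_ms,
        ibi_sd_ms=train.ibi_sd_ms,
        systole_series=train.systole_series,
        diastole_series=train.diastole_series,
        coupling=train.coupling,
        noise_sd=0.0,
        seed=train.seed,
    )
    stream, _ = synthesize_peripheral_stream(clean, spec, sampling_rate)
    return fraction * float(np.max(np.abs(stream.samples)))
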