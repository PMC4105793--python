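"""Component-pulse localization and extraction of the two tracking parameters.

Detection happens in the *second derivative* of the pulse: because the
second derivative inverts curvature, each component pulse appears there as
a local **minimum** preceded by a maximum.  P2 and P3 are found as the
deepest such minima inside their physiological arrival windows relative to
P1 (70–140 ms and 180–450 ms).  P1 itself is the first curvature trough of
the beat when it is resolved; when a strong renal reflection merges P2
into P1 (high augmentation index or high systole) the P1 location is
recovered instead from the first positive-going inversion of the second
derivative after the pulse onset, and the beat is flagged ``p1_merged``.

Two scalar parameters are extracted per beat:

* ``P2P1`` — the P2/P1 amplitude ratio measured on the integrated pulse
  envelope above the onset baseline, P2 averaged over a 50 ms window
  centered on its temporal location (robust against its dynamic shifts);
* ``T13`` — the P1→P3 arrival-time difference in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .errors import UnanalyzableBeatError
from .signal import SMOOTH_WINDOW, BeatSegment, WaveformStream, detect_beats, smooth_array

#: Width (ms) of the centered averaging window for the P2 amplitude.
P2_AVERAGING_MS = 50.0

#: Physiological arrival windows (ms) of P2 and P3 relative to P1.
P2_WINDOW_MS = (70.0, 140.0)
P3_WINDOW_MS = (180.0, 450.0)

#: Minimum prominence of a candidate curvature trough, as a fraction of the
#: beat's smoothed-d2 peak-to-peak range.
TROUGH_PROMINENCE_FRAC = 0.01


@dataclass
class ComponentSet:
    """Per-beat component-pulse annotation.

    Times are milliseconds relative to the beat onset; amplitudes are
    envelope values above the onset baseline (signal units).  ``t4_ms`` /
    ``t5_ms`` are filled only when the harmonic search is enabled and the
    re-reflections are resolvable.
    """

    t1_ms: float
    t2_ms: float
    t3_ms: float
    t4_ms: float | None = None
    t5_ms: float | None = None
    a1: float = np.nan
    a2: float = np.nan
    a3: float = np.nan
    p2p1: float = np.nan
    t13_ms: float = np.nan
    p1_merged: bool = False

    @property
    def n_components(self) -> int:
        return 3 + (self.t4_ms is not None) + (self.t5_ms is not None)


def _first_upward_crossing(d2s: np.ndarray, start: int, stop: int) -> int | None:
    """First index in [start, stop) where d2s crosses from <0 to >=0."""
    seg = d2s[start:stop]
    if seg.size < 2:
        return None
    below = seg[:-1] < 0
    above = seg[1:] >= 0
    hits = np.nonzero(below & above)[0]
    return int(start + hits[0] + 1) if hits.size else None


def _merged_p1_index(d2s: np.ndarray, t2_idx: int) -> int:
    """P1 location when it is not a prominent curvature trough.

    A partially merged P1 still inverts the second derivative upward — a
    shallow local minimum (possibly above zero) before the dominant
    merged trough.  That first positive-going inversion marks P1.  When
    even the inversion is annihilated (full merge) the estimate degrades
    gracefully: the first upward zero-crossing after the upstroke, else
    the point of strongest deceleration of the descent into the merged
    trough.  Such beats carry the ``p1_merged`` flag precisely because
    the P1 landmark is partly destroyed and its timing is approximate.
    """
    raw, _ = scipy.signal.find_peaks(-d2s[:t2_idx])
    if raw.size:
        return int(raw[0])
    neg = np.nonzero(d2s[:t2_idx] < 0)[0]
    z0 = int(neg[0]) if neg.size else 0
    up = _first_upward_crossing(d2s, z0, t2_idx)
    if up is not None:
        return up
    if t2_idx - z0 > 2:
        slope = np.gradient(d2s[z0:t2_idx])
        return z0 + int(np.argmax(slope))
    return z0


def _deepest_in_window(
    troughs: np.ndarray, depths: np.ndarray, lo: float, hi: float
) -> int | None:
    """Deepest trough index inside [lo, hi]; earliest wins ties."""
    inside = (troughs >= lo) & (troughs <= hi)
    if not np.any(inside):
        return None
    cand = troughs[inside]
    d = depths[inside]
    best = np.nonzero(d == d.max())[0][0]  # first occurrence = earliest
    return int(cand[best])


def locate_components(
    beat: BeatSegment,
    p2_window_ms: tuple[float, float] = P2_WINDOW_MS,
    p3_window_ms: tuple[float, float] = P3_WINDOW_MS,
    extended: bool = False,
    smooth_window: int = SMOOTH_WINDOW,
) -> ComponentSet:
    """Locate P1–P3 (optionally P4/P5) in a beat's second derivative.

    The second derivative is smoothed (20 samples = 40 ms at 500 Hz)
    before the peak search to reject noise spikes.  When several candidate
    minima fall in a window the deepest one wins, ties going to the
    earliest.  Raises :class:`UnanalyzableBeatError` when no candidate
    exists in the P2 or P3 window.
    """
    fs = beat.sampling_rate
    dt_ms = 1000.0 / fs
    d2s = smooth_array(beat.d2, smooth_window)
    scale = float(np.ptp(d2s))
    if scale <= 0:
        raise UnanalyzableBeatError("flat second derivative")

    troughs, props = scipy.signal.find_peaks(-d2s, prominence=TROUGH_PROMINENCE_FRAC * scale)
    # a component trough is a true curvature inversion (negative second
    # derivative) preceded by a curvature maximum; the upstroke
    # acceleration at the very onset counts as a maximum even when it sits
    # on the segment edge where no interior peak exists
    positive_seen = np.logical_or.accumulate(d2s > 0)
    preceded = np.array([t > 0 and positive_seen[t - 1] for t in troughs], dtype=bool)
    keep = preceded & (d2s[troughs] < 0)
    troughs, depths = troughs[keep], -d2s[troughs[keep]]
    if troughs.size == 0:
        raise UnanalyzableBeatError("no curvature troughs found")

    lo2, hi2 = (w / dt_ms for w in p2_window_ms)
    lo3, hi3 = (w / dt_ms for w in p3_window_ms)

    # tentative isolated P1 = first trough, provided a P2 candidate follows
    # inside its window; otherwise the first trough is the merged P1+P2
    # complex and P1 is recovered from the inflection before it.
    t1_idx = int(troughs[0])
    merged = _deepest_in_window(troughs, depths, t1_idx + lo2, t1_idx + hi2) is None
    if merged:
        t2_idx = t1_idx
        t1_idx = _merged_p1_index(d2s, t2_idx)
        if not (lo2 <= t2_idx - t1_idx <= hi2):
            raise UnanalyzableBeatError("no candidate in the P2 window")
    else:
        t2_idx = _deepest_in_window(troughs, depths, t1_idx + lo2, t1_idx + hi2)

    t3_idx = _deepest_in_window(troughs, depths, t1_idx + lo3, t1_idx + hi3)
    if t3_idx is None:
        raise UnanalyzableBeatError("no candidate in the P3 window")

    comps = ComponentSet(
        t1_ms=t1_idx * dt_ms,
        t2_ms=t2_idx * dt_ms,
        t3_ms=t3_idx * dt_ms,
        p1_merged=bool(merged),
    )

    if extended:
        # re-reflection harmonics trail P3 at the P2->P3 spacing; search a
        # window around each predicted arrival with no prominence floor
        # (harmonics are tiny), requiring only a genuine local minimum.
        raw_troughs, _ = scipy.signal.find_peaks(-d2s)
        raw_depths = -d2s[raw_troughs]
        spacing = t3_idx - t2_idx
        prev = t3_idx
        found = []
        for _ in range(2):
            lo = prev + 0.5 * spacing
            hi = prev + 1.5 * spacing
            idx = _deepest_in_window(raw_troughs, raw_depths, lo, hi)
            if idx is None:
                break
            found.append(idx * dt_ms)
            prev = idx
        comps.t4_ms = found[0] if len(found) > 0 else None
        comps.t5_ms = found[1] if len(found) > 1 else None

    return comps


def compute_p2p1(beat: BeatSegment, comps: ComponentSet) -> float:
    """P2/P1 amplitude ratio on the integrated envelope.

    P1's amplitude is the envelope value at its second-derivative
    location; P2's is the envelope averaged over a 50 ms window centered
    on its location.  Both are referenced to the envelope value at beat
    onset, which makes the ratio invariant to DC drift.  Fills
    ``comps.a1/a2/p2p1`` and returns the ratio.
    """
    fs = beat.sampling_rate
    env = beat.envelope
    baseline = env[0]
    i1 = int(round(comps.t1_ms * fs / 1000.0))
    i2 = int(round(comps.t2_ms * fs / 1000.0))
    if i1 >= env.size:
        raise UnanalyzableBeatError("P1 outside the beat segment")
    half = int(round(P2_AVERAGING_MS / 2.0 * fs / 1000.0))
    w0, w1 = max(0, i2 - half), min(env.size, i2 + half + 1)
    a1 = float(env[i1] - baseline)
    a2 = float(np.mean(env[w0:w1]) - baseline)
    if a1 <= 0:
        raise UnanalyzableBeatError("non-positive P1 amplitude")
    i3 = int(round(comps.t3_ms * fs / 1000.0))
    comps.a1, comps.a2 = a1, a2
    comps.a3 = float(env[i3] - baseline) if i3 < env.size else np.nan
    comps.p2p1 = a2 / a1
    return comps.p2p1


def compute_t13(comps: ComponentSet) -> float:
    """T13 = t3 - t1 in milliseconds; fills ``comps.t13_ms``."""
    comps.t13_ms = comps.t3_ms - comps.t1_ms
    return comps.t13_ms


def analyze_beat(beat: BeatSegment, extended: bool = False) -> ComponentSet:
    """Full per-beat analysis: locate components, then P2P1 and T13."""
    comps = locate_components(beat, extended=extended)
    compute_p2p1(beat, comps)
    compute_t13(comps)
    return comps


def analyze_stream(stream: WaveformStream, extended: bool = False) -> pd.DataFrame:
    """Analyze every beat of a first-derivative stream.

    Returns the per-beat parameter table with columns ``onset_s, t1_ms,
    t2_ms, t3_ms, p2p1, t13_ms, p1_merged, accepted, reason`` (plus
    ``t4_ms``/``t5_ms`` in extended mode).  Beats where detection fails
    are retained with ``accepted=False`` and the failure reason.
    """
    beats, _ = detect_beats(stream)
    rows = []
    for beat in beats:
        row = {
            "onset_s": beat.onset_time_s + stream.start_time_s,
            "t1_ms": np.nan,
            "t2_ms": np.nan,
            "t3_ms": np.nan,
            "p2p1": np.nan,
            "t13_ms": np.nan,
            "p1_merged": False,
            "accepted": False,
            "reason": "",
        }
        if extended:
            row["t4_ms"] = np.nan
            row["t5_ms"] = np.nan
        try:
            comps = analyze_beat(beat, extended=extended)
        except UnanalyzableBeatError as exc:
            row["reason"] = exc.reason
        else:
            row.update(
                t1_ms=comps.t1_ms,
                t2_ms=comps.t2_ms,
                t3_ms=comps.t3_ms,
                p2p1=comps.p2p1,
                t13_ms=comps.t13_ms,
                p1_merged=comps.p1_merged,
                accepted=True,
            )
            if extended:
                row["t4_ms"] = np.nan if comps.t4_ms is None else comps.t4_ms
                row["t5_ms"] = np.nan if comps.t5_ms is None else comps.t5_ms
        rows.append(row)
    return pd.DataFrame(rows)
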