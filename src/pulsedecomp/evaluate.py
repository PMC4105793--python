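"""Stream synchronization and agreement statistics.

Two independently recorded beat series (e.g. catheter pressures and the
noninvasive parameter stream) are synchronized by matching their
inter-beat-interval (IBI) sequences: beat-to-beat IBI variability is
random enough to act as a unique time-stamped fingerprint, so an
exhaustive integer-lag search minimizing the mean squared IBI difference
recovers the offset between the streams.

Agreement between paired pressure series is summarized the way device
validation studies do: Pearson R^2 with an OLS fit, and a Bland-Altman
analysis (bias, SD of the paired differences, 1.96-SD limits of
agreement).  The AAMI SP-10 trend criterion — SD of differences at most
8 mmHg — is evaluated on the Bland-Altman SD.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import scipy.stats

from .errors import AlignmentFailureError, DegenerateFitError, InsufficientDataError

#: AAMI SP-10 bound on the standard deviation of paired differences (mmHg).
AAMI_SD_LIMIT_MMHG = 8.0

#: Minimum overlap (beats) for a valid IBI alignment.
MIN_ALIGN_OVERLAP = 5


@dataclass
class AlignmentResult:
    """Best integer beat lag between two IBI series.

    Positive ``lag_beats`` means series ``b`` starts ``lag_beats`` beats
    later than series ``a``.  ``match_score`` is the mean squared IBI
    difference (ms^2) at the best lag; ``degenerate`` flags series with
    too little IBI variability to identify a unique lag.
    """

    lag_beats: int
    lag_s: float
    match_score: float
    degenerate: bool = False


@dataclass
class CorrelationResult:
    """Pearson/OLS summary of two aligned series."""

    n_pairs: int
    r_squared: float
    slope: float
    intercept: float
    p_value: float


@dataclass
class AgreementReport:
    """Bland-Altman + correlation agreement summary of two paired series."""

    n_pairs: int
    r_squared: float
    fit_slope: float
    fit_intercept: float
    bland_bias_mmHg: float
    bland_sd_mmHg: float
    limits_of_agreement: tuple[float, float]
    pass_aami: bool

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["limits_of_agreement"] = list(self.limits_of_agreement)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "AgreementReport":
        with open(path) as fh:
            payload = json.load(fh)
        payload["limits_of_agreement"] = tuple(payload["limits_of_agreement"])
        return cls(**payload)


def align_by_ibi(ibi_a, ibi_b, max_lag_beats: int) -> AlignmentResult:
    """Exhaustive integer-lag alignment of two IBI series (ms).

    Searches lags in ``[-max_lag_beats, +max_lag_beats]`` and returns the
    lag minimizing the mean squared IBI difference over the overlapping
    window.  Raises :class:`AlignmentFailureError` when no lag leaves at
    least 5 overlapping beats.  Constant (variability-free) series cannot
    be uniquely aligned and come back with ``degenerate=True``.
    """
    a = np.asarray(ibi_a, dtype=float)
    b = np.asarray(ibi_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise InsufficientDataError("IBI alignment needs at least 10 intervals per series")

    scores: dict[int, float] = {}
    for lag in range(-max_lag_beats, max_lag_beats + 1):
        if lag >= 0:
            seg_a, seg_b = a[lag:], b
        else:
            seg_a, seg_b = a, b[-lag:]
        n = min(seg_a.size, seg_b.size)
        if n < MIN_ALIGN_OVERLAP:
            continue
        d = seg_a[:n] - seg_b[:n]
        scores[lag] = float(np.mean(d * d))
    if not scores:
        raise AlignmentFailureError("no lag leaves enough overlapping beats")

    best_lag = min(scores, key=lambda k: (scores[k], abs(k)))
    best = scores[best_lag]
    # a unique fingerprint requires the best lag to beat the others clearly;
    # constant series tie everywhere
    others = [s for k, s in scores.items() if k != best_lag]
    spread = max(np.std(a), np.std(b))
    degenerate = spread < 1e-9 or (
        len(others) > 0 and min(others) - best <= 1e-9 * max(1.0, best)
    )
    mean_ibi_s = float(np.mean(a)) / 1000.0
    return AlignmentResult(
        lag_beats=int(best_lag),
        lag_s=best_lag * mean_ibi_s,
        match_score=best,
        degenerate=bool(degenerate),
    )


def match_beats(times_a, times_b, tol_s: float = 0.25) -> np.ndarray:
    """Pair beats of two streams by onset-time proximity.

    Returns an ``(n, 2)`` integer array of indices ``(i_a, i_b)`` where
    each beat of ``a`` is matched to the nearest beat of ``b`` within
    ``tol_s`` seconds; duplicate matches keep the closer pair.  Useful for
    evaluating a detected beat series against a ground-truth table
    recorded on the same clock (streams on different clocks need
    :func:`align_by_ibi` first).
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    pairs: dict[int, tuple[int, float]] = {}
    for i, t in enumerate(a):
        j = int(np.argmin(np.abs(b - t)))
        d = abs(b[j] - t)
        if d <= tol_s and (j not in pairs or d < pairs[j][1]):
            pairs[j] = (i, d)
    out = np.array([[i, j] for j, (i, _) in sorted(pairs.items())], dtype=int)
    return out.reshape(-1, 2)


def correlation_report(series_a, series_b) -> CorrelationResult:
    """Pearson R^2 and OLS fit of ``b`` on ``a`` with slope p-value."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise InsufficientDataError("series must be paired")
    if a.size < 3:
        raise InsufficientDataError("correlation needs at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateFitError("a series has zero variance")
    res = scipy.stats.linregress(a, b)
    return CorrelationResult(
        n_pairs=int(a.size),
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


def bland_altman(series_a, series_b) -> AgreementReport:
    """Bland-Altman agreement of paired series (differences ``a - b``).

    Bias is the mean difference, SD the (n-1) sample standard deviation,
    limits of agreement bias +/- 1.96 SD.  The AAMI flag compares the SD
    against the 8 mmHg trend bound.  The correlation fields of the report
    are filled from :func:`correlation_report` on the same pairs (when the
    series are non-degenerate; identical series give R^2 = 1 by
    convention).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise InsufficientDataError("series must be paired")
    if a.size < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    try:
        corr = correlation_report(a, b)
        r2, slope, intercept = corr.r_squared, corr.slope, corr.intercept
    except DegenerateFitError:
        identical = bool(np.allclose(d, d[0]))
        r2 = 1.0 if identical else float("nan")
        slope, intercept = float("nan"), float("nan")
    return AgreementReport(
        n_pairs=int(a.size),
        r_squared=r2,
        fit_slope=slope,
        fit_intercept=intercept,
        bland_bias_mmHg=bias,
        bland_sd_mmHg=sd,
        limits_of_agreement=(bias - 1.96 * sd, bias + 1.96 * sd),
        pass_aami=bool(sd <= AAMI_SD_LIMIT_MMHG),
    )


@dataclass
class SlopeHistogram:
    """Binned distribution of per-patient conversion slopes."""

    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float
    sd: float
    reference: float | None = None


def slope_histogram(per_patient_slopes, bin_width: float, reference: float | None = None) -> SlopeHistogram:
    """Histogram of per-patient fitted gains, with an optional reference
    marker (e.g. a prior-cohort mean) carried through for plotting."""
    slopes = np.asarray(per_patient_slopes, dtype=float)
    if slopes.size < 1:
        raise InsufficientDataError("need at least one fitted slope")
    if not bin_width > 0:
        raise InsufficientDataError("bin_width must be positive")
    lo = np.floor(slopes.min() / bin_width) * bin_width
    hi = np.ceil(slopes.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(slopes, bins=edges)
    return SlopeHistogram(
        counts=counts,
        bin_edges=edges,
        mean=float(np.mean(slopes)),
        sd=float(np.std(slopes, ddof=1)) if slopes.size > 1 else 0.0,
        reference=reference,
    )


def plot_correlation(series_a, series_b, path, label_a="reference", label_b="estimate") -> None:
    """Scatter + OLS line, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    corr = correlation_report(series_a, series_b)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(series_a, series_b, "k.", ms=3)
    xs = np.array([np.min(series_a), np.max(series_a)])
    ax.plot(xs, corr.slope * xs + corr.intercept, "r-", lw=1)
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    ax.set_title(f"R$^2$ = {corr.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(series_a, series_b, path) -> None:
    """Bland-Altman difference-vs-mean plot, written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(series_a, series_b)
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot((a + b) / 2, a - b, "k.", ms=3)
    ax.axhline(report.bland_bias_mmHg, color="b", lw=1)
    for lim in report.limits_of_agreement:
        ax.axhline(lim, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of pair (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    ax.set_title(f"bias {report.bland_bias_mmHg:.2f}, SD {report.bland_sd_mmHg:.2f} mmHg")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
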