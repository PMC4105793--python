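"""Linear conversion of decomposition parameters to blood pressures.

Blood-pressure tracking uses two fixed-gain linear models:

* systole  (mmHg) = ``gain_s`` x P2P1 + ``offset_s``, with gain_s = 100;
* pulse pressure (mmHg) = ``gain_p`` x T13 (ms) + ``offset_p``, with
  gain_p = 0.2;
* diastole = systole - pulse pressure.

The gains are population constants; the offsets are patient specific and
are obtained by chi-square (unweighted least-squares) minimization against
a short reference blood-pressure series, which has the closed form
``offset = mean(ref - gain * x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateFitError, InsufficientDataError, InvalidParameterError

#: Population conversion gains used throughout.
GAIN_SYSTOLE = 100.0  # mmHg per unit P2P1
GAIN_PULSE_PRESSURE = 0.2  # mmHg per ms of T13


@dataclass(frozen=True)
class ConversionModel:
    """A gain/offset pair mapping one decomposition parameter to mmHg.

    ``parameter`` is ``"p2p1"`` (target: systole) or ``"t13"`` (target:
    pulse pressure).  ``calibration_n`` records how many paired beats the
    offset was fitted on (0 for an uncalibrated/assumed offset).
    """

    gain: float
    offset: float
    parameter: str
    calibration_n: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise InvalidParameterError("gain must be positive")
        if self.parameter not in ("p2p1", "t13"):
            raise InvalidParameterError("parameter must be 'p2p1' or 't13'")

    def apply(self, x):
        """pressure = gain * x + offset."""
        return self.gain * np.asarray(x, dtype=float) + self.offset

    def invert(self, pressure):
        """x = (pressure - offset) / gain."""
        return (np.asarray(pressure, dtype=float) - self.offset) / self.gain


@dataclass
class BPSeries:
    """Beat-by-beat converted blood pressures (mmHg)."""

    beat_times_s: np.ndarray
    systole_mmHg: np.ndarray
    diastole_mmHg: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.systole_mmHg = np.asarray(self.systole_mmHg, dtype=float)
        self.diastole_mmHg = np.asarray(self.diastole_mmHg, dtype=float)

    @property
    def pulse_pressure_mmHg(self) -> np.ndarray:
        return self.systole_mmHg - self.diastole_mmHg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.beat_times_s,
                "systole": self.systole_mmHg,
                "diastole": self.diastole_mmHg,
                "pulse_pressure": self.pulse_pressure_mmHg,
            }
        )


def apply_model(model: ConversionModel, parameter_series) -> np.ndarray:
    """Convert a parameter series to pressures: ``gain * x + offset``."""
    return model.apply(parameter_series)


def calibrate_offset(parameter_series, reference_series, gain: float, parameter: str) -> ConversionModel:
    """Fit the patient-specific offset at a fixed population gain.

    Chi-square minimization of ``sum (ref_i - gain*x_i - b)^2`` over the
    offset ``b`` alone has the closed form ``b = mean(ref - gain * x)``;
    no iteration is involved.
    """
    x = np.asarray(parameter_series, dtype=float)
    ref = np.asarray(reference_series, dtype=float)
    if x.shape != ref.shape:
        raise InvalidParameterError("parameter and reference series must be paired")
    if x.size < 2:
        raise InsufficientDataError("offset calibration needs at least 2 paired beats")
    offset = float(np.mean(ref - gain * x))
    return ConversionModel(gain=gain, offset=offset, parameter=parameter, calibration_n=x.size)


def fit_gain(parameter_series, reference_series):
    """Ordinary least-squares fit of reference pressure on the parameter.

    Returns ``(slope, intercept)``.  This is the per-patient fit whose
    slopes populate the cohort gain histograms.
    """
    x = np.asarray(parameter_series, dtype=float)
    ref = np.asarray(reference_series, dtype=float)
    if x.size != ref.size:
        raise InvalidParameterError("parameter and reference series must be paired")
    if x.size < 3:
        raise InsufficientDataError("gain fit needs at least 3 paired beats")
    if np.ptp(x) == 0:
        raise DegenerateFitError("parameter series has zero variance")
    res = scipy.stats.linregress(x, ref)
    return float(res.slope), float(res.intercept)


def to_bp_series(
    beat_times_s,
    p2p1_series,
    t13_series,
    model_s: ConversionModel,
    model_p: ConversionModel,
) -> tuple[BPSeries, int]:
    """Convert aligned P2P1 and T13 series to a blood-pressure series.

    systole from the P2P1 model, pulse pressure from the T13 model,
    diastole as their difference.  Beats yielding a negative diastole are
    excluded; the count of exclusions is returned alongside.
    """
    t = np.asarray(beat_times_s, dtype=float)
    p2p1 = np.asarray(p2p1_series, dtype=float)
    t13 = np.asarray(t13_series, dtype=float)
    if not (t.size == p2p1.size == t13.size):
        raise InvalidParameterError("beat series must be aligned and equal length")
    if model_s.parameter != "p2p1" or model_p.parameter != "t13":
        raise InvalidParameterError("model_s must map p2p1, model_p must map t13")
    systole = model_s.apply(p2p1)
    pp = model_p.apply(t13)
    diastole = systole - pp
    ok = diastole >= 0
    n_excluded = int(np.sum(~ok))
    return BPSeries(t[ok], systole[ok], diastole[ok]), n_excluded
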