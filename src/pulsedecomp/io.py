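"""Delimited-text stream files and their JSON sidecars.

A stream is stored as a two-column comma-delimited text file with a
header row (``time_s,value``), '.' decimal separator, UTF-8.  Metadata —
signal kind, sampling rate, the generating specification and any
ground-truth table — lives in a JSON sidecar next to the stream file
(``<stem>.meta.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StreamFormatError
from .signal import WaveformStream


def sidecar_path(stream_path) -> Path:
    p = Path(stream_path)
    return p.with_name(p.name + ".meta.json")


def write_stream(path, stream: WaveformStream, sidecar: dict | None = None) -> None:
    """Write a stream as two-column CSV plus an optional JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": stream.times, "value": stream.samples})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "kind": stream.kind,
        "sampling_rate": stream.sampling_rate,
        "start_time_s": stream.start_time_s,
        "n_samples": int(stream.samples.size),
    }
    if sidecar:
        meta.update(sidecar)
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_stream(path) -> tuple[WaveformStream, dict]:
    """Read a stream CSV (+ sidecar if present) back into memory.

    The sampling rate is taken from the sidecar when available, otherwise
    inferred from the median time step.  Raises
    :class:`StreamFormatError` on malformed files, naming the offense.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise StreamFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise StreamFormatError(f"{path}: missing required column '{col}'")
    if len(df) < 2:
        raise StreamFormatError(f"{path}: a stream needs at least 2 samples")
    times = df["time_s"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    fs = meta.get("sampling_rate")
    if fs is None:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise StreamFormatError(f"{path}: time column is not strictly increasing")
        fs = 1.0 / float(np.median(steps))
    stream = WaveformStream(
        samples=values,
        sampling_rate=float(fs),
        kind=meta.get("kind", "d1"),
        start_time_s=float(meta.get("start_time_s", times[0])),
    )
    return stream, meta


def write_parameter_table(path, table: pd.DataFrame) -> None:
    """Per-beat parameter CSV (comma-delimited, header row, UTF-8)."""
    table.to_csv(Path(path), index=False, float_format="%.10g")


def read_parameter_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise StreamFormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if df.empty:
        raise StreamFormatError(f"{path}: empty parameter table")
    return df


def write_calibration(path, model, extra: dict | None = None) -> None:
    """Calibration JSON: parameter, gain, offset, calibration_n."""
    payload = {
        "parameter": model.parameter,
        "gain": model.gain,
        "offset": model.offset,
        "calibration_n": model.calibration_n,
    }
    if extra:
        payload.update(extra)
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_calibration(path):
    from .convert import ConversionModel

    with open(Path(path)) as fh:
        payload = json.load(fh)
    return ConversionModel(
        gain=payload["gain"],
        offset=payload["offset"],
        parameter=payload["parameter"],
        calibration_n=payload.get("calibration_n", 0),
    )
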