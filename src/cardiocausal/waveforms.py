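"""Fiducial-point detection and per-beat feature extraction from ECG + PPG.

The per-beat pipeline is:

1. :func:`preprocess` - zero-phase band-pass filtering of both channels and
   smoothed differentiation of the PPG (dPPG, sdPPG).
2. :func:`detect_r_peaks` - ECG R peaks anchor the cardiac cycles.
3. :func:`detect_fiducials` - the eleven PPG/dPPG/sdPPG landmarks per beat,
   located by windowed extremum search between the R anchors; beats whose
   landmark sequence cannot be resolved in the canonical order are flagged
   invalid rather than silently kept.
4. :func:`extract_beat_features` - the 205 registry features of one beat.

All timing is in seconds; sample indices are 0-based; windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .registry import (
    LANDMARKS,
    FeatureDef,
    build_registry,
    feature_column,
)

__all__ = [
    "WaveformRecord",
    "PreprocessedSegment",
    "FiducialSet",
    "QualityError",
    "preprocess",
    "detect_r_peaks",
    "detect_fiducials",
    "extract_beat_features",
    "extract_record_features",
]

log = logging.getLogger(__name__)

#: physiological bounds on the inter-beat interval (s)
RRI_BOUNDS = (0.3, 2.0)


class QualityError(ValueError):
    """Segment fails basic signal-quality requirements."""


@dataclass
class WaveformRecord:
    """One subject's paired ECG/PPG segments.

    ``segments`` is a list of ``(ecg, ppg)`` sample arrays of equal length
    (per segment).  ``meta`` may carry generator ground truth (beat
    schedules, pulse parameters) or acquisition annotations.
    """

    subject_id: str
    sampling_rate_hz: float
    segments: list[tuple[np.ndarray, np.ndarray]]
    label: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        for k, (ecg, ppg) in enumerate(self.segments):
            if len(ecg) != len(ppg):
                raise ValueError(
                    f"segment {k}: ECG and PPG lengths differ ({len(ecg)} vs {len(ppg)})"
                )


@dataclass
class PreprocessedSegment:
    segment_id: int
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    dppg: np.ndarray
    sdppg: np.ndarray


@dataclass
class FiducialSet:
    """The eleven landmark times/values of one beat.

    ``landmark_times_s`` maps landmark name -> time (s from segment start)
    in the canonical order; values are read off the landmark's own channel
    (PPG landmarks from the PPG, dPPG/sdPPG landmarks from the respective
    derivative).  ``valid`` is False when the landmark sequence could not be
    resolved; ``reason`` then carries a diagnostic code.
    """

    beat_index: int
    r_peak_time_s: float
    rri_s: float
    landmark_times_s: dict[str, float]
    landmark_values: dict[str, float]
    valid: bool = True
    reason: str | None = None


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

ECG_BAND = (0.5, 40.0)
PPG_BAND = (0.5, 8.0)


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _savgol_window(fs: float) -> int:
    w = int(round(0.07 * fs))
    w = max(w, 5)
    return w + 1 if w % 2 == 0 else w


def preprocess(
    record: WaveformRecord, min_duration_s: float = 3.0
) -> list[PreprocessedSegment]:
    """Filter both channels (zero-phase, so no inter-channel lag) and compute
    the smoothed first/second PPG derivatives.

    Segments shorter than ``min_duration_s``, non-finite or flat are dropped
    with a log entry; an empty result means no segment survived.
    """
    fs = record.sampling_rate_hz
    win = _savgol_window(fs)
    out: list[PreprocessedSegment] = []
    for k, (ecg, ppg) in enumerate(record.segments):
        try:
            ecg = np.asarray(ecg, dtype=float)
            ppg = np.asarray(ppg, dtype=float)
            if len(ecg) < min_duration_s * fs:
                raise QualityError(f"segment {k}: shorter than {min_duration_s} s")
            if not (np.all(np.isfinite(ecg)) and np.all(np.isfinite(ppg))):
                raise QualityError(f"segment {k}: non-finite samples")
            if np.ptp(ecg) == 0 or np.ptp(ppg) == 0:
                raise QualityError(f"segment {k}: flat channel")
            ecg_f = _bandpass(ecg, fs, ECG_BAND)
            ppg_f = _bandpass(ppg, fs, PPG_BAND)
            dppg = signal.savgol_filter(ppg_f, win, 3, deriv=1, delta=1.0 / fs)
            sdppg = signal.savgol_filter(ppg_f, win, 3, deriv=2, delta=1.0 / fs)
            out.append(PreprocessedSegment(k, fs, ecg_f, ppg_f, dppg, sdppg))
        except QualityError as err:
            log.warning("dropping segment: %s (subject %s)", err, record.subject_id)
    return out


# ---------------------------------------------------------------------------
# R peaks
# ---------------------------------------------------------------------------


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (s) of a preprocessed ECG.

    Peaks are prominences exceeding half the robust signal maximum, at least
    0.3 s apart.  Returns an empty array (with a warning) when nothing
    resembling a QRS complex is present.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0 or np.ptp(ecg) == 0:
        log.warning("no R peaks: flat or empty ECG")
        return np.array([])
    amp = np.percentile(ecg, 99.8)
    if amp <= 0:
        log.warning("no R peaks: non-positive ECG excursion")
        return np.array([])
    idx, _ = signal.find_peaks(
        ecg, height=0.5 * amp, distance=max(1, int(RRI_BOUNDS[0] * fs))
    )
    if idx.size == 0:
        log.warning("no R peaks found")
    return idx / fs


# ---------------------------------------------------------------------------
# fiducial landmarks
# ---------------------------------------------------------------------------


def _argmax_in(x: np.ndarray, lo: int, hi: int) -> int | None:
    """Index of the maximum of x over the half-open window [lo, hi)."""
    lo, hi = max(lo, 0), min(hi, len(x))
    if hi <= lo:
        return None
    return lo + int(np.argmax(x[lo:hi]))


def _argmin_in(x: np.ndarray, lo: int, hi: int) -> int | None:
    lo, hi = max(lo, 0), min(hi, len(x))
    if hi <= lo:
        return None
    return lo + int(np.argmin(x[lo:hi]))


def detect_fiducials(
    ppg: np.ndarray,
    dppg: np.ndarray,
    sdppg: np.ndarray,
    r_times: np.ndarray,
    fs: float,
) -> list[FiducialSet]:
    """Locate the eleven landmarks of each beat between consecutive R peaks.

    The search runs in the canonical temporal order, each landmark's window
    bounded by the previous one, which enforces the strictly-increasing
    ordering by construction; beats whose windows collapse (e.g. a monotone
    ramp with no dicrotic activity) or whose R-R interval is outside
    physiological bounds come back flagged invalid with a reason code.
    The last R peak anchors no beat (it has no following pulse onset).
    """
    r_idx = np.round(np.asarray(r_times) * fs).astype(int)
    n_beats = len(r_idx) - 1
    if n_beats < 1:
        return []

    # first pass: systolic peak and pulse onset (valley) for every anchor
    peaks: list[int | None] = []
    valleys: list[int | None] = []
    for k in range(len(r_idx)):
        rri = (
            r_idx[k + 1] - r_idx[k]
            if k + 1 < len(r_idx)
            else int(np.median(np.diff(r_idx)))
        )
        p = _argmax_in(ppg, r_idx[k] + int(0.08 * fs), r_idx[k] + int(0.65 * rri))
        v = _argmin_in(ppg, r_idx[k], p) if p is not None else None
        peaks.append(p)
        valleys.append(v)

    out: list[FiducialSet] = []
    for k in range(n_beats):
        r_t = r_idx[k] / fs
        rri = (r_idx[k + 1] - r_idx[k]) / fs

        def invalid(reason: str) -> FiducialSet:
            return FiducialSet(k, r_t, rri, {}, {}, valid=False, reason=reason)

        if not (RRI_BOUNDS[0] <= rri <= RRI_BOUNDS[1]):
            out.append(invalid("rri_out_of_bounds"))
            continue
        peak, valley, nxt = peaks[k], valleys[k], valleys[k + 1]
        if peak is None or valley is None or nxt is None:
            out.append(invalid("no_systolic_peak"))
            continue
        dp = _argmax_in(dppg, valley + 1, peak)
        a = _argmax_in(sdppg, valley + 1, dp) if dp is not None else None
        b = _argmin_in(sdppg, dp + 1, peak) if dp is not None else None
        c = _argmax_in(sdppg, peak + 1, nxt)
        d = _argmin_in(sdppg, c + 1, nxt) if c is not None else None
        dv = _argmin_in(dppg, d + 1, nxt) if d is not None else None
        e = _argmax_in(sdppg, dv + 1, nxt) if dv is not None else None
        f = _argmin_in(sdppg, e + 1, nxt) if e is not None else None
        marks = [valley, a, dp, b, peak, c, d, dv, e, f, nxt]
        if any(m is None for m in marks):
            out.append(invalid("unresolved_landmark"))
            continue
        if any(m2 <= m1 for m1, m2 in zip(marks, marks[1:])):
            out.append(invalid("landmarks_out_of_order"))
            continue
        channels = {"ppg": ppg, "dppg": dppg, "sdppg": sdppg}
        times = {lm: m / fs for lm, m in zip(LANDMARKS, marks)}
        values = {
            lm: float(channels[_owning_channel(lm)][m])
            for lm, m in zip(LANDMARKS, marks)
        }
        out.append(FiducialSet(k, r_t, rri, times, values))
    return out


def _owning_channel(landmark: str) -> str:
    if landmark.startswith("sdppg"):
        return "sdppg"
    if landmark.startswith("dppg"):
        return "dppg"
    return "ppg"


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

_EPS = 1e-9


def extract_beat_features(
    fid: FiducialSet,
    ppg: np.ndarray,
    dppg: np.ndarray,
    sdppg: np.ndarray,
    fs: float,
) -> np.ndarray:
    """The 205 registry features of one valid beat, as a float vector.

    Ratio indices whose denominator vanishes are reported as NaN rather
    than raising; downstream aggregation is NaN-aware.
    """
    if not fid.valid:
        raise ValueError(f"beat {fid.beat_index} is invalid ({fid.reason})")
    t = fid.landmark_times_s
    idx = {lm: int(round(t[lm] * fs)) for lm in LANDMARKS}
    chan = {"ppg": ppg, "dppg": dppg, "sdppg": sdppg}
    vals = np.empty(205, dtype=float)
    for fd in build_registry():
        vals[fd.index - 1] = _one_feature(fd, fid, t, idx, chan, fs)
    return vals


def _area(ppg: np.ndarray, i: int, j: int, fs: float) -> float:
    return float(np.trapezoid(ppg[i : j + 1], dx=1.0 / fs))


def _one_feature(
    fd: FeatureDef,
    fid: FiducialSet,
    t: dict[str, float],
    idx: dict[str, int],
    chan: dict[str, np.ndarray],
    fs: float,
) -> float:
    kind = fd.kind
    if kind == "ptt":
        return t[fd.params[0]] - fid.r_peak_time_s
    if kind == "rri":
        return fid.rri_s
    if kind == "td":
        li, lj = fd.params
        return t[lj] - t[li]
    if kind == "am":
        li, lj = fd.params
        return float(chan["ppg"][idx[lj]] - chan["ppg"][idx[li]])
    if kind == "ai":
        ch, lm = fd.params
        return float(chan[ch][idx[lm]])
    if kind == "ar":
        li, lj = fd.params
        return _area(chan["ppg"], idx[li], idx[lj], fs)
    if kind == "ri":
        return _ratio_index(fd.params[0], fid, t, idx, chan, fs)
    raise ValueError(f"unknown feature kind {kind!r}")  # pragma: no cover


def _ratio_index(
    name: str,
    fid: FiducialSet,
    t: dict[str, float],
    idx: dict[str, int],
    chan: dict[str, np.ndarray],
    fs: float,
) -> float:
    ppg, dppg, sdppg = chan["ppg"], chan["dppg"], chan["sdppg"]
    rri = fid.rri_s

    def safe(num: float, den: float) -> float:
        return num / den if abs(den) > _EPS else float("nan")

    pv = float(ppg[idx["ppg_valley"]])
    pp = float(ppg[idx["ppg_peak"]])
    amp = pp - pv
    sa = float(sdppg[idx["sdppg_a"]])
    rise = t["ppg_peak"] - t["ppg_valley"]
    fall = t["ppg_valley_next"] - t["ppg_peak"]
    if name == "relative_rising_time":
        return safe(rise, rri)
    if name == "relative_falling_time":
        return safe(fall, rri)
    if name == "rise_fall_ratio":
        return safe(rise, fall)
    if name == "relative_crest_time":
        return safe(t["dppg_peak"] - t["ppg_valley"], rri)
    if name == "relative_c_wave_time":
        return safe(t["sdppg_c"] - t["ppg_valley"], rri)
    if name == "relative_notch_time":
        return safe(t["dppg_valley"] - t["ppg_valley"], rri)
    if name == "late_systolic_width_ratio":
        return safe(t["sdppg_d"] - t["sdppg_b"], rri)
    if name == "slope_transit_time_ratio":
        return safe(safe(amp, float(dppg[idx["dppg_peak"]])), rri)
    if name == "augmentation_index":
        return safe(float(ppg[idx["sdppg_c"]]) - pv, amp)
    if name == "dicrotic_diastolic_ratio":
        return safe(float(ppg[idx["dppg_valley"]]) - pv, amp)
    if name == "sdppg_cdb_a":
        return safe(
            float(sdppg[idx["sdppg_c"]])
            + float(sdppg[idx["sdppg_d"]])
            - float(sdppg[idx["sdppg_b"]]),
            sa,
        )
    if name == "inflection_point_area_ratio":
        a1 = _area(ppg, idx["ppg_valley"], idx["dppg_valley"], fs)
        a2 = _area(ppg, idx["dppg_valley"], idx["ppg_valley_next"], fs)
        return safe(a2, a1)
    if name == "sdppg_b_a":
        return safe(float(sdppg[idx["sdppg_b"]]), sa)
    if name == "sdppg_c_a":
        return safe(float(sdppg[idx["sdppg_c"]]), sa)
    if name == "sdppg_d_a":
        return safe(float(sdppg[idx["sdppg_d"]]), sa)
    if name == "sdppg_e_a":
        return safe(float(sdppg[idx["sdppg_e"]]), sa)
    if name == "sdppg_f_a":
        return safe(float(sdppg[idx["sdppg_f"]]), sa)
    if name == "aging_index":
        return safe(
            float(sdppg[idx["sdppg_b"]])
            - float(sdppg[idx["sdppg_c"]])
            - float(sdppg[idx["sdppg_d"]])
            - float(sdppg[idx["sdppg_e"]]),
            sa,
        )
    if name == "ppg_intensity_ratio":
        return safe(pp, pv)
    if name == "perfusion_index":
        beat = ppg[idx["ppg_valley"] : idx["ppg_valley_next"] + 1]
        return safe(amp, float(np.mean(beat)))
    raise ValueError(f"unknown ratio index {name!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# record-level convenience
# ---------------------------------------------------------------------------


def extract_record_features(record: WaveformRecord) -> pd.DataFrame:
    """Tidy per-beat feature table for one subject.

    Columns: ``subject_id, segment_id, beat_index, f001..f205``.  Only valid
    beats are emitted; invalid beats are counted in the log.
    """
    cols = [feature_column(i) for i in range(1, 206)]
    rows: list[dict] = []
    n_invalid = 0
    for seg in preprocess(record):
        r_times = detect_r_peaks(seg.ecg, seg.fs)
        if len(r_times) < 2:
            continue
        for fid in detect_fiducials(seg.ppg, seg.dppg, seg.sdppg, r_times, seg.fs):
            if not fid.valid:
                n_invalid += 1
                continue
            vec = extract_beat_features(fid, seg.ppg, seg.dppg, seg.sdppg, seg.fs)
            row = {
                "subject_id": record.subject_id,
                "segment_id": seg.segment_id,
                "beat_index": fid.beat_index,
            }
            row.update(dict(zip(cols, vec)))
            rows.append(row)
    if n_invalid:
        log.info("subject %s: %d invalid beats skipped", record.subject_id, n_invalid)
    return pd.DataFrame(rows, columns=["subject_id", "segment_id", "beat_index", *cols])
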