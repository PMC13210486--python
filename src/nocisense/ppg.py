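"""PPG filtering, envelope-gated pulse-peak detection and 4 Hz heart rate.

The pulse chain: band-pass the raw photoplethysmogram to isolate pulse
morphology, detect one systolic peak per cardiac cycle with a waveform
envelope peak detector (WEPD-style: a short squared-signal envelope gated
against a beat-scale envelope, so dicrotic notches are not double counted),
apply a deterministic false-peak correction, and interpolate the beatwise
heart rate onto the common 4 Hz grid with a monotone piecewise-cubic
(PCHIP) interpolant, which cannot overshoot between beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "PulseSeries",
    "HeartRateSignal",
    "filter_ppg",
    "detect_peaks_wepd",
    "apply_peak_edits",
    "correct_false_peaks",
    "hr_signal",
]

PPG_FS = 50.0
#: physiologic peak-to-peak interval bounds (ms); 30-200 bpm
PPI_BOUNDS = (300.0, 2000.0)


@dataclass(frozen=True)
class PulseSeries:
    """Detected pulse peaks and the peak-to-peak intervals between them.

    ``ppi[i]`` is the interval (ms) between ``peak_times[i]`` and
    ``peak_times[i+1]``; ``valid_mask[i]`` marks intervals surviving
    false-peak correction.
    """

    peak_times: np.ndarray  # seconds, strictly increasing
    valid_mask: np.ndarray | None = None
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        object.__setattr__(self, "peak_times", pt)
        if len(pt) > 1 and not np.all(np.diff(pt) > 0):
            raise ValueError("peak_times must be strictly increasing")
        if self.valid_mask is None:
            object.__setattr__(self, "valid_mask",
                               np.ones(max(len(pt) - 1, 0), dtype=bool))
        else:
            vm = np.asarray(self.valid_mask, dtype=bool)
            if len(vm) != max(len(pt) - 1, 0):
                raise ValueError("valid_mask must have len(peak_times) - 1 entries")
            object.__setattr__(self, "valid_mask", vm)

    @property
    def ppi(self) -> np.ndarray:
        """All successive intervals in milliseconds."""
        return np.diff(self.peak_times) * 1000.0

    @property
    def valid_ppi(self) -> np.ndarray:
        return self.ppi[self.valid_mask]


@dataclass(frozen=True)
class HeartRateSignal:
    t: np.ndarray  # seconds, 4 Hz grid
    hr: np.ndarray  # beats/min

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        m = (self.t >= t_start) & (self.t < t_end)
        return self.hr[m]


def filter_ppg(samples: np.ndarray, fs: float = PPG_FS,
               band: tuple[float, float] = (0.5, 8.0), order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass retaining pulse morphology.

    The 0.5 Hz high-pass removes baseline wander; the 8 Hz low-pass keeps
    the systolic upstroke and dicrotic notch while suppressing sensor noise.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input sample")
    sos = signal.butter(order, band, btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(width, 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_peaks_wepd(
    ppg: np.ndarray,
    fs: float = PPG_FS,
    t0: float = 0.0,
    pulse_window: float = 0.125,
    beat_window: float = 1.3,
    min_block_width: float = 0.1,
    offset_scale: float = 0.02,
) -> PulseSeries:
    """Envelope-gated systolic-peak detection.

    The squared filtered signal is smoothed with two moving averages — one
    at pulse-width scale, one at beat scale. Wherever the short envelope
    exceeds the long envelope (plus a small amplitude-scaled offset that
    rejects flat records) a candidate block opens; blocks narrower than
    *min_block_width* seconds are discarded and each surviving block
    contributes the maximum of the filtered signal as one peak. The beat-
    scale gate keeps dicrotic notches inside the same block as their
    systolic peak, so they are never double counted.
    """
    x = np.asarray(ppg, dtype=float)
    if len(x) < 3 * fs:
        raise ValueError("need at least 3 s of signal")
    sq = np.square(x)
    env_short = _moving_average(sq, int(round(pulse_window * fs)))
    env_long = _moving_average(sq, int(round(beat_window * fs)))
    offset = offset_scale * sq.mean()
    gate = env_short > env_long + offset

    if not gate.any():
        warnings.warn("no detectable pulsatility; returning empty pulse series")
        return PulseSeries(peak_times=np.array([]), flagged_empty=True)

    edges = np.flatnonzero(np.diff(gate.astype(int)))
    starts = edges[gate[edges + 1]] + 1
    ends = edges[~gate[edges + 1]] + 1
    if gate[0]:
        starts = np.concatenate([[0], starts])
    if gate[-1]:
        ends = np.concatenate([ends, [len(x)]])

    min_width = int(round(min_block_width * fs))
    peaks = []
    for s, e in zip(starts, ends):
        if e - s < min_width:
            continue
        peaks.append(s + int(np.argmax(x[s:e])))
    if not peaks:
        warnings.warn("no detectable pulsatility; returning empty pulse series")
        return PulseSeries(peak_times=np.array([]), flagged_empty=True)
    return PulseSeries(peak_times=t0 + np.asarray(peaks) / fs)


def apply_peak_edits(pulses: PulseSeries, edits: dict,
                     match_tol: float = 0.05) -> PulseSeries:
    """Apply a reproducible hand-override sidecar before PPI computation.

    *edits* is ``{"add": [times], "remove": [times]}`` in seconds; removals
    match the nearest detected peak within *match_tol* seconds (unmatched
    removals are ignored), additions are inserted in time order.
    """
    times = list(pulses.peak_times)
    for t_rm in edits.get("remove", []):
        if not times:
            break
        j = int(np.argmin(np.abs(np.asarray(times) - t_rm)))
        if abs(times[j] - t_rm) <= match_tol:
            times.pop(j)
    for t_add in edits.get("add", []):
        if not times or np.min(np.abs(np.asarray(times) - t_add)) > 1e-9:
            times.append(float(t_add))
    return PulseSeries(peak_times=np.sort(times),
                       flagged_empty=pulses.flagged_empty)


def correct_false_peaks(
    pulses: PulseSeries,
    limits: tuple[float, float] = PPI_BOUNDS,
    jump_ratio: float = 0.4,
    median_window: int = 5,
) -> PulseSeries:
    """Deterministic replacement for manual false-peak editing.

    Two rules, applied in one left-to-right pass over the intervals:

    1. A spuriously detected extra peak splits one beat into two short
       intervals; when merging the peak away restores an interval close to
       the running median (within *jump_ratio*), the peak is removed.
    2. Any remaining interval outside *limits*, or deviating from the
       running median of the previous *median_window* valid intervals by
       more than *jump_ratio*, is flagged invalid — never fabricated.
    """
    times = list(pulses.peak_times)
    if len(times) < 3:
        return pulses

    # pass 1: merge double-detections
    merged = [times[0]]
    history: list[float] = []
    i = 1
    while i < len(times):
        ppi = (times[i] - merged[-1]) * 1000.0
        ref = float(np.median(history[-median_window:])) if history else None
        is_short = ppi < limits[0] or (
            ref is not None and ppi < (1 - jump_ratio) * ref)
        if is_short and i + 1 < len(times):
            merged_ppi = (times[i + 1] - merged[-1]) * 1000.0
            ok_merged = limits[0] <= merged_ppi <= limits[1] and (
                ref is None or abs(merged_ppi - ref) <= jump_ratio * ref)
            if ok_merged:
                i += 1  # skip the spurious peak
                continue
        merged.append(times[i])
        if limits[0] <= ppi <= limits[1]:
            history.append(ppi)
        i += 1

    # pass 2: flag out-of-bounds / jump intervals
    merged_arr = np.asarray(merged)
    ppis = np.diff(merged_arr) * 1000.0
    valid = np.ones(len(ppis), dtype=bool)
    history = []
    for j, ppi in enumerate(ppis):
        ok = limits[0] <= ppi <= limits[1]
        if ok and history:
            ref = float(np.median(history[-median_window:]))
            ok = abs(ppi - ref) <= jump_ratio * ref
        valid[j] = ok
        if ok:
            history.append(float(ppi))
    return PulseSeries(peak_times=merged_arr, valid_mask=valid,
                       flagged_empty=pulses.flagged_empty)


def hr_signal(pulses: PulseSeries, target_fs: float = 4.0) -> HeartRateSignal:
    """Beatwise HR (60000/PPI at interval midpoints) PCHIP-interpolated to 4 Hz.

    The monotone interpolant is exact at the knots and cannot overshoot the
    beatwise HR range between them. Only valid-flagged intervals contribute
    knots.
    """
    pt = pulses.peak_times
    if len(pt) < 2:
        raise ValueError("insufficient beats: need at least 2 valid peaks")
    mid = (pt[:-1] + pt[1:]) / 2.0
    hr = 60000.0 / pulses.ppi
    mid, hr = mid[pulses.valid_mask], hr[pulses.valid_mask]
    if len(mid) == 0:
        raise ValueError("insufficient beats: no valid intervals")
    if len(mid) == 1:
        grid = np.arange(np.ceil(mid[0] * target_fs),
                         np.floor(mid[0] * target_fs) + 1) / target_fs
        return HeartRateSignal(t=grid, hr=np.full(len(grid), hr[0]))
    interp = interpolate.PchipInterpolator(mid, hr)
    grid = np.arange(np.ceil(mid[0] * target_fs),
                     np.floor(mid[-1] * target_fs) + 1) / target_fs
    return HeartRateSignal(t=grid, hr=interp(grid))
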