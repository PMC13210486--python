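"""Per-segment feature extraction for ultra-short (<=10 s) windows.

Each trial contributes two analysis windows: the 10 s anticipation
countdown before the stimulus (anxiety window) and the 10 s of stimulation
(pain window). A per-session baseline window from the pre-test rest
provides the reference for baseline normalization. From each window the
registry below is computed over the continuous subsignals (SCL, SCR,
TVSymp, MTVSymp, filtered EDA, HR, PPI), producing a raw value and a
baseline-subtracted variant of every feature.

Feature registry (raw names; append ``_bn`` for the baseline-normalized
variant):

==================  =====================================================
nsscr               upward 0.05 µS threshold crossings of the SCR series
scl_mean/var/max    tonic level statistics (µS)
scl_slope           OLS slope of SCL vs time (µS/s)
scl_stp             slope from SCL maximum back to preceding trough/elbow
tvsymp_mean/max     sympathetic-band instantaneous amplitude (normalized)
mtvsymp_mean/max    trailing-mean-excess variant
tvsymp_n_*          TVSymp statistics / total segment EDA power
mtvsymp_n_*         MTVSymp statistics / total segment EDA power
tvsymp_stp          slope to TVSymp maximum
mtvsymp_stp         slope to MTVSymp maximum
total_eda_power     Welch power over 0-2 Hz (µS²)
edasymp             Welch power in the sympathetic band (µS²)
edasymp_n           edasymp / total_eda_power
hjorth_activity     variance of filtered EDA
hjorth_mobility     RMS-frequency proxy
hjorth_complexity   bandwidth proxy
hr_mean, hr_range   4 Hz heart-rate statistics (bpm)
ppi_sd, ppi_rmssd   pulse-interval variability (ms)
==================  =====================================================

Features that cannot be computed (too few beats in a window) are missing
(NaN), never zero; imputation happens later inside training folds only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nocisense import eda as eda_mod
from nocisense import ppg as ppg_mod
from nocisense.signal_io import Session

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_REGISTRY",
    "Segment",
    "FeatureVector",
    "ProcessedSession",
    "process_session",
    "segment_session",
    "nsscr",
    "hjorth",
    "scl_slope",
    "slope_to_peak",
    "prv_features",
    "spectral_features",
    "power_normalize",
    "extract_features",
    "baseline_normalize",
    "build_feature_table",
]

#: closed registry — extraction never emits a feature outside this list
FEATURE_REGISTRY: tuple[str, ...] = (
    "nsscr",
    "scl_mean", "scl_var", "scl_max", "scl_slope", "scl_stp",
    "tvsymp_mean", "tvsymp_max", "mtvsymp_mean", "mtvsymp_max",
    "tvsymp_n_mean", "tvsymp_n_max", "mtvsymp_n_mean", "mtvsymp_n_max",
    "tvsymp_stp", "mtvsymp_stp",
    "total_eda_power", "edasymp", "edasymp_n",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "hr_mean", "hr_range", "ppi_sd", "ppi_rmssd",
)

METADATA_COLUMNS = ("subject_id", "trial_index", "modality", "level",
                    "phase", "anxiety_vas", "pain_vas")

MIN_SEGMENT_S = 5.0
NSSCR_THRESHOLD = 0.05  # µS


@dataclass(frozen=True)
class ProcessedSession:
    """Whole-recording subsignals computed once per session."""

    session: Session
    t4: np.ndarray  # 4 Hz time grid (shared by the EDA-derived subsignals)
    eda_filtered: np.ndarray
    scl: np.ndarray
    scr: np.ndarray
    tvsymp: np.ndarray
    mtvsymp: np.ndarray
    pulses: ppg_mod.PulseSeries
    hr: ppg_mod.HeartRateSignal


@dataclass(frozen=True)
class Segment:
    subject_id: str
    trial_index: int
    modality: str
    level: int
    phase: str
    t_start: float
    t_end: float
    t4: np.ndarray
    eda: np.ndarray
    scl: np.ndarray
    scr: np.ndarray
    tvsymp: np.ndarray
    mtvsymp: np.ndarray
    hr: np.ndarray
    pulses: ppg_mod.PulseSeries

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    trial_index: int
    modality: str
    level: int
    phase: str
    anxiety_vas: int | None
    pain_vas: int | None
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.values) - set(FEATURE_REGISTRY)
        if extra:
            raise ValueError(f"features outside the registry: {sorted(extra)}")


def process_session(session: Session, decomposition: str = "cvx") -> ProcessedSession:
    """Run the full subsignal chain on one session's continuous recordings.

    EDA: filter -> tonic/phasic decomposition -> VFCDM -> TVSymp/MTVSymp,
    all over the entire recording (the TVSymp variance normalization spans
    the whole session so between-segment amplitude differences survive).
    PPG: filter -> envelope peak detection -> false-peak correction -> 4 Hz
    HR by monotone interpolation.
    """
    eda_f = eda_mod.filter_eda(session.eda.samples, fs=session.eda.sampling_rate)
    dec = eda_mod.decompose_eda(eda_f, fs=session.eda.sampling_rate,
                                method=decomposition)
    tf = eda_mod.vfcdm(eda_f, fs=session.eda.sampling_rate)
    tv = eda_mod.compute_tvsymp(tf)
    mtv = eda_mod.compute_mtvsymp(tv, fs=session.eda.sampling_rate)

    ppg_f = ppg_mod.filter_ppg(session.ppg.samples, fs=session.ppg.sampling_rate)
    pulses = ppg_mod.detect_peaks_wepd(ppg_f, fs=session.ppg.sampling_rate,
                                       t0=session.ppg.t0)
    pulses = ppg_mod.correct_false_peaks(pulses)
    hr = ppg_mod.hr_signal(pulses)

    return ProcessedSession(
        session=session, t4=session.eda.times, eda_filtered=eda_f,
        scl=dec.scl, scr=dec.scr, tvsymp=tv, mtvsymp=mtv,
        pulses=pulses, hr=hr)


def _segment_view(proc: ProcessedSession, trial_index: int, modality: str,
                  level: int, phase: str, t_start: float, t_end: float) -> Segment:
    m = (proc.t4 >= t_start) & (proc.t4 < t_end)
    pt = proc.pulses.peak_times
    in_win = (pt >= t_start) & (pt < t_end)
    idx = np.flatnonzero(in_win)
    if idx.size:
        sub = ppg_mod.PulseSeries(
            peak_times=pt[idx],
            valid_mask=proc.pulses.valid_mask[idx[0]:idx[-1]] if idx.size > 1 else None)
    else:
        sub = ppg_mod.PulseSeries(peak_times=np.array([]))
    return Segment(
        subject_id=proc.session.subject_id, trial_index=trial_index,
        modality=modality, level=level, phase=phase,
        t_start=t_start, t_end=t_end,
        t4=proc.t4[m], eda=proc.eda_filtered[m], scl=proc.scl[m],
        scr=proc.scr[m], tvsymp=proc.tvsymp[m], mtvsymp=proc.mtvsymp[m],
        hr=proc.hr.slice(t_start, t_end), pulses=sub)


def segment_session(proc: ProcessedSession,
                    min_duration: float = MIN_SEGMENT_S,
                    include_rampdown: bool = False) -> list[Segment]:
    """One anticipation + one stimulation segment per trial, plus the
    session baseline; half-open slicing; segments shorter than
    *min_duration* are dropped with a warning (early withdrawals).
    """
    sess = proc.session
    segments: list[Segment] = []
    b0, b1 = sess.baseline_window
    segments.append(_segment_view(proc, -1, "NONE", 0, "baseline", b0, b1))
    wanted = ("anticipation", "stimulation") + (("rampdown",) if include_rampdown else ())
    for ti in sess.trial_indices:
        for marker in sess.trial_markers(ti):
            if marker.phase not in wanted:
                continue
            if marker.t_start < proc.t4[0] - 1e-9 or marker.t_end > proc.t4[-1] + 1.0:
                raise ValueError(
                    f"trial {ti} {marker.phase} marker not covered by subsignals")
            if marker.duration < min_duration:
                logger.warning(
                    "dropping %s segment of trial %s (%.1f s < %.1f s minimum)",
                    marker.phase, ti, marker.duration, min_duration)
                continue
            segments.append(_segment_view(
                proc, ti, marker.modality, marker.level, marker.phase,
                marker.t_start, marker.t_end))
    return segments


# ---------------------------------------------------------------------------
# individual feature operations

def nsscr(scr: np.ndarray, threshold: float = NSSCR_THRESHOLD) -> int:
    """Count of non-specific SCRs: upward crossings of *threshold*.

    A crossing at index t requires ``scr[t] >= threshold`` and
    ``scr[t-1] < threshold``; a series that starts above threshold and
    never dips below contributes no crossing.
    """
    x = np.asarray(scr, dtype=float)
    if len(x) < 2:
        return 0
    above = x >= threshold
    return int(np.count_nonzero(above[1:] & ~above[:-1]))


def hjorth(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Hjorth Activity, Mobility and Complexity of a sampled signal.

    Activity is the (population) variance; Mobility the ratio
    ``sqrt(var(x') / var(x))`` — an RMS-frequency proxy in rad-free units
    of Hz when the derivative is the first difference scaled by *fs*; and
    Complexity the mobility of the derivative over the mobility of the
    signal, a bandwidth proxy that equals 1 for a pure sinusoid.
    Zero-variance (constant) input returns ``(0, 0, 0)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return (0.0, 0.0, 0.0)
    activity = float(np.var(x))
    if activity == 0.0:
        return (0.0, 0.0, 0.0)
    dx = np.diff(x) * fs
    var_dx = float(np.var(dx))
    mobility = float(np.sqrt(var_dx / activity))
    if var_dx == 0.0:
        return (activity, 0.0, 0.0)
    ddx = np.diff(dx) * fs
    mobility_dx = float(np.sqrt(np.var(ddx) / var_dx))
    return (activity, mobility, mobility_dx / mobility if mobility > 0 else 0.0)


def scl_slope(scl: np.ndarray, t: np.ndarray) -> float:
    """Ordinary least-squares slope of the tonic level against time (µS/s)."""
    scl = np.asarray(scl, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(scl) < 2:
        return 0.0
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(tc, scl - scl.mean()) / denom)


def slope_to_peak(sig: np.ndarray, t: np.ndarray) -> float:
    """Rise rate into the segment's global maximum (units/s).

    Anchor selection: the last local minimum before the maximum; if the
    rise is monotone from the segment start, the point of maximum curvature
    (largest second difference) on the rise; segment start as the final
    fallback. Returns 0 when the maximum is the first sample.
    """
    x = np.asarray(sig, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(x) < 3:
        return 0.0
    peak = int(np.argmax(x))
    if peak == 0:
        return 0.0
    anchor = None
    for i in range(peak - 1, 0, -1):
        if x[i] <= x[i - 1] and x[i] <= x[i + 1]:
            anchor = i
            break
    if anchor is None:
        # monotone rise: elbow = maximum-curvature point (second-difference extremum)
        if peak >= 2:
            d2 = np.diff(x[: peak + 1], n=2)
            anchor = int(np.argmax(d2)) + 1
        else:
            anchor = 0
    dt = t[peak] - t[anchor]
    if dt <= 0:
        return 0.0
    return float((x[peak] - x[anchor]) / dt)


def prv_features(segment: Segment) -> dict[str, float]:
    """Mean HR, HR range, PPI s.d. and RMSSD for one window.

    HR statistics use the 4 Hz interpolated series over the window; the PPI
    statistics use valid intervals whose two bounding peaks both fall inside
    the window. RMSSD follows the root-mean-square of successive interval
    differences; with fewer than two intervals (or successive pairs) the
    corresponding features are missing (NaN), not zero.
    """
    out = {"hr_mean": np.nan, "hr_range": np.nan,
           "ppi_sd": np.nan, "ppi_rmssd": np.nan}
    if len(segment.hr):
        out["hr_mean"] = float(np.mean(segment.hr))
        out["hr_range"] = float(np.max(segment.hr) - np.min(segment.hr))
    ppi = segment.pulses.ppi
    valid = segment.pulses.valid_mask
    vppi = ppi[valid]
    if len(vppi) >= 2:
        out["ppi_sd"] = float(np.std(vppi))
    diffs = [ppi[i + 1] - ppi[i]
             for i in range(len(ppi) - 1) if valid[i] and valid[i + 1]]
    if len(diffs) >= 1 and len(vppi) >= 2:
        out["ppi_rmssd"] = float(np.sqrt(np.mean(np.square(diffs))))
    return out


def spectral_features(eda_segment: np.ndarray, fs: float = 4.0) -> dict[str, float]:
    """Total 0-2 Hz Welch power, sympathetic-band power, and their ratio."""
    summary = eda_mod.welch_summary(eda_segment, fs=fs, nperseg=len(eda_segment))
    total = summary.total_power
    ratio = summary.edasymp / total if total > 0 else 0.0
    return {"total_eda_power": total, "edasymp": summary.edasymp,
            "edasymp_n": ratio}


def power_normalize(values: dict[str, float], total_power: float) -> dict[str, float]:
    """Divide time-frequency amplitude features by total segment EDA power.

    Reduces between-subject amplitude variance; zero total power maps every
    normalized value to 0 (with a logged warning).
    """
    if total_power < 0:
        raise ValueError("total_power must be >= 0")
    if total_power == 0:
        logger.warning("zero total EDA power; normalized features set to 0")
        return {k: 0.0 for k in values}
    return {k: v / total_power for k, v in values.items()}


def extract_features(segment: Segment) -> dict[str, float]:
    """Compute the full registry for one segment (raw values)."""
    v: dict[str, float] = {}
    v["nsscr"] = float(nsscr(segment.scr))
    v["scl_mean"] = float(np.mean(segment.scl))
    v["scl_var"] = float(np.var(segment.scl))
    v["scl_max"] = float(np.max(segment.scl))
    v["scl_slope"] = scl_slope(segment.scl, segment.t4)
    v["scl_stp"] = slope_to_peak(segment.scl, segment.t4)
    v["tvsymp_mean"] = float(np.mean(segment.tvsymp))
    v["tvsymp_max"] = float(np.max(segment.tvsymp))
    v["mtvsymp_mean"] = float(np.mean(segment.mtvsymp))
    v["mtvsymp_max"] = float(np.max(segment.mtvsymp))
    v["tvsymp_stp"] = slope_to_peak(segment.tvsymp, segment.t4)
    v["mtvsymp_stp"] = slope_to_peak(segment.mtvsymp, segment.t4)
    v.update(spectral_features(segment.eda))
    tf_norm = power_normalize(
        {"tvsymp_n_mean": v["tvsymp_mean"], "tvsymp_n_max": v["tvsymp_max"],
         "mtvsymp_n_mean": v["mtvsymp_mean"], "mtvsymp_n_max": v["mtvsymp_max"]},
        v["total_eda_power"])
    v.update(tf_norm)
    act, mob, comp = hjorth(segment.eda, fs=4.0)
    v["hjorth_activity"], v["hjorth_mobility"], v["hjorth_complexity"] = act, mob, comp
    v.update(prv_features(segment))
    return v


def baseline_normalize(fv: FeatureVector, baseline_fv: FeatureVector) -> FeatureVector:
    """Subtract the subject's baseline feature values from the raw values.

    A missing baseline feature propagates to a missing normalized value;
    applying the baseline to itself yields all zeros.
    """
    if fv.subject_id != baseline_fv.subject_id:
        raise ValueError(
            f"subject mismatch: {fv.subject_id!r} vs {baseline_fv.subject_id!r}")
    normalized = {}
    for name, value in fv.values.items():
        base = baseline_fv.values.get(name, np.nan)
        normalized[name] = value - base
    return FeatureVector(
        subject_id=fv.subject_id, trial_index=fv.trial_index,
        modality=fv.modality, level=fv.level, phase=fv.phase,
        anxiety_vas=fv.anxiety_vas, pain_vas=fv.pain_vas, values=normalized)


def build_feature_table(sessions: list[Session],
                        decomposition: str = "cvx") -> pd.DataFrame:
    """Feature table: one row per (subject, trial, phase).

    Columns are the metadata block followed by every registry feature (raw)
    and its ``_bn`` baseline-normalized variant, in fixed order so repeated
    runs export byte-identical CSVs. Duplicate (subject, trial, phase) rows
    raise.
    """
    rows = []
    seen = set()
    for sess in sessions:
        proc = process_session(sess, decomposition=decomposition)
        segments = segment_session(proc)
        baseline_seg = next(s for s in segments if s.phase == "baseline")
        baseline_fv = FeatureVector(
            subject_id=sess.subject_id, trial_index=-1, modality="NONE",
            level=0, phase="baseline", anxiety_vas=None, pain_vas=None,
            values=extract_features(baseline_seg))
        for seg in segments:
            if seg.phase == "baseline":
                continue
            key = (sess.subject_id, seg.trial_index, seg.phase)
            if key in seen:
                raise ValueError(f"duplicate segment {key}")
            seen.add(key)
            vas = sess.vas_for(seg.trial_index)
            fv = FeatureVector(
                subject_id=sess.subject_id, trial_index=seg.trial_index,
                modality=seg.modality, level=seg.level, phase=seg.phase,
                anxiety_vas=vas.anxiety_score, pain_vas=vas.pain_score,
                values=extract_features(seg))
            bn = baseline_normalize(fv, baseline_fv)
            row = {
                "subject_id": fv.subject_id, "trial_index": fv.trial_index,
                "modality": fv.modality, "level": fv.level, "phase": fv.phase,
                "anxiety_vas": fv.anxiety_vas, "pain_vas": fv.pain_vas,
            }
            for name in FEATURE_REGISTRY:
                row[name] = fv.values[name]
                row[f"{name}_bn"] = bn.values[name]
            rows.append(row)
    columns = list(METADATA_COLUMNS)
    for name in FEATURE_REGISTRY:
        columns += [name, f"{name}_bn"]
    return pd.DataFrame(rows, columns=columns)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature (non-metadata) columns of a table, in registry order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
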