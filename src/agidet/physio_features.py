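"""Cleaning, filtering, 1-minute segmentation and multi-domain features
for the raw wristband signals.

The canonical feature manifest (name set and order) is fixed here and
written alongside every feature matrix so runs are comparable.  Feature
names follow ``<channel>_<domain>_<statistic>`` (e.g. ``eda_tonic_stat_mean``,
``acc_mag_freq_dominant``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .data_model import ChannelSeries, FeatureWindow, RawPhysioStream, interval_overlap
from .errors import DataError

logger = logging.getLogger(__name__)

#: channels receiving statistical + time-domain features
STAT_CHANNELS = (
    "acc_x", "acc_y", "acc_z", "acc_mag", "eda", "eda_tonic", "eda_phasic",
    "temp", "pulse",
)
#: channels additionally receiving Welch-spectrum features
FREQ_CHANNELS = ("acc_mag", "eda", "eda_phasic", "temp")
#: channels additionally receiving wavelet sub-band features
WAVELET_CHANNELS = ("acc_mag", "eda")

STAT_NAMES = ("mean", "sd", "min", "max", "median", "iqr", "skewness", "kurtosis")
TIME_NAMES = ("rms", "energy", "zero_crossings", "mad1", "line_length", "slope")
FREQ_BANDS = ((0.0, 0.5), (0.5, 2.0), (2.0, 5.0))

# Daubechies-4 low-pass decomposition filter (PyWavelets 'db4' dec_lo)
_DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
_DB4_HI = _DB4_LO[::-1] * np.array([(-1) ** k for k in range(len(_DB4_LO))])

GAP_FILL_MAX_S = 5.0


@dataclass
class FeatureConfig:
    window_s: float = 60.0
    stride_s: float = 60.0
    welch_max_segment_s: float = 32.0
    wavelet_levels: int = 4
    eda_lowpass_hz: float = 1.0
    temp_lowpass_hz: float = 0.1
    tonic_cutoff_hz: float = 0.05


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _fill_gaps(series: ChannelSeries, max_gap_s: float = GAP_FILL_MAX_S) -> ChannelSeries:
    """Re-grid onto the uniform lattice; interpolate gaps <= max_gap_s and
    flag longer gaps unusable."""
    ts, vals = series.timestamps, series.values
    if ts.size < 2:
        return series
    dt = 1.0 / series.sampling_rate_hz
    grid = ts[0] + np.arange(int(round((ts[-1] - ts[0]) / dt)) + 1) * dt
    filled = np.interp(grid, ts, vals)
    unusable = list(series.unusable)
    gaps = np.diff(ts)
    # a gap only counts as missing data when it exceeds both the fill limit
    # and 1.5x the channel's own sampling interval (slow channels are sparse)
    threshold = max(max_gap_s, 1.5 * dt)
    for i in np.nonzero(gaps > threshold)[0]:
        unusable.append((float(ts[i]), float(ts[i + 1])))
    return ChannelSeries(series.sampling_rate_hz, grid, filled, series.unit, unusable)


def _lowpass(values: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass; identity when the cutoff
    is at/above Nyquist or the series is too short for filtfilt padding."""
    if cutoff_hz >= fs / 2 or values.size < 30:
        return values
    b, a = sps.butter(4, cutoff_hz, fs=fs)
    return sps.filtfilt(b, a, values)


def preprocess(stream: RawPhysioStream, config: FeatureConfig | None = None) -> RawPhysioStream:
    """Clip, gap-fill, low-pass filter, and derive acc_mag / EDA components."""
    config = config or FeatureConfig()
    if not stream.channels:
        raise DataError("empty stream")
    clip_ranges = {"eda": (0.0, 100.0), "temp": (20.0, 45.0), "pulse": (20.0, 250.0)}
    out: dict[str, ChannelSeries] = {}
    for name, series in stream.channels.items():
        s = _fill_gaps(series)
        vals = s.values
        if name in clip_ranges:
            vals = np.clip(vals, *clip_ranges[name])
        if name.startswith("acc"):
            vals = np.clip(vals, -8.0, 8.0)
        if name == "eda":
            vals = _lowpass(vals, config.eda_lowpass_hz, s.sampling_rate_hz)
        elif name == "temp":
            vals = _lowpass(vals, config.temp_lowpass_hz, s.sampling_rate_hz)
        out[name] = ChannelSeries(s.sampling_rate_hz, s.timestamps, vals, s.unit, s.unusable)
    if all(k in out for k in ("acc_x", "acc_y", "acc_z")):
        x, y, z = out["acc_x"], out["acc_y"], out["acc_z"]
        n = min(x.values.size, y.values.size, z.values.size)
        mag = np.sqrt(x.values[:n] ** 2 + y.values[:n] ** 2 + z.values[:n] ** 2)
        out["acc_mag"] = ChannelSeries(x.sampling_rate_hz, x.timestamps[:n], mag, "g",
                                       list(x.unusable))
    if "eda" in out and out["eda"].duration_s >= 60.0:
        tonic, phasic = decompose_eda(out["eda"], cutoff_hz=config.tonic_cutoff_hz)
        out["eda_tonic"] = tonic
        out["eda_phasic"] = phasic
    return RawPhysioStream(stream.participant_id, out)


def decompose_eda(eda: ChannelSeries, cutoff_hz: float = 0.05) -> tuple[ChannelSeries, ChannelSeries]:
    """Split EDA into a tonic low-pass component and the phasic residual.

    ``tonic + phasic == eda`` pointwise by construction.
    """
    if eda.duration_s < 60.0:
        raise DataError("EDA series must be at least 60 s for decomposition")
    tonic_vals = _lowpass(eda.values, cutoff_hz, eda.sampling_rate_hz)
    phasic_vals = eda.values - tonic_vals
    tonic = ChannelSeries(eda.sampling_rate_hz, eda.timestamps, tonic_vals, eda.unit,
                          list(eda.unusable))
    phasic = ChannelSeries(eda.sampling_rate_hz, eda.timestamps, phasic_vals, eda.unit,
                           list(eda.unusable))
    return tonic, phasic


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class WindowSlice:
    """One fixed-duration window holding per-channel sample arrays."""

    start: float
    end: float
    channels: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)  # name -> (fs, values)


def segment_windows(
    stream: RawPhysioStream,
    window_s: float = 60.0,
    stride_s: float = 60.0,
) -> list[WindowSlice]:
    """Cut ``[t0 + k*stride, t0 + k*stride + window)`` slices.

    Windows intersecting an unusable span of any channel are dropped (and
    counted in the log).  Count on gapless input is
    ``floor((T - window)/stride) + 1``.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window and stride must be positive")
    t0, T = stream.t0, stream.duration_s
    if T < window_s:
        logger.warning("stream of %.1fs shorter than window %.1fs", T, window_s)
        return []
    k_max = int(np.floor((T - window_s) / stride_s + 1e-9))
    unusable = [iv for s in stream.channels.values() for iv in s.unusable]
    windows, dropped = [], 0
    for k in range(k_max + 1):
        start = t0 + k * stride_s
        end = start + window_s
        if any(interval_overlap(start, end, u0, u1) > 0 for u0, u1 in unusable):
            dropped += 1
            continue
        w = WindowSlice(start, end)
        for name, series in stream.channels.items():
            w.channels[name] = (series.sampling_rate_hz, series.slice(start, end))
        windows.append(w)
    if dropped:
        logger.info("dropped %d windows overlapping unusable spans", dropped)
    return windows


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _dwt_level(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the db4 DWT with periodic extension."""
    n = x.size
    if n % 2:
        x = np.append(x, x[-1])
        n += 1
    L = _DB4_LO.size
    ext = np.concatenate([x[-(L - 1):], x])  # periodic left extension
    lo = np.convolve(ext, _DB4_LO[::-1], mode="valid")[1::2]
    hi = np.convolve(ext, _DB4_HI[::-1], mode="valid")[1::2]
    return lo, hi


def wavelet_energies(x: np.ndarray, levels: int = 4) -> tuple[list[float], float]:
    """Sub-band energies of a db4 decomposition: details d1..dL and the
    final approximation."""
    detail_e = []
    approx = x.astype(float)
    for _ in range(levels):
        if approx.size < 2:
            detail_e.append(0.0)
            continue
        approx, detail = _dwt_level(approx)
        detail_e.append(float(np.sum(detail**2)))
    return detail_e, float(np.sum(approx**2))


def _channel_feature_names(ch: str, fs: float) -> list[str]:
    names = [f"{ch}_stat_{s}" for s in STAT_NAMES]
    names += [f"{ch}_time_{s}" for s in TIME_NAMES]
    if ch in FREQ_CHANNELS:
        names += [f"{ch}_freq_dominant", f"{ch}_freq_power_total", f"{ch}_freq_entropy"]
        for lo, hi in FREQ_BANDS:
            if lo < fs / 2:
                names.append(f"{ch}_freq_band_{lo:g}_{hi:g}")
    if ch in WAVELET_CHANNELS:
        levels = 4
        names += [f"{ch}_tf_d{i + 1}_energy" for i in range(levels)]
        names.append(f"{ch}_tf_a{levels}_energy")
        names += [f"{ch}_tf_d{i + 1}_ratio" for i in range(levels)]
    return names


def feature_manifest(rates: dict[str, float] | None = None) -> list[str]:
    """Canonical ordered feature-name list for a channel-rate layout."""
    rates = rates or {
        "acc_x": 32.0, "acc_y": 32.0, "acc_z": 32.0, "acc_mag": 32.0,
        "eda": 4.0, "eda_tonic": 4.0, "eda_phasic": 4.0, "temp": 1.0, "pulse": 0.1,
    }
    names: list[str] = []
    for ch in STAT_CHANNELS:
        if ch in rates:
            names.extend(_channel_feature_names(ch, rates[ch]))
    return names


def _stat_features(x: np.ndarray) -> list[float]:
    sd = float(np.std(x))
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))
    q75, q25 = np.percentile(x, [75, 25])
    return [float(np.mean(x)), sd, float(np.min(x)), float(np.max(x)),
            float(np.median(x)), float(q75 - q25), skew, kurt]


def _time_features(x: np.ndarray, fs: float) -> list[float]:
    n = x.size
    rms = float(np.sqrt(np.mean(x**2)))
    energy = float(np.sum(x**2))
    xm = x - x.mean()
    zc = int(np.sum(np.abs(np.diff(np.signbit(xm).astype(int))))) if n > 1 else 0
    diffs = np.abs(np.diff(x)) if n > 1 else np.array([0.0])
    mad1 = float(np.mean(diffs))
    line_length = float(np.sum(diffs))
    t = np.arange(n) / fs
    slope = float(np.polyfit(t, x, 1)[0]) if n > 1 and np.ptp(t) > 0 else 0.0
    return [rms, energy, zc, mad1, line_length, slope]


def _freq_features(x: np.ndarray, fs: float, max_seg_s: float = 32.0) -> list[float]:
    nperseg = min(x.size, int(max_seg_s * fs))
    out: list[float] = []
    if x.size < 8 or np.std(x) == 0.0:
        out = [0.0, 0.0, 0.0]
        out += [0.0 for lo, hi in FREQ_BANDS if lo < fs / 2]
        return out
    f, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    psd_nodc = psd.copy()
    psd_nodc[f == 0.0] = 0.0
    dominant = float(f[np.argmax(psd_nodc)]) if psd_nodc.max() > 0 else 0.0
    total = float(np.trapezoid(psd, f))
    p = psd / psd.sum() if psd.sum() > 0 else psd
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p))) if len(p) > 1 else 0.0
    out = [dominant, total, entropy]
    for lo, hi in FREQ_BANDS:
        if lo < fs / 2:
            m = (f >= lo) & (f < hi)
            out.append(float(np.trapezoid(psd[m], f[m])) if m.sum() > 1 else 0.0)
    return out


def _tf_features(x: np.ndarray, levels: int = 4) -> list[float]:
    detail, approx = wavelet_energies(x, levels)
    total = sum(detail) + approx
    ratios = [d / total if total > 0 else 0.0 for d in detail]
    return detail + [approx] + ratios


def extract_features(window: WindowSlice, config: FeatureConfig | None = None) -> FeatureWindow:
    """Compute the multi-domain feature vector for one window slice.

    Channels absent from the slice contribute NaN features (the model layer
    excludes them); the name set and order always follow the manifest.
    """
    config = config or FeatureConfig()
    rates = {ch: fs for ch, (fs, _) in window.channels.items()}
    features: dict[str, float] = {}
    for ch in STAT_CHANNELS:
        if ch not in window.channels:
            continue
        fs, x = window.channels[ch]
        names = _channel_feature_names(ch, fs)
        if x.size == 0:
            features.update({n: float("nan") for n in names})
            continue
        vals = _stat_features(x) + _time_features(x, fs)
        if ch in FREQ_CHANNELS:
            vals += _freq_features(x, fs, config.welch_max_segment_s)
        if ch in WAVELET_CHANNELS:
            vals += _tf_features(x, config.wavelet_levels)
        features.update(dict(zip(names, vals, strict=True)))
    return FeatureWindow(window.start, window.end, features)


def extract_feature_matrix(
    stream: RawPhysioStream,
    config: FeatureConfig | None = None,
) -> list[FeatureWindow]:
    """Preprocess, segment and extract features for a whole stream."""
    config = config or FeatureConfig()
    pre = preprocess(stream, config)
    return [extract_features(w, config) for w in segment_windows(pre, config.window_s, config.stride_s)]


def windows_to_frame(windows: list[FeatureWindow]) -> pd.DataFrame:
    """Feature windows as a DataFrame: window_start, window_end, label, features."""
    rows = []
    for w in windows:
        row = {"window_start": w.window_start, "window_end": w.window_end, "label": w.label}
        row.update(w.features)
        rows.append(row)
    return pd.DataFrame(rows)


def save_feature_matrix(windows: list[FeatureWindow], csv_path, manifest_path=None) -> None:
    df = windows_to_frame(windows)
    df.to_csv(csv_path, index=False, float_format="%.12g")
    if manifest_path is not None:
        names = [c for c in df.columns if c not in ("window_start", "window_end", "label")]
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump({"features": names}, fh, indent=2)


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------

def rank_features(model, names: list[str]) -> list[tuple[str, float]]:
    """Descending importances; ties broken by canonical (input) order."""
    importances = getattr(model, "feature_importances_", None)
    if importances is None:
        raise AttributeError("model does not expose feature_importances_")
    order = sorted(range(len(names)), key=lambda i: (-importances[i], i))
    return [(names[i], float(importances[i])) for i in order]
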