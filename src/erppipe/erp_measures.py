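"""ERP waveform aggregation and quantification.

Builds per-file ERP waveforms (trial averages over selected channels) and a
grand average with standard error and 95% confidence band, then quantifies
peaks/latencies in user windows, global and local extrema, mean amplitudes,
signed area under the curve, and the 50%-area latency, with window bounds
taken either from the user or from zero crossings of the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AxisError(ValueError):
    pass


@dataclass
class ERPWaveform:
    values: np.ndarray
    time: np.ndarray  # ms, includes the pre-stimulus baseline
    n_trials: int = 0
    source_file: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.size != self.time.size:
            raise AxisError("values and time must have equal length")

    def post_stimulus(self) -> "ERPWaveform":
        sel = self.time >= 0
        return ERPWaveform(self.values[sel], self.time[sel], self.n_trials,
                           self.source_file)


@dataclass
class MeasureWindow:
    name: str
    start_ms: float
    end_ms: float
    polarity: str  # "max" | "min"


#: Default component windows for the simulated VEP complex.
DEFAULT_VEP_WINDOWS = [
    MeasureWindow("N1", 150.0, 190.0, "min"),
    MeasureWindow("P1", 180.0, 220.0, "max"),
    MeasureWindow("N2", 215.0, 255.0, "min"),
]


def average_trials(epochs, channels: list[str] | None = None,
                   exclude: list[str] | None = None,
                   source_file: str = "") -> ERPWaveform:
    """Mean over kept trials, then over the selected channels."""
    labels = epochs.labels
    selected = channels if channels is not None else list(labels)
    if exclude:
        selected = [lb for lb in selected if lb not in set(exclude)]
    idx = [labels.index(lb) for lb in selected]
    kept = epochs.data[epochs.kept]
    if kept.shape[0] == 0 or not idx:
        wf = ERPWaveform(np.full(epochs.time.size, np.nan), epochs.time, 0,
                         source_file)
        return wf
    values = kept[:, idx, :].mean(axis=(0, 1))
    return ERPWaveform(values, epochs.time, int(kept.shape[0]), source_file)


def grand_average(waveforms: list[ERPWaveform]):
    """Across-file mean with per-timepoint SE and 95% CI.

    Returns ``(mean, se, ci_low, ci_high)`` as arrays on the shared axis.
    """
    if len(waveforms) < 2:
        raise AxisError("grand average needs >= 2 waveforms")
    t0 = waveforms[0].time
    for wf in waveforms[1:]:
        if wf.time.size != t0.size or not np.allclose(wf.time, t0):
            raise AxisError("waveforms are not on a common time axis")
    stack = np.stack([wf.values for wf in waveforms])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return mean, se, mean - 1.96 * se, mean + 1.96 * se


def _window_slice(erp: ERPWaveform, start_ms: float, end_ms: float) -> np.ndarray:
    sel = (erp.time >= start_ms) & (erp.time <= end_ms)
    if not sel.any():
        raise AxisError(f"window [{start_ms}, {end_ms}] ms outside the axis")
    return sel


def find_peaks(erp: ERPWaveform, windows: list[MeasureWindow]) -> dict:
    """Windowed peaks plus global and local extrema with latencies.

    Ties inside a window resolve to the earliest sample.
    """
    out: dict = {"windows": {}, "local_maxima": [], "local_minima": []}
    for w in windows:
        sel = _window_slice(erp, w.start_ms, w.end_ms)
        vals, times = erp.values[sel], erp.time[sel]
        i = int(np.argmin(vals)) if w.polarity == "min" else int(np.argmax(vals))
        out["windows"][w.name] = {
            "amplitude_uv": float(vals[i]),
            "latency_ms": float(times[i]),
            "polarity": w.polarity,
        }
    i_max, i_min = int(np.argmax(erp.values)), int(np.argmin(erp.values))
    out["global_max"] = (float(erp.values[i_max]), float(erp.time[i_max]))
    out["global_min"] = (float(erp.values[i_min]), float(erp.time[i_min]))
    v = erp.values
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            out["local_maxima"].append((float(v[i]), float(erp.time[i])))
        if v[i] < v[i - 1] and v[i] <= v[i + 1]:
            out["local_minima"].append((float(v[i]), float(erp.time[i])))
    return out


def zero_crossing_windows(erp: ERPWaveform) -> list[tuple[float, float]]:
    """Partition the post-stimulus axis at sign changes.

    A boundary falls on the first sample after each sign change; exact
    zeros are boundaries themselves. The returned windows tile the axis.
    """
    post = erp.post_stimulus()
    if post.time.size == 0:
        raise AxisError("no post-stimulus samples")
    t, v = post.time, post.values
    bounds = [0]
    for i in range(1, v.size):
        if v[i] == 0.0 and 0 < i < v.size - 1:
            bounds.append(i)
        elif v[i - 1] != 0.0 and np.sign(v[i]) != np.sign(v[i - 1]) and v[i] != 0.0:
            bounds.append(i)
    bounds.append(v.size - 1)
    bounds = sorted(set(bounds))
    windows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        windows.append((float(t[a]), float(t[b])))
    return windows


def mean_amplitude(erp: ERPWaveform, window: tuple[float, float]) -> float:
    sel = _window_slice(erp, window[0], window[1])
    return float(erp.values[sel].mean())


def area_measures(erp: ERPWaveform, window: tuple[float, float] | None = None,
                  mode: str = "window") -> dict:
    """Signed AUC (uV*ms), 50%-|area| latency and global absolute AUC.

    With ``mode="zero-crossing"`` the measures are reported per
    zero-crossing window; the global AUC always integrates |values| over
    the whole post-stimulus waveform.
    """
    post = erp.post_stimulus()
    global_auc = float(np.trapezoid(np.abs(post.values), post.time))

    def one(win: tuple[float, float]) -> dict:
        sel = _window_slice(erp, win[0], win[1])
        t, v = erp.time[sel], erp.values[sel]
        auc = float(np.trapezoid(v, t))
        av = np.abs(v)
        total = float(np.trapezoid(av, t))
        if total <= 0:
            return {"window": win, "auc_uvms": auc, "auc50_uvms": 0.0,
                    "auc50_latency_ms": float("nan")}
        cum = np.concatenate(
            ([0.0], np.cumsum(0.5 * (av[1:] + av[:-1]) * np.diff(t)))
        )
        half = total / 2.0
        i = int(np.searchsorted(cum, half))
        i = min(i, t.size - 1)
        return {"window": win, "auc_uvms": auc, "auc50_uvms": half,
                "auc50_latency_ms": float(t[i])}

    if mode == "zero-crossing":
        return {"mode": mode, "global_abs_auc_uvms": global_auc,
                "windows": [one(w) for w in zero_crossing_windows(erp)]}
    if window is None:
        raise AxisError("window mode requires a window")
    res = one(window)
    res.update({"mode": "window", "global_abs_auc_uvms": global_auc})
    return res


def peak_to_peak(peaks_in_order: list[tuple[str, float]]) -> dict[str, float]:
    """Successive-component differences, current minus prior.

    For the N1 -> P1 -> N2 train this yields positive N1-P1 and P1-N2
    peak-to-peak amplitudes.
    """
    if len(peaks_in_order) < 2:
        raise ValueError("need >= 2 ordered component peaks")
    out = {}
    for (prev_name, prev_val), (name, val) in zip(peaks_in_order[:-1],
                                                  peaks_in_order[1:]):
        out[f"{prev_name}-{name}"] = float(val - prev_val)
    return out


@dataclass
class MeasureTable:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def measure_erp(erp: ERPWaveform, windows: list[MeasureWindow],
                bound_mode: str = "window") -> dict:
    """The full measure suite for one waveform (one table row)."""
    row: dict = {"source_file": erp.source_file, "n_trials": erp.n_trials}
    pk = find_peaks(erp, windows)
    ordered = []
    for w in sorted(windows, key=lambda w: w.start_ms):
        res = pk["windows"][w.name]
        row[f"{w.name}_amplitude_uv"] = res["amplitude_uv"]
        row[f"{w.name}_latency_ms"] = res["latency_ms"]
        ordered.append((w.name, res["amplitude_uv"]))
    if len(ordered) >= 2:
        row.update({f"{k}_uv": v for k, v in peak_to_peak(ordered).items()})
    row["global_max_uv"], row["global_max_latency_ms"] = pk["global_max"]
    row["global_min_uv"], row["global_min_latency_ms"] = pk["global_min"]
    row["local_maxima"] = pk["local_maxima"]
    row["local_minima"] = pk["local_minima"]
    if bound_mode in ("window", "both"):
        for w in windows:
            win = (w.start_ms, w.end_ms)
            row[f"{w.name}_mean_amplitude_uv"] = mean_amplitude(erp, win)
            area = area_measures(erp, win)
            row[f"{w.name}_auc_uvms"] = area["auc_uvms"]
            row[f"{w.name}_auc50_latency_ms"] = area["auc50_latency_ms"]
    if bound_mode in ("zero-crossing", "both"):
        area = area_measures(erp, mode="zero-crossing")
        row["zero_crossing_areas"] = area["windows"]
    post = erp.post_stimulus()
    row["global_abs_auc_uvms"] = float(np.trapezoid(np.abs(post.values), post.time))
    return row
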