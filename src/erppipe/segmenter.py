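"""Epoching, baseline correction, per-segment channel repair and rejection.

Epoch windows are half-open in samples, mapped from milliseconds by
round(ms * rate / 1000) and shifted by a user timing offset. Within-segment
channel repair follows the FASTER statistics (variance, median gradient,
amplitude range, deviation from mean amplitude, z > 3 across trials), with
repaired channels re-estimated by spherical splines. Segment rejection
marks trials (never deletes them) on amplitude and/or joint-probability
criteria, optionally restricted to a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EpochSet, Recording
from .spatial import SplineSettings, spherical_spline_interpolate


class WindowError(ValueError):
    pass


class PolicyError(ValueError):
    pass


@dataclass
class SegmentationSettings:
    window_ms: tuple[float, float] = (-100.0, 400.0)
    timing_offset_ms: float = 0.0
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)

    def validate(self) -> None:
        if not self.window_ms[0] < self.window_ms[1]:
            raise WindowError("segment window start must precede end")
        b0, b1 = self.baseline_window_ms
        if b1 > 0 or b0 < self.window_ms[0]:
            raise WindowError("baseline window must lie in the pre-stimulus part")


@dataclass
class RejectionPolicy:
    criteria: str = "amplitude"  # amplitude | jointprob | both
    amp_low: float = -150.0
    amp_high: float = 150.0
    jp_sd: float = 3.0
    roi: list[str] | None = None

    def validate(self) -> None:
        if self.criteria not in ("amplitude", "jointprob", "both"):
            raise PolicyError(f"unknown criteria {self.criteria!r}")
        if not self.amp_low < self.amp_high:
            raise PolicyError("amp_low must be below amp_high")
        if self.jp_sd <= 0:
            raise PolicyError("jp_sd must be positive")


@dataclass
class FasterSettings:
    z_cut: float = 3.0
    metrics: tuple[str, ...] = (
        "variance", "median_gradient", "amplitude_range", "mean_amplitude_deviation",
    )


def _ms_to_samples(ms: float, rate: float) -> int:
    return int(round(ms * rate / 1000.0))


def segment_events(rec: Recording, markers: list[str],
                   settings: SegmentationSettings) -> EpochSet:
    """Cut one epoch per matching event; out-of-bounds events are dropped."""
    if not markers:
        raise ValueError("markers must be nonempty")
    settings.validate()
    start = _ms_to_samples(settings.window_ms[0] + settings.timing_offset_ms, rec.rate)
    stop = _ms_to_samples(settings.window_ms[1] + settings.timing_offset_ms, rec.rate)
    n_samp = stop - start
    time = (np.arange(n_samp) + _ms_to_samples(settings.window_ms[0], rec.rate)) \
        * 1000.0 / rec.rate
    trials, conditions = [], []
    dropped = 0
    marker_set = set(markers)
    for ev in rec.events:
        if ev.name not in marker_set:
            continue
        lo, hi = ev.onset + start, ev.onset + stop
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
        conditions.append(ev.name)
    notes = []
    if not trials:
        notes.append(f"no trials detected for markers {sorted(marker_set)}")
        data = np.empty((0, rec.n_channels, n_samp))
    else:
        data = np.stack(trials)
    return EpochSet(
        data=data,
        time=time,
        labels=list(rec.labels),
        rate=rec.rate,
        trial_conditions=conditions,
        n_dropped_events=dropped,
        notes=notes,
    )


def baseline_correct(epochs: EpochSet, baseline_window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial per-channel mean over the baseline window."""
    b0, b1 = baseline_window_ms
    sel = (epochs.time >= b0) & (epochs.time <= b1)
    if not sel.any():
        raise WindowError(f"baseline window {baseline_window_ms} has no samples")
    out = epochs.copy()
    if out.n_trials:
        out.data = out.data - out.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


def _faster_metrics(epochs: EpochSet) -> dict[str, np.ndarray]:
    x = epochs.data  # trials x channels x samples
    grand = x.mean(axis=(0, 2))  # channel grand mean
    return {
        "variance": x.var(axis=2),
        "median_gradient": np.median(np.abs(np.diff(x, axis=2)), axis=2),
        "amplitude_range": x.max(axis=2) - x.min(axis=2),
        "mean_amplitude_deviation": np.abs(x.mean(axis=2) - grand[np.newaxis, :]),
    }


def faster_epoch_channel_flags(epochs: EpochSet,
                               settings: FasterSettings | None = None) -> np.ndarray:
    """Boolean (trial, channel) flags from the four FASTER statistics.

    Each metric is z-scored per channel across trials; a pair is flagged
    when any |z| exceeds the cut (homogeneous files give zero flags via the
    zero-SD guard).
    """
    settings = settings or FasterSettings()
    if epochs.n_trials < 3:
        raise ValueError("FASTER flags need >= 3 trials")
    flags = np.zeros((epochs.n_trials, len(epochs.labels)), dtype=bool)
    metrics = _faster_metrics(epochs)
    for name in settings.metrics:
        m = metrics[name]
        mean = m.mean(axis=0)
        sd = m.std(axis=0)
        z = np.where(sd[np.newaxis, :] > 1e-12,
                     (m - mean[np.newaxis, :]) / np.where(sd > 1e-12, sd, 1.0),
                     0.0)
        flags |= np.abs(z) > settings.z_cut
    return flags


def interpolate_within_segments(epochs: EpochSet, flags: np.ndarray,
                                montage: dict[str, tuple[float, float, float]],
                                spline_settings: SplineSettings | None = None) -> EpochSet:
    """Spline-repair flagged (trial, channel) pairs from that trial's good channels.

    Trials with fewer than four clean channels cannot be repaired and are
    marked for rejection instead.
    """
    if not montage:
        raise ValueError("within-segment interpolation needs a montage")
    out = epochs.copy()
    positions = np.array([montage[lb] for lb in epochs.labels], dtype=float)
    for t in range(epochs.n_trials):
        bad_idx = np.flatnonzero(flags[t])
        if bad_idx.size == 0:
            continue
        good_idx = np.flatnonzero(~flags[t])
        if good_idx.size < 4:
            out.kept[t] = False
            out.notes.append(f"trial {t}: too few good channels to repair")
            continue
        est = spherical_spline_interpolate(
            epochs.data[t, good_idx], positions[good_idx], positions[bad_idx],
            spline_settings,
        )
        out.data[t, bad_idx] = est
        out.interpolated_in_segment[t] = [epochs.labels[i] for i in bad_idx]
    return out


def _jointprob_scores(data: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Per (trial, channel) sum of log-densities of the trial's samples.

    The density per channel is a 256-bin histogram over samples pooled
    across trials, with add-one smoothing.
    """
    n_t, n_c, n_s = data.shape
    scores = np.zeros((n_t, n_c))
    for c in range(n_c):
        pooled = data[:, c, :].ravel()
        lo, hi = pooled.min(), pooled.max()
        if hi - lo < 1e-12:
            continue
        counts, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi))
        logp = np.log((counts + 1.0) / (pooled.size + n_bins))
        idx = np.clip(np.digitize(data[:, c, :], edges) - 1, 0, n_bins - 1)
        scores[:, c] = logp[idx].sum(axis=1)
    return scores


def _trial_z(scores: np.ndarray) -> np.ndarray:
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0)
    return np.where(sd[np.newaxis, :] > 1e-12,
                    (scores - mean[np.newaxis, :]) / np.where(sd > 1e-12, sd, 1.0),
                    0.0)


@dataclass
class RejectionReport:
    n_trials: int
    n_rejected: int
    by_amplitude: list[int] = field(default_factory=list)
    by_jointprob: list[int] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_trials - self.n_rejected


def reject_segments(epochs: EpochSet, policy: RejectionPolicy):
    """Mark trials for rejection; returns (epochs with kept flags, report).

    All marks are applied simultaneously in a single step; trials are
    flagged, never removed from the set.
    """
    policy.validate()
    if policy.roi is not None:
        roi = [lb for lb in policy.roi if lb in epochs.labels]
        if not roi:
            raise PolicyError("ROI does not intersect the channel set")
        ch_idx = [epochs.labels.index(lb) for lb in roi]
    else:
        ch_idx = list(range(len(epochs.labels)))
    out = epochs.copy()
    amp_marks: list[int] = []
    jp_marks: list[int] = []
    if epochs.n_trials == 0:
        return out, RejectionReport(0, 0)
    sub = epochs.data[:, ch_idx, :]
    if policy.criteria in ("amplitude", "both"):
        over = (sub < policy.amp_low) | (sub > policy.amp_high)
        amp_marks = list(np.flatnonzero(over.any(axis=(1, 2))))
    if policy.criteria in ("jointprob", "both") and epochs.n_trials >= 3:
        scores = _jointprob_scores(sub)
        z_single = _trial_z(scores)  # z across trials, per channel
        # electrode-group: z across channels of the trial-normalised scores
        mean_c = z_single.mean(axis=1, keepdims=True)
        sd_c = z_single.std(axis=1, keepdims=True)
        z_group = np.where(sd_c > 1e-12, (z_single - mean_c) / np.where(sd_c > 1e-12, sd_c, 1.0), 0.0)
        bad = (np.abs(z_single) > policy.jp_sd).any(axis=1) | \
              (np.abs(z_group) > policy.jp_sd).any(axis=1)
        jp_marks = list(np.flatnonzero(bad))
    marked = sorted(set(amp_marks) | set(jp_marks))
    out.kept = out.kept.copy()
    out.kept[marked] = False
    report = RejectionReport(
        n_trials=epochs.n_trials,
        n_rejected=len(marked),
        by_amplitude=[int(i) for i in amp_marks],
        by_jointprob=[int(i) for i in jp_marks],
    )
    return out, report


def split_by_condition(epochs: EpochSet,
                       condition_map: dict[str, list[str]] | None = None) -> dict[str, EpochSet]:
    """Partition trials by event marker and by named condition groups.

    Returns the full set under ``"all"``, one set per marker present in the
    metadata, and one set per condition group; absent markers yield empty
    sets with a note rather than an error.
    """
    out: dict[str, EpochSet] = {"all": epochs.copy()}

    def take(indices: list[int], note: str | None) -> EpochSet:
        sub = EpochSet(
            data=epochs.data[indices] if indices else
            np.empty((0, len(epochs.labels), epochs.time.size)),
            time=epochs.time.copy(),
            labels=list(epochs.labels),
            rate=epochs.rate,
            trial_conditions=[epochs.trial_conditions[i] for i in indices],
            kept=epochs.kept[indices] if indices else np.ones(0, dtype=bool),
            interpolated_in_segment=[epochs.interpolated_in_segment[i] for i in indices],
        )
        if note:
            sub.notes.append(note)
        return sub

    markers = sorted(set(epochs.trial_conditions))
    for mk in markers:
        idx = [i for i, c in enumerate(epochs.trial_conditions) if c == mk]
        out[mk] = take(idx, None)
    for cond, mks in (condition_map or {}).items():
        idx = [i for i, c in enumerate(epochs.trial_conditions) if c in set(mks)]
        note = None if idx else f"no trials detected for condition {cond!r}"
        out[cond] = take(idx, note)
    return out
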