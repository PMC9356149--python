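"""Composite whole-recording bad-channel detection.

Four criteria are applied in a fixed order, each to the channels surviving
the previous one: flatline runs, power-spectrum outliers (two passes),
line-noise-to-signal ratio outliers, and low best-neighbour correlation.
Thresholds follow the empirically optimised defaults: spectrum z in
(-5, 3.5), line ratio z > 6, correlation < 0.8, flatline > 5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import Recording


class DetectionError(ValueError):
    pass


@dataclass
class BadChannelSettings:
    flatline_max_s: float = 5.0
    spec_band: tuple[float, float] = (1.0, 100.0)
    spec_low_sd: float = -5.0
    spec_high_sd: float = 3.5
    spec_passes: int = 2
    line_ratio_sd: float = 6.0
    corr_min: float = 0.8
    corr_window_s: float = 1.0

    def validate(self) -> None:
        if not self.spec_low_sd < 0 < self.spec_high_sd:
            raise ValueError("spectrum thresholds must straddle zero")
        if not 0 < self.corr_min < 1:
            raise ValueError("corr_min must be in (0, 1)")


@dataclass
class BadChannelReport:
    verdicts: dict[str, str]  # label -> "good" | "bad"
    criteria: dict[str, list[str]] = field(default_factory=dict)
    percent_good: float = 100.0

    @property
    def bad_labels(self) -> list[str]:
        return [lb for lb, v in self.verdicts.items() if v == "bad"]

    @property
    def good_labels(self) -> list[str]:
        return [lb for lb, v in self.verdicts.items() if v == "good"]


def detect_flatline(channel: np.ndarray, rate: float, flatline_max_s: float = 5.0) -> bool:
    """True iff a contiguous near-constant run lasts strictly longer than the limit."""
    x = np.asarray(channel, dtype=float)
    flat = np.abs(np.diff(x)) < 1e-8
    if not flat.any():
        return False
    # longest run of consecutive flat first-differences; a run of k diffs
    # spans k+1 samples
    padded = np.concatenate(([False], flat, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    run_lengths = edges[1::2] - edges[::2]
    longest_s = (run_lengths.max() + 1) / rate
    return bool(longest_s > flatline_max_s)


def _mean_log_power(data: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    nper = min(int(rate), data.shape[1])
    freqs, psd = sps.welch(data, fs=rate, nperseg=nper, noverlap=nper // 2, axis=-1)
    hi = min(band[1], 0.999 * rate / 2)
    sel = (freqs >= band[0]) & (freqs <= hi)
    power = psd[:, sel].mean(axis=1)
    return np.log10(np.maximum(power, 1e-30))


def _zscores(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd < 1e-12:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def detect_spectral_outliers(rec: Recording, settings: BadChannelSettings | None = None) -> set[str]:
    """Channels whose band-average log power is a cross-channel outlier.

    The z-pass is run twice: flagged channels are dropped, the z-scores are
    re-estimated on the survivors and flagged again; the union is returned.
    The lower threshold is deliberately lenient (-5 SD) so that genuinely
    low-amplitude channels near the online reference are not rejected.
    """
    settings = settings or BadChannelSettings()
    settings.validate()
    if rec.n_channels < 2:
        raise DetectionError("spectral outlier detection needs >= 2 channels")
    logp = _mean_log_power(rec.data, rec.rate, settings.spec_band)
    labels = np.array(rec.labels)
    flagged: set[str] = set()
    active = np.ones(rec.n_channels, dtype=bool)
    for _ in range(max(1, settings.spec_passes)):
        if active.sum() < 2:
            break
        z = _zscores(logp[active])
        bad = (z > settings.spec_high_sd) | (z < settings.spec_low_sd)
        newly = set(labels[active][bad])
        if not newly:
            break
        flagged |= newly
        active &= ~np.isin(labels, list(flagged))
    return flagged


def detect_line_ratio_outliers(rec: Recording, settings: BadChannelSettings | None = None,
                               line_freq: float = 60.0) -> set[str]:
    """Channels with an outlying line-noise-to-neural-signal power ratio.

    The criterion is relative across channels (robust z of the log ratio),
    so uniform contamination of every channel flags nothing.
    """
    settings = settings or BadChannelSettings()
    if line_freq >= rec.rate / 2:
        return set()
    nper = min(int(rec.rate), rec.n_samples)
    freqs, psd = sps.welch(rec.data, fs=rec.rate, nperseg=nper,
                           noverlap=nper // 2, axis=-1)
    line_sel = np.abs(freqs - line_freq) <= 1.0
    hi = min(settings.spec_band[1], 0.999 * rec.rate / 2)
    band_sel = (freqs >= settings.spec_band[0]) & (freqs <= hi) & ~line_sel
    if not line_sel.any() or not band_sel.any():
        return set()
    ratio = np.log10(np.maximum(psd[:, line_sel].mean(axis=1), 1e-30)) - \
        np.log10(np.maximum(psd[:, band_sel].mean(axis=1), 1e-30))
    med = np.median(ratio)
    mad = np.median(np.abs(ratio - med))
    if mad < 1e-12:
        return set()
    z = (ratio - med) / (1.4826 * mad)
    return {rec.labels[i] for i in np.flatnonzero(z > settings.line_ratio_sd)}


def _best_neighbour_scores(data: np.ndarray, win: int) -> np.ndarray:
    n_win = max(1, data.shape[1] // win)
    score = np.zeros((n_win, data.shape[0]))
    for w in range(n_win):
        seg = data[:, w * win:(w + 1) * win]
        sd = seg.std(axis=1)
        cc = np.corrcoef(seg)
        cc[~np.isfinite(cc)] = 0.0
        np.fill_diagonal(cc, 0.0)
        score[w] = np.abs(cc).max(axis=1)
        score[w, sd < 1e-12] = 0.0
    return score.mean(axis=0)


def _reconstruction_scores(data: np.ndarray, positions: np.ndarray,
                           win: int) -> np.ndarray:
    from .spatial import spherical_spline_interpolate

    n_ch = data.shape[0]
    n_win = max(1, data.shape[1] // win)
    recon = np.empty_like(data)
    for c in range(n_ch):
        others = [i for i in range(n_ch) if i != c]
        recon[c] = spherical_spline_interpolate(
            data[others], positions[others], positions[c:c + 1])[0]
    score = np.zeros((n_win, n_ch))
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        a, b = data[:, sl], recon[:, sl]
        sa, sb = a.std(axis=1), b.std(axis=1)
        cov = ((a - a.mean(axis=1, keepdims=True))
               * (b - b.mean(axis=1, keepdims=True))).mean(axis=1)
        ok = (sa > 1e-12) & (sb > 1e-12)
        score[w] = np.where(ok, np.abs(cov) / np.where(ok, sa * sb, 1.0), 0.0)
    return score.mean(axis=0)


def channel_predictability(rec: Recording,
                           settings: BadChannelSettings | None = None) -> np.ndarray:
    """Per-channel mean windowed agreement with the rest of the scalp.

    A channel counts as predictable if either its spherical-spline
    reconstruction from all other channels matches it (Clean-Rawdata-style
    channel criterion; requires a montage) or some single other channel
    correlates strongly with it (catches bridged/duplicated electrodes
    whose signal belongs to another site). Without positions only the
    best-neighbour route is available. Correlations are computed per
    ``corr_window_s`` window and averaged over windows.
    """
    settings = settings or BadChannelSettings()
    win = max(2, int(round(settings.corr_window_s * rec.rate)))
    best = _best_neighbour_scores(rec.data, win)
    if not rec.montage or rec.n_channels < 5:
        return best
    recon = _reconstruction_scores(rec.data, rec.positions(), win)
    return np.maximum(best, recon)


def detect_low_correlation(rec: Recording, settings: BadChannelSettings | None = None) -> set[str]:
    """Channels poorly correlated with (unpredictable from) the others.

    Flagging is greedy: the worst channel below ``corr_min`` is removed
    and scores are recomputed, so one grossly aberrant channel does not
    drag its neighbours' predictability down with it.
    """
    settings = settings or BadChannelSettings()
    if rec.n_channels < 3:
        raise DetectionError("correlation detection needs >= 3 channels")
    active = list(range(rec.n_channels))
    flagged: set[str] = set()
    while len(active) >= 3:
        sub = Recording(
            data=rec.data[active], rate=rec.rate,
            labels=[rec.labels[i] for i in active],
            montage={rec.labels[i]: rec.montage[rec.labels[i]]
                     for i in active} if rec.montage else {})
        scores = channel_predictability(sub, settings)
        worst = int(np.argmin(scores))
        if scores[worst] >= settings.corr_min:
            break
        flagged.add(sub.labels[worst])
        active.pop(worst)
    return flagged


def detect_bad_channels(rec: Recording, settings: BadChannelSettings | None = None,
                        line_freq: float = 60.0) -> BadChannelReport:
    """Run all four criteria in order, each on the survivors of the last."""
    settings = settings or BadChannelSettings()
    settings.validate()
    criteria: dict[str, list[str]] = {}

    def mark(label: str, crit: str) -> None:
        criteria.setdefault(label, []).append(crit)

    survivors = list(rec.labels)
    for lb in rec.labels:
        ch = rec.data[rec.labels.index(lb)]
        if rec.n_samples / rec.rate >= settings.flatline_max_s and \
                detect_flatline(ch, rec.rate, settings.flatline_max_s):
            mark(lb, "flatline")
            survivors.remove(lb)

    def sub(labels: list[str]) -> Recording:
        idx = [rec.labels.index(lb) for lb in labels]
        montage = {lb: rec.montage[lb] for lb in labels} if rec.montage else {}
        return Recording(data=rec.data[idx], rate=rec.rate, labels=labels,
                         montage=montage)

    if len(survivors) >= 2:
        for lb in detect_spectral_outliers(sub(survivors), settings):
            mark(lb, "spectrum")
        survivors = [lb for lb in survivors if "spectrum" not in criteria.get(lb, [])]
    if len(survivors) >= 2:
        for lb in detect_line_ratio_outliers(sub(survivors), settings, line_freq):
            mark(lb, "line_ratio")
        survivors = [lb for lb in survivors if "line_ratio" not in criteria.get(lb, [])]
    if len(survivors) >= 3:
        for lb in detect_low_correlation(sub(survivors), settings):
            mark(lb, "correlation")
        survivors = [lb for lb in survivors if "correlation" not in criteria.get(lb, [])]

    verdicts = {lb: ("bad" if lb in criteria else "good") for lb in rec.labels}
    n_good = sum(v == "good" for v in verdicts.values())
    return BadChannelReport(
        verdicts=verdicts,
        criteria=criteria,
        percent_good=100.0 * n_good / rec.n_channels,
    )
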