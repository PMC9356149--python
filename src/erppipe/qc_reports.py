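"""Data-quality and pipeline-quality report tables.

Two CSVs are produced per batch, one row per file: a data-quality table
(file length, segment counts, percent good channels, interpolated channel
identities, percent variance retained, per-segment interpolation lists)
and a pipeline-quality table of pre/post correlations around the line
frequency and at ten probe frequencies spanning the canonical EEG bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import Recording


class FrequencyError(ValueError):
    pass


@dataclass
class QCFrequencies:
    wavelet_probe_freqs: tuple[float, ...] = (0.5, 1, 2, 5, 8, 12, 20, 30, 45, 70)
    line_probe_offsets: tuple[float, ...] = (-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5)

    def line_probes(self, target: float, rate: float) -> list[float]:
        return [target + off for off in self.line_probe_offsets
                if 0 < target + off < rate / 2]

    def wavelet_probes(self, rate: float) -> list[float]:
        return [f for f in self.wavelet_probe_freqs if f < rate / 2]


DATA_QUALITY_COLUMNS = [
    "FileName",
    "File_Length_s",
    "Number_Segs_Pre-Seg_Rej",
    "Number_Segs_Post-Seg_Rej",
    "Percent_Good_Chans_Selected",
    "Interpolated_Chan_IDs",
    "Percent_Var_Retained_Post-Wav",
    "ICA_Metrics",
    "Chans_Interpolated_Per_Seg",
]


def band_correlation(pre: Recording, post: Recording, f: float) -> float:
    """Median per-channel correlation after band-limiting both to f +/- 1 Hz.

    Below 2 Hz the band is proportional ([f/2, 3f/2]) so the passband stays
    positive. A low value at the line frequency with high values at the
    neighbours is the signature of well-targeted line-noise removal.
    """
    if f >= pre.rate / 2:
        raise FrequencyError(f"{f} Hz at or above Nyquist")
    if pre.data.shape != post.data.shape:
        raise ValueError("pre/post recordings differ in shape")
    if f < 2.0:
        lo, hi = f / 2.0, 1.5 * f
    else:
        lo, hi = f - 1.0, f + 1.0
    hi = min(hi, 0.999 * pre.rate / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=pre.rate, output="sos")
    a = sps.sosfiltfilt(sos, pre.data, axis=-1)
    b = sps.sosfiltfilt(sos, post.data, axis=-1)
    rs = []
    for c in range(pre.n_channels):
        sa, sb = a[c].std(), b[c].std()
        if sa < 1e-12 or sb < 1e-12:
            rs.append(1.0 if sa < 1e-12 and sb < 1e-12 else 0.0)
            continue
        rs.append(float(np.corrcoef(a[c], b[c])[0, 1]))
    return float(np.median(rs))


def broadband_correlation(pre: Recording, post: Recording) -> float:
    rs = []
    for c in range(pre.n_channels):
        sa, sb = pre.data[c].std(), post.data[c].std()
        if sa < 1e-12 or sb < 1e-12:
            rs.append(1.0 if sa < 1e-12 and sb < 1e-12 else 0.0)
            continue
        rs.append(float(np.corrcoef(pre.data[c], post.data[c])[0, 1]))
    return float(np.median(rs))


def variance_retained(pre: Recording, post: Recording) -> float:
    """Mean over channels of 100 * (1 - var(pre - post) / var(pre)).

    Large removals can legitimately drive this strongly negative; zero
    variance channels are excluded from the mean.
    """
    if pre.data.shape != post.data.shape:
        raise ValueError("pre/post recordings differ in shape")
    vals = []
    for c in range(pre.n_channels):
        v_pre = pre.data[c].var()
        if v_pre < 1e-24:
            continue
        vals.append(100.0 * (1.0 - (pre.data[c] - post.data[c]).var() / v_pre))
    return float(np.mean(vals)) if vals else 100.0


@dataclass
class FileQCRecord:
    """Per-file artifacts collected while the pipeline runs."""

    file_name: str
    file_length_s: float = float("nan")
    segs_pre: int | None = None
    segs_post: int | None = None
    percent_good_channels: float = float("nan")
    interpolated_channel_ids: list[str] = field(default_factory=list)
    percent_variance_retained: float = float("nan")
    chans_interpolated_per_seg: list[list[str]] | None = None
    line_pre: Recording | None = None
    line_post: Recording | None = None
    wav_pre: Recording | None = None
    wav_post: Recording | None = None
    line_freq: float = 60.0


def build_data_quality_table(records: list[FileQCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        seg_lists = r.chans_interpolated_per_seg
        if seg_lists is None:
            per_seg = "N/A"
        else:
            per_seg = "; ".join(
                f"seg{i + 1}:{','.join(chs)}" for i, chs in enumerate(seg_lists) if chs
            ) or "none"
        rows.append({
            "FileName": r.file_name,
            "File_Length_s": r.file_length_s,
            "Number_Segs_Pre-Seg_Rej": r.segs_pre if r.segs_pre is not None else "NA",
            "Number_Segs_Post-Seg_Rej": r.segs_post if r.segs_post is not None else "NA",
            "Percent_Good_Chans_Selected": r.percent_good_channels,
            "Interpolated_Chan_IDs": " ".join(r.interpolated_channel_ids) or "none",
            "Percent_Var_Retained_Post-Wav": r.percent_variance_retained,
            "ICA_Metrics": "NA",
            "Chans_Interpolated_Per_Seg": per_seg,
        })
    return pd.DataFrame(rows, columns=DATA_QUALITY_COLUMNS)


def build_pipeline_quality_table(records: list[FileQCRecord],
                                 freqs: QCFrequencies | None = None) -> pd.DataFrame:
    freqs = freqs or QCFrequencies()
    rows = []
    for r in records:
        row: dict = {"FileName": r.file_name}
        if r.line_pre is not None and r.line_post is not None:
            for f in freqs.line_probes(r.line_freq, r.line_pre.rate):
                row[f"r_line_{f:g}Hz"] = band_correlation(r.line_pre, r.line_post, f)
        if r.wav_pre is not None and r.wav_post is not None:
            row["r_wav_all"] = broadband_correlation(r.wav_pre, r.wav_post)
            for f in freqs.wavelet_probes(r.wav_pre.rate):
                row[f"r_wav_{f:g}Hz"] = band_correlation(r.wav_pre, r.wav_post, f)
        rows.append(row)
    return pd.DataFrame(rows)


def write_qc_tables(records: list[FileQCRecord], out_dir: str | Path,
                    freqs: QCFrequencies | None = None) -> tuple[Path, Path]:
    out = Path(out_dir) / "quality_assessment_outputs"
    out.mkdir(parents=True, exist_ok=True)
    dq = out / "data_quality.csv"
    pq = out / "pipeline_quality.csv"
    build_data_quality_table(records).to_csv(dq, index=False)
    build_pipeline_quality_table(records, freqs).to_csv(pq, index=False)
    return dq, pq
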