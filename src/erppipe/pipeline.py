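"""Configuration-driven batch driver tying the processing stages together.

Stage order is fixed: load -> channel selection -> 100 Hz lowpass +
line-noise removal -> optional resample -> optional bad-channel detection
-> wavelet thresholding -> ERP band filter -> optional segmentation
(baseline correction, within-segment repair) -> optional segment rejection
-> bad-channel spline interpolation -> optional re-referencing ->
condition split -> outputs. Intermediate results are saved per stage,
quality tables per batch, and the configuration echo alongside so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core_io, filters, line_noise, qc_reports, segmenter, spatial
from . import bad_channels as bc
from . import wavelet_denoise as wd

log = logging.getLogger("erppipe")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    input_dir: str = "."
    input_format: str = "fixture"  # one file type per run
    montage_path: str | None = None
    out_dir: str = "erppipe_out"
    output_formats: list[str] = field(default_factory=lambda: ["fixture", "txt"])
    seed: int = 0

    channel_mode: str = "all"
    channel_names: list[str] = field(default_factory=list)

    line_noise: dict = field(default_factory=dict)
    resample_to: float | None = None

    bad_channel_detection: bool = True
    bad_channel: dict = field(default_factory=dict)

    wavelet: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)

    segment: bool = True
    markers: list[str] = field(default_factory=list)
    conditions: dict[str, list[str]] = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    baseline_correction: bool = True
    segment_interpolation: bool = False
    segment_rejection: bool = True
    rejection: dict = field(default_factory=dict)

    rereference_mode: str | None = None  # None | "average" | "subset"
    rereference_subset: list[str] = field(default_factory=list)
    recover_prior_reference: bool = False

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.input_format not in ("fixture", "edf"):
            raise ConfigError(f"unknown input format {self.input_format!r}")
        if self.channel_mode not in ("all", "include", "exclude"):
            raise ConfigError(f"unknown channel mode {self.channel_mode!r}")
        if self.segment and not self.markers:
            raise ConfigError("segmentation requires event markers")
        if self.rereference_mode not in (None, "average", "subset"):
            raise ConfigError(f"unknown re-reference mode {self.rereference_mode!r}")

    # -- typed settings --------------------------------------------------
    def line_settings(self) -> line_noise.LineNoiseSettings:
        return line_noise.LineNoiseSettings(**self.line_noise)

    def bad_channel_settings(self) -> bc.BadChannelSettings:
        return bc.BadChannelSettings(**{
            k: tuple(v) if k == "spec_band" else v
            for k, v in self.bad_channel.items()
        })

    def wavelet_settings(self) -> wd.WaveletSettings:
        return wd.WaveletSettings(**self.wavelet)

    def filter_spec(self) -> filters.FilterSpec:
        return filters.FilterSpec(**self.filter)

    def segmentation_settings(self) -> segmenter.SegmentationSettings:
        return segmenter.SegmentationSettings(**{
            k: tuple(v) if k.endswith("_ms") and isinstance(v, list) else v
            for k, v in self.segmentation.items()
        })

    def rejection_policy(self) -> segmenter.RejectionPolicy:
        return segmenter.RejectionPolicy(**self.rejection)


def list_input_files(config: RunConfig) -> list[Path]:
    root = Path(config.input_dir)
    if config.input_format == "fixture":
        return sorted(p.with_suffix("") for p in root.glob("*.json")
                      if p.with_suffix(".npy").exists())
    return sorted(root.glob("*.edf"))


def process_recording(rec: core_io.Recording, config: RunConfig,
                      qc: qc_reports.FileQCRecord, out_dir: Path | None = None):
    """Run one recording through every enabled stage.

    Returns ``(result, qc)`` where result is the condition-split dict of
    epoch sets when segmenting, or the processed continuous recording.
    """
    save = out_dir is not None

    def dump(obj, stage):
        if save:
            core_io.write_stage_outputs(obj, stage, out_dir, ["fixture"])

    qc.file_length_s = rec.duration_s
    rec = core_io.select_channels(rec, config.channel_mode, config.channel_names)

    rec = filters.pre_clean_lowpass(rec)
    ln = config.line_settings()
    rec, pre_line = line_noise.remove_line_noise(rec, ln)
    qc.line_pre, qc.line_post, qc.line_freq = pre_line, rec.copy(), ln.target_freq
    dump(rec, "1_filtered_linenoise")

    if config.resample_to:
        rec = core_io.resample_recording(rec, config.resample_to)
        qc.line_pre = core_io.resample_recording(qc.line_pre, config.resample_to)
        qc.line_post = core_io.resample_recording(qc.line_post, config.resample_to)

    bad_labels: list[str] = []
    if config.bad_channel_detection:
        report = bc.detect_bad_channels(rec, config.bad_channel_settings(),
                                        line_freq=ln.target_freq)
        bad_labels = report.bad_labels
        qc.percent_good_channels = report.percent_good
        qc.interpolated_channel_ids = bad_labels
        dump(rec, "2_bad_channels_detected")
    else:
        qc.percent_good_channels = 100.0

    wav = config.wavelet_settings()
    pre_wav = rec.copy()
    rec, _removed = wd.wavelet_clean(rec, wav)
    qc.wav_pre, qc.wav_post = pre_wav, rec.copy()
    qc.percent_variance_retained = qc_reports.variance_retained(pre_wav, rec)
    dump(rec, "3_wavelet_thresholded")

    rec = filters.apply_filter(rec, config.filter_spec())
    dump(rec, "4_erp_filtered")

    if not config.segment:
        if bad_labels and rec.montage:
            rec = spatial.interpolate_bad_channels(rec, bad_labels)
        if config.rereference_mode:
            rec = spatial.rereference(rec, config.rereference_mode,
                                      config.rereference_subset,
                                      config.recover_prior_reference)
        qc.segs_pre = qc.segs_post = None
        dump(rec, "7_final")
        return rec, qc

    seg = config.segmentation_settings()
    epochs = segmenter.segment_events(rec, config.markers, seg)
    qc.segs_pre = epochs.n_trials
    dump(epochs, "5_segmented")

    if config.baseline_correction and epochs.n_trials:
        epochs = segmenter.baseline_correct(epochs, seg.baseline_window_ms)
        dump(epochs, "6_baseline_corrected")

    if config.segment_interpolation and epochs.n_trials >= 3 and rec.montage:
        flags = segmenter.faster_epoch_channel_flags(epochs)
        epochs = segmenter.interpolate_within_segments(epochs, flags, rec.montage)
        qc.chans_interpolated_per_seg = epochs.interpolated_in_segment
        dump(epochs, "6b_segment_interpolated")

    if config.segment_rejection and epochs.n_trials:
        epochs, _rep = segmenter.reject_segments(epochs, config.rejection_policy())
        qc.segs_post = epochs.n_kept
        dump(epochs, "6c_segment_rejected")
    else:
        qc.segs_post = qc.segs_pre

    if bad_labels and rec.montage:
        positions = np.array([rec.montage[lb] for lb in epochs.labels])
        good_idx = [i for i, lb in enumerate(epochs.labels) if lb not in set(bad_labels)]
        bad_idx = [i for i, lb in enumerate(epochs.labels) if lb in set(bad_labels)]
        if len(good_idx) >= 4 and bad_idx and epochs.n_trials:
            n_t, _, n_s = epochs.data.shape
            flat = epochs.data[:, good_idx, :].transpose(1, 0, 2).reshape(len(good_idx), -1)
            est = spatial.spherical_spline_interpolate(
                flat, positions[good_idx], positions[bad_idx])
            epochs.data[:, bad_idx, :] = est.reshape(len(bad_idx), n_t, n_s) \
                .transpose(1, 0, 2)

    if config.rereference_mode and epochs.n_trials:
        if config.rereference_mode == "average":
            epochs.data -= epochs.data.mean(axis=1, keepdims=True)
        else:
            idx = [epochs.labels.index(lb) for lb in config.rereference_subset]
            epochs.data -= epochs.data[:, idx, :].mean(axis=1, keepdims=True)

    split = segmenter.split_by_condition(epochs, config.conditions)
    if save:
        for name, eps in split.items():
            core_io.write_stage_outputs(eps, f"7_final_{name}", out_dir,
                                        config.output_formats)
    return split, qc


def run_pipeline(config: RunConfig) -> dict:
    """Process every input file; per-file failures are logged, not fatal."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    (out_root / "config_echo.json").write_text(config.to_json())
    files = list_input_files(config)
    records: list[qc_reports.FileQCRecord] = []
    summary: dict = {"files": [], "failed": []}
    for path in files:
        name = path.stem if path.suffix else path.name
        qc = qc_reports.FileQCRecord(file_name=name)
        try:
            rec = core_io.load_recording(path, config.input_format,
                                         config.montage_path)
            result, qc = process_recording(rec, config, qc,
                                           out_root / name)
            summary["files"].append(name)
        except Exception as exc:  # noqa: BLE001 - batch continues
            log.error("file %s failed: %s", name, exc)
            summary["failed"].append({"file": name, "error": str(exc)})
        records.append(qc)
    dq, pq = qc_reports.write_qc_tables(records, out_root)
    summary["data_quality_csv"] = str(dq)
    summary["pipeline_quality_csv"] = str(pq)
    return summary
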