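"""Core data model and I/O for continuous EEG and epoched ERP data.

All signal data are held in microvolts, channels x samples, with 0-based
integer sample indices internally; user-facing reports use seconds or
milliseconds. Two on-disk forms are supported: EDF/EDF+ (read only, via
:mod:`mne`) and a simple "fixture" container (a ``.npy`` array next to a JSON
sidecar carrying rate, labels, events, montage and reference), which
round-trips losslessly and serves as the open interchange format.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps


class FormatError(ValueError):
    """Unreadable file or file/format mismatch."""


class MontageError(ValueError):
    """Montage inconsistent with channel labels."""


class SelectionError(ValueError):
    """Unknown channel names in a selection request."""


class UpsampleError(ValueError):
    """Requested resampling rate exceeds the recording rate."""


@dataclass
class EventMarker:
    """A stimulus/condition marker at an integer sample onset."""

    name: str
    onset: int
    condition: str | None = None

    def __post_init__(self) -> None:
        self.onset = int(self.onset)
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")


@dataclass
class ProvenanceEntry:
    stage: str
    params: dict
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now().isoformat(timespec="seconds")


@dataclass
class Recording:
    """Continuous multichannel EEG: channels x samples, in microvolts."""

    data: np.ndarray
    rate: float
    labels: list[str]
    montage: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    events: list[EventMarker] = field(default_factory=list)
    reference: str = "unknown"
    provenance: list[ProvenanceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise MontageError(
                f"{self.data.shape[0]} data rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.montage:
            missing = [lb for lb in self.labels if lb not in self.montage]
            if missing:
                raise MontageError(f"montage missing positions for {missing}")
        for ev in self.events:
            if not 0 <= ev.onset < self.n_samples:
                raise ValueError(f"event {ev.name} onset {ev.onset} out of range")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            rate=self.rate,
            labels=list(self.labels),
            montage=dict(self.montage),
            events=[EventMarker(e.name, e.onset, e.condition) for e in self.events],
            reference=self.reference,
            provenance=list(self.provenance),
        )

    def with_data(self, data: np.ndarray, stage: str | None = None, **params) -> "Recording":
        """Same metadata, new samples (shape must keep the channel count)."""
        rec = self.copy()
        rec.data = np.asarray(data, dtype=float)
        if rec.data.shape[0] != rec.n_channels and rec.data.ndim == 2:
            raise ValueError("with_data cannot change the channel count")
        if stage:
            rec.provenance.append(ProvenanceEntry(stage, params))
        return rec

    def log(self, stage: str, **params) -> None:
        self.provenance.append(ProvenanceEntry(stage, params))

    def positions(self, labels: list[str] | None = None) -> np.ndarray:
        if not self.montage:
            raise MontageError("recording has no montage")
        labels = labels if labels is not None else self.labels
        return np.array([self.montage[lb] for lb in labels], dtype=float)


@dataclass
class EpochSet:
    """Trials x channels x samples around stimulus events (microvolts).

    ``time`` is in milliseconds relative to the stimulus (negative values
    span the pre-stimulus baseline); ``kept`` flags trials surviving segment
    rejection — nothing is ever deleted, so provenance is preserved.
    """

    data: np.ndarray
    time: np.ndarray
    labels: list[str]
    rate: float
    trial_conditions: list[str] = field(default_factory=list)
    kept: np.ndarray | None = None
    interpolated_in_segment: list[list[str]] = field(default_factory=list)
    n_dropped_events: int = 0
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length mismatch")
        if self.time.size > 1:
            steps = np.diff(self.time)
            if not np.all(steps > 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.rate, rtol=1e-6):
                raise ValueError("time step must be 1000/rate ms")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.kept.size != self.data.shape[0]:
            raise ValueError("kept flags must match trial count")
        if not self.trial_conditions:
            self.trial_conditions = [""] * self.data.shape[0]
        if not self.interpolated_in_segment:
            self.interpolated_in_segment = [[] for _ in range(self.data.shape[0])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            time=self.time.copy(),
            labels=list(self.labels),
            rate=self.rate,
            trial_conditions=list(self.trial_conditions),
            kept=self.kept.copy(),
            interpolated_in_segment=[list(x) for x in self.interpolated_in_segment],
            n_dropped_events=self.n_dropped_events,
            notes=list(self.notes),
        )


# ---------------------------------------------------------------------------
# montage files ("name x y z", whitespace separated, SFP style)
# ---------------------------------------------------------------------------

def read_montage(path: str | Path) -> dict[str, tuple[float, float, float]]:
    montage: dict[str, tuple[float, float, float]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) != 4:
            raise MontageError(f"bad montage line: {line!r}")
        montage[parts[0]] = (float(parts[1]), float(parts[2]), float(parts[3]))
    return montage


def write_montage(montage: dict[str, tuple[float, float, float]], path: str | Path) -> None:
    lines = [f"{name} {x:.6f} {y:.6f} {z:.6f}" for name, (x, y, z) in montage.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixture container: <base>.npy + <base>.json
# ---------------------------------------------------------------------------

def write_fixture(rec: Recording, base: str | Path) -> list[Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    npy = base.with_suffix(".npy")
    js = base.with_suffix(".json")
    np.save(npy, rec.data)
    sidecar = {
        "rate": rec.rate,
        "labels": rec.labels,
        "events": [
            {"name": e.name, "onset": e.onset, "condition": e.condition}
            for e in rec.events
        ],
        "montage": {k: list(v) for k, v in rec.montage.items()},
        "reference": rec.reference,
        "provenance": [
            {"stage": p.stage, "params": p.params, "timestamp": p.timestamp}
            for p in rec.provenance
        ],
    }
    js.write_text(json.dumps(sidecar, indent=1))
    return [npy, js]


def _read_fixture(base: Path, montage_path=None) -> Recording:
    npy, js = base.with_suffix(".npy"), base.with_suffix(".json")
    if not npy.exists() or not js.exists():
        raise FormatError(f"fixture needs {npy.name} and {js.name}")
    try:
        data = np.load(npy)
        sidecar = json.loads(js.read_text())
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"unreadable fixture {base}: {exc}") from exc
    labels = list(sidecar["labels"])
    if data.shape[0] != len(labels):
        raise MontageError(
            f"sidecar lists {len(labels)} labels but matrix has {data.shape[0]} rows"
        )
    montage = {k: tuple(v) for k, v in sidecar.get("montage", {}).items()}
    if montage_path is not None:
        montage = read_montage(montage_path)
    events = [
        EventMarker(e["name"], e["onset"], e.get("condition"))
        for e in sidecar.get("events", [])
    ]
    rec = Recording(
        data=data,
        rate=float(sidecar["rate"]),
        labels=labels,
        montage=montage,
        events=events,
        reference=sidecar.get("reference", "unknown"),
    )
    for p in sidecar.get("provenance", []):
        rec.provenance.append(ProvenanceEntry(p["stage"], p["params"], p["timestamp"]))
    return rec


def _read_edf(path: Path, montage_path=None) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable EDF {path}: {exc}") from exc
    rate = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    events = []
    for ann in raw.annotations:
        onset = int(round(float(ann["onset"]) * rate))
        if 0 <= onset < data.shape[1]:
            events.append(EventMarker(str(ann["description"]), onset))
    montage = read_montage(montage_path) if montage_path else {}
    if montage:
        missing = [lb for lb in labels if lb not in montage]
        if missing:
            raise MontageError(f"montage file missing channels {missing}")
        montage = {lb: montage[lb] for lb in labels}
    rec = Recording(data=data, rate=rate, labels=labels, montage=montage, events=events)
    rec.log("load_recording", path=str(path), format="edf")
    return rec


def load_recording(path: str | Path, format: str = "fixture", montage_path=None) -> Recording:
    """Read a continuous recording from disk.

    ``format`` is ``"edf"`` or ``"fixture"``; for fixtures ``path`` may be
    the base name or either of the two component files.
    """
    path = Path(path)
    if format == "fixture":
        rec = _read_fixture(path if path.suffix == "" else path.with_suffix(""), montage_path)
        rec.log("load_recording", path=str(path), format="fixture")
        return rec
    if format == "edf":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return _read_edf(path, montage_path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# channel selection and resampling
# ---------------------------------------------------------------------------

def select_channels(rec: Recording, mode: str = "all", names=()) -> Recording:
    """Keep all channels, an inclusion subset (COI) or an exclusion complement (COD).

    Removed channels are genuinely gone from the returned recording and
    cannot be recovered downstream; original channel order is preserved.
    """
    if mode == "all":
        out = rec.copy()
        out.log("select_channels", mode="all")
        return out
    if mode not in ("include", "exclude"):
        raise SelectionError(f"unknown selection mode {mode!r}")
    names = list(names)
    unknown = [n for n in names if n not in rec.labels]
    if unknown:
        raise SelectionError(f"unknown channel names: {unknown}")
    if mode == "include":
        keep = [lb for lb in rec.labels if lb in set(names)]
    else:
        keep = [lb for lb in rec.labels if lb not in set(names)]
    idx = [rec.labels.index(lb) for lb in keep]
    out = Recording(
        data=rec.data[idx],
        rate=rec.rate,
        labels=keep,
        montage={lb: rec.montage[lb] for lb in keep} if rec.montage else {},
        events=[EventMarker(e.name, e.onset, e.condition) for e in rec.events],
        reference=rec.reference,
        provenance=list(rec.provenance),
    )
    out.log("select_channels", mode=mode, names=names)
    return out


def resample_recording(rec: Recording, target: float) -> Recording:
    """Polyphase anti-aliased resampling to a lower (or equal) rate.

    Event onsets are rescaled by the same ratio; upsampling is refused.
    """
    if target > rec.rate:
        raise UpsampleError(
            f"cannot upsample from {rec.rate} to {target} Hz"
        )
    if math.isclose(target, rec.rate):
        out = rec.copy()
        out.log("resample", target=target)
        return out
    frac = Fraction(target / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(rec.data, up, down, axis=1)
    ratio = target / rec.rate
    n_new = data.shape[1]
    events = []
    for e in rec.events:
        onset = int(round(e.onset * ratio))
        if onset >= n_new:
            onset = n_new - 1
        events.append(EventMarker(e.name, onset, e.condition))
    out = Recording(
        data=data,
        rate=float(target),
        labels=list(rec.labels),
        montage=dict(rec.montage),
        events=events,
        reference=rec.reference,
        provenance=list(rec.provenance),
    )
    out.log("resample", target=target)
    return out


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def write_epochs_fixture(epochs: EpochSet, base: str | Path) -> list[Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    npy, js = base.with_suffix(".npy"), base.with_suffix(".json")
    np.save(npy, epochs.data)
    js.write_text(
        json.dumps(
            {
                "time_ms": epochs.time.tolist(),
                "labels": epochs.labels,
                "rate": epochs.rate,
                "trial_conditions": epochs.trial_conditions,
                "kept": epochs.kept.astype(int).tolist(),
                "interpolated_in_segment": epochs.interpolated_in_segment,
                "n_dropped_events": epochs.n_dropped_events,
                "notes": epochs.notes,
            },
            indent=1,
        )
    )
    return [npy, js]


def read_epochs_fixture(base: str | Path) -> EpochSet:
    base = Path(base)
    data = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        time=np.array(meta["time_ms"]),
        labels=meta["labels"],
        rate=meta["rate"],
        trial_conditions=meta["trial_conditions"],
        kept=np.array(meta["kept"], dtype=bool),
        interpolated_in_segment=meta["interpolated_in_segment"],
        n_dropped_events=meta.get("n_dropped_events", 0),
        notes=meta.get("notes", []),
    )


def _write_tsv(path: Path, matrix: np.ndarray, row_names: list[str], col_ms: np.ndarray) -> None:
    header = "channel\t" + "\t".join(f"{ms:g}" for ms in col_ms)
    lines = [header]
    for name, row in zip(row_names, matrix):
        lines.append(name + "\t" + "\t".join(f"{v:.6f}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_stage_outputs(obj, stage: str, out_dir: str | Path, formats=("fixture",)) -> list[Path]:
    """Persist an intermediate stage result.

    For an ERP-ready :class:`EpochSet` with ``txt`` format this writes the
    trial-average matrix (channels x timepoints) and the per-trial matrix
    (trials*channels rows) as tab-separated tables with channel-name row
    headers and millisecond column headers.
    """
    out_dir = Path(out_dir) / stage
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create stage folder {out_dir}: {exc}") from exc
    written: list[Path] = []
    try:
        for fmt in formats:
            if isinstance(obj, Recording):
                if fmt == "fixture":
                    written += write_fixture(obj, out_dir / "recording")
                elif fmt == "txt":
                    path = out_dir / "recording.txt"
                    t_ms = np.arange(obj.n_samples) * 1000.0 / obj.rate
                    _write_tsv(path, obj.data, obj.labels, t_ms)
                    written.append(path)
            elif isinstance(obj, EpochSet):
                if fmt == "fixture":
                    written += write_epochs_fixture(obj, out_dir / "epochs")
                elif fmt == "txt":
                    kept = obj.data[obj.kept]
                    avg = kept.mean(axis=0) if kept.shape[0] else np.zeros_like(obj.data[0])
                    avg_path = out_dir / "average.txt"
                    _write_tsv(avg_path, avg, obj.labels, obj.time)
                    trials_path = out_dir / "trials.txt"
                    n_t, n_c, n_s = kept.shape
                    rows = [
                        f"trial{t + 1}_{lb}"
                        for t in range(n_t)
                        for lb in obj.labels
                    ]
                    _write_tsv(trials_path, kept.reshape(n_t * n_c, n_s), rows, obj.time)
                    written += [avg_path, trials_path]
            else:
                raise TypeError(f"cannot write object of type {type(obj)}")
    except OSError as exc:
        raise IOError(f"write failure in {out_dir}: {exc}") from exc
    return written
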