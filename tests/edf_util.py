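"""Minimal EDF+C writer used only to create read-fixtures in tests.

Writes a spec-compliant EDF+ continuous file with one annotation channel
carrying time-stamped event labels. Not a shipped feature: the package
reads EDF via mne; this helper exists so tests can synthesize inputs on
the fly instead of storing binary files.
"""

from __future__ import annotations

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    assert len(b) <= width, text
    return b + b" " * (width - len(b))


def write_edf(path, data_uv: np.ndarray, rate: float, labels: list[str],
              annotations: list[tuple[float, str]] | None = None) -> None:
    """data_uv: channels x samples in microvolts; one data record per second."""
    annotations = annotations or []
    n_ch, n_samp = data_uv.shape
    spr = int(round(rate))
    n_records = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = data_uv

    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((padded - phys_min) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")

    ann_bytes_per_record = 64
    n_signals = n_ch + 1

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate 01-JAN-2020 X X X", 80)
    header += _pad("01.01.20", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (n_signals + 1)), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(n_signals), 4)

    def sig_field(values, width):
        return b"".join(_pad(v, width) for v in values)

    sig_labels = labels + ["EDF Annotations"]
    header += sig_field(sig_labels, 16)
    header += sig_field(["" for _ in sig_labels], 80)  # transducer
    header += sig_field(["uV"] * n_ch + [""], 8)
    header += sig_field([f"{phys_min}"] * n_ch + ["-1"], 8)
    header += sig_field([f"{phys_max}"] * n_ch + ["1"], 8)
    header += sig_field([str(dig_min)] * n_ch + [str(dig_min)], 8)
    header += sig_field([str(dig_max)] * n_ch + [str(dig_max)], 8)
    header += sig_field(["" for _ in sig_labels], 80)  # prefiltering
    header += sig_field([str(spr)] * n_ch + [str(ann_bytes_per_record // 2)], 8)
    header += sig_field(["" for _ in sig_labels], 32)  # reserved

    by_record: dict[int, list[tuple[float, str]]] = {}
    for onset_s, label in annotations:
        by_record.setdefault(int(onset_s), []).append((onset_s, label))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            fh.write(digital[:, rec_i * spr:(rec_i + 1) * spr].tobytes())
            tal = f"+{rec_i}\x14\x14\x00".encode("ascii")
            for onset_s, label in by_record.get(rec_i, []):
                tal += f"+{onset_s:g}\x14{label}\x14\x00".encode("ascii")
            assert len(tal) <= ann_bytes_per_record
            fh.write(tal + b"\x00" * (ann_bytes_per_record - len(tal)))
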