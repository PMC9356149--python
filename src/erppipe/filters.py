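"""Zero-phase filtering: 100 Hz pre-cleaning lowpass and ERP band filters.

Two user-selectable designs are offered for the ERP band: a Hamming
windowed-sinc FIR applied as a centred symmetric convolution (exactly zero
phase), and a Butterworth IIR applied forward-backward over second-order
sections. Both are preceded in the pipeline by an automatic 100 Hz lowpass
so that artifact detection operates within the neural frequency range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import Recording


class FilterSpecError(ValueError):
    pass


@dataclass
class FilterSpec:
    kind: str = "fir_hamming"  # or "iir_butterworth"
    highpass: float | None = None
    lowpass: float | None = None
    pre_clean_lowpass: float = 100.0
    order: int | str = "auto"

    def validate(self, rate: float) -> None:
        if self.kind not in ("fir_hamming", "iir_butterworth"):
            raise FilterSpecError(f"unknown filter kind {self.kind!r}")
        nyq = rate / 2.0
        if self.highpass is not None and not 0 < self.highpass < nyq:
            raise FilterSpecError(f"highpass {self.highpass} outside (0, {nyq})")
        if self.lowpass is not None and not 0 < self.lowpass < nyq:
            raise FilterSpecError(f"lowpass {self.lowpass} outside (0, {nyq})")
        if self.highpass is not None and self.lowpass is not None:
            if not self.highpass < self.lowpass:
                raise FilterSpecError("highpass must be below lowpass")


def _transition_width(f_edge: float) -> float:
    # 25% of the edge frequency, at least 2 Hz, never wider than the edge
    return min(max(0.25 * f_edge, 2.0), f_edge)


def _fir_kernel(rate: float, highpass, lowpass, order="auto") -> np.ndarray:
    edges = [f for f in (highpass, lowpass) if f is not None]
    if not edges:
        return np.array([1.0])
    tb = min(_transition_width(f) for f in edges)
    if order == "auto" or order is None:
        numtaps = int(math.ceil(3.3 * rate / tb))
    else:
        numtaps = int(order)
    if numtaps % 2 == 0:
        numtaps += 1
    if highpass is not None and lowpass is not None:
        return sps.firwin(numtaps, [highpass, lowpass], pass_zero="bandpass",
                          window="hamming", fs=rate)
    if highpass is not None:
        return sps.firwin(numtaps, highpass, pass_zero="highpass",
                          window="hamming", fs=rate)
    return sps.firwin(numtaps, lowpass, pass_zero="lowpass",
                      window="hamming", fs=rate)


def _zero_phase_fir(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if kernel.size == 1:
        return data.copy()
    n = data.shape[-1]
    pad = min(kernel.size, n - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, kernel[np.newaxis, :] if data.ndim == 2 else kernel,
                          mode="same", axes=-1)
    return out[..., pad:pad + n]


def fir_bandpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Hamming windowed-sinc FIR, centred (zero group delay)."""
    spec.validate(rec.rate)
    kernel = _fir_kernel(rec.rate, spec.highpass, spec.lowpass, spec.order)
    out = rec.with_data(_zero_phase_fir(rec.data, kernel), "fir_bandpass",
                        highpass=spec.highpass, lowpass=spec.lowpass,
                        taps=int(kernel.size))
    return out


def iir_bandpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Butterworth IIR, forward-backward over second-order sections.

    The design order follows the literal rate/highpass rule but is capped
    at 8 for numerical stability (uncapped it reaches the thousands for
    ERP-range highpass cutoffs); lowpass-only designs use order 4.
    """
    spec.validate(rec.rate)
    if spec.highpass is None and spec.lowpass is None:
        out = rec.copy()
        out.log("iir_bandpass", identity=True)
        return out
    data = rec.data
    if spec.highpass is not None:
        if spec.order == "auto" or spec.order is None:
            order = min(3 * int(rec.rate / spec.highpass), 8)
        else:
            order = int(spec.order)
        order = max(order, 2)
        sos = sps.butter(order, spec.highpass, btype="highpass", fs=rec.rate,
                         output="sos")
        if not np.all(np.isfinite(sos)):
            raise FilterSpecError("unstable highpass design")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    if spec.lowpass is not None:
        order = 4 if spec.order in ("auto", None) else max(int(spec.order), 2)
        order = min(order, 8)
        sos = sps.butter(order, spec.lowpass, btype="lowpass", fs=rec.rate,
                         output="sos")
        if not np.all(np.isfinite(sos)):
            raise FilterSpecError("unstable lowpass design")
        data = sps.sosfiltfilt(sos, data, axis=-1)
    return rec.with_data(data, "iir_bandpass",
                         highpass=spec.highpass, lowpass=spec.lowpass)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    if spec.kind == "iir_butterworth":
        return iir_bandpass(rec, spec)
    return fir_bandpass(rec, spec)


def pre_clean_lowpass(rec: Recording, cutoff: float = 100.0) -> Recording:
    """Automatic lowpass applied before artifact and bad-channel detection."""
    if cutoff >= rec.rate / 2.0:
        out = rec.copy()
        out.log("pre_clean_lowpass", cutoff=cutoff, skipped="above Nyquist")
        return out
    kernel = _fir_kernel(rec.rate, None, cutoff)
    return rec.with_data(_zero_phase_fir(rec.data, kernel), "pre_clean_lowpass",
                         cutoff=cutoff)
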