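"""Spherical-spline interpolation of scalp potentials and re-referencing.

Interpolation follows the Perrin spline on the unit sphere: the kernel is a
truncated Legendre series g(cos theta) = (1/4pi) sum_n (2n+1) /
(n^m (n+1)^m) P_n(cos theta) (seven terms by default, stiffness m = 4); the
spline system is solved with a small ridge term and a constant constraint,
making the estimate exactly linear in the data and exact for constant
fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .core_io import EventMarker, Recording
from .core_io import SelectionError


class GeometryError(ValueError):
    pass


@dataclass
class SplineSettings:
    legendre_order: int = 7
    stiffness_m: int = 4
    regularization: float = 1e-5

    def validate(self) -> None:
        if self.legendre_order < 1:
            raise ValueError("legendre_order must be >= 1")
        if self.stiffness_m < 2:
            raise ValueError("stiffness_m must be >= 2")


def _unit(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise GeometryError("electrode position at the origin")
    return pos / norms


def _g_matrix(cosang: np.ndarray, settings: SplineSettings) -> np.ndarray:
    coeffs = np.zeros(settings.legendre_order + 1)
    for n in range(1, settings.legendre_order + 1):
        coeffs[n] = (2 * n + 1) / (n**settings.stiffness_m * (n + 1) ** settings.stiffness_m)
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4.0 * np.pi)


def spherical_spline_interpolate(good_data: np.ndarray, good_positions: np.ndarray,
                                 target_positions: np.ndarray,
                                 settings: SplineSettings | None = None) -> np.ndarray:
    """Estimate potentials at target electrode sites from good channels.

    ``good_data`` is (n_good, n_samples); returns (n_targets, n_samples).
    """
    settings = settings or SplineSettings()
    settings.validate()
    good_data = np.atleast_2d(np.asarray(good_data, dtype=float))
    pos = _unit(np.atleast_2d(good_positions))
    tgt = _unit(np.atleast_2d(target_positions))
    n_good = pos.shape[0]
    if n_good < 4:
        raise GeometryError("need >= 4 good channels with positions")
    if np.linalg.matrix_rank(pos - pos.mean(axis=0), tol=1e-8) < 2:
        raise GeometryError("electrode geometry is degenerate (collinear)")
    g = _g_matrix(pos @ pos.T, settings)
    g_reg = g + settings.regularization * np.eye(n_good)
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_reg
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, good_data.shape[1]))
    rhs[:n_good] = good_data
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise GeometryError(f"singular spline system: {exc}") from exc
    weights, const = sol[:n_good], sol[n_good]
    g_t = _g_matrix(tgt @ pos.T, settings)
    return g_t @ weights + const[np.newaxis, :]


def interpolate_bad_channels(rec: Recording, bad_labels: list[str],
                             settings: SplineSettings | None = None) -> Recording:
    """Replace whole bad channels in a recording by spline estimates."""
    if not bad_labels:
        out = rec.copy()
        out.log("interpolate_bad_channels", bad=[])
        return out
    good = [lb for lb in rec.labels if lb not in set(bad_labels)]
    est = spherical_spline_interpolate(
        rec.data[[rec.labels.index(lb) for lb in good]],
        rec.positions(good),
        rec.positions(bad_labels),
        settings,
    )
    data = rec.data.copy()
    for i, lb in enumerate(bad_labels):
        data[rec.labels.index(lb)] = est[i]
    return rec.with_data(data, "interpolate_bad_channels", bad=list(bad_labels))


def rereference(rec: Recording, mode: str = "average", subset_names=None,
                recover_prior: bool = False) -> Recording:
    """Subtract a new reference (all-channel average or channel subset).

    With ``recover_prior`` and a known prior online reference, a zero
    channel named after that reference is appended before subtraction, so
    its signal reappears in the re-referenced data. If the montage lacks a
    position for it, the montage is cleared to keep it consistent.
    """
    if mode not in ("average", "subset"):
        raise SelectionError(f"unknown re-reference mode {mode!r}")
    data = rec.data
    labels = list(rec.labels)
    montage = dict(rec.montage)
    if recover_prior and rec.reference not in ("unknown", "", None) \
            and rec.reference not in labels:
        data = np.vstack([data, np.zeros((1, rec.n_samples))])
        labels.append(rec.reference)
        if montage and rec.reference not in montage:
            montage = {}
    if mode == "average":
        ref = data.mean(axis=0)
    else:
        subset = list(subset_names or [])
        unknown = [n for n in subset if n not in labels]
        if unknown:
            raise SelectionError(f"unknown reference channels: {unknown}")
        if not subset:
            raise SelectionError("subset re-referencing needs channel names")
        ref = data[[labels.index(n) for n in subset]].mean(axis=0)
    out = Recording(
        data=data - ref[np.newaxis, :],
        rate=rec.rate,
        labels=labels,
        montage=montage,
        events=[EventMarker(e.name, e.onset, e.condition) for e in rec.events],
        reference="average" if mode == "average" else "+".join(subset_names or []),
        provenance=list(rec.provenance),
    )
    out.log("rereference", mode=mode, subset=list(subset_names or []),
            recover_prior=recover_prior)
    return out
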