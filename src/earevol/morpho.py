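"""Scalar morphometrics of the auditory region.

Small, exact computations linking ear anatomy to the transfer-function
results: cochlear outer-wall polyline length (a proxy for basilar
membrane length), the idealized middle-ear impedance transformer ratio,
and the bony-to-total external-ear-canal length scaling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LandmarkPath", "MiddleEarDims", "polyline_length",
           "transformer_ratio", "eec_total_length"]


@dataclass
class LandmarkPath:
    """Ordered 3-D landmarks (mm) along a structure."""
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("need at least 2 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")


@dataclass
class MiddleEarDims:
    """Middle-ear dimensions entering the transformer ratio.

    ``a_tm``/``a_fp``: tympanic-membrane and stapes-footplate areas
    (mm^2); ``l_m``/``l_i``: malleus and incus functional lengths (mm).
    """
    a_tm: float
    a_fp: float
    l_m: float
    l_i: float
    bony_eec_length: float = np.nan

    def __post_init__(self):
        if min(self.a_tm, self.a_fp, self.l_m, self.l_i) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.a_tm <= self.a_fp:
            raise ValueError("tympanic membrane must exceed the footplate")


def polyline_length(path: LandmarkPath) -> float:
    """Sum of Euclidean distances between successive landmarks (mm)."""
    if not isinstance(path, LandmarkPath):
        path = LandmarkPath(np.asarray(path))
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def transformer_ratio(d: MiddleEarDims) -> tuple:
    """Idealized middle-ear pressure amplification.

    (area ratio) x (ossicular lever ratio), with the lever taken as
    malleus over incus functional length so a value > 1 amplifies.
    Returns (pressure ratio, dB = 20 log10 ratio).
    """
    ratio = (d.a_tm / d.a_fp) * (d.l_m / d.l_i)
    return float(ratio), float(20.0 * np.log10(ratio))


def eec_total_length(bony_mm: float, factor: float = 1.5) -> float:
    """Total (bony + cartilaginous) canal length from the bony part."""
    if bony_mm <= 0 or factor <= 0:
        raise ValueError("length and factor must be positive")
    return float(factor * bony_mm)
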