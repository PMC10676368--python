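"""Audiogram ingestion, cross-method correction, and the AT18m statistic.

Comparative audiograms come from three kinds of measurement: behavioural
testing with speakers (the reference), behavioural testing with
headphones, and auditory brainstem response (ABR) recordings in sedated
animals.  The latter two yield systematically higher thresholds, so
they are scaled to speaker-reference levels with per-frequency
correction factors computed from species measured with both methods.

The harmonized trait is AT18m: the average auditory threshold between
1 and 8 kHz, i.e. the audiogram's integral over log10(frequency)
normalized by the interval length log10(8).  Interpolation is linear in
log10(frequency) throughout, matching the integration variable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METHODS", "Audiogram", "CorrectionTable", "TraitValue",
    "default_correction_freqs", "interpolate_thresholds",
    "compute_correction", "average_corrections", "apply_correction",
    "compute_at18m", "load_audiograms", "audiograms_to_frame", "harmonize",
]

METHODS = ("speaker", "headphone", "ABR", "speaker-corrected")


@dataclass
class Audiogram:
    """Threshold-vs-frequency curve for one species and method.

    ``freqs_khz`` must be strictly increasing and positive; thresholds
    are dB re the source study's reference (only differences are ever
    compared, so no SPL re-referencing is attempted).
    """
    species: str
    method: str
    freqs_khz: np.ndarray
    thresholds_db: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.freqs_khz.size < 2:
            raise ValueError("audiogram needs at least 2 points")
        if self.freqs_khz.size != self.thresholds_db.size:
            raise ValueError("frequency/threshold length mismatch")
        if np.any(self.freqs_khz <= 0) or np.any(np.diff(self.freqs_khz) <= 0):
            raise ValueError("frequencies must be positive, strictly increasing")
        if not np.all(np.isfinite(self.thresholds_db)):
            raise ValueError("thresholds must be finite")

    @property
    def span(self):
        return float(self.freqs_khz[0]), float(self.freqs_khz[-1])


@dataclass
class CorrectionTable:
    """Per-frequency offsets (other-method minus speaker), in dB."""
    target_method: str
    freqs_khz: np.ndarray
    offsets_db: np.ndarray

    def __post_init__(self):
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.offsets_db = np.asarray(self.offsets_db, dtype=float)
        if self.target_method not in ("ABR", "headphone"):
            raise ValueError("correction target must be 'ABR' or 'headphone'")
        if self.freqs_khz.size != 11:
            raise ValueError("correction table uses exactly 11 frequencies")
        if self.freqs_khz.min() < 1.0 - 1e-9 or self.freqs_khz.max() > 8.0 + 1e-9:
            raise ValueError("correction frequencies must lie in [1, 8] kHz")


@dataclass
class TraitValue:
    species: str
    at18m: float

    def __post_init__(self):
        if not np.isfinite(self.at18m):
            raise ValueError("AT18m must be finite")


def default_correction_freqs() -> np.ndarray:
    """Eleven log-equidistant frequencies from 1 to 8 kHz: 8**(k/10)."""
    return 8.0 ** (np.arange(11) / 10.0)


def interpolate_thresholds(audiogram: Audiogram, freqs_khz) -> np.ndarray:
    """Thresholds at query frequencies, linear in log10(frequency).

    Queries outside the measured span raise rather than extrapolate.
    """
    q = np.atleast_1d(np.asarray(freqs_khz, dtype=float))
    lo, hi = audiogram.span
    if np.any(q < lo * (1 - 1e-12)) or np.any(q > hi * (1 + 1e-12)):
        raise ValueError(
            f"query outside measured span [{lo}, {hi}] kHz for "
            f"{audiogram.species} ({audiogram.method})")
    return np.interp(np.log10(q), np.log10(audiogram.freqs_khz),
                     audiogram.thresholds_db)


def compute_correction(other: Audiogram, speaker: Audiogram,
                       freqs_khz=None) -> CorrectionTable:
    """Per-frequency threshold difference other-method minus speaker."""
    if other.species != speaker.species:
        raise ValueError("correction pair must be the same species")
    if speaker.method != "speaker" or other.method not in ("ABR", "headphone"):
        raise ValueError("need one speaker and one ABR/headphone audiogram")
    f = default_correction_freqs() if freqs_khz is None else np.asarray(freqs_khz, float)
    off = interpolate_thresholds(other, f) - interpolate_thresholds(speaker, f)
    return CorrectionTable(other.method, f, off)


def average_corrections(a: CorrectionTable, b: CorrectionTable) -> CorrectionTable:
    if a.target_method != b.target_method:
        raise ValueError("cannot average corrections for different methods")
    if not np.allclose(a.freqs_khz, b.freqs_khz):
        raise ValueError("correction frequency grids differ")
    return CorrectionTable(a.target_method, a.freqs_khz,
                           0.5 * (a.offsets_db + b.offsets_db))


def apply_correction(audiogram: Audiogram, table: CorrectionTable,
                     grid: str = "table") -> Audiogram:
    """Scale an ABR/headphone audiogram to speaker-reference level.

    ``grid='table'`` (default) samples the corrected audiogram at the
    table's 11 frequencies; ``grid='native'`` keeps the audiogram's own
    points within [1, 8] kHz, with offsets interpolated onto them.
    """
    if audiogram.method != table.target_method:
        raise ValueError(
            f"audiogram method {audiogram.method!r} does not match "
            f"correction target {table.target_method!r}")
    if grid == "table":
        f = table.freqs_khz
        thr = interpolate_thresholds(audiogram, f) - table.offsets_db
    elif grid == "native":
        sel = (audiogram.freqs_khz >= table.freqs_khz[0]) & \
              (audiogram.freqs_khz <= table.freqs_khz[-1])
        f = audiogram.freqs_khz[sel]
        off = np.interp(np.log10(f), np.log10(table.freqs_khz), table.offsets_db)
        thr = audiogram.thresholds_db[sel] - off
    else:
        raise ValueError("grid must be 'table' or 'native'")
    return Audiogram(audiogram.species, "speaker-corrected", f, thr,
                     source=audiogram.source)


def compute_at18m(audiogram: Audiogram) -> TraitValue:
    """Average auditory threshold between 1 and 8 kHz.

    Trapezoidal integral of threshold against log10(frequency/1 kHz)
    over [0, log10 8], normalized by log10 8, using all measured points
    inside the interval plus interpolated endpoints.  Lower values mean
    more sensitive hearing.
    """
    lo, hi = audiogram.span
    if lo > 1.0 + 1e-12 or hi < 8.0 - 1e-12:
        raise ValueError(
            f"audiogram span [{lo}, {hi}] kHz does not cover [1, 8] kHz "
            f"({audiogram.species})")
    inner = audiogram.freqs_khz[(audiogram.freqs_khz > 1.0) &
                                (audiogram.freqs_khz < 8.0)]
    f = np.concatenate(([1.0], inner, [8.0]))
    thr = interpolate_thresholds(audiogram, f)
    val = np.trapezoid(thr, np.log10(f)) / np.log10(8.0)
    return TraitValue(audiogram.species, float(val))


# ----------------------------------------------------------------------
# table I/O and the end-to-end harmonization
# ----------------------------------------------------------------------

_COLUMNS = ["species", "method", "frequency_khz", "threshold_db", "source"]


def load_audiograms(table) -> list:
    """Audiograms from a CSV path or DataFrame with columns
    species, method, frequency_khz, threshold_db[, source]."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "source" not in df.columns:
        df = df.assign(source="")
    out = []
    for (sp, method, src), g in df.groupby(["species", "method", "source"],
                                           sort=False):
        g = g.sort_values("frequency_khz")
        out.append(Audiogram(sp, method, g["frequency_khz"].to_numpy(),
                             g["threshold_db"].to_numpy(), source=src))
    return out


def audiograms_to_frame(audiograms) -> pd.DataFrame:
    rows = []
    for a in audiograms:
        for f, t in zip(a.freqs_khz, a.thresholds_db):
            rows.append((a.species, a.method, f, t, a.source))
    return pd.DataFrame(rows, columns=_COLUMNS)


def harmonize(audiograms, abr_pair=("Lemur catta", "Nycticebus coucang"),
              headphone_pair=("Macaca fuscata", "Macaca fascicularis"),
              correction_freqs=None, grid="table"):
    """Speaker-reference AT18m for every species in a compilation.

    Correction factors are computed from the two species measured with
    both ABR and speakers, and from the two measured with both
    headphones and speakers, averaged within each method, and applied
    to all ABR/headphone audiograms.  Species with a speaker audiogram
    use it directly.  Returns ({species: at18m_db}, diagnostics dict).
    """
    by_sp_meth: dict = {}
    for a in audiograms:
        by_sp_meth.setdefault((a.species, a.method), []).append(a)

    def one(sp, meth):
        lst = by_sp_meth.get((sp, meth), [])
        if len(lst) != 1:
            raise ValueError(f"expected exactly one {meth} audiogram for {sp}")
        return lst[0]

    tables = {}
    for meth, pair in (("ABR", abr_pair), ("headphone", headphone_pair)):
        ct = [compute_correction(one(sp, meth), one(sp, "speaker"),
                                 correction_freqs) for sp in pair]
        tables[meth] = average_corrections(ct[0], ct[1])

    at18m, used = {}, {}
    for a in audiograms:
        if a.method == "speaker":
            at18m[a.species] = compute_at18m(a).at18m
            used[a.species] = a.method
    for a in audiograms:
        if a.species in at18m or a.method not in ("ABR", "headphone"):
            continue
        corrected = apply_correction(a, tables[a.method], grid=grid)
        at18m[a.species] = compute_at18m(corrected).at18m
        used[a.species] = f"{a.method} (corrected)"
    diagnostics = {
        "correction_tables": tables,
        "method_used": used,
        "mean_abr_offset_db": float(tables["ABR"].offsets_db.mean()),
        "mean_headphone_offset_db": float(tables["headphone"].offsets_db.mean()),
    }
    return at18m, diagnostics
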