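"""External/middle ear transfer-function (EMTF) curves and statistics.

The middle ear transfer function (METF) is the complex ratio of stapes
footplate velocity to sound pressure at the tympanic membrane.  Frames
are averaged coherently (complex mean), segments measured over
overlapping frequency ranges are concatenated, and magnitudes are
resampled onto a common logarithmic grid in dB re 1 mm s^-1/Pa.  Adding
the ear-canal pressure gain (dB) yields the EMTF.

Group comparisons follow the audiometric convention: at every grid
frequency (0.03-octave spacing, 0.2-9.8 kHz) a two-sided variance-ratio
test gates the choice between a pooled-variance t test and a Welch
t test, and Benjamini-Hochberg adjustment across all grid frequencies
controls the false discovery rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GRID_STEP_OCTAVES", "default_grid_khz", "FrequencyResponse",
    "EMTFCurve", "FeatureSet", "ComparisonResult",
    "average_frames", "concat_segments", "metf_db", "combine_emtf",
    "extract_features", "compare_groups", "group_mean",
    "load_frf_table", "emtf_from_frf",
]

GRID_STEP_OCTAVES = 0.03


def default_grid_khz(fmin: float = 0.2, fmax: float = 9.8) -> np.ndarray:
    """The analysis grid: fmin * 2**(0.03 i), last point <= fmax."""
    n = int(np.floor(np.log2(fmax / fmin) / GRID_STEP_OCTAVES + 1e-9)) + 1
    return fmin * 2.0 ** (GRID_STEP_OCTAVES * np.arange(n))


@dataclass
class FrequencyResponse:
    """Complex FRF frames of one specimen on one measurement grid."""
    specimen: str
    species: str
    freq_hz: np.ndarray
    frames: np.ndarray          # (n_frames, n_freq) complex
    segment: int = 0

    def __post_init__(self):
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=complex))
        if np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency grid must be ascending")
        if self.frames.shape[1] != self.freq_hz.size:
            raise ValueError("frames do not match the frequency grid")


@dataclass
class EMTFCurve:
    """dB magnitude on the common log grid for one specimen (or a mean)."""
    specimen: str
    species: str
    grid_khz: np.ndarray
    magnitude_db: np.ndarray

    def __post_init__(self):
        self.grid_khz = np.asarray(self.grid_khz, dtype=float)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=float)
        if self.grid_khz.shape != self.magnitude_db.shape:
            raise ValueError("grid/magnitude length mismatch")
        if not np.all(np.isfinite(self.magnitude_db)):
            raise ValueError("magnitudes must be finite")

    def value_at(self, freq_khz):
        q = np.atleast_1d(np.asarray(freq_khz, dtype=float))
        if q.min() < self.grid_khz[0] * (1 - 1e-9) or \
           q.max() > self.grid_khz[-1] * (1 + 1e-9):
            raise ValueError("query outside the curve's grid")
        return np.interp(np.log2(q), np.log2(self.grid_khz), self.magnitude_db)


@dataclass
class FeatureSet:
    """Ordered alternating extrema and the slopes between them."""
    extrema: list                # (kind 'max'/'min', freq kHz, magnitude dB)
    slopes: list                 # dB/octave between consecutive extrema

    def frequency(self, kind: str, order: int) -> float:
        """Frequency of the order-th (1-based) extremum of a kind."""
        sel = [f for k, f, m in self.extrema if k == kind]
        return sel[order - 1]

    def magnitude(self, kind: str, order: int) -> float:
        sel = [m for k, f, m in self.extrema if k == kind]
        return sel[order - 1]


# ----------------------------------------------------------------------
# curve construction
# ----------------------------------------------------------------------

def average_frames(fr) -> np.ndarray:
    """Coherent (complex pointwise) mean across measurement frames."""
    frames = fr.frames if isinstance(fr, FrequencyResponse) else \
        np.atleast_2d(np.asarray(fr, dtype=complex))
    if frames.shape[0] < 1 or frames.size == 0:
        raise ValueError("no frames to average")
    return frames.mean(axis=0)


def concat_segments(parts) -> tuple:
    """Merge averaged spectra measured over overlapping frequency ranges.

    ``parts`` is a list of (freq_hz, complex spectrum).  Consecutive
    segments must overlap; within an overlap the merged value combines
    the log-domain (geometric) mean magnitude -- so two segments a flat
    2 dB apart merge to 1 dB from each -- with the circular mean phase.
    Returns (freq_hz, spectrum) on the union grid.
    """
    if not parts:
        raise ValueError("no segments")
    parts = sorted(((np.asarray(f, float), np.asarray(z, complex))
                    for f, z in parts), key=lambda p: p[0][0])
    for (fa, _), (fb, _) in zip(parts, parts[1:]):
        if fb[0] > fa[-1] * (1 + 1e-9):
            raise ValueError(f"gap between segments at {fa[-1]}..{fb[0]} Hz")
    union = np.unique(np.concatenate([f for f, _ in parts]))
    logmag = np.zeros(union.size)
    phasor = np.zeros(union.size, dtype=complex)
    count = np.zeros(union.size)
    for f, z in parts:
        idx = np.searchsorted(union, f)
        logmag[idx] += np.log(np.abs(z))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(np.abs(z) > 0, z / np.abs(z), 0.0)
        phasor[idx] += unit
        count[idx] += 1
    mag = np.exp(logmag / count)
    ang = np.angle(np.where(np.abs(phasor) > 0, phasor, 1.0))
    return union, mag * np.exp(1j * ang)


def metf_db(freq_hz, spectrum, grid_out_khz) -> np.ndarray:
    """Magnitude in dB re 1 mm s^-1/Pa, resampled to the output grid.

    Interpolation is linear in (log2 frequency, dB); the measured span
    must cover the output grid.
    """
    f = np.asarray(freq_hz, dtype=float)
    g = np.asarray(grid_out_khz, dtype=float) * 1e3
    if g.min() < f.min() * (1 - 1e-9) or g.max() > f.max() * (1 + 1e-9):
        raise ValueError("output grid outside the measured span")
    db = 20.0 * np.log10(np.abs(np.asarray(spectrum)))
    return np.interp(np.log2(g), np.log2(f), db)


def combine_emtf(metf: EMTFCurve, gain: EMTFCurve) -> EMTFCurve:
    """EMTF = METF + ear-canal pressure gain (pointwise dB sum)."""
    if not np.allclose(metf.grid_khz, gain.grid_khz, rtol=1e-9):
        raise ValueError("curves are not on a common grid")
    return EMTFCurve(metf.specimen, metf.species, metf.grid_khz,
                     metf.magnitude_db + gain.magnitude_db)


def load_frf_table(table) -> list:
    """FrequencyResponse objects from the CSV FRF dialect
    (frequency_hz, real, imag, frame, specimen, species[, segment])."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "segment" not in df.columns:
        df = df.assign(segment=0)
    out = []
    for (spec, species, seg), g in df.groupby(["specimen", "species",
                                               "segment"], sort=False):
        piv = g.pivot_table(index="frame", columns="frequency_hz",
                            values=["real", "imag"], sort=True)
        freq = piv["real"].columns.to_numpy(dtype=float)
        frames = piv["real"].to_numpy() + 1j * piv["imag"].to_numpy()
        out.append(FrequencyResponse(spec, species, freq, frames, int(seg)))
    return out


def emtf_from_frf(frf_table, gain_by_species, grid_khz=None) -> list:
    """Per-specimen EMTF curves from FRF frames plus canal gain.

    ``gain_by_species`` maps species to a (frequency_hz, gain_db) table
    (DataFrame or tuple of arrays).  Frames are averaged coherently,
    segments concatenated, magnitudes resampled to the analysis grid
    and the species' canal gain added.
    """
    grid = default_grid_khz() if grid_khz is None else np.asarray(grid_khz)
    responses = load_frf_table(frf_table) if not (
        isinstance(frf_table, list)) else frf_table
    by_spec: dict = {}
    for fr in responses:
        by_spec.setdefault((fr.specimen, fr.species), []).append(fr)
    curves = []
    for (specimen, species), frs in by_spec.items():
        parts = [(fr.freq_hz, average_frames(fr)) for fr in
                 sorted(frs, key=lambda r: r.segment)]
        freq, spectrum = concat_segments(parts)
        m = metf_db(freq, spectrum, grid)
        g = gain_by_species[species]
        if isinstance(g, pd.DataFrame):
            gf, gv = g["frequency_hz"].to_numpy(), g["gain_db"].to_numpy()
        else:
            gf, gv = np.asarray(g[0], float), np.asarray(g[1], float)
        gain = np.interp(np.log2(grid * 1e3), np.log2(gf), gv)
        curves.append(EMTFCurve(specimen, species, grid, m + gain))
    return curves


def group_mean(curves, label="mean") -> EMTFCurve:
    """Arithmetic mean of per-specimen dB magnitudes."""
    grid = curves[0].grid_khz
    for c in curves[1:]:
        if not np.allclose(c.grid_khz, grid):
            raise ValueError("curves are not on a common grid")
    mags = np.vstack([c.magnitude_db for c in curves])
    return EMTFCurve(label, curves[0].species, grid, mags.mean(axis=0))


# ----------------------------------------------------------------------
# feature extraction
# ----------------------------------------------------------------------

def _smooth(mag, window):
    if window <= 1:
        return mag
    pad = window // 2
    ext = np.concatenate([mag[pad:0:-1], mag, mag[-2:-2 - pad:-1]])
    return np.convolve(ext, np.ones(window) / window, mode="valid")


def extract_features(curve: EMTFCurve,
                     smoothing_octaves: float = 0.06) -> FeatureSet:
    """Ordered local extrema of the (smoothed) curve and the slopes
    between them.

    Smoothing is a centered moving average of width
    ``2*smoothing_octaves`` (default 5 grid points); ties on plateaus
    break toward the lower frequency.  Adjacent same-kind candidates are
    collapsed to the more extreme one so kinds alternate.
    """
    m = curve.magnitude_db
    window = 2 * int(round(smoothing_octaves / GRID_STEP_OCTAVES)) + 1
    if m.size < window + 2:
        raise ValueError("curve too short for the smoothing window")
    ms = _smooth(m, window)
    d = np.diff(ms)
    sign = np.sign(d)
    for i in range(1, sign.size):     # plateaus inherit the previous slope
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    cands = []
    for i in range(1, sign.size):
        if sign[i - 1] > 0 and sign[i] < 0:
            cands.append(("max", i))
        elif sign[i - 1] < 0 and sign[i] > 0:
            cands.append(("min", i))
    ext = []
    for kind, i in cands:
        if ext and ext[-1][0] == kind:
            j = ext[-1][1]
            better = ms[i] > ms[j] if kind == "max" else ms[i] < ms[j]
            if better:
                ext[-1] = (kind, i)
        else:
            ext.append((kind, i))
    if not any(k == "max" for k, _ in ext):
        raise ValueError("no maximum found on the curve")
    extrema = [(k, float(curve.grid_khz[i]), float(ms[i])) for k, i in ext]
    slopes = [
        (m2 - m1) / np.log2(f2 / f1)
        for (_, f1, m1), (_, f2, m2) in zip(extrema, extrema[1:])
    ]
    return FeatureSet(extrema=extrema, slopes=slopes)


# ----------------------------------------------------------------------
# group comparison
# ----------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Per-frequency two-group comparison with FDR control."""
    grid_khz: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    diff: np.ndarray             # mean_a - mean_b, dB
    p_variance: np.ndarray
    p_mean: np.ndarray
    p_adjusted: np.ndarray
    used_welch: np.ndarray
    significant: np.ndarray
    bands: list = field(default_factory=list)
    fraction_significant: dict = field(default_factory=dict)


def _bands(grid, sig, diff):
    out = []
    i, n = 0, grid.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        s = np.sign(diff[i])
        j = i
        while j + 1 < n and sig[j + 1] and np.sign(diff[j + 1]) == s:
            j += 1
        out.append({
            "start_khz": float(grid[i]), "stop_khz": float(grid[j]),
            "sign": int(s), "n_points": int(j - i + 1),
            "mean_diff_db": float(diff[i:j + 1].mean()),
        })
        i = j + 1
    return out


def compare_groups(a, b, variance_gate: float = 0.05,
                   q: float = 0.05) -> ComparisonResult:
    """Frequency-wise comparison of two groups of EMTF curves.

    At each grid frequency a two-sided F test on the variances decides
    (at ``variance_gate``, unadjusted) between the pooled-variance and
    the Welch t test; Benjamini-Hochberg adjustment across all grid
    frequencies then flags significance at adjusted p < ``q``.  Bands
    are maximal runs of significant frequencies with a common sign of
    the mean difference; the significant fraction per direction is the
    log-frequency measure of those bands (one 0.03-octave step per
    point) relative to the full logged range.
    """
    A = np.vstack([c.magnitude_db for c in a])
    B = np.vstack([c.magnitude_db for c in b])
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least two curves per group")
    grid = a[0].grid_khz
    for c in list(a) + list(b):
        if not np.allclose(c.grid_khz, grid):
            raise ValueError("curves are not on a common grid")
    na, nb = A.shape[0], B.shape[0]
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    F = va / vb
    cdf = stats.f.cdf(F, na - 1, nb - 1)
    p_var = 2.0 * np.minimum(cdf, 1.0 - cdf)
    t_pool = stats.ttest_ind(A, B, axis=0, equal_var=True)
    t_welch = stats.ttest_ind(A, B, axis=0, equal_var=False)
    use_welch = p_var < variance_gate
    p_mean = np.where(use_welch, t_welch.pvalue, t_pool.pvalue)
    p_adj = multipletests(p_mean, method="fdr_bh")[1]
    sig = p_adj < q
    diff = A.mean(axis=0) - B.mean(axis=0)
    bands = _bands(grid, sig, diff)
    steps = grid.size - 1
    frac = {
        "a_higher": float(np.sum(sig & (diff > 0)) / steps),
        "b_higher": float(np.sum(sig & (diff < 0)) / steps),
    }
    return ComparisonResult(
        grid_khz=grid, mean_a=A.mean(axis=0), mean_b=B.mean(axis=0),
        diff=diff, p_variance=p_var, p_mean=p_mean, p_adjusted=p_adj,
        used_welch=use_welch, significant=sig, bands=bands,
        fraction_significant=frac)
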