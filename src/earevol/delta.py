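"""Chimpanzee/human difference sets and their linear-model comparison.

Difference sets are built at fixed published frequency lists.  By
convention audiogram differences are chimpanzee minus human while
transfer-function and sound-power differences are human minus
chimpanzee, so that a negative value always means the chimpanzee ear is
the more sensitive one.  The transfer-function difference at 125 Hz is
extrapolated with two quadratic fits over 200-400 Hz and 200-800 Hz
whose predictions are averaged.  Candidate explanations are ranked by
AICc evidence ratios exp(dAICc / 2).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .audiograms import Audiogram, interpolate_thresholds
from .phylo import aicc
from .transfer import EMTFCurve

__all__ = [
    "DELTA_FREQS_HZ", "DeltaSet", "RegressionFit",
    "build_delta", "extrapolate_delta_125", "fit_linear",
    "adjust_family", "evidence_ratios",
]

# published per-label measurement frequencies (Hz)
DELTA_FREQS_HZ = {
    "ELDER": [125, 250, 500, 1000, 2000, 4000, 8000],
    "KOJIMA": [125, 250, 500, 1000, 2000, 4000, 8000],
    "AVERAGE": [125, 250, 500, 1000, 2000, 4000, 8000],
    "POWER": [125, 250, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000,
              4500, 5000],
    "EMTF": [125, 250, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000,
             4500, 5000, 8000],
}
_LABELS = tuple(DELTA_FREQS_HZ)


@dataclass
class DeltaSet:
    """Signed species differences (dB) at named frequencies."""
    label: str
    freqs_hz: np.ndarray
    values_db: np.ndarray
    orientation: str = ""        # e.g. "chimp-human" or "human-chimp"

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.values_db = np.asarray(self.values_db, dtype=float)
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.freqs_hz.size != self.values_db.size:
            raise ValueError("frequency/value length mismatch")

    def restrict(self, freqs_hz) -> "DeltaSet":
        f = np.asarray(freqs_hz, dtype=float)
        idx = [int(np.argmin(np.abs(self.freqs_hz - q))) for q in f]
        if np.any(np.abs(self.freqs_hz[idx] - f) > 1e-6 * f):
            raise ValueError("requested frequency not in the set")
        return DeltaSet(self.label, f, self.values_db[idx], self.orientation)


@dataclass
class RegressionFit:
    """OLS summary of one difference-vs-difference regression."""
    label: str
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    p_adjusted: float
    aicc: float
    n: int


def _eval_curve(obj, freqs_hz):
    """Value of an audiogram (dB threshold) or EMTF curve (dB magnitude)
    at the given frequencies in Hz."""
    f = np.asarray(freqs_hz, dtype=float)
    if isinstance(obj, Audiogram):
        return interpolate_thresholds(obj, f / 1e3)
    if isinstance(obj, EMTFCurve):
        return obj.value_at(f / 1e3)
    raise TypeError(f"cannot evaluate {type(obj)!r} at frequencies")


def build_delta(a, b, freqs_hz, label, orientation="a-b") -> DeltaSet:
    """Pointwise signed difference a(f) - b(f) at the listed frequencies.

    ``a``/``b`` are audiograms or EMTF curves (interpolated as needed).
    Pick the operand order so that negative values mean the chimpanzee
    ear is more sensitive: chimp - human for audiogram thresholds,
    human - chimp for transfer functions.
    """
    f = np.asarray(freqs_hz, dtype=float)
    return DeltaSet(label, f, _eval_curve(a, f) - _eval_curve(b, f),
                    orientation)


def extrapolate_delta_125(emtf_human: EMTFCurve, emtf_chimp: EMTFCurve,
                          abscissa: str = "hz") -> float:
    """Human-minus-chimp transfer-function difference at 125 Hz.

    For each species a 2nd-degree polynomial is fitted to the mean
    curve over 200-400 Hz and over 200-800 Hz (at least 31 points are
    required in the narrow window); the two 125 Hz predictions are
    averaged per species before differencing.  ``abscissa`` selects raw
    frequency in Hz (default) or log10 frequency.
    """
    preds = {}
    for name, curve in (("human", emtf_human), ("chimp", emtf_chimp)):
        f = curve.grid_khz * 1e3
        vals = []
        for lo, hi in ((200.0, 400.0), (200.0, 800.0)):
            sel = (f >= lo * (1 - 1e-9)) & (f <= hi * (1 + 1e-9))
            if lo == 200.0 and hi == 400.0 and sel.sum() < 31:
                raise ValueError("need >= 31 points in the 200-400 Hz window")
            x = f[sel] if abscissa == "hz" else np.log10(f[sel])
            x0 = 125.0 if abscissa == "hz" else np.log10(125.0)
            coef = np.polyfit(x, curve.magnitude_db[sel], 2)
            vals.append(float(np.polyval(coef, x0)))
        preds[name] = float(np.mean(vals))
    return preds["human"] - preds["chimp"]


def fit_linear(y: DeltaSet, x: DeltaSet) -> RegressionFit:
    """OLS regression y = slope * x + intercept with AICc.

    AICc uses the Gaussian residual likelihood with k = 3 (slope,
    intercept, residual variance).  The reported p value is the
    two-sided slope test; use :func:`adjust_family` to FDR-adjust
    p values across the family of reported regressions.
    """
    if y.freqs_hz.size != x.freqs_hz.size or \
            not np.allclose(y.freqs_hz, x.freqs_hz):
        raise ValueError("difference sets are on different frequency lists")
    n = y.freqs_hz.size
    if n < 3:
        raise ValueError("need at least 3 frequencies")
    if np.var(x.values_db) == 0:
        raise ValueError("zero variance in the predictor")
    X = sm.add_constant(x.values_db)
    res = sm.OLS(y.values_db, X).fit()
    rss = float(res.ssr)
    sigma2 = max(rss / n, 1e-300)      # ML residual variance
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return RegressionFit(
        label=x.label, slope=float(res.params[1]),
        intercept=float(res.params[0]), adj_r2=float(res.rsquared_adj),
        p_value=float(res.pvalues[1]), p_adjusted=np.nan,
        aicc=aicc(ll, 3, n), n=n)


def adjust_family(fits) -> list:
    """Benjamini-Hochberg adjustment of slope p values across the
    declared family of regression models (returns new fits)."""
    padj = multipletests([f.p_value for f in fits], method="fdr_bh")[1]
    out = []
    for f, p in zip(fits, padj):
        out.append(RegressionFit(f.label, f.slope, f.intercept, f.adj_r2,
                                 f.p_value, float(p), f.aicc, f.n))
    return out


def evidence_ratios(fits) -> dict:
    """exp((AICc_i - AICc_min)/2): how many times less probable each
    model is than the best one (best model maps to 1)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    pairs = []
    for i, f in enumerate(fits):
        if isinstance(f, RegressionFit):
            pairs.append((f.label, f.aicc))
        elif isinstance(f, (int, float, np.floating)):
            pairs.append((f"model_{i + 1}", float(f)))
        else:
            pairs.append(tuple(f))
    amin = min(a for _, a in pairs)
    return {lab: float(np.exp((a - amin) / 2.0)) for lab, a in pairs}
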