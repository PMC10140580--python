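"""Versioned catalog of automated time-series functionals.

Each functional maps a 1-D float array (one fully imputed feature-window
series) to one scalar. The catalog is a fixed ordered list so that feature
vectors are deterministic and comparable across runs; the version string is
recorded in feature provenance. Functionals that are undefined on a
degenerate input (e.g. autocorrelation of a constant series) return the
documented sentinel 0.0 instead of a missing value.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pywt
from scipy import stats

CATALOG_VERSION = "1.0"

_SENTINEL = 0.0


def _safe(f: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    def wrapped(x: np.ndarray) -> float:
        try:
            v = float(f(x))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            return _SENTINEL
        return v if np.isfinite(v) else _SENTINEL

    return wrapped


def _autocorr(x: np.ndarray, lag: int) -> float:
    if len(x) <= lag or np.std(x) == 0:
        return _SENTINEL
    a, b = x[:-lag], x[lag:]
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return _SENTINEL
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _fft_abs(x: np.ndarray, k: int) -> float:
    coeffs = np.fft.rfft(x - np.mean(x) if k > 0 else x)
    if k >= len(coeffs):
        return _SENTINEL
    return float(np.abs(coeffs[k])) / len(x)


def _wavelet_energy(x: np.ndarray, level: int) -> float:
    """Energy fraction in decomposition level (0 = approximation)."""
    max_level = pywt.dwt_max_level(len(x), "db2")
    if max_level < 1:
        return _SENTINEL
    coeffs = pywt.wavedec(x, "db2", level=min(3, max_level))
    if level >= len(coeffs):
        return _SENTINEL
    total = sum(float(np.sum(c * c)) for c in coeffs)
    if total == 0:
        return _SENTINEL
    return float(np.sum(coeffs[level] ** 2)) / total


def _binned_entropy(x: np.ndarray, bins: int = 10) -> float:
    if np.ptp(x) == 0:
        return _SENTINEL
    hist, _ = np.histogram(x, bins=bins)
    p = hist[hist > 0] / len(x)
    return float(-(p * np.log(p)).sum())


def _trend_slope(x: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0:
        return _SENTINEL
    return float(stats.linregress(np.arange(len(x)), x).slope)


def _trend_r(x: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0:
        return _SENTINEL
    return float(stats.linregress(np.arange(len(x)), x).rvalue)


def _mean_crossings(x: np.ndarray) -> float:
    centered = x - np.mean(x)
    return float(np.sum(np.diff(np.signbit(centered)) != 0))


def _longest_strike_above_mean(x: np.ndarray) -> float:
    above = x > np.mean(x)
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return float(best)


def build_catalog() -> list[tuple[str, Callable[[np.ndarray], float]]]:
    """The ordered (name, functional) catalog, version :data:`CATALOG_VERSION`."""
    cat: list[tuple[str, Callable[[np.ndarray], float]]] = [
        ("mean", _safe(np.mean)),
        ("median", _safe(np.median)),
        ("variance", _safe(lambda x: np.var(x))),
        ("std", _safe(lambda x: np.std(x))),
        ("skewness", _safe(lambda x: stats.skew(x) if np.std(x) > 0 else _SENTINEL)),
        ("kurtosis", _safe(lambda x: stats.kurtosis(x) if np.std(x) > 0 else _SENTINEL)),
        ("minimum", _safe(np.min)),
        ("maximum", _safe(np.max)),
        ("range", _safe(np.ptp)),
        ("iqr", _safe(lambda x: stats.iqr(x))),
        ("rms", _safe(lambda x: np.sqrt(np.mean(x * x)))),
        ("mean_abs_change", _safe(lambda x: np.mean(np.abs(np.diff(x))))),
        ("mean_change", _safe(lambda x: (x[-1] - x[0]) / (len(x) - 1))),
        ("count_above_mean", _safe(lambda x: np.sum(x > np.mean(x)))),
        ("mean_crossings", _safe(_mean_crossings)),
        ("longest_strike_above_mean", _safe(_longest_strike_above_mean)),
        ("binned_entropy__bins_10", _safe(_binned_entropy)),
        ("linear_trend__slope", _safe(_trend_slope)),
        ("linear_trend__rvalue", _safe(_trend_r)),
    ]
    for lag in (1, 2, 3, 6, 12):
        cat.append((f"autocorrelation__lag_{lag}",
                    _safe(lambda x, lag=lag: _autocorr(x, lag))))
    for k in range(6):
        cat.append((f"fft_abs__coeff_{k}", _safe(lambda x, k=k: _fft_abs(x, k))))
    for level in range(4):
        cat.append((f"wavelet_db2__energy_level_{level}",
                    _safe(lambda x, level=level: _wavelet_energy(x, level))))
    return cat
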