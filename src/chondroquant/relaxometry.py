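"""Per-voxel T2 fitting and robust per-VOI aggregation.

The fit is a monoexponential ``S(TE) = S0 * exp(-TE / T2)`` estimated by
least squares on ``ln S`` versus TE.  The first echo is excluded by default
to avoid stimulated-echo contamination.  Per-VOI medians apply the Raya
exclusion rule: drop values strictly below 0 ms, then drop values above
``median + 3 * IQR`` of the remainder (single pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from .geometry import VolumeGeometry

__all__ = [
    "MultiEchoVolume",
    "T2Map",
    "MedianT2Result",
    "fit_voxel_t2",
    "fit_t2_map",
    "median_t2",
    "ml_ratio",
    "annualized_change",
    "ML_RATIO_PAIRS",
]

# validity reason codes
REASON_OK = 0
REASON_OUTSIDE_MASK = 1
REASON_NONPOSITIVE_SIGNAL = 2
REASON_TOO_FEW_ECHOES = 3

#: medial / lateral VOI pairs entering ratio computation
ML_RATIO_PAIRS: dict[str, tuple[str, str]] = {
    "Ra": ("Ma", "La"),
    "Rc": ("Mc", "Lc"),
    "Rp": ("Mp", "Lp"),
    "Rae": ("Mae", "Lae"),
    "Rac": ("Mac", "Lac"),
    "Rai": ("Mai", "Lai"),
}


@dataclass
class MultiEchoVolume:
    """Multi-slice multi-echo acquisition: one magnitude volume per echo."""

    echo_times: np.ndarray  # ms, strictly ascending
    signals: np.ndarray  # (n_echoes, nx, ny, nz), magnitudes >= 0
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if te.ndim != 1 or len(te) < 3:
            raise ValueError("need at least 3 echo times")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly ascending")
        if sig.ndim != 4 or sig.shape[0] != len(te):
            raise ValueError("signals must be (n_echoes, nx, ny, nz)")
        if tuple(sig.shape[1:]) != tuple(self.geometry.dims):
            raise ValueError("signal dims do not match geometry dims")
        if np.any(sig < 0):
            raise ValueError("magnitude signals must be non-negative")
        self.echo_times = te
        self.signals = sig

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


@dataclass
class T2Map:
    """Per-voxel fitted T2 (ms), S0, log-linear R^2 and validity."""

    t2: np.ndarray
    s0: np.ndarray
    r2: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    geometry: VolumeGeometry | None = None


@dataclass
class MedianT2Result:
    median: float
    n_used: int
    n_excluded_negative: int
    n_excluded_outlier: int
    missing: bool = False
    reason: str = ""


def _loglinear(te: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (te, y); returns slope, intercept, r2."""
    tbar = te.mean()
    ybar = y.mean()
    dt = te - tbar
    sxx = float(dt @ dt)
    slope = float(dt @ (y - ybar)) / sxx
    intercept = ybar - slope * tbar
    ss_tot = float(((y - ybar) ** 2).sum())
    ss_res = float(((y - (intercept + slope * te)) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_voxel_t2(
    signal: np.ndarray,
    echo_times: np.ndarray,
    exclude_first: bool = True,
    method: str = "loglinear",
) -> tuple[float, float, float]:
    """Fit one voxel's decay; returns ``(T2 ms, S0, R^2)``.

    A non-increasing log signal yields a negative or infinite T2, returned
    as-is: the downstream median exclusion rule removes it.  Non-positive
    signal at a used echo, or fewer than two usable echoes, raises
    ``ValueError`` (the voxel is invalid).
    """
    s = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if s.shape != te.shape:
        raise ValueError("signal and echo_times must align")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly ascending")
    if exclude_first:
        s, te = s[1:], te[1:]
    if len(te) < 2:
        raise ValueError("fewer than 2 usable echoes")
    if np.any(s <= 0):
        raise ValueError("non-positive signal at a used echo")
    slope, intercept, r2 = _loglinear(te, np.log(s))
    t2 = np.inf if slope == 0 else -1.0 / slope
    s0 = float(np.exp(intercept))
    if method == "nonlinear":
        if np.isfinite(t2) and t2 > 0:
            try:
                popt, _ = curve_fit(
                    lambda t, a, b: a * np.exp(-t / b), te, s, p0=(s0, t2), maxfev=500
                )
                s0, t2 = float(popt[0]), float(popt[1])
                pred = popt[0] * np.exp(-te / popt[1])
                ss_tot = float(((s - s.mean()) ** 2).sum())
                r2 = 1.0 if ss_tot == 0 else 1.0 - float(((s - pred) ** 2).sum()) / ss_tot
            except RuntimeError:
                pass  # keep log-linear estimate
    elif method != "loglinear":
        raise ValueError(f"unknown fit method {method!r}")
    return float(t2), float(s0), float(r2)


def fit_t2_map(
    volume: MultiEchoVolume,
    mask: np.ndarray | None = None,
    exclude_first: bool = True,
) -> T2Map:
    """Vectorized log-linear fit over a voxel mask.

    Identical in value to calling :func:`fit_voxel_t2` voxel by voxel.
    Voxels outside the mask, or with non-positive signal at a used echo,
    are invalid with a reason code.
    """
    dims = volume.geometry.dims
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(dims):
        raise ValueError("mask shape does not match volume dims")
    if not mask.any():
        warnings.warn("empty mask: no voxels to fit", stacklevel=2)

    start = 1 if exclude_first else 0
    te = volume.echo_times[start:]
    sig = volume.signals[start:]

    t2 = np.full(dims, np.nan)
    s0 = np.full(dims, np.nan)
    r2 = np.full(dims, np.nan)
    reason = np.full(dims, REASON_OUTSIDE_MASK, dtype=np.int8)
    reason[mask] = REASON_OK

    if len(te) < 2:
        reason[mask] = REASON_TOO_FEW_ECHOES
        return T2Map(t2, s0, r2, np.zeros(dims, bool), reason, volume.geometry)

    sel = sig[:, mask]  # (E, V)
    bad = np.any(sel <= 0, axis=0)
    reason_flat = reason[mask]
    reason_flat[bad] = REASON_NONPOSITIVE_SIGNAL
    reason[mask] = reason_flat

    good = ~bad
    if good.any():
        y = np.log(sel[:, good])
        tbar = te.mean()
        dt = te - tbar
        sxx = float(dt @ dt)
        ybar = y.mean(axis=0)
        slope = (dt @ (y - ybar)) / sxx
        intercept = ybar - slope * tbar
        with np.errstate(divide="ignore"):
            t2_flat = np.where(slope == 0, np.inf, -1.0 / slope)
        pred = intercept[None, :] + np.outer(te, slope)
        ss_tot = ((y - ybar) ** 2).sum(axis=0)
        ss_res = ((y - pred) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_flat = np.where(ss_tot == 0, 1.0, 1.0 - ss_res / ss_tot)

        t2_full = np.full(good.shape, np.nan)
        s0_full = np.full(good.shape, np.nan)
        r2_full = np.full(good.shape, np.nan)
        t2_full[good] = t2_flat
        s0_full[good] = np.exp(intercept)
        r2_full[good] = r2_flat
        t2[mask] = t2_full
        s0[mask] = s0_full
        r2[mask] = r2_full

    valid = reason == REASON_OK
    return T2Map(t2, s0, r2, valid, reason, volume.geometry)


def median_t2(
    values: np.ndarray,
    quantile_method: str = "linear",
    order: str = "negatives_first",
) -> MedianT2Result:
    """Robust per-VOI median with the two-step exclusion rule.

    Step 1 removes values strictly less than 0 ms (0 itself is kept).
    Step 2 computes the median and IQR of the remainder and removes values
    strictly above ``median + 3 * IQR``; infinite or NaN values count as
    outliers above any finite cutoff.  ``order="pooled"`` computes the
    cutoff on the full collection before negative removal (the rule's
    wording does not fix this; negatives-first is the default).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty collection")
    neg = v < 0
    survivors = v[~neg]
    n_neg = int(neg.sum())
    if survivors.size == 0:
        return MedianT2Result(np.nan, 0, n_neg, 0, missing=True, reason="all values negative")

    cutoff_pool = survivors if order == "negatives_first" else v
    finite_pool = cutoff_pool[np.isfinite(cutoff_pool)]
    if finite_pool.size == 0:
        return MedianT2Result(
            np.nan, 0, n_neg, int(survivors.size), missing=True, reason="no finite values"
        )
    med = float(np.median(finite_pool))
    q75, q25 = np.quantile(finite_pool, [0.75, 0.25], method=quantile_method)
    cutoff = med + 3.0 * float(q75 - q25)

    outlier = (survivors > cutoff) | ~np.isfinite(survivors)
    used = survivors[~outlier]
    n_out = int(outlier.sum())
    if used.size == 0:
        return MedianT2Result(np.nan, 0, n_neg, n_out, missing=True, reason="all values excluded")
    return MedianT2Result(float(np.median(used)), int(used.size), n_neg, n_out)


def ml_ratio(summaries: Mapping[str, float]) -> dict[str, float]:
    """Medial/lateral ratios (e.g. Ra = Ma / La) for every available pair.

    A missing, NaN or zero lateral value makes the ratio NaN.
    """
    out: dict[str, float] = {}
    for name, (med, lat) in ML_RATIO_PAIRS.items():
        if med not in summaries or lat not in summaries:
            continue
        m, l = float(summaries[med]), float(summaries[lat])
        if not np.isfinite(l) or l == 0 or not np.isfinite(m):
            out[name] = np.nan
        else:
            out[name] = m / l
    return out


def annualized_change(v_start: float, v_end: float, months_between: float) -> float:
    """Percent change per year: ``100 * ((v_end - v_start)/v_start) / (months/12)``.

    NaN when v_start is 0 (undefined baseline).
    """
    if months_between <= 0:
        raise ValueError("months_between must be positive")
    if v_start == 0:
        return float("nan")
    return 100.0 * ((v_end - v_start) / v_start) / (months_between / 12.0)
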