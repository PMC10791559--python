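"""Thresholded Pearson colocalization with Costes automatic thresholds.

The Pearson correlation coefficient (PCC) over all masked pixels is dominated
by the background in sparse images.  The Costes procedure removes that bias:
fit an orthogonal regression line ``b = s*a + c`` through the joint histogram,
then lower a threshold pair ``(Ta, s*Ta + c)`` along that line until the
pixels *below* both thresholds are uncorrelated (PCC <= 0); the PCC reported
is then computed over the remaining (above-threshold) pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgeo import RegionMask


@dataclass
class ColocResult:
    pcc_all: float
    pcc_above_threshold: float  # NaN when thresholds are undefined
    threshold_a: float
    threshold_b: float
    regression_slope: float
    regression_intercept: float
    n_pixels_used: int
    pixel_convention: str


def pearson(a: np.ndarray, b: np.ndarray, mask: RegionMask | np.ndarray | None = None) -> float:
    """Sample Pearson correlation over masked pixels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one channel")
    return float((da @ db) / np.sqrt(va * vb))


def _orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Total least squares line b = s*a + c via the principal axis."""
    da = a - a.mean()
    db = b - b.mean()
    cov = np.cov(np.vstack([da, db]))
    # principal eigenvector of the 2x2 covariance
    _, vecs = np.linalg.eigh(cov)
    vx, vy = vecs[:, -1]
    if vx == 0:
        return np.inf, np.nan
    s = vy / vx
    c = b.mean() - s * a.mean()
    return float(s), float(c)


def _below_pcc(a: np.ndarray, b: np.ndarray, ta: float, s: float, c: float) -> float:
    """PCC of pixels below the candidate threshold pair; 0 when degenerate.

    Fewer than two below-threshold pixels, or zero variance among them, count
    as "uncorrelated" so the bisection can keep descending.
    """
    sel = (a < ta) & (b < s * ta + c)
    if sel.sum() < 2:
        return 0.0
    try:
        return pearson(a[sel], b[sel])
    except ValueError:
        return 0.0


def costes_thresholds(
    a: np.ndarray,
    b: np.ndarray,
    mask: RegionMask | np.ndarray | None = None,
    tol: float = 0.5,
    max_iter: int = 200,
) -> tuple[float, float, float, float]:
    """Find the Costes automatic threshold pair ``(Ta, Tb)``.

    ``Ta`` descends from the channel maximum in steps of ``tol`` and stops at
    the first (highest) threshold whose below-threshold pixel population is
    non-positively correlated; ``Tb = s*Ta + c`` on the orthogonal regression
    line.  The below-threshold PCC is not monotone in the threshold (it
    fluctuates around zero at the sampling-noise scale), so a descending scan
    — not bisection — matches the first-crossing definition.  If no crossing
    exists the threshold falls to the channel minimum (every pixel
    colocalized); a non-positive regression slope leaves the thresholds
    undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    s, c = _orthogonal_regression(a, b)
    if not np.isfinite(s) or s <= 0:
        warnings.warn("regression slope <= 0; Costes thresholds undefined")
        return np.nan, np.nan, s, c
    lo, hi = float(a.min()), float(a.max())
    n_steps = min(int(np.ceil((hi - lo) / tol)), max_iter * 100)
    ta = lo
    for t in np.linspace(hi, lo, n_steps + 1):
        if _below_pcc(a, b, t, s, c) <= 0:
            ta = float(t)
            break
    return ta, float(s * ta + c), s, c


def thresholded_pcc(
    a: np.ndarray,
    b: np.ndarray,
    mask: RegionMask | np.ndarray | None = None,
    pixel_convention: str = "either",
    tol: float = 0.5,
) -> ColocResult:
    """Full thresholded-PCC analysis of a channel pair.

    ``pixel_convention`` selects which pixels enter the above-threshold PCC:
    ``either`` (default — a > Ta or b > Tb), ``both``, or ``all`` (no
    thresholding).
    """
    if pixel_convention not in ("either", "both", "all"):
        raise ValueError(f"unknown pixel convention {pixel_convention!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is not None:
        m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, bool)
        av, bv = a[m], b[m]
    else:
        av, bv = a.ravel(), b.ravel()
    pcc_all = pearson(av, bv)
    ta, tb, s, c = costes_thresholds(av, bv, tol=tol)
    if not np.isfinite(ta):
        return ColocResult(pcc_all, np.nan, ta, tb, s, c, 0, pixel_convention)
    if pixel_convention == "all":
        sel = np.ones_like(av, dtype=bool)
    elif pixel_convention == "both":
        sel = (av > ta) & (bv > tb)
    else:
        sel = (av > ta) | (bv > tb)
    n = int(sel.sum())
    if n < 2:
        warnings.warn("fewer than 2 above-threshold pixels; PCC missing")
        return ColocResult(pcc_all, np.nan, ta, tb, s, c, n, pixel_convention)
    try:
        pcc_thr = pearson(av[sel], bv[sel])
    except ValueError:
        warnings.warn("zero variance above threshold; PCC missing")
        pcc_thr = np.nan
    return ColocResult(pcc_all, pcc_thr, ta, tb, s, c, n, pixel_convention)
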