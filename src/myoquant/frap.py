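"""FRAP trace correction, normalization, and constrained biexponential fits.

Processing order for a bleached ROI:

1. subtract the cell-free background ROI (ROI 4),
2. divide out acquisition photobleaching using the unbleached reference
   (ROI 3), rescaled to its prebleach mean,
3. normalize to 1 at the last prebleach scan and 0 at the first post-bleach
   scan,
4. fit ``N(t) = A1*(1 - exp(-t/tau1)) + A2*(1 - exp(-t/tau2))`` over the
   post-bleach scans, with ``t = 0`` at the first post-bleach scan.

``A1 + A2`` is the mobile fraction; the headline statistic is the fitted
percent recovery 2 min after photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

TAU_MIN_S = 0.1
TAU_MAX_S = 1.0e4
AMP_MAX = 1.5  # loose physical bound; a mobile fraction > 1 is flagged, not clipped


@dataclass
class FRAPTrace:
    """Per-ROI mean intensity per scan.

    ROI ids follow the acquisition convention: 1 = cell center (bleached),
    2 = cell end (bleached), 3 = unbleached reference, 4 = cell-free
    background.
    """

    roi_id: int
    values: np.ndarray
    scan_interval_s: float = 0.5
    n_prebleach: int = 25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.values.size <= self.n_prebleach:
            raise ValueError("trace shorter than the prebleach segment")

    @property
    def n_postbleach(self) -> int:
        return self.values.size - self.n_prebleach

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.scan_interval_s


@dataclass
class FRAPFit:
    A1: float
    A2: float
    tau1_s: float
    tau2_s: float
    rss: float
    recovery_2min_pct: float
    recovery_2min_pct_raw: float

    @property
    def mobile_fraction(self) -> float:
        return self.A1 + self.A2


def traces_from_table(table: pd.DataFrame, scan_interval_s: float = 0.5,
                      n_prebleach: int = 25) -> dict[int, FRAPTrace]:
    """Build per-ROI traces from a long-format (roi, scan, value) table."""
    out = {}
    for roi, grp in table.groupby("roi"):
        vals = grp.sort_values("scan")["value"].to_numpy()
        out[int(roi)] = FRAPTrace(int(roi), vals, scan_interval_s, n_prebleach)
    return out


def subtract_background(trace: FRAPTrace, background: FRAPTrace) -> FRAPTrace:
    if trace.values.size != background.values.size:
        raise ValueError("trace lengths differ")
    return replace(trace, values=trace.values - background.values)


def bleach_correct(target: FRAPTrace, reference: FRAPTrace) -> FRAPTrace:
    """Remove acquisition photobleaching using the unbleached reference ROI.

    ``corrected(t) = target(t) * ref_pre / reference(t)`` where ``ref_pre``
    is the reference mean over the prebleach scans.
    """
    if target.values.size != reference.values.size:
        raise ValueError("trace lengths differ")
    if np.any(reference.values <= 0):
        raise ValueError("reference trace crosses zero; cannot bleach-correct")
    ref_pre = reference.values[: reference.n_prebleach].mean()
    return replace(target, values=target.values * ref_pre / reference.values)


def normalize_frap(trace: FRAPTrace) -> FRAPTrace:
    """Normalize to 1 at the last prebleach scan and 0 at the first
    post-bleach scan (single scans, per the acquisition convention)."""
    f_pre = trace.values[trace.n_prebleach - 1]
    f_post = trace.values[trace.n_prebleach]
    span = f_pre - f_post
    if span <= 0:
        raise ValueError("non-positive bleach span: photobleaching failed")
    return replace(trace, values=(trace.values - f_post) / span)


def _model(t: np.ndarray, a1: float, a2: float, t1: float, t2: float) -> np.ndarray:
    return a1 * (1 - np.exp(-t / t1)) + a2 * (1 - np.exp(-t / t2))


def _amp_init(t: np.ndarray, y: np.ndarray, t1: float, t2: float) -> tuple[float, float]:
    """Linear least-squares amplitudes for fixed time constants."""
    basis = np.column_stack([1 - np.exp(-t / t1), 1 - np.exp(-t / t2)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return tuple(np.clip(coef, 0.0, AMP_MAX))


_TAU_STARTS = [(1.0, 30.0), (5.0, 60.0), (0.5, 300.0), (10.0, 1000.0),
               (2.0, 20.0), (30.0, 3000.0)]


def fit_biexponential(trace: FRAPTrace) -> FRAPFit:
    """Fit the constrained biexponential recovery to a normalized trace.

    Multi-start least squares (amplitude inits solved linearly per tau pair);
    the best-RSS solution wins and taus are ordered ``tau1 < tau2``.
    """
    if trace.n_postbleach < 20:
        raise ValueError("need at least 20 post-bleach scans")
    t = (np.arange(trace.n_postbleach)) * trace.scan_interval_s
    y = trace.values[trace.n_prebleach:]

    def residuals(p):
        return _model(t, *p) - y

    best = None
    lb = [0.0, 0.0, TAU_MIN_S, TAU_MIN_S]
    ub = [AMP_MAX, AMP_MAX, TAU_MAX_S, TAU_MAX_S]
    for t1, t2 in _TAU_STARTS:
        a1, a2 = _amp_init(t, y, t1, t2)
        try:
            sol = least_squares(
                residuals, [a1, a2, t1, t2], bounds=(lb, ub),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("biexponential fit failed to converge from all starts")
    rss, (a1, a2, t1, t2) = best
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1
    fit_2min = 100.0 * _model(np.array([120.0]), a1, a2, t1, t2)[0]
    idx_2min = min(int(round(120.0 / trace.scan_interval_s)), y.size - 1)
    return FRAPFit(
        A1=float(a1), A2=float(a2), tau1_s=float(t1), tau2_s=float(t2),
        rss=rss, recovery_2min_pct=fit_2min,
        recovery_2min_pct_raw=100.0 * float(y[idx_2min]),
    )


def analyze_frap_table(
    table: pd.DataFrame,
    scan_interval_s: float = 0.5,
    n_prebleach: int = 25,
) -> dict[int, FRAPFit]:
    """Full pipeline on a four-ROI table: background subtraction, bleach
    correction against ROI 3, normalization, and biexponential fits of the
    bleached ROIs 1 and 2."""
    traces = traces_from_table(table, scan_interval_s, n_prebleach)
    for roi in (1, 2, 3, 4):
        if roi not in traces:
            raise ValueError(f"ROI {roi} missing from the table")
    bg = traces[4]
    ref = subtract_background(traces[3], bg)
    fits = {}
    for roi in (1, 2):
        target = subtract_background(traces[roi], bg)
        corrected = bleach_correct(target, ref)
        fits[roi] = fit_biexponential(normalize_frap(corrected))
    return fits
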