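"""Ensemble-current analysis of cell-attached sodium-current sweep families.

A patch is probed by a voltage ladder repeated several times; repeats are
averaged into an ensemble current per test voltage, and the headline metrics
are the maximal peak inward current across the ladder and the time constant
of inactivation of that maximal current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class SweepFamily:
    """Raw sweeps: (repeats, voltages, time) in pA, inward negative."""

    current: np.ndarray
    time_step_ms: float
    test_voltages_mV: np.ndarray
    pulse_start_idx: int
    pulse_end_idx: int

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        self.test_voltages_mV = np.asarray(self.test_voltages_mV, dtype=float)
        if self.current.ndim != 3:
            raise ValueError("current must be (repeats, voltages, time)")
        if self.current.shape[1] != self.test_voltages_mV.size:
            raise ValueError("voltage ladder does not match sweep array")
        steps = np.diff(self.test_voltages_mV)
        if steps.size and not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("voltage ladder must be strictly monotone")

    @property
    def n_repeats(self) -> int:
        return self.current.shape[0]

    def to_table(self) -> pd.DataFrame:
        """Long format (repeat, voltage, time_ms, current_pA)."""
        r, v, t = self.current.shape
        rep, vi, ti = np.meshgrid(np.arange(r), np.arange(v), np.arange(t),
                                  indexing="ij")
        return pd.DataFrame({
            "repeat": rep.ravel(),
            "voltage_mV": self.test_voltages_mV[vi.ravel()],
            "time_ms": ti.ravel() * self.time_step_ms,
            "current_pA": self.current.ravel(),
        })


def family_from_table(table: pd.DataFrame, time_step_ms: float,
                      pulse_start_idx: int, pulse_end_idx: int | None = None) -> SweepFamily:
    volts = np.sort(table["voltage_mV"].unique())
    reps = np.sort(table["repeat"].unique())
    piv = table.pivot_table(index=["repeat", "voltage_mV"], columns="time_ms",
                            values="current_pA", sort=True)
    n_t = piv.shape[1]
    cur = piv.to_numpy().reshape(reps.size, volts.size, n_t)
    return SweepFamily(cur, time_step_ms, volts, pulse_start_idx,
                       pulse_end_idx if pulse_end_idx is not None else n_t)


@dataclass
class INaStats:
    peak_amplitude_pA: float  # magnitude, >= 0
    peak_voltage_mV: float
    peak_time_ms: float
    tau_inact_ms: float
    fit_rss: float
    fit_offset_pA: float


def ensemble_average(family: SweepFamily) -> np.ndarray:
    """Mean over repeats: (voltages, time)."""
    if family.n_repeats < 1:
        raise ValueError("family has no repeats")
    return family.current.mean(axis=0)


def subtract_baseline(ensemble: np.ndarray, family: SweepFamily,
                      baseline_ms: float = 5.0) -> np.ndarray:
    """Subtract the mean of the pre-pulse window per voltage."""
    n = min(int(round(baseline_ms / family.time_step_ms)), family.pulse_start_idx)
    if n <= 0:
        return ensemble
    base = ensemble[:, family.pulse_start_idx - n:family.pulse_start_idx].mean(axis=1)
    return ensemble - base[:, None]


def peak_ina(
    ensemble: np.ndarray,
    family: SweepFamily,
    blank_ms: float = 0.3,
    baseline_ms: float = 5.0,
) -> tuple[float, float, float]:
    """Maximal peak inward current across the ladder.

    The first ``blank_ms`` of the pulse is excluded (residual capacitive
    transient); currents are baseline-subtracted per voltage.  Returns
    ``(amplitude_pA >= 0, voltage_mV, time_ms from pulse onset)``; an
    all-outward family yields amplitude 0 with a warning.
    """
    ens = subtract_baseline(ensemble, family, baseline_ms)
    start = family.pulse_start_idx + int(round(blank_ms / family.time_step_ms))
    stop = family.pulse_end_idx
    if start >= stop:
        raise ValueError("empty analysis window after blanking")
    window = ens[:, start:stop]
    minima = window.min(axis=1)
    j = int(np.argmin(minima))
    if minima[j] >= 0:
        warnings.warn("no inward current in any sweep; peak amplitude 0")
        return 0.0, float(family.test_voltages_mV[j]), np.nan
    k = int(np.argmin(window[j]))
    t_peak = (start + k - family.pulse_start_idx) * family.time_step_ms
    return float(-minima[j]), float(family.test_voltages_mV[j]), t_peak


def fit_inactivation(
    trace: np.ndarray,
    time_step_ms: float,
    peak_idx: int | None = None,
    end_idx: int | None = None,
) -> tuple[float, float, float] | None:
    """Monoexponential decay fit from the peak of an inward ensemble trace.

    Fits ``I(t) = I_peak * exp(-(t - t_peak)/tau) + c`` from the most-negative
    sample to ``end_idx``.  Returns ``(tau_ms, rss, c)``; a non-decaying trace
    yields ``None`` with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    if peak_idx is None:
        peak_idx = int(np.argmin(trace))
    seg = trace[peak_idx:end_idx]
    if seg.size < 10:
        raise ValueError("need at least 10 samples after the peak")
    tail = seg[-max(seg.size // 10, 1):].mean()
    i0 = seg[0] - tail
    if i0 >= 0:  # inward current must be more negative at the peak
        warnings.warn("trace does not decay from an inward peak; fit missing")
        return None
    t = np.arange(seg.size) * time_step_ms

    # log-linear initial guess on the decaying span
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(np.clip((seg - tail) / i0, 1e-12, None))
    good = z < 0
    tau0 = -1.0 / np.polyfit(t[good], z[good], 1)[0] if good.sum() >= 2 else t[-1] / 3
    tau0 = float(np.clip(tau0, time_step_ms, t[-1] * 10))

    def model(tt, i_pk, tau, c):
        return i_pk * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(
            model, t, seg, p0=[i0, tau0, tail],
            maxfev=10000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError:
        warnings.warn("inactivation fit did not converge")
        return None
    resid = model(t, *popt) - seg
    return float(popt[1]), float(resid @ resid), float(popt[2])


def analyze_family(family: SweepFamily, blank_ms: float = 0.3,
                   baseline_ms: float = 5.0) -> INaStats:
    """Ensemble-average a family and extract the peak and inactivation tau."""
    ens = subtract_baseline(ensemble_average(family), family, baseline_ms)
    amp, v_peak, t_peak = peak_ina(ens, family, blank_ms, baseline_ms)
    if amp == 0.0:
        return INaStats(0.0, v_peak, np.nan, np.nan, np.nan, np.nan)
    j = int(np.where(family.test_voltages_mV == v_peak)[0][0])
    start = family.pulse_start_idx + int(round(blank_ms / family.time_step_ms))
    trace = ens[j, start:family.pulse_end_idx]
    fit = fit_inactivation(trace, family.time_step_ms)
    tau, rss, c = fit if fit is not None else (np.nan, np.nan, np.nan)
    return INaStats(amp, v_peak, t_peak, tau, rss, c)
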