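"""Synthetic ventricular-myocyte data with known ground truth.

Four generators emulate the study geometry end to end:

* :func:`make_myocyte_stack` — multi-channel 3-D fluorescence stacks of a
  striated myocyte with lateral-rim and intercalated-disc (ICD) enrichment,
  random surface clusters, anisotropic Gaussian PSF blur and Poisson +
  Gaussian camera noise.
* :func:`make_frap_dataset` — four-ROI FRAP time series (bleached center and
  end ROIs, unbleached reference, cell-free background) with biexponential
  recovery over a decaying background.
* :func:`make_ina_dataset` — Hodgkin–Huxley-style inward sodium-current sweep
  families over a voltage ladder.
* :func:`make_band_table` — immunoblot band-intensity tables with known
  condition ratios.

Every generator is bit-deterministic given its spec and seed, and the
returned ground truth (:class:`PhantomTruth`) is exact for the noiseless,
unblurred image: with PSF and noise disabled, downstream measurements recover
the truth to floating-point accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgeo import ImageStack, RegionMask, rim_mask

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))


# --------------------------------------------------------------------------
# imaging phantom
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the synthetic myocyte image stack.

    Geometry defaults emulate an adult rat ventricular myocyte imaged in
    whole-cell mode (100-nm XY pixels, 300-nm Z steps); pass
    ``pixel_xy_nm=50, z_step_nm=50`` for cluster-view geometry.
    """

    cell_length_um: float = 120.0
    cell_width_um: float = 25.0
    striation_period_um: float = 2.0
    striation_amplitude: float = 0.3
    rim_width_um: float = 1.0
    lateral_enrichment: float = 1.0
    icd_enrichment: float = 1.0
    icd_depth_um: float = 1.5
    cluster_density_pct: float = 0.0
    cluster_radius_um: float = 0.25
    cluster_intensity: float = 300.0
    base_intensity: float = 100.0
    background: float = 10.0
    psf_fwhm_xy_nm: float = 100.0
    psf_fwhm_z_nm: float = 300.0
    pixel_xy_nm: float = 100.0
    z_step_nm: float = 300.0
    photon_scale: float = 1.0
    read_noise_sd: float = 1.0
    apply_psf: bool = True
    apply_noise: bool = True
    frame_margin_um: float = 2.0
    frame_yx_um: tuple[float, float] | None = None
    n_z: int = 7
    surface_standoff_um: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "cell_length_um": self.cell_length_um,
            "cell_width_um": self.cell_width_um,
            "striation_period_um": self.striation_period_um,
            "icd_depth_um": self.icd_depth_um,
            "cluster_radius_um": self.cluster_radius_um,
            "cluster_intensity": self.cluster_intensity,
            "base_intensity": self.base_intensity,
            "pixel_xy_nm": self.pixel_xy_nm,
            "z_step_nm": self.z_step_nm,
            "psf_fwhm_xy_nm": self.psf_fwhm_xy_nm,
            "psf_fwhm_z_nm": self.psf_fwhm_z_nm,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.apply_noise and self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.rim_width_um < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("rim_width_um, background, read_noise_sd must be >= 0")
        if self.lateral_enrichment < 0 or self.icd_enrichment < 0:
            raise ValueError("enrichment factors must be >= 0")
        if not 0.0 <= self.cluster_density_pct <= 100.0:
            raise ValueError("cluster_density_pct must be in [0, 100]")
        if self.n_z < 3:
            raise ValueError("need at least 3 z-planes")


@dataclass
class PhantomTruth:
    """Ground-truth record for one generated stack."""

    cell_mask: RegionMask
    rim_mask: RegionMask
    icd_mask: RegionMask
    cluster_table: list[tuple[tuple[float, float], float, float]]
    true_lateral_enrichment: float
    true_icd_enrichment: float
    true_cluster_density_pct: float
    true_cluster_mean_size_um2: float
    cluster_mask: RegionMask | None = None
    surface_z: int = 0
    central_z: int = 0
    background: float = 0.0


def _stadium_mask(ny: int, nx: int, pitch: float, length: float, width: float) -> np.ndarray:
    """Rectangle with semicircular end caps, centered in the frame."""
    cy = ny * pitch / 2.0
    cx = nx * pitch / 2.0
    r = width / 2.0
    half = length / 2.0 - r  # half-length of the straight section
    x = (np.arange(nx) + 0.5) * pitch - cx
    y = (np.arange(ny) + 0.5) * pitch - cy
    gx, gy = np.meshgrid(x, y)
    dx = np.maximum(np.abs(gx) - half, 0.0)
    return dx**2 + gy**2 <= r**2


def _place_clusters(
    cell: np.ndarray,
    pitch: float,
    density_pct: float,
    radius_um: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Rejection-sample non-touching disks inside the cell footprint.

    Disk centers sit on pixel centers so every disk rasterizes identically;
    a one-pixel exclusion ring keeps 8-connected components separate.
    """
    ny, nx = cell.shape
    r_px = radius_um / pitch
    k = int(np.ceil(r_px)) + 1  # one-pixel margin for the exclusion ring
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    disk = yy**2 + xx**2 <= r_px**2
    disk_px = int(disk.sum())
    if disk_px == 0:
        raise ValueError("cluster radius below one pixel")
    n_cell = int(cell.sum())
    n_target = int(round(density_pct / 100.0 * n_cell / disk_px))
    # erode so disks stay fully inside the cell
    interior = ndimage.binary_erosion(
        cell, structure=disk, border_value=0)
    mask = np.zeros_like(cell)
    centers: list[tuple[int, int]] = []
    order = rng.permutation(np.flatnonzero(interior))
    ring = ndimage.binary_dilation(disk, structure=np.ones((3, 3), bool))
    half = ring.shape[0] // 2
    for flat in order:
        if len(centers) >= n_target:
            break
        iy, ix = divmod(int(flat), nx)
        sl = (slice(iy - half, iy + half + 1), slice(ix - half, ix + half + 1))
        if iy - half < 0 or ix - half < 0 or mask[sl].shape != ring.shape:
            continue
        if (mask[sl] & ring).any():  # would touch an existing cluster
            continue
        mask[sl] |= disk
        centers.append((iy, ix))
    if len(centers) < n_target:
        warnings.warn(
            f"placed {len(centers)} of {n_target} requested clusters "
            "(cell too crowded)"
        )
    return mask, centers


def make_myocyte_stack(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Generate a two-channel myocyte stack and its ground truth.

    Channel 0 carries the target protein (striated interior, enriched rim and
    ICD, surface clusters); channel 1 carries an ICD junction marker
    (nCadherin-like).  The rim and ICD plateau intensities are solved so the
    background-subtracted enrichment factors of the noiseless image equal the
    requested ``lateral_enrichment`` and ``icd_enrichment`` exactly, striation
    texture included.
    """
    spec.validate()
    pitch = spec.pixel_xy_nm / 1000.0
    z_step = spec.z_step_nm / 1000.0
    if spec.frame_yx_um is None:
        fy = spec.cell_width_um + 2 * spec.frame_margin_um
        fx = spec.cell_length_um + 2 * spec.frame_margin_um
    else:
        fy, fx = spec.frame_yx_um
        if fy < spec.cell_width_um or fx < spec.cell_length_um:
            raise ValueError(
                f"cell ({spec.cell_length_um} x {spec.cell_width_um} µm) "
                f"does not fit the requested frame ({fx} x {fy} µm)"
            )
    ny = int(round(fy / pitch))
    nx = int(round(fx / pitch))
    nz = spec.n_z
    rng = np.random.default_rng(spec.seed)

    cell = _stadium_mask(ny, nx, pitch, spec.cell_length_um, spec.cell_width_um)
    cell_rm = RegionMask(cell, pitch)
    rim = rim_mask(cell_rm, spec.rim_width_um).mask
    # ICD: transverse band of icd_depth_um at each cell end
    x_phys = (np.arange(nx) + 0.5) * pitch
    inside_x = x_phys[cell.any(axis=0)]
    x_lo, x_hi = inside_x.min(), inside_x.max()
    icd = cell & (
        (x_phys[None, :] <= x_lo + spec.icd_depth_um)
        | (x_phys[None, :] >= x_hi - spec.icd_depth_um)
    )

    # disjoint partition of the cell footprint
    ic = icd
    rim_only = rim & ~ic
    interior = cell & ~rim & ~ic
    a_cell = int(cell.sum())
    a_rim = int(rim.sum())
    a_ic = int(ic.sum())
    a_overlap = int((rim & ic).sum())

    stri = 1.0 + spec.striation_amplitude * np.cos(
        2 * np.pi * x_phys / spec.striation_period_um
    )
    pattern = spec.base_intensity * np.broadcast_to(stri[None, :], (ny, nx))
    s_int = float(pattern[interior].sum())

    e_l = spec.lateral_enrichment if a_rim > 0 else np.nan
    e_i = spec.icd_enrichment if a_ic > 0 else np.nan
    denom = a_cell
    if a_rim > 0:
        denom -= e_l * a_rim
    if a_ic > 0:
        denom -= e_i * (a_ic - a_overlap)
    if denom <= 0:
        raise ValueError("enrichment factors too large for this geometry")
    mu = s_int / denom  # cell-mean signal implied by the constraints
    v_ic = (e_i * mu) if a_ic > 0 else 0.0
    if a_rim > 0:
        n_rim_only = int(rim_only.sum())
        if n_rim_only > 0:
            v_r = (e_l * a_rim * mu - v_ic * a_overlap) / n_rim_only
            if v_r < 0:
                raise ValueError(
                    "rim intensity would be negative; enrichment factors "
                    "are inconsistent with the rim/ICD overlap"
                )
        else:
            v_r = 0.0
    else:
        v_r = 0.0

    plane = np.full((ny, nx), 0.0)
    plane[interior] = pattern[interior]
    plane[rim_only] = v_r
    plane[ic] = v_ic

    # z layout: one empty plane below and above; cell occupies the middle.
    # Interior signal stops a standoff below the surface plane so the surface
    # cluster view separates from interior striations after PSF blur, as the
    # real surface/interior contrast does.
    z_cell = list(range(1, nz - 1))
    surface_z = z_cell[-1]
    gap = max(int(np.ceil(spec.surface_standoff_um / z_step)), 1)
    z_interior = [z for z in z_cell if z <= surface_z - gap]
    central_z = z_interior[len(z_interior) // 2] if z_interior else z_cell[0]

    target = np.full((nz, ny, nx), spec.background, dtype=np.float64)
    for z in z_interior:
        target[z] += plane
    # surface plane: clusters only (flat pedestal inside the cell)
    if spec.cluster_density_pct > 0:
        cmask, centers = _place_clusters(
            cell, pitch, spec.cluster_density_pct, spec.cluster_radius_um, rng
        )
    else:
        cmask, centers = np.zeros_like(cell), []
    target[surface_z][cmask] += spec.cluster_intensity

    marker = np.full((nz, ny, nx), spec.background, dtype=np.float64)
    for z in z_cell:
        marker[z][ic] += spec.base_intensity

    vox = np.stack([target, marker])

    if spec.apply_psf:
        sxy = spec.psf_fwhm_xy_nm * FWHM_TO_SIGMA / spec.pixel_xy_nm
        sz = spec.psf_fwhm_z_nm * FWHM_TO_SIGMA / spec.z_step_nm
        for c in range(vox.shape[0]):
            vox[c] = ndimage.gaussian_filter(
                vox[c], sigma=(sz, sxy, sxy), truncate=4.0, mode="nearest"
            )
    if spec.apply_noise:
        vox = rng.poisson(np.clip(vox, 0, None) * spec.photon_scale) / spec.photon_scale
        vox = vox + rng.normal(0.0, spec.read_noise_sd, size=vox.shape)
        vox = np.clip(vox, 0.0, None)

    stack = ImageStack(vox, pitch, z_step, ["target", "icd_marker"])

    n_cluster_px = int(cmask.sum())
    n_clusters = len(centers)
    disk_area = (n_cluster_px / n_clusters * pitch**2) if n_clusters else np.nan
    truth = PhantomTruth(
        cell_mask=cell_rm,
        rim_mask=RegionMask(rim, pitch),
        icd_mask=RegionMask(ic, pitch),
        cluster_table=[
            (((iy + 0.5) * pitch, (ix + 0.5) * pitch), spec.cluster_radius_um,
             spec.cluster_intensity)
            for iy, ix in centers
        ],
        true_lateral_enrichment=float(e_l) if a_rim > 0 else np.nan,
        true_icd_enrichment=float(e_i) if a_ic > 0 else np.nan,
        true_cluster_density_pct=100.0 * n_cluster_px / a_cell,
        true_cluster_mean_size_um2=disk_area,
        cluster_mask=RegionMask(cmask, pitch),
        surface_z=surface_z,
        central_z=central_z,
        background=spec.background,
    )
    return stack, truth


# --------------------------------------------------------------------------
# FRAP phantom
# --------------------------------------------------------------------------

@dataclass
class FRAPSimSpec:
    """Biexponential FRAP recovery over a decaying background.

    Amplitudes are fractions of the bleached span; ``A1 + A2`` is the mobile
    fraction.  Defaults follow the acquisition protocol of 25 baseline scans
    and 275 recovery scans at 0.5-s intervals.
    """

    A1: float = 0.3
    A2: float = 0.4
    tau1_s: float = 5.0
    tau2_s: float = 60.0
    bleach_depth: float = 0.25
    background_bleach_rate_per_s: float = 0.0
    noise_sd: float = 0.0
    n_prebleach: int = 25
    n_postbleach: int = 275
    scan_interval_s: float = 0.5
    prebleach_intensity: float = 1000.0
    background_offset: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.A1 + self.A2 > 1:
            raise ValueError("A1 + A2 must be <= 1")
        if self.tau1_s <= 0 or self.tau2_s <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau1_s >= self.tau2_s:
            raise ValueError("tau1_s must be < tau2_s")
        if not 0 < self.bleach_depth < 1:
            raise ValueError("bleach_depth must be in (0, 1)")
        if self.background_bleach_rate_per_s < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.n_prebleach < 2 or self.n_postbleach < 1:
            raise ValueError("need >= 2 prebleach and >= 1 postbleach scans")


def make_frap_dataset(spec: FRAPSimSpec) -> pd.DataFrame:
    """Simulate the four-ROI FRAP table (long format: roi, scan, time_s, value).

    ROI 1 (cell center) and ROI 2 (cell end) are bleached and recover; ROI 3
    carries only the background bleach decay; ROI 4 is a constant cell-free
    offset.  All ROIs share the photometric gain and offset.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_prebleach + spec.n_postbleach
    scans = np.arange(1, n + 1)
    t = (scans - 1) * spec.scan_interval_s
    t_bleach = t[spec.n_prebleach]  # time of the first post-bleach scan
    decay = np.exp(-spec.background_bleach_rate_per_s * t)

    post = t >= t_bleach
    dt = t - t_bleach
    recov = spec.A1 * (1 - np.exp(-np.clip(dt, 0, None) / spec.tau1_s)) + \
        spec.A2 * (1 - np.exp(-np.clip(dt, 0, None) / spec.tau2_s))
    bleached = np.where(post, spec.bleach_depth + (1 - spec.bleach_depth) * recov, 1.0)

    rows = []
    for roi, model in ((1, bleached * decay), (2, bleached * decay),
                       (3, decay), (4, np.zeros(n))):
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        values = spec.background_offset + spec.prebleach_intensity * (model + noise)
        rows.append(pd.DataFrame({
            "roi": roi, "scan": scans, "time_s": t, "value": values,
        }))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# sodium-current phantom
# --------------------------------------------------------------------------

@dataclass
class INaSimSpec:
    """Hodgkin–Huxley-style inward sodium current over a voltage ladder.

    Voltages are patch-membrane potentials in mV.  The current during the
    test pulse is ``I(t) = -gmax * m_inf(V)^3 * (1-exp(-t/tau_act))^3 *
    exp(-t/tau_inact) * (e_rev - V)`` sign-arranged so current is inward
    (negative) below the reversal potential.  Default activation parameters
    put the maximal peak near -35 mV, as reported for cell-attached myocyte
    patches with a zeroed resting potential.
    """

    gmax: float = 1.0
    v_half_act: float = -50.0
    k_act: float = 4.0
    e_rev: float = 70.0
    tau_act_ms: float | Callable[[float], float] = 0.3
    tau_inact_ms: float | Callable[[float], float] = 1.5
    sweep_noise_sd: float = 0.0
    n_repeats: int = 6
    v_hold: float = -120.0
    v_start: float = -100.0
    v_stop: float = 75.0
    v_step: float = 5.0
    pulse_ms: float = 200.0
    pre_ms: float = 5.0
    dt_ms: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.v_step == 0 or (self.v_stop - self.v_start) * self.v_step < 0:
            raise ValueError("voltage ladder inconsistent with v_step sign")
        if self.pulse_ms <= 0 or self.dt_ms <= 0 or self.pre_ms < 0:
            raise ValueError("pulse_ms, dt_ms must be > 0 and pre_ms >= 0")
        if self.sweep_noise_sd < 0:
            raise ValueError("sweep_noise_sd must be >= 0")

    @property
    def voltages(self) -> np.ndarray:
        n = int(round((self.v_stop - self.v_start) / self.v_step)) + 1
        return self.v_start + self.v_step * np.arange(n)

    def _tau(self, tau, v: float) -> float:
        return float(tau(v)) if callable(tau) else float(tau)

    def noiseless_sweep(self, v: float, t_ms: np.ndarray) -> np.ndarray:
        """Ideal current (pA) during the test pulse at voltage ``v``."""
        m_inf = 1.0 / (1.0 + np.exp(-(v - self.v_half_act) / self.k_act))
        ta = self._tau(self.tau_act_ms, v)
        ti = self._tau(self.tau_inact_ms, v)
        act = (1.0 - np.exp(-t_ms / ta)) ** 3
        return -self.gmax * m_inf**3 * act * np.exp(-t_ms / ti) * (self.e_rev - v)

    def designed_peak_voltage(self) -> float:
        """Brute-force scan of the ladder for the max-|peak| voltage."""
        t = np.arange(0.0, self.pulse_ms, self.dt_ms)
        peaks = [abs(self.noiseless_sweep(v, t).min()) for v in self.voltages]
        return float(self.voltages[int(np.argmax(peaks))])


def make_ina_dataset(spec: INaSimSpec):
    """Simulate a sweep family (repeats x voltages x time) for one patch."""
    from .ephys import SweepFamily

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    volts = spec.voltages
    n_pre = int(round(spec.pre_ms / spec.dt_ms))
    t_pulse = np.arange(0.0, spec.pulse_ms, spec.dt_ms)
    n_t = n_pre + t_pulse.size
    current = np.zeros((spec.n_repeats, volts.size, n_t))
    for j, v in enumerate(volts):
        ideal = np.concatenate([np.zeros(n_pre), spec.noiseless_sweep(v, t_pulse)])
        current[:, j, :] = ideal[None, :]
    if spec.sweep_noise_sd > 0:
        current += rng.normal(0.0, spec.sweep_noise_sd, size=current.shape)
    return SweepFamily(
        current=current,
        time_step_ms=spec.dt_ms,
        test_voltages_mV=volts,
        pulse_start_idx=n_pre,
        pulse_end_idx=n_t,
    )


# --------------------------------------------------------------------------
# immunoblot phantom
# --------------------------------------------------------------------------

def make_band_table(
    true_ratios: dict[str, float],
    lane_noise_cv: float,
    seed: int,
    scheme: str = "pka_con",
    n_experiments: int = 1,
    base_intensity: float = 100.0,
    cb_intensity: float = 500.0,
    baseline_degree: float = 0.15,
) -> pd.DataFrame:
    """Generate an immunoblot band-intensity table with known PKA:CON ratios.

    ``scheme`` selects the lane layout: ``pka_con`` (one WCL-style lane per
    condition), ``coip`` (WCL + [+]IP lanes; the ratio applies to the
    IP/WCL degree), or ``surface`` (WCL + biotinylated lanes).  Lane noise is
    multiplicative log-normal with coefficient of variation ``lane_noise_cv``.
    """
    if lane_noise_cv < 0:
        raise ValueError("lane_noise_cv must be >= 0")
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be > 0")
    if scheme not in ("pka_con", "coip", "surface"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(lane_noise_cv**2))

    def lognorm() -> float:
        if sigma == 0:
            return 1.0
        return float(np.exp(rng.normal(-sigma**2 / 2, sigma)))

    pull_kind = {"coip": "IP_pos", "surface": "biotinylated"}.get(scheme)
    rows = []
    for target, ratio in true_ratios.items():
        for exp in range(n_experiments):
            eid = f"{target}_e{exp}"
            degree = {"CON": baseline_degree, "PKA": baseline_degree * ratio}
            level = {"CON": base_intensity, "PKA": base_intensity * ratio}
            for cond in ("CON", "PKA"):
                if scheme == "pka_con":
                    rows.append((eid, cond, "WCL", target,
                                 level[cond] * lognorm(), cb_intensity * lognorm()))
                else:
                    wcl = base_intensity * lognorm()
                    rows.append((eid, cond, "WCL", target, wcl, np.nan))
                    rows.append((eid, cond, pull_kind, target,
                                 wcl * degree[cond] * lognorm(), np.nan))
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "condition", "lane_kind", "target",
                 "band_intensity", "cb_intensity"],
    )
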