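"""Voxel-wise and regional hemodynamic metrics.

* vorticity omega = curl(V) by mask-aware finite differences,
* local normalized helicity LNH = |V . omega| / (|V| |omega|), in [0, 1],
* intravoxel fluctuation sigma_i^2 = (2/k_v^2) ln(|S|/|S_i|), k_v = pi/VENC,
  kept signed so noise can drive regional TKE slightly negative,
* turbulent kinetic energy TKE = (1/2) rho sum_i sigma_i^2 [J/m^3],
* peak-systole detection with a +/-5%-of-cycle averaging window,
* spatial-mean velocity and Reynolds number Re = rho * V * D / mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ALL_REGIONS, FlowDataset, RegionGeometry, RegionPartition


@dataclass
class HemoParams:
    """Physical constants and analysis windows.

    rho: blood density [kg/m^3]; mu: dynamic viscosity [Pa s];
    systole_window_halfwidth: half-width of the averaging window as a fraction
    of the cardiac cycle; lnh_epsilon: floor on the product |V||omega|
    [m/s * 1/s] below which LNH is treated as undefined (0/0).
    """

    rho: float = 1060.0
    mu: float = 3.5e-3
    systole_window_halfwidth: float = 0.05
    lnh_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")
        if not (0 <= self.systole_window_halfwidth < 0.5):
            raise ValueError("systole_window_halfwidth must lie in [0, 0.5)")


@dataclass
class VorticityField:
    """Curl of the velocity field (1/s) with a validity mask."""

    omega: np.ndarray          # (X, Y, Z, 3)
    defined: np.ndarray        # (X, Y, Z) bool


def _masked_derivative(f: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """d f / d axis with central differences inside the mask.

    Central where both neighbours along the axis are in-mask, one-sided where
    only one is, undefined otherwise. ``h`` in metres. Returns (deriv, ok).
    """
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(mask, -1, axis=axis)
    mm = np.roll(mask, 1, axis=axis)
    # voxels rolled in across the boundary are invalid
    sl_hi = [slice(None)] * f.ndim
    sl_hi[axis] = -1
    sl_lo = [slice(None)] * f.ndim
    sl_lo[axis] = 0
    mp[tuple(sl_hi)] = False
    mm[tuple(sl_lo)] = False

    deriv = np.zeros_like(f, dtype=float)
    ok = mask & (mp | mm)
    central = mask & mp & mm
    fwd = mask & mp & ~mm
    bwd = mask & mm & ~mp
    deriv[central] = (fp[central] - fm[central]) / (2 * h)
    deriv[fwd] = (fp[fwd] - f[fwd]) / h
    deriv[bwd] = (f[bwd] - fm[bwd]) / h
    return deriv, ok


def compute_vorticity(
    velocity_frame: np.ndarray, mask: np.ndarray, voxel_spacing
) -> VorticityField:
    """curl(V) on one timeframe, defined where all needed partials exist.

    ``velocity_frame``: (X, Y, Z, 3) m/s; ``voxel_spacing``: mm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing_m = np.atleast_1d(np.asarray(voxel_spacing, dtype=float)) / 1000.0
    if spacing_m.size == 1:
        spacing_m = np.repeat(spacing_m, 3)
    if np.any(spacing_m <= 0):
        raise ValueError("voxel spacing must be positive")

    d = {}
    ok_all = np.ones(mask.shape, dtype=bool)
    for comp in range(3):
        for axis in range(3):
            if comp == axis:
                continue
            deriv, ok = _masked_derivative(
                velocity_frame[..., comp], mask, axis, spacing_m[axis]
            )
            d[(comp, axis)] = deriv
            ok_all &= ok
    omega = np.stack(
        [
            d[(2, 1)] - d[(1, 2)],
            d[(0, 2)] - d[(2, 0)],
            d[(1, 0)] - d[(0, 1)],
        ],
        axis=-1,
    )
    defined = mask & ok_all
    omega[~defined] = 0.0
    return VorticityField(omega=omega, defined=defined)


def compute_lnh(
    velocity_frame: np.ndarray,
    vorticity: VorticityField,
    params: HemoParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute local normalized helicity and its validity mask.

    LNH = |V . omega| / (|V| |omega|); 0 means no helical flow, 1 maximally
    helical. Voxels where |V||omega| falls below ``lnh_epsilon`` are flagged
    undefined rather than set to zero, so they are excluded from averages.
    """
    params = params or HemoParams()
    vmag = np.linalg.norm(velocity_frame, axis=-1)
    wmag = np.linalg.norm(vorticity.omega, axis=-1)
    prod = vmag * wmag
    defined = vorticity.defined & (prod >= params.lnh_epsilon)
    dot = np.abs(np.einsum("...i,...i->...", velocity_frame, vorticity.omega))
    lnh = np.zeros_like(prod)
    lnh[defined] = dot[defined] / prod[defined]
    np.clip(lnh, 0.0, 1.0, out=lnh)
    return lnh, defined


def compute_sigma_squared(
    magnitudes_frame: np.ndarray, venc
) -> tuple[np.ndarray, np.ndarray]:
    """Signed sigma_i^2 fields (m^2/s^2) from one frame's magnitude volumes.

    sigma_i^2 = (2/k_v^2) ln(|S|/|S_i|) with k_v = pi/VENC. The sign is kept:
    noise can push |S_i| above |S|, making sigma^2 (and hence regional TKE)
    slightly negative — a zero-TKE estimate buried in noise. Voxels with
    non-positive |S| or |S_i| are flagged undefined.
    """
    mags = np.asarray(magnitudes_frame, dtype=float)
    if mags.ndim != 4 or mags.shape[0] != 4:
        raise ValueError("magnitudes_frame must have shape (4, X, Y, Z)")
    venc = np.atleast_1d(np.asarray(venc, dtype=float))
    if venc.size == 1:
        venc = np.repeat(venc, 3)
    s_ref = mags[0]
    defined = s_ref > 0
    sigma2 = np.zeros((3,) + s_ref.shape)
    for i in range(3):
        kv = np.pi / venc[i]
        si = mags[1 + i]
        ok = defined & (si > 0)
        defined = ok
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2[i][ok] = (2.0 / kv**2) * np.log(s_ref[ok] / si[ok])
    return sigma2, defined


def compute_tke(sigma2: np.ndarray, params: HemoParams | None = None) -> np.ndarray:
    """TKE = (1/2) rho sum_i sigma_i^2 [J/m^3]; signed per the sigma^2 convention."""
    params = params or HemoParams()
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.shape[0] != 3:
        raise ValueError("expected three sigma^2 fields stacked on axis 0")
    return 0.5 * params.rho * sigma2.sum(axis=0)


def find_peak_systole(
    data: FlowDataset,
    region_voxels: np.ndarray,
    params: HemoParams | None = None,
    speed: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Peak-systole frame and the +/- window frames for one region.

    The peak frame maximizes the spatial-mean speed in the region (earliest
    frame on ties); the window contains the frames whose cycle fraction lies
    within ``systole_window_halfwidth`` of the peak's, cyclically. A
    precomputed ``speed`` array (T, X, Y, Z) avoids recomputation.
    """
    params = params or HemoParams()
    region_voxels = np.asarray(region_voxels, dtype=bool)
    if not region_voxels.any():
        raise ValueError("region is empty")
    if speed is None:
        speed = data.speed()
    mean_speed = speed[:, region_voxels].mean(axis=1)
    peak = int(np.argmax(mean_speed))
    frac = data.timeframe_fractions
    delta = np.abs(frac - frac[peak])
    delta = np.minimum(delta, 1.0 - delta)
    window = np.flatnonzero(delta <= params.systole_window_halfwidth + 1e-12)
    return peak, window


def compute_reynolds(
    velocity: float, diameter_mm: float, params: HemoParams | None = None
) -> float:
    """Re = rho * velocity * D / mu with D converted from mm to metres."""
    params = params or HemoParams()
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    return params.rho * velocity * (diameter_mm / 1000.0) / params.mu


def aggregate_regional_metrics(
    data: FlowDataset,
    partition: RegionPartition,
    geometry: dict[str, RegionGeometry],
    params: HemoParams | None = None,
) -> pd.DataFrame:
    """Regional helicity, TKE, velocity, Reynolds over each region's window.

    For every region (four segments + whole aorta): peak systole is located on
    the regional mean-speed curve; LNH, signed TKE and speed are averaged over
    the region's lumen voxels and its window frames, excluding voxels whose
    LNH or sigma^2 is undefined. Returns one row per region.
    """
    params = params or HemoParams()
    lumen = partition.region_voxels("Whole")
    speed = data.speed()

    peaks, windows = {}, {}
    needed_frames: set[int] = set()
    for region in ALL_REGIONS:
        voxels = partition.region_voxels(region)
        if not voxels.any():
            continue
        peak, window = find_peak_systole(data, voxels, params, speed=speed)
        peaks[region], windows[region] = peak, window
        needed_frames.update(int(f) for f in window)

    lnh_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    tke_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t in sorted(needed_frames):
        vort = compute_vorticity(data.velocity[t], lumen, data.voxel_spacing)
        lnh_cache[t] = compute_lnh(data.velocity[t], vort, params)
        sigma2, s_def = compute_sigma_squared(data.magnitudes[t], data.venc)
        tke_cache[t] = (compute_tke(sigma2, params), s_def)

    rows = []
    for region in ALL_REGIONS:
        voxels = partition.region_voxels(region)
        if not voxels.any():
            rows.append({"region": region})
            continue
        window = windows[region]
        lnh_vals, tke_vals, speed_vals = [], [], []
        excluded = 0
        for t in window:
            lnh, l_def = lnh_cache[int(t)]
            sel = voxels & l_def
            lnh_vals.append(lnh[sel])
            excluded += int(voxels.sum() - sel.sum())
            tke, t_def = tke_cache[int(t)]
            tke_vals.append(tke[voxels & t_def])
            speed_vals.append(speed[int(t)][voxels])
        lnh_all = np.concatenate(lnh_vals)
        tke_all = np.concatenate(tke_vals)
        speed_all = np.concatenate(speed_vals)
        vel = float(speed_all.mean())
        rows.append(
            {
                "region": region,
                "helicity": float(lnh_all.mean()) if lnh_all.size else np.nan,
                "tke": float(tke_all.mean()) if tke_all.size else np.nan,
                "velocity": vel,
                "reynolds": compute_reynolds(vel, geometry[region].diameter, params),
                "peak_frame": peaks[region],
                "n_window_frames": len(window),
                "n_lnh_excluded": excluded,
                "tortuosity": geometry[region].tortuosity,
                "diameter": geometry[region].diameter,
                "length": geometry[region].length,
                "volume": geometry[region].volume,
            }
        )
    return pd.DataFrame(rows)
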