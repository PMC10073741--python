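"""Offline velocity corrections applied before analysis.

Two corrections are supported, mirroring standard 4D flow practice:

* phase-unwrap by comparison with the 6-neighbourhood median (velocities that
  alias past +/-VENC reappear shifted by multiples of 2*VENC);
* background phase-offset removal by a weighted polynomial fit (default total
  degree 4) to static tissue, with the reference magnitude |S| as weights.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datatypes import FlowDataset, StaticTissueMask

_CROSS6 = np.zeros((3, 3, 3), dtype=bool)
_CROSS6[0, 1, 1] = _CROSS6[2, 1, 1] = True
_CROSS6[1, 0, 1] = _CROSS6[1, 2, 1] = True
_CROSS6[1, 1, 0] = _CROSS6[1, 1, 2] = True


def unwrap_velocity(data: FlowDataset, max_passes: int = 5) -> FlowDataset:
    """Correct velocity aliasing against the 6-neighbourhood median.

    A voxel whose value differs from the median of its 6 face neighbours by
    more than VENC is shifted by 2*VENC toward that median; passes repeat until
    no voxel moves or ``max_passes`` is reached.
    """
    out = data.copy()
    total = 0
    for t in range(out.n_timeframes):
        for c in range(3):
            venc = out.venc[c]
            v = out.velocity[t, ..., c]
            for _ in range(max_passes):
                med = ndimage.median_filter(v, footprint=_CROSS6, mode="nearest")
                diff = v - med
                wrapped = np.abs(diff) > venc
                if not wrapped.any():
                    break
                v[wrapped] -= 2.0 * venc * np.sign(diff[wrapped])
                total += int(wrapped.sum())
            else:
                still = np.abs(v - ndimage.median_filter(v, footprint=_CROSS6, mode="nearest")) > venc
                if still.any():
                    warnings.warn(
                        f"unwrap did not converge in {max_passes} passes "
                        f"({int(still.sum())} voxels remain); partial correction kept",
                        stacklevel=2,
                    )
                    out.log("unwrap: non-convergent, partial correction kept")
    out.log(f"unwrap: corrected {total} voxel values")
    return out


def identify_static_tissue(data: FlowDataset, threshold: float | None = None) -> StaticTissueMask:
    """Mark voxels with low temporal speed variation and above-noise magnitude.

    ``threshold`` is the ceiling on the temporal standard deviation of speed
    (m/s); the default is 0.05 * min(VENC). The noise floor on the time-mean
    reference magnitude |S| is set by Otsu's threshold.
    """
    if data.n_timeframes < 2:
        raise ValueError("static-tissue detection needs >= 2 timeframes")
    if threshold is None:
        threshold = 0.05 * float(np.min(data.venc))
    speed = data.speed()
    tstd = speed.std(axis=0, ddof=0)
    mean_mag = data.magnitudes[:, 0].mean(axis=0)
    floor = threshold_otsu(mean_mag) if mean_mag.max() > mean_mag.min() else -np.inf
    mask = (tstd < threshold) & (mean_mag > floor)
    if not mask.any():
        raise ValueError(
            "static-tissue mask is empty; raise the temporal-std threshold "
            f"(currently {threshold:g} m/s) or check the magnitude data"
        )
    return StaticTissueMask(mask=mask, temporal_std=tstd)


def _design_matrix(coords: np.ndarray, shape, order: int) -> np.ndarray:
    """Monomials of total degree <= order on coordinates scaled to [-1, 1]."""
    scaled = np.empty_like(coords, dtype=float)
    for k in range(3):
        half = max((shape[k] - 1) / 2.0, 1.0)
        scaled[:, k] = (coords[:, k] - (shape[k] - 1) / 2.0) / half
    cols = []
    for px, py, pz in itertools.product(range(order + 1), repeat=3):
        if px + py + pz <= order:
            cols.append(scaled[:, 0] ** px * scaled[:, 1] ** py * scaled[:, 2] ** pz)
    return np.column_stack(cols)


def correct_background_phase(
    data: FlowDataset,
    static: StaticTissueMask,
    order: int = 4,
    per_timeframe: bool = False,
) -> FlowDataset:
    """Fit and subtract a polynomial background offset per velocity component.

    The polynomial (total degree <= ``order``) is fit by weighted least squares
    to the static-tissue velocities, with the time-mean reference magnitude
    |S| as weights, and subtracted everywhere. By default the fit uses the
    time-averaged velocity (offsets are quasi-static); ``per_timeframe=True``
    refits each frame.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n_terms = sum(
        1
        for px, py, pz in itertools.product(range(order + 1), repeat=3)
        if px + py + pz <= order
    )
    static_idx = np.argwhere(static.mask)
    if static_idx.shape[0] < n_terms:
        raise ValueError(
            f"static mask has {static_idx.shape[0]} voxels, fewer than the "
            f"{n_terms} polynomial terms of degree {order}"
        )
    shape = data.grid_shape
    X_static = _design_matrix(static_idx.astype(float), shape, order)
    weights = data.magnitudes[:, 0].mean(axis=0)[static.mask]
    sw = np.sqrt(np.maximum(weights, 0.0))
    Xw = X_static * sw[:, None]
    # rank check on the weighted design
    if np.linalg.matrix_rank(Xw) < n_terms:
        raise ValueError(
            "rank-deficient polynomial design: static voxels too few or collinear"
        )

    all_idx = np.argwhere(np.ones(shape, dtype=bool))
    X_all = _design_matrix(all_idx.astype(float), shape, order)

    out = data.copy()
    frames = range(out.n_timeframes) if per_timeframe else [None]
    for c in range(3):
        for t in frames:
            if t is None:
                v_static = out.velocity[:, ..., c].mean(axis=0)[static.mask]
            else:
                v_static = out.velocity[t, ..., c][static.mask]
            coef, *_ = np.linalg.lstsq(Xw, v_static * sw, rcond=None)
            offset = (X_all @ coef).reshape(shape)
            if t is None:
                out.velocity[:, ..., c] -= offset[None]
            else:
                out.velocity[t, ..., c] -= offset
    residual = float(
        np.linalg.norm(out.velocity[:, static.mask, :], axis=-1).mean()
    )
    out.log(
        f"background correction: order={order}, "
        f"{'per-frame' if per_timeframe else 'time-averaged'}, "
        f"residual static mean speed {residual:.3e} m/s"
    )
    return out


def preprocess(data: FlowDataset, order: int = 4, static_threshold: float | None = None) -> FlowDataset:
    """Standard correction chain: unwrap, then background-offset removal."""
    out = unwrap_velocity(data)
    static = identify_static_tissue(out, threshold=static_threshold)
    return correct_background_phase(out, static, order=order)
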