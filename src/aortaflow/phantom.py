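"""Synthetic 4D flow MRI phantoms with analytically known ground truth.

The generator produces tubular vessel geometries (straight tube, circular
arc, helix, and a candy-cane ``aorta_like`` shape), fills them with pulsatile
axial flow plus a forced-vortex (solid-body) swirl component, and encodes a
prescribed intravoxel velocity-fluctuation intensity ``sigma`` into the
four-point motion-encoding magnitude volumes via the exponential attenuation

    |S_i| = |S| * exp(-k_v^2 * sigma_i^2 / 2),      k_v = pi / VENC,

which is the exact inverse of the estimation model used downstream, so a
noise-free encode -> decode round trip is an identity.  Rician noise can be
added to the magnitudes and (optionally) Gaussian noise to the velocities.

The forced-vortex swirl is chosen for testability: combined with a plug
axial profile its local normalized helicity has the closed form
``W / sqrt(W^2 + (Omega r)^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import REGION_NAMES, Centerline, FlowDataset

GEOMETRY_KINDS = ("straight", "arc", "helix", "aorta_like")

_DEFAULT_GEOMETRY_PARAMS: dict[str, dict[str, float]] = {
    "straight": {"length": 100.0},
    "arc": {"radius": 50.0, "angle": math.pi},
    "helix": {"radius": 10.0, "pitch": 20.0, "turns": 1.0},
    "aorta_like": {
        "arch_radius": 16.0,
        "arch_angle": 2.2,        # rad of arc from valve to the arch apex
        "desc_length": 90.0,      # mm, arch end to iliac bifurcation
        "thoracic_amp": 1.0,      # mm, in-plane sinusoid at the arch end
        "abdominal_amp": 0.8,     # mm, sinusoid amplitude at the iliac end
        "wavelength": 36.0,       # mm, sinusoid wavelength on the limb
        "renal_fraction": 0.72,   # renal branches at this fraction of the limb
    },
}


def default_waveform(n_timeframes: int) -> np.ndarray:
    """Smooth single-peak systolic pulse with a diastolic baseline.

    Peaks at 25% of the cardiac cycle; the maximum is unique for any
    ``n_timeframes >= 1``.
    """
    frac = np.arange(n_timeframes) / n_timeframes
    return 0.15 + 0.85 * np.exp(-(((frac - 0.25) / 0.09) ** 2))


@dataclass
class PhantomSpec:
    """Full parametric description of one synthetic subject."""

    geometry_kind: str = "aorta_like"
    geometry_params: dict = field(default_factory=dict)
    lumen_radius: float = 7.0            # mm
    peak_axial_velocity: float = 0.9     # m/s at the vessel axis, peak systole
    swirl_ratio: float = 0.3             # peak azimuthal / peak axial velocity
    sigma_level: float = 0.1             # m/s intravoxel fluctuation, per direction
    axial_profile: str = "parabolic"     # "parabolic" (Poiseuille) or "plug"
    n_timeframes: int = 40
    temporal_waveform: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None   # auto-sized when None
    voxel_spacing: float = 2.5           # mm, isotropic
    venc: float = 1.5                    # m/s, per direction
    snr: float = math.inf                # baseline magnitude / Rician noise scale
    velocity_noise: bool = False         # add Gaussian velocity noise VENC/(SNR*pi)
    baseline_magnitude: float = 100.0    # |S| inside the lumen, a.u.
    tissue_magnitude_frac: float = 0.6   # |S| of static tissue relative to lumen
    body_margin: float = 12.0            # mm of tissue around the lumen; beyond: air
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_kind not in GEOMETRY_KINDS:
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")
        params = dict(_DEFAULT_GEOMETRY_PARAMS[self.geometry_kind])
        params.update(self.geometry_params)
        self.geometry_params = params
        if self.axial_profile not in ("parabolic", "plug"):
            raise ValueError("axial_profile must be 'parabolic' or 'plug'")
        if self.swirl_ratio < 0:
            raise ValueError("swirl_ratio must be >= 0")
        if self.sigma_level < 0:
            raise ValueError("sigma_level must be >= 0")
        if self.sigma_level >= self.venc:
            raise ValueError(
                f"sigma_level {self.sigma_level} >= venc {self.venc}: the "
                "magnitude signal model is outside its valid regime"
            )
        if self.n_timeframes < 1:
            raise ValueError("n_timeframes must be >= 1")
        if self.geometry_kind == "aorta_like":
            # the candy-cane hook must clear the descending limb, else the
            # voxelized lumen self-touches and the centerline can short-circuit
            phi_v = math.pi / 2 - float(self.geometry_params["arch_angle"])
            clearance = (
                float(self.geometry_params["arch_radius"]) * (1.0 + math.cos(phi_v))
                - 2.0 * self.lumen_radius
            )
            if clearance < 2.0 * self.voxel_spacing:
                raise ValueError(
                    "invalid aorta_like geometry: ascending limb clears the "
                    f"descending limb by {clearance:.1f} mm (< 2 voxels)"
                )
        if self.temporal_waveform is None:
            self.temporal_waveform = default_waveform(self.n_timeframes)
        self.temporal_waveform = np.asarray(self.temporal_waveform, dtype=float)
        if self.temporal_waveform.shape != (self.n_timeframes,):
            raise ValueError("temporal_waveform length must equal n_timeframes")
        if np.any(self.temporal_waveform < 0):
            raise ValueError("temporal_waveform weights must be non-negative")


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying one generated phantom."""

    points: np.ndarray                  # dense centerline samples, mm
    s: np.ndarray                       # cumulative arc length, mm
    length: float                       # analytic L of the whole curve, mm
    chord: float                        # analytic D (straight-line), mm
    tortuosity: float                   # (L/D - 1) * 100, %
    landmarks_s: dict[str, float]       # arc-length positions, mm
    landmarks_xyz: dict[str, np.ndarray]
    regional_tortuosity: dict[str, float] | None = None
    lumen_mask: np.ndarray | None = None
    sigma_level: float = 0.0
    swirl_ratio: float = 0.0
    peak_frame: int = 0
    regional_mean_speed: dict[str, float] | None = None

    @property
    def centerline(self) -> Centerline:
        return Centerline(points=self.points, s=self.s)


# ---------------------------------------------------------------------------
# Centerline geometry
# ---------------------------------------------------------------------------

def _polyline_tortuosity(points: np.ndarray) -> tuple[float, float, float]:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    length = float(steps.sum())
    chord = float(np.linalg.norm(points[-1] - points[0]))
    if chord == 0:
        raise ValueError("degenerate curve: coincident endpoints")
    return length, chord, (length / chord - 1.0) * 100.0


def _aorta_like_param(p: dict[str, float]):
    """Return (sample_points, landmark parameter values) for the candy cane.

    The curve lives in natural coordinates (y is the out-of-plane perturbation
    axis, z the superior axis) and is later translated into the grid frame.
    Parametrised by t in [0, 1]: the arc portion covers t in [0, t_arc], the
    descending limb t in (t_arc, 1].
    """
    R = float(p["arch_radius"])
    theta = float(p["arch_angle"])
    ldesc = float(p["desc_length"])
    if R <= 0 or ldesc <= 0 or not (0 < theta < math.pi):
        raise ValueError("invalid aorta_like geometry parameters")
    phi_v = math.pi / 2 - theta            # valve angle on the arch circle
    arc_span = math.pi - phi_v             # valve -> arch end (phi = pi)
    approx_len = R * arc_span + ldesc
    t_arc = R * arc_span / approx_len

    amp0 = float(p["thoracic_amp"])
    amp1 = float(p["abdominal_amp"])
    lam = float(p["wavelength"])
    if lam <= 0:
        raise ValueError("wavelength must be positive")

    def curve(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        pts = np.empty(t.shape + (3,))
        on_arc = t <= t_arc
        phi = phi_v + (t[on_arc] / t_arc) * arc_span
        pts[on_arc, 0] = R * np.cos(phi)
        pts[on_arc, 1] = 0.0
        pts[on_arc, 2] = R * np.sin(phi)
        u = (t[~on_arc] - t_arc) / (1 - t_arc) * ldesc
        amp = amp0 + (amp1 - amp0) * (u / ldesc)
        pts[~on_arc, 0] = -R
        pts[~on_arc, 1] = amp * np.sin(2 * math.pi * u / lam)
        pts[~on_arc, 2] = -u
        return pts

    # landmark parameter positions
    t_apex = (math.pi / 2 - phi_v) / arc_span * t_arc
    t_sub = t_arc                                    # left subclavian at arch end
    t_renal = t_arc + float(p["renal_fraction"]) * (1 - t_arc)
    landmarks_t = {
        "aortic_valve": 0.0,
        "arch_top": t_apex,
        "left_subclavian": t_sub,
        "renal_branches": t_renal,
        "iliac_bifurcation": 1.0,
    }
    return curve, landmarks_t


def generate_centerline(spec: PhantomSpec, n_samples: int | None = None) -> GroundTruth:
    """Densely sampled analytic centerline with exact L, D, and tortuosity.

    For straight/arc/helix the arc length and chord are closed-form; for the
    ``aorta_like`` candy cane they are evaluated by dense quadrature on the
    parametric curve (sampling step ~0.05 mm).
    """
    kind = spec.geometry_kind
    p = spec.geometry_params

    if kind == "straight":
        length = float(p["length"])
        if length <= 0:
            raise ValueError("degenerate curve: zero length")
        n = n_samples or max(int(length / 0.5) + 1, 64)
        z = np.linspace(0.0, length, n)
        points = np.column_stack([np.zeros(n), np.zeros(n), z])
        L, D = length, length
        landmarks_t = {"aortic_valve": 0.0, "iliac_bifurcation": 1.0}
        s = z.copy()
    elif kind == "arc":
        R, angle = float(p["radius"]), float(p["angle"])
        if R <= 0 or angle <= 0:
            raise ValueError("degenerate curve: zero length")
        n = n_samples or max(int(R * angle / 0.5) + 1, 64)
        # arc in the x-z plane, apex at the top (z maximal at phi = pi/2)
        phi = np.linspace(math.pi / 2 - angle / 2, math.pi / 2 + angle / 2, n)
        points = np.column_stack([R * np.cos(phi), np.zeros(n), R * np.sin(phi)])
        L = R * angle
        D = 2 * R * math.sin(angle / 2)
        landmarks_t = {"aortic_valve": 0.0, "iliac_bifurcation": 1.0}
        s = R * (phi - phi[0])
    elif kind == "helix":
        a, b, turns = float(p["radius"]), float(p["pitch"]), float(p["turns"])
        t_max = 2 * math.pi * turns
        if a < 0 or b <= 0 or t_max <= 0:
            raise ValueError("degenerate curve: zero length")
        n = n_samples or max(int(t_max * math.hypot(a, b) / 0.5) + 1, 64)
        t = np.linspace(0.0, t_max, n)
        points = np.column_stack([a * np.cos(t), a * np.sin(t), b * t])
        L = t_max * math.hypot(a, b)
        D = math.sqrt(2 * a * a * (1 - math.cos(t_max)) + (b * t_max) ** 2)
        landmarks_t = {"aortic_valve": 0.0, "iliac_bifurcation": 1.0}
        s = t * math.hypot(a, b)
    elif kind == "aorta_like":
        curve, landmarks_t = _aorta_like_param(p)
        # fine quadrature for ground-truth lengths
        R, theta, ldesc = p["arch_radius"], p["arch_angle"], p["desc_length"]
        approx_len = R * (math.pi - (math.pi / 2 - theta)) + ldesc
        n_fine = max(int(approx_len / 0.05), 4000)
        t_fine = np.linspace(0.0, 1.0, n_fine)
        pts_fine = curve(t_fine)
        s_fine = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts_fine, axis=0), axis=1))]
        )
        L = float(s_fine[-1])
        D = float(np.linalg.norm(pts_fine[-1] - pts_fine[0]))
        n = n_samples or max(int(L / 0.5) + 1, 200)
        t = np.linspace(0.0, 1.0, n)
        points = curve(t)
        s = np.interp(t, t_fine, s_fine)
        landmarks_t = dict(landmarks_t)
        landmarks_s_fine = {
            k: float(np.interp(v, t_fine, s_fine)) for k, v in landmarks_t.items()
        }
    else:  # pragma: no cover
        raise ValueError(kind)

    T = (L / D - 1.0) * 100.0

    if kind != "aorta_like":
        landmarks_s_fine = {"aortic_valve": 0.0, "iliac_bifurcation": L}

    landmarks_xyz = {}
    for name, sv in landmarks_s_fine.items():
        idx = int(np.searchsorted(s, sv))
        idx = min(idx, len(s) - 1)
        landmarks_xyz[name] = points[idx].copy()

    regional_T = None
    if kind == "aorta_like":
        regional_T = _regional_tortuosity(points, s, landmarks_s_fine)

    return GroundTruth(
        points=points,
        s=s,
        length=L,
        chord=D,
        tortuosity=T,
        landmarks_s=landmarks_s_fine,
        landmarks_xyz=landmarks_xyz,
        regional_tortuosity=regional_T,
        sigma_level=spec.sigma_level,
        swirl_ratio=spec.swirl_ratio,
        peak_frame=int(np.argmax(spec.temporal_waveform)),
    )


def _regional_tortuosity(points, s, lms) -> dict[str, float]:
    mid = 0.5 * (lms["left_subclavian"] + lms["renal_branches"])
    bounds = {
        "AAo": (lms["aortic_valve"], lms["arch_top"]),
        "DAo": (lms["arch_top"], mid),
        "SAA": (mid, lms["renal_branches"]),
        "IAA": (lms["renal_branches"], lms["iliac_bifurcation"]),
    }
    out = {}
    for name, (lo, hi) in bounds.items():
        sel = (s >= lo) & (s <= hi)
        seg = points[sel]
        if seg.shape[0] >= 2:
            out[name] = _polyline_tortuosity(seg)[2]
    return out


# ---------------------------------------------------------------------------
# Velocity field and MR signal
# ---------------------------------------------------------------------------

def _grid_layout(spec: PhantomSpec, gt: GroundTruth):
    """Translate the curve into the grid frame; return (offset, grid_shape)."""
    margin = spec.lumen_radius + spec.body_margin + 2 * spec.voxel_spacing
    lo = gt.points.min(axis=0) - margin
    hi = gt.points.max(axis=0) + margin
    if spec.grid_shape is not None:
        shape = tuple(int(v) for v in spec.grid_shape)
        extent = (np.array(shape) - 1) * spec.voxel_spacing
        if np.any(extent < hi - lo):
            raise ValueError("lumen (plus margins) does not fit inside grid_shape")
        offset = -lo + (extent - (hi - lo)) / 2
    else:
        shape = tuple(int(math.ceil(v / spec.voxel_spacing)) + 1 for v in hi - lo)
        offset = -lo
    return offset, shape


def _render_geometry(spec: PhantomSpec, gt: GroundTruth):
    """Rasterize the curve onto the grid; one KD-tree pass serves everything.

    Translates the ground-truth curve into the grid frame and returns a dict
    with the velocity pattern (X, Y, Z, 3), the lumen and body-tissue masks,
    and the per-lumen-voxel centerline arc length (for regional bookkeeping).
    """
    offset, shape = _grid_layout(spec, gt)
    gt.points = gt.points + offset
    for k in gt.landmarks_xyz:
        gt.landmarks_xyz[k] = gt.landmarks_xyz[k] + offset

    sp = spec.voxel_spacing
    if 2 * spec.lumen_radius < 3 * sp:
        import warnings

        warnings.warn(
            "voxel spacing too coarse: fewer than 3 voxels across the lumen",
            stacklevel=2,
        )

    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    vox = np.stack(grids, axis=-1).reshape(-1, 3) * sp

    tree = cKDTree(gt.points)
    dist, idx = tree.query(vox, k=1)
    nearest = gt.points[idx]
    tangents = np.gradient(gt.points, gt.s, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    tan = tangents[idx]

    d = vox - nearest
    axial_off = np.einsum("ij,ij->i", d, tan)
    radial = d - axial_off[:, None] * tan
    r = np.linalg.norm(radial, axis=1)

    ds = float(np.median(np.diff(gt.s)))
    inside = (r <= spec.lumen_radius) & (np.abs(axial_off) <= ds)
    body = (dist <= spec.lumen_radius + spec.body_margin) | inside

    rho = r[inside] / spec.lumen_radius
    if spec.axial_profile == "parabolic":
        axial_speed = spec.peak_axial_velocity * (1.0 - rho**2)
    else:
        axial_speed = np.full_like(rho, spec.peak_axial_velocity)
    az_speed = spec.swirl_ratio * spec.peak_axial_velocity * rho

    r_in = np.maximum(r[inside], 1e-30)
    radial_unit = radial[inside] / r_in[:, None]
    az_unit = np.cross(tan[inside], radial_unit)

    pattern = np.zeros((vox.shape[0], 3))
    pattern[inside] = axial_speed[:, None] * tan[inside] + az_speed[:, None] * az_unit
    pattern = pattern.reshape(shape + (3,))
    lumen = inside.reshape(shape)
    gt.lumen_mask = lumen
    return {
        "pattern": pattern,
        "lumen": lumen,
        "body": body.reshape(shape),
        "lumen_s": gt.s[idx[inside]],
        "shape": shape,
    }


def generate_velocity_field(
    spec: PhantomSpec, gt: GroundTruth
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render the spatial velocity pattern of the phantom onto its grid.

    Returns ``(pattern, lumen_mask, gt)`` where ``pattern`` has shape
    (X, Y, Z, 3) in m/s at unit waveform; the per-frame field is
    ``pattern * waveform[t]``. The ground truth is updated in place with the
    grid-frame centerline and lumen mask. Inside the lumen the axial
    component follows the chosen profile (Poiseuille or plug) and the
    azimuthal component is the forced vortex
    ``swirl_ratio * peak_axial * (r / lumen_radius)``; outside it is zero.
    """
    rendered = _render_geometry(spec, gt)
    return rendered["pattern"], rendered["lumen"], gt


def encode_mr_signal(
    spec: PhantomSpec,
    sigma_field: np.ndarray,
    base_magnitude: np.ndarray,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Encode a fluctuation field into the four magnitude volumes of one frame.

    Returns shape (4, X, Y, Z): the reference ``|S|`` followed by the three
    encoded magnitudes ``|S_i| = |S| exp(-k_v^2 sigma_i^2 / 2)``. Rician noise
    is applied when ``noise`` is set and the spec's SNR is finite.
    """
    sigma_field = np.asarray(sigma_field, dtype=float)
    if np.any(sigma_field < 0):
        raise ValueError("sigma_field must be non-negative")
    if np.any(sigma_field >= spec.venc):
        raise ValueError("sigma >= VENC: signal model outside its valid regime")
    kv = math.pi / spec.venc
    att = np.exp(-0.5 * kv**2 * sigma_field**2)
    mags = np.stack([base_magnitude] + [base_magnitude * att] * 3, axis=0)
    if noise and math.isfinite(spec.snr):
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        noise_scale = spec.baseline_magnitude / spec.snr
        n1 = rng.standard_normal(mags.shape) * noise_scale
        n2 = rng.standard_normal(mags.shape) * noise_scale
        mags = np.sqrt((mags + n1) ** 2 + n2**2)
    return mags


def generate_phantom(spec: PhantomSpec) -> tuple[FlowDataset, GroundTruth]:
    """Full synthetic subject: velocity + encoded magnitudes + ground truth."""
    gt = generate_centerline(spec)
    rendered = _render_geometry(spec, gt)
    pattern, lumen, body = rendered["pattern"], rendered["lumen"], rendered["body"]
    shape = rendered["shape"]
    rng = np.random.default_rng(spec.seed)

    base_mag = np.where(
        lumen,
        spec.baseline_magnitude,
        np.where(body, spec.tissue_magnitude_frac * spec.baseline_magnitude, 0.0),
    )
    sigma = np.where(lumen, spec.sigma_level, 0.0)

    wf = spec.temporal_waveform
    T = spec.n_timeframes
    velocity = pattern[None] * wf[:, None, None, None, None]
    mags_nf = encode_mr_signal(spec, sigma, base_mag, rng=None, noise=False)
    mags = np.broadcast_to(mags_nf[None], (T, 4) + tuple(shape))
    if math.isfinite(spec.snr):
        noise_scale = spec.baseline_magnitude / spec.snr
        n1 = rng.standard_normal(mags.shape) * noise_scale
        n2 = rng.standard_normal(mags.shape) * noise_scale
        mags = np.sqrt((mags + n1) ** 2 + n2**2)
    else:
        mags = np.array(mags)
    if spec.velocity_noise and math.isfinite(spec.snr):
        sd = spec.venc / (spec.snr * math.pi)
        velocity = velocity + rng.standard_normal(velocity.shape) * sd

    data = FlowDataset(
        velocity=velocity,
        magnitudes=mags,
        venc=spec.venc,
        voxel_spacing=spec.voxel_spacing,
        timeframe_fractions=np.arange(T) / T,
        superior_axis=2,
        provenance=[f"phantom geometry={spec.geometry_kind} seed={spec.seed}"],
    )

    # ground-truth regional mean speed at the peak frame (noise-free pattern)
    speed_peak = np.linalg.norm(pattern, axis=-1) * wf[gt.peak_frame]
    means = {"Whole": float(speed_peak[lumen].mean())}
    if gt.regional_tortuosity is not None:
        mid = 0.5 * (gt.landmarks_s["left_subclavian"] + gt.landmarks_s["renal_branches"])
        bounds = {
            "AAo": (0.0, gt.landmarks_s["arch_top"]),
            "DAo": (gt.landmarks_s["arch_top"], mid),
            "SAA": (mid, gt.landmarks_s["renal_branches"]),
            "IAA": (gt.landmarks_s["renal_branches"], gt.landmarks_s["iliac_bifurcation"]),
        }
        svox = rendered["lumen_s"]
        sp_l = speed_peak[lumen]
        for name, (lo, hi) in bounds.items():
            sel = (svox >= lo) & (svox <= hi)
            if sel.any():
                means[name] = float(sp_l[sel].mean())
    gt.regional_mean_speed = means
    return data, gt


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Sampling distributions (mean, sd) for one cohort group's phantoms."""

    arch_angle: tuple[float, float] = (2.2, 0.08)
    arch_radius: tuple[float, float] = (18.0, 0.5)
    desc_length: tuple[float, float] = (90.0, 3.0)
    thoracic_amp: tuple[float, float] = (1.0, 0.3)
    abdominal_amp: tuple[float, float] = (1.0, 0.3)
    lumen_radius: tuple[float, float] = (7.0, 0.3)
    peak_velocity: tuple[float, float] = (0.9, 0.08)


def young_group() -> GroupSpec:
    return GroupSpec()


def old_group() -> GroupSpec:
    """Older subjects: more tortuous and wider, with slower flow."""
    return GroupSpec(
        arch_angle=(2.6, 0.06),
        thoracic_amp=(4.0, 0.5),
        abdominal_amp=(4.5, 0.6),
        lumen_radius=(8.5, 0.4),
        peak_velocity=(0.52, 0.06),
    )


@dataclass
class CohortSpec:
    """Two-group study design emulating a Young/Old 4D flow cohort.

    The coupling rules tie swirl positively to the tortuosity-controlling arch
    angle (tortuous aortas carry more helical flow) and the fluctuation
    intensity positively to peak velocity (faster flow is more disturbed).
    """

    n_young: int = 10
    n_old: int = 10
    young: GroupSpec = field(default_factory=young_group)
    old: GroupSpec = field(default_factory=old_group)
    swirl_base: float = 0.15
    swirl_per_angle: float = 0.6     # d swirl / d arch_angle, anchored at 2.0 rad
    swirl_sd: float = 0.03
    sigma_per_velocity: float = 0.12  # d sigma / d peak_velocity
    sigma_sd: float = 0.008
    n_timeframes: int = 20
    venc: float = 1.5
    snr: float = 30.0
    velocity_noise: bool = True
    voxel_spacing: float = 2.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass
class SubjectRecord:
    subject: str
    group: str
    spec: PhantomSpec
    data: FlowDataset | None
    gt: GroundTruth


def _sample_spec(
    cohort: CohortSpec, group: GroupSpec, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    max_retries = 20
    for _ in range(max_retries):
        draw = {
            name: rng.normal(*getattr(group, name))
            for name in (
                "arch_angle",
                "arch_radius",
                "desc_length",
                "thoracic_amp",
                "abdominal_amp",
                "lumen_radius",
                "peak_velocity",
            )
        }
        swirl = (
            cohort.swirl_base
            + cohort.swirl_per_angle * (draw["arch_angle"] - 2.0)
            + rng.normal(0.0, cohort.swirl_sd)
        )
        sigma = cohort.sigma_per_velocity * draw["peak_velocity"] + rng.normal(
            0.0, cohort.sigma_sd
        )
        try:
            return PhantomSpec(
                geometry_kind="aorta_like",
                geometry_params={
                    "arch_radius": draw["arch_radius"],
                    "arch_angle": draw["arch_angle"],
                    "desc_length": draw["desc_length"],
                    "thoracic_amp": max(draw["thoracic_amp"], 0.0),
                    "abdominal_amp": max(draw["abdominal_amp"], 0.0),
                },
                lumen_radius=draw["lumen_radius"],
                peak_axial_velocity=draw["peak_velocity"],
                swirl_ratio=max(swirl, 0.0),
                sigma_level=max(sigma, 0.0),
                n_timeframes=cohort.n_timeframes,
                voxel_spacing=cohort.voxel_spacing,
                venc=cohort.venc,
                snr=cohort.snr,
                velocity_noise=cohort.velocity_noise,
                seed=seed,
            )
        except ValueError:
            continue
    raise ValueError("could not sample a physically valid PhantomSpec")


def generate_cohort(
    cohort: CohortSpec, fields: bool = True
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Sample a two-group cohort; deterministic for a fixed master seed.

    With ``fields=False`` only the specs and analytic ground truth are built
    (no volumetric rendering), which is enough for ground-truth-level checks.
    """
    rng = np.random.default_rng(cohort.master_seed)
    records: list[SubjectRecord] = []
    rows = []
    for group_name, group, n in (
        ("Young", cohort.young, cohort.n_young),
        ("Old", cohort.old, cohort.n_old),
    ):
        for i in range(n):
            seed = int(rng.integers(0, 2**31 - 1))
            spec = _sample_spec(cohort, group, rng, seed)
            if fields:
                data, gt = generate_phantom(spec)
            else:
                data, gt = None, generate_centerline(spec)
            subject = f"{group_name.lower()}{i:02d}"
            records.append(SubjectRecord(subject, group_name, spec, data, gt))
            row = {
                "subject": subject,
                "group": group_name,
                "tortuosity": gt.tortuosity,
                "lumen_radius": spec.lumen_radius,
                "peak_velocity": spec.peak_axial_velocity,
                "swirl_ratio": spec.swirl_ratio,
                "sigma_level": spec.sigma_level,
                "seed": spec.seed,
            }
            if gt.regional_tortuosity:
                for reg in REGION_NAMES:
                    row[f"tortuosity_{reg}"] = gt.regional_tortuosity.get(reg)
            rows.append(row)
    return records, pd.DataFrame(rows)


def make_phantom(geometry_kind: str = "aorta_like", **kwargs) -> tuple[FlowDataset, GroundTruth]:
    """Convenience wrapper: build a PhantomSpec and generate it in one call."""
    return generate_phantom(PhantomSpec(geometry_kind=geometry_kind, **kwargs))
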