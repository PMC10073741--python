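"""Lumen segmentation, centerline extraction, regional partitioning, and
geometric metrics (tortuosity, diameter).

The manual segmentation and landmarking of clinical workflows is replaced by
automated operations: a PC-MRA is synthesized from magnitude and velocity
data, thresholded (Otsu), reduced to its largest 6-connected component, and
closed; the centerline is the shortest path through the 3D skeleton between
the two supplied anatomical endpoints, anchored at those endpoints (a 3D
skeleton retreats roughly one lumen radius from tube end caps, which would
otherwise bias arc length and chord).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import ball, skeletonize

from .datatypes import (
    REGION_NAMES,
    WHOLE,
    Centerline,
    FlowDataset,
    LandmarkSet,
    RegionGeometry,
    RegionPartition,
    SegmentationMask,
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def compute_pcmra(data: FlowDataset) -> np.ndarray:
    """Phase-contrast MR angiogram: sqrt(mean_t(|S|^2 * |v|^2))."""
    speed = data.speed()
    mag = data.magnitudes[:, 0]
    return np.sqrt(np.mean((mag * speed) ** 2, axis=0))


def segment_lumen(pcmra: np.ndarray, voxel_spacing) -> SegmentationMask:
    """Otsu threshold -> largest 6-connected component -> 1-voxel closing."""
    pcmra = np.asarray(pcmra, dtype=float)
    if np.any(pcmra < 0):
        raise ValueError("PC-MRA must be non-negative")
    if pcmra.max() <= 0:
        raise ValueError("PC-MRA is identically zero; nothing to segment")
    thresh = threshold_otsu(pcmra)
    binary = pcmra > thresh
    if not binary.any():
        raise ValueError("empty segmentation after thresholding")
    labeled, n = ndimage.label(binary, structure=_STRUCT6)
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    largest = labeled == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(largest, structure=ball(1))
    return SegmentationMask(mask=closed, voxel_spacing=voxel_spacing)


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # each undirected pair once
    ]
    for off in offsets:
        step = float(np.linalg.norm(np.asarray(off) * spacing))
        for c in coords:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None:
                g.add_edge(index[tuple(c)], j, weight=step)
    return g, coords


def _nearest_skeleton_geodesic(
    mask: SegmentationMask, skel: np.ndarray, coords: np.ndarray, endpoint_mm: np.ndarray
) -> int:
    """Index (into ``coords``) of the skeleton voxel geodesically nearest an
    endpoint, travelling only through the mask."""
    from skimage.graph import MCP_Geometric

    spacing = mask.voxel_spacing
    vox = np.round(endpoint_mm / spacing).astype(int)
    vox = np.clip(vox, 0, np.asarray(mask.mask.shape) - 1)
    if not mask.mask[tuple(vox)]:
        inside = np.argwhere(mask.mask)
        vox = inside[np.argmin(np.linalg.norm((inside - vox) * spacing, axis=1))]
    cost = np.where(mask.mask, 1.0, np.inf)
    mcp = MCP_Geometric(cost, sampling=tuple(spacing))
    costs, _ = mcp.find_costs([tuple(vox)])
    d = costs[tuple(coords.T)]
    if not np.isfinite(d).any():
        raise ValueError(
            "endpoint is disconnected from the skeleton inside the mask"
        )
    return int(np.argmin(d))


def _smooth_path(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving average with a shrinking window near the ends; endpoints fixed."""
    half = window // 2
    n = len(points)
    out = np.empty_like(points)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    out[0], out[-1] = points[0], points[-1]
    return out


def extract_centerline(
    mask: SegmentationMask,
    endpoints: tuple[np.ndarray, np.ndarray],
    smoothing_window: int = 5,
) -> Centerline:
    """Skeletonize the mask and trace the centerline between two endpoints.

    ``endpoints`` are the proximal (valve) and distal (iliac) positions in mm.
    The skeleton voxels form a 26-connected graph with Euclidean edge weights;
    the centerline is the shortest path between the skeleton voxels nearest
    each endpoint, with the supplied endpoints themselves prepended/appended
    before smoothing.
    """
    spacing = mask.voxel_spacing
    skel = skeletonize(mask.mask)
    if not skel.any():
        raise ValueError("skeletonization produced no voxels")
    g, coords = _skeleton_graph(skel, spacing)
    coords_mm = coords * spacing
    ends = [np.asarray(e, dtype=float) for e in endpoints]
    # nearest skeleton voxel by geodesic (in-mask) distance: the Euclidean
    # nearest can lie in an adjacent vessel segment when the aorta folds back
    # on itself (valve beside the descending limb)
    attach = [_nearest_skeleton_geodesic(mask, skel, coords, e) for e in ends]
    ia, ib = attach
    try:
        path = nx.shortest_path(g, ia, ib, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise ValueError(
            "endpoints fall in disconnected parts of the skeleton; the "
            "segmentation is broken between them"
        ) from exc
    pts = np.vstack([ends[0], coords_mm[path], ends[1]])
    # drop duplicate consecutive points before smoothing
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    pts = _smooth_path(pts, window=smoothing_window)
    return Centerline.from_points(pts)


def locate_arch_top(centerline: Centerline, superior_axis: int = 2) -> float:
    """Arc length of the most superior centerline point (ties: smallest s)."""
    coord = centerline.points[:, superior_axis]
    return float(centerline.s[int(np.argmax(coord))])


def landmarks_from_positions(
    centerline: Centerline,
    positions_xyz: dict[str, np.ndarray],
    superior_axis: int = 2,
) -> LandmarkSet:
    """Map 3D landmark positions onto the centerline's arc length.

    ``arch_top`` is located geometrically on the centerline itself; the other
    four landmarks map to the arc length of their nearest centerline point.
    """
    tree = cKDTree(centerline.points)
    s_of = {}
    for name in ("aortic_valve", "left_subclavian", "renal_branches", "iliac_bifurcation"):
        _, idx = tree.query(np.asarray(positions_xyz[name], dtype=float))
        s_of[name] = float(centerline.s[int(idx)])
    return LandmarkSet(
        aortic_valve=s_of["aortic_valve"],
        arch_top=locate_arch_top(centerline, superior_axis),
        left_subclavian=s_of["left_subclavian"],
        renal_branches=s_of["renal_branches"],
        iliac_bifurcation=s_of["iliac_bifurcation"],
    )


def partition_regions(
    centerline: Centerline,
    landmarks: LandmarkSet,
    mask: SegmentationMask | None = None,
) -> RegionPartition:
    """Divide the aorta into AAo/DAo/SAA/IAA along centerline arc length.

    The DAo ends midway (in arc length) between the left subclavian artery and
    the renal branches. When a mask is given, every lumen voxel is labeled
    with the region of its nearest centerline point.
    """
    mid = 0.5 * (landmarks.left_subclavian + landmarks.renal_branches)
    intervals = {
        "AAo": (landmarks.aortic_valve, landmarks.arch_top),
        "DAo": (landmarks.arch_top, mid),
        "SAA": (mid, landmarks.renal_branches),
        "IAA": (landmarks.renal_branches, landmarks.iliac_bifurcation),
    }
    for name, (lo, hi) in intervals.items():
        if hi <= lo:
            raise ValueError(f"region {name} is empty: [{lo:.2f}, {hi:.2f})")
    labels = None
    if mask is not None:
        sel = (centerline.s >= landmarks.aortic_valve) & (
            centerline.s <= landmarks.iliac_bifurcation
        )
        pts, svals = centerline.points[sel], centerline.s[sel]
        tree = cKDTree(pts)
        vox = np.argwhere(mask.mask) * mask.voxel_spacing
        _, idx = tree.query(vox, k=1)
        svox = svals[idx]
        labels = np.zeros(mask.mask.shape, dtype=np.uint8)
        codes = np.zeros(len(svox), dtype=np.uint8)
        for name in REGION_NAMES:
            lo, hi = intervals[name]
            sel_v = (svox >= lo) & (svox < hi)
            codes[sel_v] = RegionPartition.REGION_CODES[name]
        codes[svox >= intervals["IAA"][1]] = RegionPartition.REGION_CODES["IAA"]
        codes[svox < intervals["AAo"][0]] = RegionPartition.REGION_CODES["AAo"]
        labels[mask.mask] = codes
    return RegionPartition(intervals=intervals, labels=labels)


def compute_tortuosity(centerline: Centerline, interval: tuple[float, float] | None = None) -> float:
    """Tortuosity T = (L/D - 1) * 100 over an arc-length interval.

    ``L`` is the centerline length of the interval and ``D`` the Euclidean
    distance between the interval's end points; T is the percentage extra
    length relative to a straight segment.
    """
    if interval is None:
        interval = (float(centerline.s[0]), float(centerline.s[-1]))
    s0, s1 = interval
    if not (centerline.s[0] - 1e-9 <= s0 < s1 <= centerline.s[-1] + 1e-9):
        raise ValueError("interval outside centerline range")
    p0, p1 = centerline.point_at(s0), centerline.point_at(s1)
    chord = float(np.linalg.norm(p1 - p0))
    if chord <= 1e-9:
        raise ValueError("coincident interval endpoints: chord is zero")
    length = s1 - s0
    return (length / chord - 1.0) * 100.0


def compute_diameter(
    mask: SegmentationMask,
    partition: RegionPartition,
    region: str,
    region_length: float,
) -> float:
    """Equivalent-circle diameter of the mean cross-section of one region.

    D = 2*sqrt(A/pi) with A = labeled region volume / centerline length.
    """
    voxels = partition.region_voxels(region)
    n = int(voxels.sum())
    if n == 0:
        raise ValueError(f"region {region} contains no labeled voxels")
    if region_length <= 0:
        raise ValueError(f"region {region} has zero centerline length")
    area = n * mask.voxel_volume / region_length
    return 2.0 * float(np.sqrt(area / np.pi))


def region_geometry(
    centerline: Centerline,
    landmarks: LandmarkSet,
    partition: RegionPartition,
    mask: SegmentationMask,
) -> dict[str, RegionGeometry]:
    """Tortuosity, lengths, diameter and volume for each region + whole aorta."""
    out = {}
    whole = (landmarks.aortic_valve, landmarks.iliac_bifurcation)
    for region in (WHOLE,) + REGION_NAMES:
        interval = whole if region == WHOLE else partition.intervals[region]
        length = interval[1] - interval[0]
        T = compute_tortuosity(centerline, interval)
        chord = length / (1.0 + T / 100.0)
        diameter = compute_diameter(mask, partition, region, length)
        volume = float(partition.region_voxels(region).sum()) * mask.voxel_volume
        out[region] = RegionGeometry(
            region=region,
            tortuosity=T,
            length=length,
            chord=chord,
            diameter=diameter,
            volume=volume,
        )
    return out
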