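"""Automated cervical biometry from a label volume.

Given a validated segmentation (outer stroma / inner stroma / canal / cyst)
and a lower-uterine-segment reference line, this module derives the full
measurement panel used to phenotype the late-gestation cervix:

* canal centerline (skeleton-based, world mm),
* internal / external os landmarks and the canal midpoint,
* 2-point and 3-point cervical length,
* os cross-sectional (Feret) diameters,
* utero-cervical angle,
* compartment volumes (total, stroma, canal, cyst).

Conventions
-----------
The centerline is the longest geodesic path through the largest
26-connected canal∪cyst component, with edge costs penalized by the inverse
squared medial distance transform so the path hugs the canal axis (a
morphological skeleton without the end erosion of voxel thinning).  The
path is re-centred on local cross-section centroids, extended tangentially
to the component boundary, and smoothed with a 5-point endpoint-preserving
moving average.  The
endpoint nearer the uterine reference line is the internal os.  The
utero-cervical angle is taken at the internal os between the uterine axis
direction (pointing away from the cervix) and the straight internal→external
os line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .volume_io import (
    LABEL_CANAL,
    LABEL_CYST,
    LABEL_INNER_STROMA,
    LABEL_OUTER_STROMA,
    LabelVolume,
    UterineAxis,
)

__all__ = [
    "Centerline",
    "OsLandmarks",
    "CervicalBiometry",
    "BiometryError",
    "MIN_CANAL_VOXELS",
    "extract_canal_centerline",
    "locate_os_landmarks",
    "cervical_length",
    "os_diameter",
    "utero_cervical_angle",
    "compartment_volumes",
    "compute_biometry",
]

#: smallest canal component considered measurable
MIN_CANAL_VOXELS = 20

#: moving-average window for centerline smoothing (points)
SMOOTHING_WINDOW = 5


class BiometryError(RuntimeError):
    """A biometry stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class Centerline:
    """Ordered polyline through the cervical canal, internal→external os.

    ``points`` are world-mm coordinates; the first point is the internal
    os end and the last the external os end.
    """

    points: np.ndarray  # (n, 3) world mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("centerline needs >=3 points of dimension 3")
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive centerline points must be distinct")
        self.points = pts

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def cumulative_lengths(self) -> np.ndarray:
        gaps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(gaps)])

    def point_at_arc_length(self, s: float) -> np.ndarray:
        """Linear interpolation of the polyline at arc length ``s`` mm."""
        cum = self.cumulative_lengths
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def tangent_at_arc_length(self, s: float, half_window: float = 1.5
                              ) -> np.ndarray:
        """Unit tangent at arc length ``s``, from a secant over
        ``s +/- half_window`` mm (robust to point-level jitter)."""
        total = self.arc_length
        s = float(np.clip(s, 0.0, total))
        p0 = self.point_at_arc_length(max(0.0, s - half_window))
        p1 = self.point_at_arc_length(min(total, s + half_window))
        d = p1 - p0
        n = np.linalg.norm(d)
        if n == 0:  # degenerate window; fall back to the local segment
            cum = self.cumulative_lengths
            i = min(int(np.searchsorted(cum, s, side="right") - 1),
                    len(self.points) - 2)
            d = self.points[i + 1] - self.points[i]
            n = np.linalg.norm(d)
        return d / n


@dataclass(frozen=True)
class OsLandmarks:
    """The two canal openings plus the mid-arc point."""

    internal_os: np.ndarray
    external_os: np.ndarray
    canal_mid: np.ndarray


@dataclass
class CervicalBiometry:
    """The per-scan measurement panel.

    Lengths and diameters in mm, volumes in cm^3, angle in degrees.
    """

    length_2pt: float
    length_3pt: float
    internal_os_diameter: float
    external_os_diameter: float
    utero_cervical_angle: float
    total_volume: float
    stroma_volume: float
    canal_volume: float
    cyst_volume: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        panel = [self.length_2pt, self.length_3pt, self.internal_os_diameter,
                 self.external_os_diameter, self.total_volume,
                 self.stroma_volume, self.canal_volume, self.cyst_volume]
        if any(v < 0 for v in panel):
            raise ValueError("lengths, diameters and volumes must be >= 0")
        if not 0.0 <= self.utero_cervical_angle <= 180.0:
            raise ValueError("utero-cervical angle must lie in [0, 180] degrees")

    def as_dict(self) -> dict[str, float]:
        return {
            "length_2pt_mm": self.length_2pt,
            "length_3pt_mm": self.length_3pt,
            "int_os_diam_mm": self.internal_os_diameter,
            "ext_os_diam_mm": self.external_os_diameter,
            "uca_deg": self.utero_cervical_angle,
            "total_vol_cm3": self.total_volume,
            "stroma_vol_cm3": self.stroma_volume,
            "canal_vol_cm3": self.canal_volume,
            "cyst_vol_cm3": self.cyst_volume,
        }


# ---------------------------------------------------------------------------
# centerline extraction

def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    labelled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask), 0
    counts = np.bincount(labelled.ravel())[1:]
    # ties broken toward the component containing the lowest-index voxel
    best = int(np.argmax(counts)) + 1
    comp = labelled == best
    return comp, int(counts[best - 1])


def _component_graphs(idx: np.ndarray, world: np.ndarray,
                      penalty: np.ndarray
                      ) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """26-neighbourhood graphs over component voxels.

    Returns (metric, penalized): the metric graph carries world gap
    lengths; the penalized graph scales them by the inverse-squared
    medial distance transform so shortest paths hug the tube axis.
    """
    n = len(world)
    tree = cKDTree(idx)
    pairs = tree.query_pairs(r=np.sqrt(3) + 1e-9, output_type="ndarray")
    if len(pairs) == 0:
        empty = sparse.csr_matrix((n, n))
        return empty, empty

    def build(w: np.ndarray) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (np.r_[w, w], (np.r_[pairs[:, 0], pairs[:, 1]],
                           np.r_[pairs[:, 1], pairs[:, 0]])),
            shape=(n, n)).tocsr()

    gap = np.linalg.norm(world[pairs[:, 0]] - world[pairs[:, 1]], axis=1)
    pen = 0.5 * (penalty[pairs[:, 0]] + penalty[pairs[:, 1]])
    return build(gap), build(gap * pen)


def _longest_geodesic_path(metric: sparse.csr_matrix,
                           penalized: sparse.csr_matrix) -> np.ndarray:
    """Vertex sequence spanning the component's geodesic diameter.

    The endpoint pair comes from two farthest-point sweeps on the metric
    graph (so endpoints sit on the tube end faces, not wherever penalized
    cost happens to accumulate); the path between them is the penalized
    shortest path, which runs along the canal axis.
    """
    d0 = dijkstra(metric, indices=0)
    d0[~np.isfinite(d0)] = -1
    a = int(np.argmax(d0))
    da = dijkstra(metric, indices=a)
    da[~np.isfinite(da)] = -1
    b = int(np.argmax(da))
    _, pred = dijkstra(penalized, indices=a, return_predecessors=True)
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return np.array(path)


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Uniform arc-length resampling by linear interpolation."""
    gaps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(gaps)])
    if cum[-1] <= step:
        return points
    s_new = np.linspace(0.0, cum[-1], max(int(round(cum[-1] / step)) + 1, 3))
    return np.column_stack(
        [np.interp(s_new, cum, points[:, j]) for j in range(3)])


def _recentre(points: np.ndarray, comp_world: np.ndarray,
              slab_half: float) -> np.ndarray:
    """Snap each path point to the centroid of its orthogonal cross-section.

    The geodesic path endpoints sit on the tube end faces but may lie at a
    face corner; the cross-section centroid restores them (and interior
    points) to the canal axis.
    """
    out = points.copy()
    n = len(points)
    for i in range(n):
        j0, j1 = max(0, i - 3), min(n - 1, i + 3)
        tangent = points[j1] - points[j0]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        proj = (comp_world - points[i]) @ tangent
        radial = comp_world - points[i] - np.outer(proj, tangent)
        near = (np.abs(proj) <= slab_half) & (
            np.linalg.norm(radial, axis=1) <= 12.0)  # mm; excludes far arms
        if near.sum() >= 1:
            out[i] = comp_world[near].mean(axis=0)
    return out


def _smooth_polyline(points: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving average with shrinking windows; endpoints are fixed."""
    half = window // 2
    n = len(points)
    out = points.copy()
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if h > 0:
            out[i] = points[i - h:i + h + 1].mean(axis=0)
    return out


def _grow_ends(points: np.ndarray, vol: LabelVolume, mask: np.ndarray,
               comp_world: np.ndarray, max_extension: float) -> np.ndarray:
    """Regrow both polyline ends out to the component boundary.

    Each end is extended by a step-and-recentre march: advance along the
    local secant tangent by half a voxel, snap the candidate laterally to
    the centroid of its orthogonal cross-section, and stop on leaving the
    component.  Unlike a straight tangential extension this follows a
    curved canal, so the regrown ends terminate on the end faces.
    """
    inv = np.linalg.inv(vol.affine)
    step = 0.5 * float(np.min(vol.spacing))
    slab_half = 0.5 * float(np.mean(vol.spacing))
    tree = cKDTree(comp_world)
    ball = 12.0  # mm; cross-section search radius, excludes far arms

    def inside(p: np.ndarray) -> bool:
        idx = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
            return False
        return bool(mask[tuple(idx)])

    def grow(pts: list[np.ndarray]) -> list[np.ndarray]:
        """Append points beyond pts[-1]; pts ordered interior -> end."""
        added = 0.0
        t0 = None
        while added < max_extension:
            j = len(pts) - 1
            back = j
            while back > 0 and np.linalg.norm(pts[j] - pts[back]) < 2.0:
                back -= 1
            tangent = pts[j] - pts[back]
            norm = np.linalg.norm(tangent)
            if norm == 0:
                break
            tangent /= norm
            if t0 is None:
                t0 = tangent
            elif tangent @ t0 < np.cos(np.radians(45.0)):
                break  # march is curling back inside the tube; stop
            cand = pts[j] + step * tangent
            if not inside(cand):
                break
            near = tree.query_ball_point(cand, ball)
            if near:
                nb = comp_world[near]
                proj = (nb - cand) @ tangent
                slab = nb[np.abs(proj) <= slab_half]
                if len(slab) > 0:
                    lateral = slab.mean(axis=0) - cand
                    lateral -= (lateral @ tangent) * tangent
                    lnorm = np.linalg.norm(lateral)
                    if lnorm > step:  # cap sideways drift per step
                        lateral *= step / lnorm
                    if inside(cand + lateral):
                        cand = cand + lateral
            pts.append(cand)
            added += step
        return pts

    rev = grow([p for p in points[::-1]])
    pts = rev[::-1]
    pts = grow(pts)
    return np.asarray(pts)


def extract_canal_centerline(vol: LabelVolume,
                             uterine_axis: UterineAxis) -> Centerline:
    """Extract the canal centerline, ordered internal→external os.

    Operates on the largest 26-connected component of canal∪cyst voxels.
    Raises :class:`BiometryError` if no canal is present or the component
    holds fewer than :data:`MIN_CANAL_VOXELS` voxels.
    """
    stage = "extract_canal_centerline"
    canal_mask = vol.mask(LABEL_CANAL, LABEL_CYST)
    if not (vol.voxels == LABEL_CANAL).any():
        raise BiometryError(stage, "no canal voxels (label 3) in volume")
    comp, count = _largest_component(canal_mask)
    if count < MIN_CANAL_VOXELS:
        raise BiometryError(
            stage, f"canal too small: largest component has {count} voxels "
                   f"(minimum {MIN_CANAL_VOXELS})")

    comp_idx = np.argwhere(comp)
    comp_world = vol.world_coords(comp_idx)
    # medial distance transform: paths through the canal core are cheap
    dt = ndimage.distance_transform_edt(comp, sampling=vol.spacing)
    dt_vals = dt[tuple(comp_idx.T)]
    penalty = 1.0 / (dt_vals + 0.5 * float(np.min(vol.spacing))) ** 2
    g_metric, g_pen = _component_graphs(comp_idx.astype(float), comp_world,
                                        penalty)
    order = _longest_geodesic_path(g_metric, g_pen)
    pts = comp_world[order]
    if len(pts) < 3:
        raise BiometryError(stage, "canal path degenerate (<3 points)")

    # tame voxel-step zigzag, then iterate recentring with good tangents
    step = float(np.min(vol.spacing))
    slab_half = 0.5 * float(np.mean(vol.spacing))
    pts = _smooth_polyline(pts)
    pts = _resample_polyline(pts, step)
    for _ in range(2):
        pts = _recentre(pts, comp_world, slab_half)
        pts = _smooth_polyline(pts)
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
        pts = _resample_polyline(pts[keep], step)
    # the raw geodesic terminates at end-face corners; trim the
    # contaminated tail points, then regrow the ends along the (accurate)
    # interior tangents out to the component boundary
    # trim scale: the geodesic leaves the axis over roughly one local
    # tube radius approaching the cap, plus one voxel diagonal
    diag = float(np.linalg.norm(vol.spacing))
    r_max = float(dt_vals.max())
    trim_len = r_max + 1.5 * diag
    trim = int(np.ceil(trim_len / step))
    if len(pts) > 2 * trim + 4:
        pts = pts[trim:len(pts) - trim]
    if len(pts) >= 3:
        pts = _grow_ends(pts, vol, comp, comp_world,
                         max_extension=trim_len + 2.0 * diag)
    # drop numerically duplicated consecutive points
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    if len(pts) < 3:
        raise BiometryError(stage, "centerline collapsed after smoothing")

    # internal os = endpoint nearer the uterine reference
    if (np.linalg.norm(pts[-1] - uterine_axis.point_a)
            < np.linalg.norm(pts[0] - uterine_axis.point_a)):
        pts = pts[::-1].copy()
    return Centerline(points=pts)


# ---------------------------------------------------------------------------
# landmarks and scalar measurements

def locate_os_landmarks(cl: Centerline) -> OsLandmarks:
    """Endpoints of the centerline plus the point at half arc length."""
    return OsLandmarks(
        internal_os=cl.points[0].copy(),
        external_os=cl.points[-1].copy(),
        canal_mid=cl.point_at_arc_length(0.5 * cl.arc_length),
    )


def cervical_length(lm: OsLandmarks) -> tuple[float, float]:
    """(2-point, 3-point) cervical length in mm.

    2-point: straight internal→external os distance.  3-point: the two
    chords via the canal midpoint, a first-order correction for canal
    curvature.
    """
    l2 = float(np.linalg.norm(lm.internal_os - lm.external_os))
    l3 = float(np.linalg.norm(lm.internal_os - lm.canal_mid)
               + np.linalg.norm(lm.canal_mid - lm.external_os))
    return l2, l3


def os_diameter(vol: LabelVolume, cl: Centerline,
                which: Literal["internal", "external"]) -> float:
    """Maximum Feret diameter of the canal cross-section at one os.

    The section is taken one voxel diagonal inward from the endpoint, in a
    1-voxel-thick slab orthogonal to the local centerline tangent; the
    diameter is the largest pairwise world distance among canal∪cyst voxel
    centres in the slab (0.0 if the slab is empty).
    """
    if which not in ("internal", "external"):
        raise ValueError(f"which must be 'internal' or 'external', got {which!r}")
    diag = float(np.linalg.norm(vol.spacing))
    total = cl.arc_length
    s = min(diag, total / 2) if which == "internal" else max(total - diag, total / 2)
    centre = cl.point_at_arc_length(s)
    tangent = cl.tangent_at_arc_length(s)

    mask = vol.mask(LABEL_CANAL, LABEL_CYST)
    pts = vol.world_coords(np.argwhere(mask))
    if len(pts) == 0:
        return 0.0
    proj = (pts - centre) @ tangent
    slab = pts[np.abs(proj) <= 0.5 * float(np.mean(vol.spacing))]
    if len(slab) < 2:
        return 0.0
    # a strongly curved canal can re-enter the cutting plane far from the
    # os; keep only the in-plane voxel cluster containing the os itself
    tree = cKDTree(slab)
    link = tree.query_pairs(r=2.0 * diag, output_type="ndarray")
    nslab = len(slab)
    adj = sparse.coo_matrix(
        (np.ones(len(link)), (link[:, 0], link[:, 1])),
        shape=(nslab, nslab))
    from scipy.sparse.csgraph import connected_components
    _, comp_lab = connected_components(adj, directed=False)
    seed = int(np.argmin(np.linalg.norm(slab - centre, axis=1)))
    slab = slab[comp_lab == comp_lab[seed]]
    if len(slab) < 2:
        return 0.0
    if len(slab) > 200:
        from scipy.spatial import ConvexHull
        try:
            hull = ConvexHull(slab, qhull_options="QJ")
            slab = slab[hull.vertices]
        except Exception:
            pass
    return float(pdist(slab).max())


def utero_cervical_angle(lm: OsLandmarks, axis: UterineAxis) -> float:
    """Angle (degrees, [0, 180]) at the internal os between the uterine
    axis direction (away from the cervix) and the internal→external os line."""
    v = lm.external_os - lm.internal_os
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("internal and external os coincide; angle undefined")
    u = axis.direction
    cosang = float(np.clip(np.dot(u, v / nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def compartment_volumes(vol: LabelVolume) -> tuple[float, float, float, float]:
    """(total, stroma, canal, cyst) volumes in cm^3 by voxel counting.

    Stroma = outer+inner stroma labels; total = stroma+canal+cyst; the
    uterine reference region is excluded.  The partition
    total = stroma + canal + cyst is exact in voxel counts.
    """
    vv = vol.voxel_volume_mm3
    counts = np.bincount(vol.voxels.ravel(), minlength=6)
    stroma = (counts[LABEL_OUTER_STROMA] + counts[LABEL_INNER_STROMA]) * vv / 1000.0
    canal = counts[LABEL_CANAL] * vv / 1000.0
    cyst = counts[LABEL_CYST] * vv / 1000.0
    # total formed from the reported parts so the partition identity is
    # exact in floating point, not just in voxel counts
    return stroma + canal + cyst, stroma, canal, cyst


def compute_biometry(vol: LabelVolume, axis: UterineAxis) -> CervicalBiometry:
    """Run the full biometry panel on one scan.

    Sub-stage failures propagate as :class:`BiometryError` carrying the
    stage name.  Provenance (centerline point count, canal component size)
    is attached in ``meta``.
    """
    cl = extract_canal_centerline(vol, axis)
    try:
        lm = locate_os_landmarks(cl)
        l2, l3 = cervical_length(lm)
        d_int = os_diameter(vol, cl, "internal")
        d_ext = os_diameter(vol, cl, "external")
        uca = utero_cervical_angle(lm, axis)
    except BiometryError:
        raise
    except Exception as exc:  # pragma: no cover - defensive stage labelling
        raise BiometryError("landmarks/measurements", str(exc)) from exc
    total, stroma, canal, cyst = compartment_volumes(vol)

    _, comp_count = _largest_component(vol.mask(LABEL_CANAL, LABEL_CYST))
    return CervicalBiometry(
        length_2pt=l2,
        length_3pt=l3,
        internal_os_diameter=d_int,
        external_os_diameter=d_ext,
        utero_cervical_angle=uca,
        total_volume=total,
        stroma_volume=stroma,
        canal_volume=canal,
        cyst_volume=cyst,
        meta={
            "centerline_points": int(len(cl.points)),
            "centerline_arc_length_mm": cl.arc_length,
            "canal_component_voxels": comp_count,
            "axis_source": axis.source,
        },
    )
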