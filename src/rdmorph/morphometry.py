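"""Layer morphometry: perpendicular-calliper thickness, RD height, ONL/INL ratio.

Thickness of a layer band is measured the way an automated calliper plugin
does it: stations are laid out along the scleral-side (outer) boundary of the
band at a fixed calliper interval, the local tangent is estimated over a
seven-point window, and a ray is cast along the inward normal until it exits
the band.  The chord length is the thickness at that station.  Detachment
height is measured with a straight calliper from the RPE to the outer ONL
boundary, perpendicular to both layers within an angular tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point

from .errors import (
    EmptyMaskError,
    NoIntersectionError,
    TopologyError,
)

TANGENT_WINDOW = 7  # points used to estimate the local tangent
RAY_STEP_PX = 0.25  # sub-pixel marching step for normal rays


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BoundaryCurve:
    """An ordered open curve of (row, col) pixel coordinates with a scale."""

    points: np.ndarray  # (N, 2) float array of (row, col)
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("BoundaryCurve points must be an (N, 2) array")
        if len(self.points) < 2:
            raise ValueError("BoundaryCurve needs at least two points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            # collapse exact duplicates rather than erroring on annotation noise
            keep = np.concatenate([[True], seg > 0])
            self.points = self.points[keep]
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if len(self.points) < 2 or seg.sum() == 0:
            raise ValueError("BoundaryCurve has zero arc length")
        self._arc_px = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arc_um(self) -> np.ndarray:
        """Cumulative arc length at each point, in micrometres."""
        return self._arc_px * self.um_per_px

    @property
    def length_um(self) -> float:
        return float(self._arc_px[-1] * self.um_per_px)

    def point_at(self, arc_um: float) -> np.ndarray:
        """Interpolate the (row, col) position at an arc position in µm."""
        a = np.atleast_1d(arc_um) / self.um_per_px
        r = np.interp(a, self._arc_px, self.points[:, 0])
        c = np.interp(a, self._arc_px, self.points[:, 1])
        out = np.stack([r, c], axis=-1)
        return out[0] if np.isscalar(arc_um) else out

    def tangent_at(self, arc_um: float) -> np.ndarray:
        """Unit tangent at an arc position, from a 7-point window."""
        a_px = arc_um / self.um_per_px
        half = (TANGENT_WINDOW - 1) / 2
        step = max(np.median(np.diff(self._arc_px)), 1e-6)
        offs = (np.arange(TANGENT_WINDOW) - half) * step
        a = np.clip(a_px + offs, self._arc_px[0], self._arc_px[-1])
        pts = np.stack(
            [
                np.interp(a, self._arc_px, self.points[:, 0]),
                np.interp(a, self._arc_px, self.points[:, 1]),
            ],
            axis=-1,
        )
        # least-squares direction through the window
        d = pts - pts.mean(axis=0)
        t = np.linalg.lstsq(
            np.arange(TANGENT_WINDOW)[:, None] - half, d, rcond=None
        )[0][0]
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("degenerate tangent")
        return t / n

    def normal_at(self, arc_um: float, toward: np.ndarray | None = None) -> np.ndarray:
        """Unit normal at an arc position, optionally oriented toward a point."""
        t = self.tangent_at(arc_um)
        n = np.array([-t[1], t[0]])
        if toward is not None:
            v = np.asarray(toward, dtype=float) - self.point_at(arc_um)
            if np.dot(n, v) < 0:
                n = -n
        return n

    def to_linestring(self) -> LineString:
        # shapely works in (x, y) = (col, row)
        return LineString(self.points[:, ::-1])

    def mirrored(self, width_px: int) -> "BoundaryCurve":
        """The curve reflected left-right in an image of the given width."""
        pts = self.points[::-1].copy()
        pts[:, 1] = (width_px - 1) - pts[:, 1]
        return BoundaryCurve(pts, self.um_per_px)


@dataclass
class ThicknessProfile:
    """Per-station thickness of one layer along its outer boundary."""

    layer: str
    arc_um: np.ndarray            # strictly increasing station arc positions
    thickness_um: np.ndarray      # >= 0 at every station
    calliper_interval_px: float
    um_per_px: float = 1.0
    station_xy: np.ndarray | None = None  # (N, 2) station (row, col), optional
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.arc_um = np.asarray(self.arc_um, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if len(self.arc_um) and np.any(np.diff(self.arc_um) <= 0):
            raise ValueError("station arc positions must be strictly increasing")
        if np.any(self.thickness_um < 0):
            raise ValueError("thickness must be non-negative")

    def mean_um(self, interval: tuple[float, float] | None = None) -> float:
        sel = self.select(interval)
        if not len(sel):
            raise ValueError("no stations in the requested interval")
        return float(np.mean(sel))

    def select(self, interval: tuple[float, float] | None) -> np.ndarray:
        if interval is None:
            return self.thickness_um
        lo, hi = interval
        m = (self.arc_um >= lo) & (self.arc_um < hi)
        return self.thickness_um[m]


@dataclass
class HeightMeasurement:
    """One straight-calliper RPE-to-ONL distance."""

    arc_um: float
    height_um: float
    perpendicular: bool = True  # False when the nearest-distance fallback fired

    def __post_init__(self) -> None:
        if self.height_um < 0:
            raise ValueError("height must be non-negative")


# ---------------------------------------------------------------------------
# skeleton-path machinery
# ---------------------------------------------------------------------------


def _skeleton_path(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Ordered (row, col) pixel path along the band's skeleton.

    Returns (path, closed).  Raises TopologyError when the mask has no usable
    elongated skeleton (e.g. a blob or a disconnected speckle field).
    """
    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) < 8:
        raise TopologyError("mask skeleton too short; mask is not band-like")

    pix = {tuple(p) for p in map(tuple, coords)}
    g = nx.Graph()
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in pix:
                    g.add_edge((r, c), (r + dr, c + dc))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    endpoints = [n for n in g if g.degree(n) <= 1]

    if endpoints:
        # double-BFS diameter of the (tree-like) skeleton
        far = max(nx.single_source_shortest_path_length(g, endpoints[0]).items(),
                  key=lambda kv: kv[1])[0]
        lengths = nx.single_source_shortest_path_length(g, far)
        other = max(lengths.items(), key=lambda kv: kv[1])[0]
        path = nx.shortest_path(g, far, other)
        arr = np.array(path, dtype=float)
        # canonical direction: arc increases with column (ties: with row)
        if (arr[-1, 1], arr[-1, 0]) < (arr[0, 1], arr[0, 0]):
            arr = arr[::-1]
        return arr, False

    # cycle (closed band, e.g. an annulus): walk it
    start = next(iter(g))
    prev, cur = None, start
    path = [start]
    while True:
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs:
            break
        # prefer unvisited neighbours to make progress around the cycle
        nxt = None
        for n in nbrs:
            if n != start and n not in path[-3:]:
                nxt = n
                break
        if nxt is None:
            break
        prev, cur = cur, nxt
        if cur == start:
            break
        path.append(cur)
        if len(path) > g.number_of_nodes():
            break
    if len(path) < 8:
        raise TopologyError("could not order the band skeleton")
    return np.array(path, dtype=float), True


def _smooth_path(path: np.ndarray, closed: bool, window: int = 5) -> np.ndarray:
    if len(path) <= window:
        return path
    k = np.ones(window) / window
    if closed:
        pad = window // 2
        ext = np.vstack([path[-pad:], path, path[:pad]])
        sm = np.stack([np.convolve(ext[:, i], k, mode="valid") for i in (0, 1)], axis=1)
        return sm
    sm = path.astype(float).copy()
    for i in (0, 1):
        sm[:, i] = np.convolve(
            np.pad(path[:, i], window // 2, mode="edge"), k, mode="valid"
        )
    return sm


def _resample(points: np.ndarray, spacing: float, closed: bool) -> np.ndarray:
    if closed:
        points = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    points = points[keep]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= spacing:
        return points
    targets = np.arange(0.0, arc[-1], spacing)
    r = np.interp(targets, arc, points[:, 0])
    c = np.interp(targets, arc, points[:, 1])
    return np.stack([r, c], axis=1)


def _window_tangents(points: np.ndarray, closed: bool) -> np.ndarray:
    """Unit tangents from a centred 7-point linear fit at each point."""
    n = len(points)
    half = (TANGENT_WINDOW - 1) // 2
    idx = np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]
    if closed:
        idx = idx % n
    else:
        idx = np.clip(idx, 0, n - 1)
    w = points[idx]  # (n, 7, 2)
    x = np.arange(-half, half + 1, dtype=float)
    x = x - x.mean()
    denom = (x**2).sum()
    t = (w * x[None, :, None]).sum(axis=1) / denom
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _march_rays(
    maskf: np.ndarray,
    starts: np.ndarray,
    dirs: np.ndarray,
    max_len: float,
    inside_level: float = 0.5,
) -> np.ndarray:
    """Distance from each start along its direction to the 0.5 mask crossing.

    Starts are assumed inside the band; NaN when the ray exits the image or
    never crosses within max_len.
    """
    steps = np.arange(RAY_STEP_PX, max_len + RAY_STEP_PX, RAY_STEP_PX)
    pts = starts[:, None, :] + dirs[:, None, :] * steps[None, :, None]
    h, w = maskf.shape
    inb = (
        (pts[..., 0] >= 0) & (pts[..., 0] <= h - 1)
        & (pts[..., 1] >= 0) & (pts[..., 1] <= w - 1)
    )
    flat = pts.reshape(-1, 2)
    vals = np.full(flat.shape[0], -1.0)
    ok = inb.reshape(-1)
    vals[ok] = ndimage.map_coordinates(
        maskf, flat[ok].T, order=1, mode="constant", cval=-1.0
    )
    vals = vals.reshape(pts.shape[:2])
    below = vals < inside_level
    out = np.full(len(starts), np.nan)
    hit = below.any(axis=1)
    first = np.argmax(below, axis=1)
    for i in np.where(hit)[0]:
        j = first[i]
        if not inb[i, j]:
            continue  # exited the image before leaving the band: drop
        if j == 0:
            v0, d0 = 1.0, 0.0
        else:
            v0, d0 = vals[i, j - 1], steps[j - 1]
        v1, d1 = vals[i, j], steps[j]
        if v0 == v1:
            out[i] = d1
        else:
            out[i] = d0 + (v0 - inside_level) / (v0 - v1) * (d1 - d0)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def band_boundaries(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Trace the two long boundaries of a band mask.

    Returns (side_a, side_b, closed) where each side is an ordered (N, 2)
    sub-pixel polyline.  Ordering is shared between the sides (station i of
    one faces station i of the other).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("mask is empty")
    maskf = mask.astype(np.float32)

    path, closed = _skeleton_path(mask)
    edt = ndimage.distance_transform_edt(mask)
    halfw = float(np.median(edt[path[:, 0].astype(int), path[:, 1].astype(int)]))
    if not closed:
        trim = int(np.ceil(2 * halfw))
        if len(path) <= 2 * trim + TANGENT_WINDOW:
            raise TopologyError("band too short relative to its width")
        path = path[trim:-trim]
    path = _smooth_path(path, closed)
    path = _resample(path, 1.0, closed)
    tang = _window_tangents(path, closed=False if not closed else True)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    max_len = max(6.0 * halfw, 12.0)
    d_plus = _march_rays(maskf, path, normals, max_len)
    d_minus = _march_rays(maskf, path, -normals, max_len)
    ok = ~np.isnan(d_plus) & ~np.isnan(d_minus)
    if ok.sum() < max(8, 0.2 * len(path)):
        raise TopologyError("could not recover two boundaries from the mask")
    side_a = path[ok] + normals[ok] * d_plus[ok, None]
    side_b = path[ok] - normals[ok] * d_minus[ok, None]
    return side_a, side_b, closed


def thickness_profile(
    mask: np.ndarray,
    calliper_interval: float = 1.0,
    um_per_px: float = 1.0,
    layer: str = "layer",
    cast_from: str = "auto",
) -> ThicknessProfile:
    """Perpendicular-calliper thickness profile of a band mask.

    Stations are spaced ``calliper_interval`` pixels apart along the outer
    boundary.  ``cast_from`` selects the casting boundary: "auto" picks the
    side with the larger mean row (the scleral side when the RPE is at the
    bottom of the image), "low_y"/"high_y" force a side.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot profile an empty mask")
    maskf = mask.astype(np.float32)

    side_a, side_b, closed = band_boundaries(mask)
    mean_rows = (side_a[:, 0].mean(), side_b[:, 0].mean())
    if cast_from == "auto" or cast_from == "high_y":
        outer, inner = (side_a, side_b) if mean_rows[0] >= mean_rows[1] else (side_b, side_a)
    elif cast_from == "low_y":
        outer, inner = (side_a, side_b) if mean_rows[0] < mean_rows[1] else (side_b, side_a)
    else:
        raise ValueError(f"unknown cast_from: {cast_from!r}")

    stations = _resample(outer, calliper_interval, closed)
    tang = _window_tangents(stations, closed)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    # orient each normal toward the opposite boundary
    from scipy.spatial import cKDTree

    tree = cKDTree(inner)
    _, nearest = tree.query(stations)
    hint = inner[nearest] - stations
    flip = (normals * hint).sum(axis=1) < 0
    normals[flip] = -normals[flip]

    edt = ndimage.distance_transform_edt(mask)
    halfw = float(np.median(edt[mask])) if mask.any() else 1.0
    max_len = max(8.0 * halfw + 8.0, 16.0)
    # nudge starts just inside the band before marching outward
    starts = stations + normals * (2 * RAY_STEP_PX)
    d = _march_rays(maskf, starts, normals, max_len)
    inside = ndimage.map_coordinates(
        maskf, starts.T, order=1, mode="constant", cval=0.0
    ) >= 0.5
    d = np.where(inside, d + 2 * RAY_STEP_PX, np.nan)

    ok = ~np.isnan(d)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{layer}: dropped {n_dropped} station(s) with undefined chords",
            stacklevel=2,
        )
    if ok.sum() == 0:
        raise TopologyError("no valid calliper stations")

    seg = np.linalg.norm(np.diff(stations, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    arc_ok = arc[ok]
    # enforce strictly increasing stations (resampling guarantees this)
    return ThicknessProfile(
        layer=layer,
        arc_um=arc_ok * um_per_px,
        thickness_um=d[ok] * um_per_px,
        calliper_interval_px=calliper_interval,
        um_per_px=um_per_px,
        station_xy=stations[ok],
        n_dropped=n_dropped,
    )


def rd_height(
    rpe: BoundaryCurve,
    onl_outer: BoundaryCurve,
    station_um: float,
    angle_tolerance_deg: float = 10.0,
) -> HeightMeasurement:
    """Straight-calliper RPE-to-ONL distance at one RPE arc station.

    The calliper is cast from the RPE point along the average of the RPE
    normal and the normal of the nearest ONL point; when perpendicularity to
    both layers cannot be satisfied within the angular tolerance the nearest
    distance to the ONL curve is reported instead and flagged.
    """
    if not (0 <= station_um <= rpe.length_um):
        raise ValueError("station outside the RPE arc range")
    p = rpe.point_at(station_um)
    onl_line = onl_outer.to_linestring()
    pt = Point(p[1], p[0])
    foot_arc_um = onl_line.project(pt) * onl_outer.um_per_px
    foot = onl_outer.point_at(foot_arc_um)
    n1 = rpe.normal_at(station_um, toward=foot)
    span = max(rpe.length_um, onl_outer.length_um) / rpe.um_per_px * 2 + 10

    def cast(direction: np.ndarray):
        ray = LineString(
            [(p[1], p[0]),
             (p[1] + direction[1] * span, p[0] + direction[0] * span)]
        )
        inter = ray.intersection(onl_line)
        if inter.is_empty:
            return None
        if inter.geom_type == "Point":
            cands = [inter]
        else:
            cands = [g for g in getattr(inter, "geoms", []) if g.geom_type == "Point"]
        if not cands:
            return None
        return min(cands, key=lambda q: pt.distance(q))

    # fixed-point iteration: cast along the RPE normal, then re-average with
    # the ONL normal at the actual hit point
    n_avg = n1.copy()
    hit = None
    for _ in range(3):
        new_hit = cast(n_avg)
        if new_hit is None:
            break
        hit = new_hit
        hit_arc_um = onl_line.project(hit) * onl_outer.um_per_px
        n2 = onl_outer.normal_at(hit_arc_um, toward=p)  # points back toward RPE
        n_avg = n1 - n2
        nrm = np.linalg.norm(n_avg)
        n_avg = n1 if nrm == 0 else n_avg / nrm

    if hit is None:
        raise NoIntersectionError(
            f"calliper ray at arc {station_um:.1f} µm does not meet the ONL curve"
        )
    hit_rc = np.array([hit.y, hit.x])
    dist_um = float(np.linalg.norm(hit_rc - p)) * rpe.um_per_px

    # perpendicularity to both layers at the final geometry
    hit_arc_um = onl_line.project(hit) * onl_outer.um_per_px
    t1 = rpe.tangent_at(station_um)
    t2 = onl_outer.tangent_at(hit_arc_um)
    ang1 = np.degrees(np.arcsin(np.clip(abs(np.dot(n_avg, t1)), 0, 1)))
    ang2 = np.degrees(np.arcsin(np.clip(abs(np.dot(n_avg, t2)), 0, 1)))
    if ang1 <= angle_tolerance_deg and ang2 <= angle_tolerance_deg:
        return HeightMeasurement(station_um, dist_um, perpendicular=True)
    d_near = float(pt.distance(onl_line)) * rpe.um_per_px
    return HeightMeasurement(station_um, d_near, perpendicular=False)


def onl_inl_ratio(
    onl: ThicknessProfile,
    inl: ThicknessProfile,
    interval_um: tuple[float, float] | None = None,
) -> float:
    """Mean ONL thickness over mean INL thickness inside an arc interval.

    ``interval_um`` may come from a RegionOfInterest's arc interval; None uses
    every station of both profiles.
    """
    onl_vals = onl.select(interval_um)
    inl_vals = inl.select(interval_um)
    if not len(onl_vals) or not len(inl_vals):
        raise ValueError("profiles do not cover the requested interval")
    denom = float(np.mean(inl_vals))
    if denom == 0:
        raise ZeroDivisionError("INL mean thickness is zero")
    return float(np.mean(onl_vals)) / denom


def medial_axis_oracle_um(mask: np.ndarray, um_per_px: float = 1.0) -> float:
    """Independent thickness estimate: twice the maximum medial-axis radius.

    Suited to bands of (near-)uniform width, where the maximum inscribed
    disc diameter equals the band thickness; corner and end spurs of the
    medial axis cannot inflate it.  Used as a cross-check for the calliper
    profile, never as the measurement.
    """
    from skimage.morphology import medial_axis

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("mask is empty")
    axis, dist = medial_axis(mask, return_distance=True)
    vals = dist[axis]
    if not len(vals):
        raise TopologyError("no medial axis")
    return 2.0 * float(np.max(vals)) * um_per_px


def align_profile_arc(
    profile: ThicknessProfile, reference: BoundaryCurve
) -> ThicknessProfile:
    """Re-express a profile's stations in a reference curve's arc coordinate.

    Mask-traced profiles start their arc at the first valid station; ROI
    intervals live on the tile's ONL outer boundary.  Projecting each station
    onto the reference curve registers the two coordinate systems.  Stations
    that project non-monotonically (boundary jitter) are dropped.
    """
    if profile.station_xy is None:
        raise ValueError("profile carries no station coordinates")
    import shapely

    line = reference.to_linestring()
    pts = shapely.points(
        profile.station_xy[:, 1], profile.station_xy[:, 0]
    )
    arc = shapely.line_locate_point(line, pts) * reference.um_per_px
    order = np.argsort(arc, kind="stable")
    arc_s = arc[order]
    th_s = profile.thickness_um[order]
    xy_s = profile.station_xy[order]
    keep = np.concatenate([[True], np.diff(arc_s) > 1e-9])
    return ThicknessProfile(
        layer=profile.layer,
        arc_um=arc_s[keep],
        thickness_um=th_s[keep],
        calliper_interval_px=profile.calliper_interval_px,
        um_per_px=profile.um_per_px,
        station_xy=xy_s[keep],
        n_dropped=profile.n_dropped + int((~keep).sum()),
    )


def curve_from_labels(
    labels: np.ndarray,
    layer: int,
    side: str,
    um_per_px: float = 1.0,
    smooth: int = 5,
) -> BoundaryCurve:
    """Column-wise boundary trace of one label band.

    ``side="upper"`` follows the minimum-row edge of the band, ``"lower"`` the
    maximum-row edge.  Suitable for near-horizontal whole-eye tiles where each
    column crosses a band at most once.
    """
    m = np.asarray(labels) == layer
    if not m.any():
        raise EmptyMaskError(f"label {layer} not present")
    cols = np.where(m.any(axis=0))[0]
    rows = np.empty(len(cols), dtype=float)
    for i, c in enumerate(cols):
        r = np.where(m[:, c])[0]
        rows[i] = r.min() if side == "upper" else r.max()
    if smooth > 1 and len(rows) > smooth:
        k = np.ones(smooth) / smooth
        rows = np.convolve(np.pad(rows, smooth // 2, mode="edge"), k, mode="valid")
    pts = np.stack([rows, cols.astype(float)], axis=1)
    return BoundaryCurve(pts, um_per_px)
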