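"""RD-peak location and the four 400 µm regions of interest.

Regions are defined by arc length along the ONL relative to the detachment
peak: the detached apex abuts the peak on the peripheral (sclerotomy) side,
the detached base starts 500 µm peripheral of the peak, and the two attached
regions sit at the posterior-pole end of the attached arc, the central one
farthest from the detachment edge.  The irregular transition zone between
attached retina and detachment edge is excluded from every ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CropError, NoDetachmentError, ROIPlacementError
from .morphometry import BoundaryCurve, rd_height

ROI_NAMES = (
    "attached_central",
    "attached_paracentral",
    "detached_apex",
    "detached_base",
)

SEGMENT_UM = 400.0
BASE_OFFSET_UM = 500.0
TRANSITION_EXCLUSION_UM = 100.0


@dataclass
class RegionOfInterest:
    """One named 400 µm ONL segment: an arc interval plus a crop outline."""

    name: str
    arc_start_um: float
    arc_end_um: float
    polygon: np.ndarray | None = None  # (K, 2) of (row, col), optional

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name: {self.name!r}")
        if self.arc_end_um <= self.arc_start_um:
            raise ValueError("ROI arc interval is empty")

    @property
    def interval_um(self) -> tuple[float, float]:
        return (self.arc_start_um, self.arc_end_um)

    @property
    def length_um(self) -> float:
        return self.arc_end_um - self.arc_start_um


@dataclass
class PeakLocation:
    """The RD peak in both arc coordinate systems, plus the detached run."""

    rpe_arc_um: float
    onl_arc_um: float
    height_um: float
    detached_onl_interval_um: tuple[float, float]
    detached_rpe_interval_um: tuple[float, float]


def locate_rd_peak(
    rpe: BoundaryCurve,
    onl_outer: BoundaryCurve,
    attached_gap_um: float | None = None,
    threshold_factor: float = 3.0,
    coarse_step_um: float = 8.0,
    fine_step_um: float = 1.0,
) -> PeakLocation:
    """Arc position of the highest RPE-to-ONL calliper station.

    Stations are laid along the RPE arc; the detachment threshold is
    ``threshold_factor`` times the attached ONL-to-RPE gap (estimated as the
    10th percentile of station heights when not given).  On a plateau of
    maxima the plateau centroid is returned.  Raises NoDetachmentError for a
    fully attached specimen.
    """
    margin = coarse_step_um
    stations = np.arange(margin, rpe.length_um - margin, coarse_step_um)
    if len(stations) < 3:
        raise ValueError("RPE arc too short for peak search")
    heights = _heights_at(rpe, onl_outer, stations)

    gap = attached_gap_um if attached_gap_um is not None else float(
        np.nanpercentile(heights, 10)
    )
    thr = threshold_factor * gap
    above = heights > thr
    if not np.any(above):
        raise NoDetachmentError(
            f"no station exceeds {threshold_factor}x the attached gap "
            f"({gap:.2f} µm); specimen appears fully attached"
        )

    i_max = int(np.nanargmax(heights))
    # contiguous detached run containing the maximum
    lo = i_max
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < len(stations) - 1 and above[hi + 1]:
        hi += 1

    # refine across the full coarse plateau (plus one coarse step each side)
    h_coarse_max = np.nanmax(heights)
    plateau_c = np.where(heights >= h_coarse_max * (1 - 1e-9))[0]
    p_lo = plateau_c[plateau_c >= lo].min() if (plateau_c >= lo).any() else i_max
    p_hi = plateau_c[plateau_c <= hi].max() if (plateau_c <= hi).any() else i_max
    f_lo = max(stations[max(p_lo, 0)] - coarse_step_um, margin)
    f_hi = min(stations[min(p_hi, len(stations) - 1)] + coarse_step_um,
               rpe.length_um - margin)
    step = max(fine_step_um, (f_hi - f_lo) / 400.0)
    fine = np.arange(f_lo, f_hi + step, step)
    fh = _heights_at(rpe, onl_outer, fine)
    h_max = np.nanmax(fh)
    plateau = fh >= h_max * (1 - 1e-9)
    peak_rpe = float(np.mean(fine[plateau]))

    hm = rd_height(rpe, onl_outer, peak_rpe)
    from shapely.geometry import Point

    line = onl_outer.to_linestring()
    p = rpe.point_at(peak_rpe)
    n = rpe.normal_at(peak_rpe, toward=onl_outer.point_at(onl_outer.length_um / 2))
    apex_pt = p + n * hm.height_um / rpe.um_per_px
    peak_onl = float(line.project(Point(apex_pt[1], apex_pt[0]))) * onl_outer.um_per_px

    def onl_arc_of(rpe_arc: float) -> float:
        q = rpe.point_at(rpe_arc)
        return float(line.project(Point(q[1], q[0]))) * onl_outer.um_per_px

    det_rpe = (float(stations[lo]), float(stations[hi]))
    det_onl = (onl_arc_of(det_rpe[0]), onl_arc_of(det_rpe[1]))
    return PeakLocation(
        rpe_arc_um=peak_rpe,
        onl_arc_um=peak_onl,
        height_um=float(h_max),
        detached_onl_interval_um=(min(det_onl), max(det_onl)),
        detached_rpe_interval_um=det_rpe,
    )


def _heights_at(rpe, onl_outer, stations):
    out = np.full(len(stations), np.nan)
    for i, s in enumerate(stations):
        try:
            out[i] = rd_height(rpe, onl_outer, float(s)).height_um
        except Exception:
            continue
    return out


def define_rois(
    peak_onl_arc_um: float,
    attached_interval_um: tuple[float, float],
    detached_interval_um: tuple[float, float],
    peripheral: str = "high",
    segment_um: float = SEGMENT_UM,
    base_offset_um: float = BASE_OFFSET_UM,
) -> dict[str, RegionOfInterest]:
    """Place the four 400 µm ROIs relative to the RD peak.

    ``peripheral`` gives the direction of the sclerotomy along the ONL arc
    ("high" = increasing arc).  The apex segment's edge touches the peak on
    the peripheral side; the base segment's near edge lies ``base_offset_um``
    from the peak on the same side.  The attached central segment is anchored
    at the posterior-pole end of the attached arc with the paracentral one
    adjacent, toward the detachment.
    """
    if peripheral not in ("high", "low"):
        raise ValueError("peripheral must be 'high' or 'low'")
    peak = peak_onl_arc_um
    det_lo, det_hi = detached_interval_um
    att_lo, att_hi = attached_interval_um

    if peripheral == "high":
        apex = (peak, peak + segment_um)
        base = (peak + base_offset_um, peak + base_offset_um + segment_um)
    else:
        apex = (peak - segment_um, peak)
        base = (peak - base_offset_um - segment_um, peak - base_offset_um)

    problems = []
    for name, (lo, hi) in (("detached_apex", apex), ("detached_base", base)):
        if lo < det_lo - 1e-6 or hi > det_hi + 1e-6:
            problems.append(
                f"{name} [{lo:.0f}, {hi:.0f}) µm outside detached arc "
                f"[{det_lo:.0f}, {det_hi:.0f})"
            )

    # attached segments: central anchored at the end of the attached arc
    # farther from the detachment, paracentral adjacent toward it
    if att_hi <= det_lo:  # attached arc below the detachment
        central = (att_lo, att_lo + segment_um)
        para = (att_lo + segment_um, att_lo + 2 * segment_um)
    else:
        central = (att_hi - segment_um, att_hi)
        para = (att_hi - 2 * segment_um, att_hi - segment_um)
    for name, (lo, hi) in (("attached_central", central), ("attached_paracentral", para)):
        if lo < att_lo - 1e-6 or hi > att_hi + 1e-6:
            problems.append(
                f"{name} [{lo:.0f}, {hi:.0f}) µm outside attached arc "
                f"[{att_lo:.0f}, {att_hi:.0f})"
            )
    if problems:
        raise ROIPlacementError("; ".join(problems))

    return {
        "attached_central": RegionOfInterest("attached_central", *central),
        "attached_paracentral": RegionOfInterest("attached_paracentral", *para),
        "detached_apex": RegionOfInterest("detached_apex", *apex),
        "detached_base": RegionOfInterest("detached_base", *base),
    }


def roi_polygon(
    outer: BoundaryCurve,
    roi: RegionOfInterest,
    depth_um: float,
    away_from: BoundaryCurve | None = None,
    step_um: float = 4.0,
) -> RegionOfInterest:
    """Attach a crop outline to an ROI by offsetting the outer boundary.

    The polygon follows the outer boundary over the ROI's arc interval and a
    parallel curve ``depth_um`` along the band-inward normal.  ``away_from``
    (typically the RPE curve) orients the normals.
    """
    arcs = np.arange(roi.arc_start_um, roi.arc_end_um + step_um / 2, step_um)
    arcs = np.clip(arcs, 0, outer.length_um)
    pts = outer.point_at(arcs)
    normals = np.stack([outer.normal_at(float(a)) for a in arcs])
    if away_from is not None:
        line = away_from.to_linestring()
        from shapely.geometry import Point

        mid = pts[len(pts) // 2]
        foot = line.interpolate(line.project(Point(mid[1], mid[0])))
        hint = mid - np.array([foot.y, foot.x])
        s = np.sign((normals[len(pts) // 2] * hint).sum())
        if s < 0:
            normals = -normals
    else:
        # orient all normals consistently with the first
        flip = (normals * normals[0]).sum(axis=1) < 0
        normals[flip] = -normals[flip]
    inner = pts + normals * (depth_um / outer.um_per_px)
    poly = np.vstack([pts, inner[::-1]])
    return RegionOfInterest(roi.name, roi.arc_start_um, roi.arc_end_um, poly)


@dataclass
class SegmentCrop:
    """A cropped ROI: image patch, restricted masks, and the crop offset."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    offset_rc: tuple[int, int]
    roi: RegionOfInterest


def extract_segment(
    image: np.ndarray,
    roi: RegionOfInterest,
    masks: dict[str, np.ndarray] | None = None,
    pad_px: int = 2,
) -> SegmentCrop:
    """Minimal axis-aligned crop containing the ROI polygon.

    Masks are additionally restricted to the polygon so that downstream
    counting only sees the ROI's arc interval.  Raises CropError when the
    polygon leaves the image bounds.
    """
    if roi.polygon is None:
        raise ValueError("ROI has no polygon; call roi_polygon first")
    poly = np.asarray(roi.polygon, dtype=float)
    h, w = image.shape[:2]
    r0, c0 = np.floor(poly.min(axis=0)).astype(int)
    r1, c1 = np.ceil(poly.max(axis=0)).astype(int)
    if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
        raise CropError(
            f"ROI {roi.name} bbox [{r0}:{r1}, {c0}:{c1}] exceeds image {h}x{w}"
        )
    r0 = max(r0 - pad_px, 0)
    c0 = max(c0 - pad_px, 0)
    r1 = min(r1 + pad_px, h - 1)
    c1 = min(c1 + pad_px, w - 1)
    crop = image[r0 : r1 + 1, c0 : c1 + 1]

    out_masks: dict[str, np.ndarray] = {}
    if masks:
        from skimage.draw import polygon as draw_polygon

        sel = np.zeros(crop.shape[:2], dtype=bool)
        rr, cc = draw_polygon(poly[:, 0] - r0, poly[:, 1] - c0, shape=sel.shape)
        sel[rr, cc] = True
        for name, m in masks.items():
            out_masks[name] = m[r0 : r1 + 1, c0 : c1 + 1] & sel
    return SegmentCrop(crop, out_masks, (r0, c0), roi)


def points_in_roi(roi: RegionOfInterest, points_rc: np.ndarray) -> np.ndarray:
    """Boolean mask of which (row, col) points fall inside the ROI polygon."""
    if roi.polygon is None:
        raise ValueError("ROI has no polygon")
    from matplotlib.path import Path

    path = Path(roi.polygon[:, ::-1])  # (x, y)
    pts = np.asarray(points_rc, dtype=float)[:, ::-1]
    return path.contains_points(pts)
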