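"""Synthetic cryosection phantoms and longitudinal cohort tables.

The phantom emulates an axial whole-eye cryosection of a murine eye with a
bullous retinal detachment: a shallow circular RPE arc, an attached retina
whose ONL/INL bands ride at a small subretinal gap, and a detached portion
elevated as a smooth cosine bell roughly 1.1 mm high at its peak.  Layer
bands are built as parallel (normal-offset) curves of the deformed outer ONL
boundary, so perpendicular-calliper thickness equals the constructed value
everywhere, including the steep flanks of the bulge.  Nuclei are rendered as
2-D Gaussian blobs placed by dart-throwing with a hard-core separation that
a configurable fraction of candidates is allowed to relax (touching nuclei).
Everything placed is recorded as ground truth.

Cohort tables reproduce the statistical structure of the study's
cross-sectional design: per (region, day) cell a mean and SD for the ONL
cell count and the ONL/INL ratio, n animals per day, truncated-Gaussian
sampling.  The default design carries the published group means/SDs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import regions as _regions
from .errors import InvalidDesignError, InvalidSpecError

LABEL_BACKGROUND = 0
LABEL_RPE = 1
LABEL_ONL = 2
LABEL_INL = 3

DAYS = (0, 1, 7, 14)

_EDGE_MARGIN_UM = 100.0      # attached arc kept clear of the section edge
_STRETCH_RAMP_UM = (450.0, 500.0)  # ONL-arc distance from peak over which the
                                   # base stretch ramps in (apex zone is spared)


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of one synthetic cryosection tile.

    Lengths in µm unless suffixed _px; defaults follow the attached-central
    morphometry of the murine model (ONL 94.20 µm, ONL/INL 2.0, detachment
    1126.75 µm high, ~1250 ONL nuclei per 400 µm attached segment, detached
    base stretched to 0.81x).
    """

    image_shape: tuple[int, int] = (1480, 3960)  # (rows, cols) px
    um_per_px: float = 1.0
    attached_arc_um: float = 1400.0
    detached_arc_um: float = 2400.0     # RPE-arc footprint; 0 = fully attached
    rd_height_um: float = 1126.75       # RPE-to-ONL distance at the peak
    onl_um: float = 94.20
    inl_um: float = 47.10
    base_stretch: float = 0.81          # scales density and thickness at the base
    nucleus_radius_um: float = 2.0
    nucleus_radius_sd_um: float = 0.2
    onl_density_per_100um: float = 312.5  # nuclei per 100 µm of ONL arc
    background: float = 200.0
    noise_sd: float = 8.0
    overlap_fraction: float = 0.10
    # geometry / rendering details
    subretinal_gap_um: float = 20.0
    rpe_thickness_um: float = 10.0
    tail_arc_um: float = 100.0
    rpe_radius_um: float = 12000.0
    foreground: float = 6000.0

    def validate(self) -> None:
        pos = {
            "um_per_px": self.um_per_px,
            "attached_arc_um": self.attached_arc_um,
            "onl_um": self.onl_um,
            "inl_um": self.inl_um,
            "nucleus_radius_um": self.nucleus_radius_um,
            "onl_density_per_100um": self.onl_density_per_100um,
            "rpe_radius_um": self.rpe_radius_um,
        }
        for name, v in pos.items():
            if v <= 0:
                raise InvalidSpecError(f"{name} must be > 0 (got {v})")
        if self.rd_height_um < 0:
            raise InvalidSpecError("rd_height_um must be >= 0")
        if self.detached_arc_um < 0:
            raise InvalidSpecError("detached_arc_um must be >= 0")
        if not (0 < self.base_stretch <= 1):
            raise InvalidSpecError("base_stretch must be in (0, 1]")
        if not (0 <= self.overlap_fraction < 1):
            raise InvalidSpecError("overlap_fraction must be in [0, 1)")
        total = self.attached_arc_um + self.detached_arc_um + self.tail_arc_um
        half_angle = total / 2 / self.rpe_radius_um
        if half_angle >= np.pi / 2:
            raise InvalidSpecError("total arc exceeds the RPE hemicircle")
        width_um = (self.image_shape[1] - 40) * self.um_per_px
        if total > width_um / np.sinc(half_angle / np.pi):
            raise InvalidSpecError(
                f"total arc {total:.0f} µm does not fit the image width"
            )
        if self.detached_arc_um and self.rd_height_um:
            # the parallel-offset construction needs the bell's curvature
            # radius to exceed the total band depth
            elev = self.rd_height_um - self.subretinal_gap_um
            kappa = max(elev, 0) / 2 * (2 * np.pi / self.detached_arc_um) ** 2
            if kappa > 0 and 1 / kappa <= (self.onl_um + self.inl_um):
                raise InvalidSpecError(
                    "detachment too steep: band offsets would self-intersect"
                )

    @property
    def detached(self) -> bool:
        return self.detached_arc_um > 0 and self.rd_height_um > 0


def attached_only_spec(**overrides) -> PhantomSpec:
    """A compact fully-attached phantom, handy for counting experiments."""
    base = dict(
        image_shape=(280, 840),
        attached_arc_um=800.0,
        detached_arc_um=0.0,
        rd_height_um=0.0,
        tail_arc_um=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class GroundTruth:
    """Everything the generator placed, for downstream oracles."""

    region_counts: dict[str, int]
    region_onl_um: dict[str, float]
    region_inl_um: dict[str, float]
    region_intervals_um: dict[str, tuple[float, float]]
    peak_onl_arc_um: float | None     # None for a fully attached phantom
    peak_rpe_arc_um: float | None
    rd_height_um: float | None
    centroids_rc: np.ndarray          # (N, 2) ONL nucleus centroids, px
    centroid_arc_um: np.ndarray       # ONL-arc position of each centroid
    centroid_radius_um: np.ndarray
    total_onl_nuclei: int
    attached_onl_interval_um: tuple[float, float]
    detached_onl_interval_um: tuple[float, float] | None
    rpe_curve: np.ndarray             # (M, 2) upper-RPE boundary, px
    onl_outer_curve: np.ndarray       # (M, 2) outer ONL boundary, px
    onl_arc_um: np.ndarray            # arc positions of onl_outer_curve points

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in (self.centroids_rc, self.centroid_arc_um, self.onl_outer_curve):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(repr(sorted(self.region_counts.items())).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# tile generation
# ---------------------------------------------------------------------------


def _geometry(spec: PhantomSpec):
    """RPE arc, deformed ONL outer curve, per-point arc/stretch/thickness."""
    upp = spec.um_per_px
    R = spec.rpe_radius_um / upp
    total_um = spec.attached_arc_um + spec.detached_arc_um + spec.tail_arc_um
    S = total_um / upp                      # RPE arc length, px
    h_img, w_img = spec.image_shape
    theta_max = S / 2 / R
    cx = (w_img - 1) / 2
    sag = R * (1 - np.cos(theta_max))
    y_center = (h_img - 1) - 30 - sag       # row of the dome apex
    cy = y_center + R

    s = np.arange(0.0, S + 0.5, 0.5)        # RPE arc grid, px
    theta = s / R - theta_max
    radial = np.stack([-np.cos(theta), np.sin(theta)], axis=1)  # (row, col)
    rpe_pts = np.stack([cy, cx], axis=0)[None, :] + R * radial

    gap_px = spec.subretinal_gap_um / upp
    elev = np.zeros_like(s)
    if spec.detached:
        a0 = spec.attached_arc_um / upp
        Ld = spec.detached_arc_um / upp
        u = (s - a0) / Ld
        inside = (u >= 0) & (u <= 1)
        amp = (spec.rd_height_um - spec.subretinal_gap_um) / upp
        elev[inside] = amp / 2 * (1 - np.cos(2 * np.pi * u[inside]))
    g = gap_px + elev                       # radial RPE->ONL offset

    onl_outer = np.stack([cy, cx], axis=0)[None, :] + (R + g)[:, None] * radial
    seg = np.linalg.norm(np.diff(onl_outer, axis=0), axis=1)
    t_px = np.concatenate([[0.0], np.cumsum(seg)])
    t_um = t_px * upp

    # band-inward unit normals of the deformed outer curve
    tang = np.gradient(onl_outer, t_px, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    flip = (normal * radial).sum(axis=1) < 0
    normal[flip] = -normal[flip]

    # arc coordinates of the detachment along the ONL
    if spec.detached:
        a0 = spec.attached_arc_um / upp
        t_det_lo = float(np.interp(a0, s, t_um))
        t_det_hi = float(np.interp(a0 + spec.detached_arc_um / upp, s, t_um))
        s_peak = a0 + spec.detached_arc_um / upp / 2
        t_peak = float(np.interp(s_peak, s, t_um))
        det_interval = (t_det_lo, t_det_hi)
    else:
        t_peak, det_interval = None, None

    stretch = _stretch_profile(spec, t_um, t_peak, det_interval)
    T_onl = spec.onl_um / upp * stretch
    T_inl = spec.inl_um / upp * stretch
    return dict(
        cx=cx, cy=cy, R=R, theta_max=theta_max, s=s, rpe_pts=rpe_pts,
        onl_outer=onl_outer, t_px=t_px, t_um=t_um, normal=normal,
        stretch=stretch, T_onl=T_onl, T_inl=T_inl, t_peak=t_peak,
        det_interval=det_interval,
    )


def _stretch_profile(spec, t_um, t_peak, det_interval):
    """Mechanical-stretch multiplier along the ONL arc.

    1 everywhere except peripheral of the peak inside the detachment, where
    it ramps down to ``base_stretch`` beyond the apex zone — the detached
    base is stretched, the apex is spared.
    """
    sigma = np.ones_like(t_um)
    if not spec.detached or spec.base_stretch >= 1.0:
        return sigma
    lo, hi = _STRETCH_RAMP_UM
    d = t_um - t_peak                        # peripheral side: d > 0
    ramp = np.clip((d - lo) / (hi - lo), 0.0, 1.0)
    ramp = ramp * ramp * (3 - 2 * ramp)      # smoothstep
    in_det = (t_um >= det_interval[0]) & (t_um <= det_interval[1])
    sigma = 1.0 - (1.0 - spec.base_stretch) * np.where(in_det, ramp, 0.0)
    return sigma


def _label_mask(spec: PhantomSpec, geo) -> np.ndarray:
    h_img, w_img = spec.image_shape
    rows, cols = np.mgrid[0:h_img, 0:w_img].astype(np.float32)
    cy, cx, R = geo["cy"], geo["cx"], geo["R"]
    r_pix = np.hypot(rows - cy, cols - cx)
    theta_pix = np.arctan2(cols - cx, cy - rows)
    in_arc = np.abs(theta_pix) <= geo["theta_max"]

    labels = np.zeros(spec.image_shape, dtype=np.uint8)
    rpe_band = (r_pix >= R - spec.rpe_thickness_um / spec.um_per_px) & (r_pix < R)
    labels[rpe_band & in_arc] = LABEL_RPE

    # signed normal distance to the deformed ONL outer curve, via EDT
    curve = geo["onl_outer"]
    raster = np.zeros(spec.image_shape, dtype=bool)
    rr = np.clip(np.round(curve[:, 0]).astype(int), 0, h_img - 1)
    cc = np.clip(np.round(curve[:, 1]).astype(int), 0, w_img - 1)
    raster[rr, cc] = True
    idx_of = np.full(spec.image_shape, -1, dtype=np.int32)
    idx_of[rr, cc] = np.arange(len(curve), dtype=np.int32)
    _, (ir, ic) = ndimage.distance_transform_edt(~raster, return_indices=True)
    near = idx_of[ir, ic]

    end_margin = 8
    valid = (near >= end_margin) & (near < len(curve) - end_margin)
    qr = curve[near, 0]
    qc = curve[near, 1]
    nr = geo["normal"][near, 0]
    nc = geo["normal"][near, 1]
    signed = (rows - qr) * nr + (cols - qc) * nc
    T_onl = geo["T_onl"][near]
    T_inl = geo["T_inl"][near]
    onl = valid & (signed >= 0) & (signed < T_onl) & in_arc
    inl = valid & (signed >= T_onl) & (signed < T_onl + T_inl) & in_arc
    labels[onl & (labels == 0)] = LABEL_ONL
    labels[inl & (labels == 0)] = LABEL_INL
    return labels


def _place_nuclei(spec, geo, rng, layer: str):
    """Dart-throwing placement inside one band; returns arrays of placements."""
    upp = spec.um_per_px
    t_um = geo["t_um"]
    density = spec.onl_density_per_100um / 100.0  # per µm of ONL arc
    if layer == "inl":
        density *= spec.inl_um / spec.onl_um  # comparable areal packing
    lam = density * geo["stretch"]

    margin = 3.0 * upp
    usable = (t_um >= margin) & (t_um <= t_um[-1] - margin)
    lam_u = np.where(usable, lam, 0.0)
    cdf = np.concatenate([[0.0], np.cumsum((lam_u[1:] + lam_u[:-1]) / 2 * np.diff(t_um))])
    total = cdf[-1]
    n_target = rng.poisson(total)

    r_mean_px = spec.nucleus_radius_um / upp
    r_sd_px = spec.nucleus_radius_sd_um / upp
    cell = max(2 * (r_mean_px + 3 * r_sd_px) * 1.05, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    acc_rc: list[tuple[float, float]] = []
    acc_t: list[float] = []
    acc_r: list[float] = []

    T_band = geo["T_onl"] if layer == "onl" else geo["T_inl"]
    base_off = np.zeros_like(T_band) if layer == "onl" else geo["T_onl"]

    def neighbours(rr, cc):
        gi, gj = int(rr // cell), int(cc // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    yield k

    h_img, w_img = spec.image_shape
    for _ in range(n_target):
        radius = float(np.clip(
            rng.normal(r_mean_px, r_sd_px), 0.5 * r_mean_px, 1.5 * r_mean_px
        ))
        relax = rng.random() < spec.overlap_fraction
        factor = rng.uniform(0.6, 1.0) if relax else 1.02
        placed = False
        for _try in range(80):
            u = rng.random() * total
            tq = float(np.interp(u, cdf, t_um))
            i = int(np.searchsorted(t_um, tq))
            i = min(i, len(t_um) - 1)
            depth_lo = base_off[i] + radius + 0.5
            depth_hi = base_off[i] + T_band[i] - radius - 0.5
            if depth_hi <= depth_lo:
                depth = base_off[i] + T_band[i] / 2
            else:
                depth = rng.uniform(depth_lo, depth_hi)
            p = geo["onl_outer"][i] + geo["normal"][i] * depth
            if not (1 <= p[0] < h_img - 1 and 1 <= p[1] < w_img - 1):
                continue
            ok = True
            for k in neighbours(p[0], p[1]):
                qr, qc = acc_rc[k]
                dmin = factor * (radius + acc_r[k])
                if (p[0] - qr) ** 2 + (p[1] - qc) ** 2 < dmin * dmin:
                    ok = False
                    break
            if ok:
                idx = len(acc_rc)
                acc_rc.append((float(p[0]), float(p[1])))
                acc_t.append(float(t_um[i]))
                acc_r.append(radius)
                grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(idx)
                placed = True
                break
        if not placed:
            continue
    return (
        np.array(acc_rc, dtype=float).reshape(-1, 2),
        np.array(acc_t, dtype=float),
        np.array(acc_r, dtype=float),
    )


def _render(spec, rng, placements):
    h_img, w_img = spec.image_shape
    img = rng.normal(spec.background, spec.noise_sd, (h_img, w_img))
    for rc, radii in placements:
        for (r0, c0), radius in zip(rc, radii):
            amp = spec.foreground * float(
                np.clip(1 + 0.15 * rng.standard_normal(), 0.3, 2.0)
            )
            sigma = radius / 2
            half = int(np.ceil(3 * sigma)) + 1
            ra, rb = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
            ca, cb = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
            ra, ca = max(ra, 0), max(ca, 0)
            rb, cb = min(rb, h_img), min(cb, w_img)
            if rb <= ra or cb <= ca:
                continue
            yy = np.arange(ra, rb)[:, None] - r0
            xx = np.arange(ca, cb)[None, :] - c0
            img[ra:rb, ca:cb] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return np.clip(img, 0, 65535).astype(np.uint16)


def _ground_truth_regions(spec, geo):
    """ROI arc intervals from the true construction geometry."""
    t_end = float(geo["t_um"][-1])
    if spec.detached:
        att = (_EDGE_MARGIN_UM,
               geo["det_interval"][0] - _regions.TRANSITION_EXCLUSION_UM)
        rois = _regions.define_rois(
            geo["t_peak"], att, geo["det_interval"], peripheral="high"
        )
        return {name: r.interval_um for name, r in rois.items()}, att
    att = (_EDGE_MARGIN_UM, t_end - _EDGE_MARGIN_UM)
    out = {}
    if att[1] - att[0] >= _regions.SEGMENT_UM:
        out["attached_central"] = (att[0], att[0] + _regions.SEGMENT_UM)
    if att[1] - att[0] >= 2 * _regions.SEGMENT_UM:
        out["attached_paracentral"] = (
            att[0] + _regions.SEGMENT_UM, att[0] + 2 * _regions.SEGMENT_UM
        )
    return out, att


def generate_phantom_tile(spec: PhantomSpec, seed: int):
    """Build one phantom tile.

    Returns (image uint16, label mask uint8, GroundTruth).  Identical
    (spec, seed) pairs produce bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    geo = _geometry(spec)
    labels = _label_mask(spec, geo)

    onl_rc, onl_t, onl_r = _place_nuclei(spec, geo, rng, "onl")
    inl_rc, inl_t, inl_r = _place_nuclei(spec, geo, rng, "inl")
    image = _render(spec, rng, [(onl_rc, onl_r), (inl_rc, inl_r)])

    intervals, att_interval = _ground_truth_regions(spec, geo)
    counts, onl_th, inl_th = {}, {}, {}
    t_um = geo["t_um"]
    for name, (lo, hi) in intervals.items():
        sel = (onl_t >= lo) & (onl_t < hi)
        counts[name] = int(sel.sum())
        band = (t_um >= lo) & (t_um < hi)
        onl_th[name] = float(spec.onl_um * np.mean(geo["stretch"][band]))
        inl_th[name] = float(spec.inl_um * np.mean(geo["stretch"][band]))

    sub = slice(None, None, 2)  # thin the curves for storage
    s_px = geo["s"]
    if spec.detached:
        s_peak_px = (spec.attached_arc_um + spec.detached_arc_um / 2) / spec.um_per_px
        peak_rpe_um = float(s_peak_px * spec.um_per_px)
    else:
        peak_rpe_um = None
    gt = GroundTruth(
        region_counts=counts,
        region_onl_um=onl_th,
        region_inl_um=inl_th,
        region_intervals_um=intervals,
        peak_onl_arc_um=geo["t_peak"],
        peak_rpe_arc_um=peak_rpe_um,
        rd_height_um=spec.rd_height_um if spec.detached else None,
        centroids_rc=onl_rc,
        centroid_arc_um=onl_t,
        centroid_radius_um=onl_r * spec.um_per_px,
        total_onl_nuclei=len(onl_rc),
        attached_onl_interval_um=att_interval,
        detached_onl_interval_um=geo["det_interval"],
        rpe_curve=geo["rpe_pts"][sub].copy(),
        onl_outer_curve=geo["onl_outer"][sub].copy(),
        onl_arc_um=t_um[sub].copy(),
    )
    return image, labels, gt


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

REGIONS = _regions.ROI_NAMES


@dataclass
class CohortDesign:
    """Per (region, day) means/SDs for ONL count and ONL/INL ratio, plus n."""

    table: pd.DataFrame  # region, day, count_mean, count_sd, ratio_mean, ratio_sd, n

    REQUIRED = ("region", "day", "count_mean", "count_sd", "ratio_mean", "ratio_sd", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InvalidDesignError(f"design table missing columns: {missing}")
        t = self.table
        if (t["count_sd"] < 0).any() or (t["ratio_sd"] < 0).any():
            raise InvalidDesignError("SD must be >= 0")
        if (t["n"] < 2).any():
            raise InvalidDesignError("each cell needs n >= 2")
        for day, grp in t.groupby("day"):
            if grp["n"].nunique() != 1:
                raise InvalidDesignError(
                    f"day {day}: per-cell n must agree within a day "
                    "(each animal contributes every region)"
                )

    def cell(self, region: str, day: int) -> pd.Series:
        sel = self.table[(self.table.region == region) & (self.table.day == day)]
        if not len(sel):
            raise KeyError((region, day))
        return sel.iloc[0]

    @property
    def days(self) -> list[int]:
        return sorted(self.table.day.unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.table.region.unique())


# Published group means/SDs: ONL cell count and ONL/INL ratio per region/day.
# Attached regions showed no change over time, so their day-0 statistics are
# carried across later days.
_PUBLISHED_COUNTS = {
    "attached_central": {0: (1247.60, 64.62)},
    "attached_paracentral": {0: (1157.80, 163.33)},
    "detached_apex": {
        0: (1264.00, 150.71), 1: (984.40, 158.07),
        7: (785.80, 89.18), 14: (709.20, 108.30),
    },
    "detached_base": {
        0: (1013.80, 67.16), 1: (1017.60, 163.62),
        7: (1001.00, 27.93), 14: (954.00, 122.38),
    },
}
_PUBLISHED_RATIOS = {
    "attached_central": {0: (2.00, 0.17)},
    "attached_paracentral": {0: (1.92, 0.23)},
    "detached_apex": {
        0: (1.98, 0.16), 1: (1.36, 0.31), 7: (1.05, 0.20), 14: (1.08, 0.23),
    },
    "detached_base": {
        0: (1.85, 0.15), 1: (1.79, 0.23), 7: (1.66, 0.15), 14: (1.81, 0.24),
    },
}

# Baseline subgroup values used in worked examples (µm and dimensionless).
PUBLISHED_BASELINE_ONL_UM = {
    "attached_central": 94.20,
    "attached_paracentral": 85.43,
    "detached_apex": 88.99,
    "detached_base": 79.96,
}
PUBLISHED_RD_HEIGHT_UM = {"detached_apex": 1126.75, "detached_base": 1171.03}


def published_cohort_design(n: int = 6) -> CohortDesign:
    """The published cross-sectional design (n animals per day, default 6)."""
    rows = []
    for region in REGIONS:
        for day in DAYS:
            cm, cs = _PUBLISHED_COUNTS[region].get(day, _PUBLISHED_COUNTS[region][0])
            rm, rs = _PUBLISHED_RATIOS[region].get(day, _PUBLISHED_RATIOS[region][0])
            rows.append(dict(
                region=region, day=day, count_mean=cm, count_sd=cs,
                ratio_mean=rm, ratio_sd=rs, n=n,
            ))
    return CohortDesign(pd.DataFrame(rows))


def generate_cohort_table(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Draw one synthetic cohort: per cell, n truncated-Gaussian samples.

    Each animal is euthanised at a single day and contributes one tile with
    all four regions; columns: animal_id, day, region, onl_count,
    onl_inl_ratio.  Reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for day in design.days:
        n = int(design.cell(design.regions[0], day)["n"])
        for i in range(n):
            animal = f"d{int(day):02d}_a{i}"
            for region in design.regions:
                c = design.cell(region, day)
                count = _trunc_normal(rng, c.count_mean, c.count_sd)
                ratio = _trunc_normal(rng, c.ratio_mean, c.ratio_sd)
                rows.append(dict(
                    animal_id=animal, day=int(day), region=region,
                    onl_count=count, onl_inl_ratio=ratio,
                ))
    return pd.DataFrame(rows)


def _trunc_normal(rng, mean, sd, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0
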