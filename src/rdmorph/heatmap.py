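"""Relative ONL-thickness heatmap over a whole-retina tile.

Station thicknesses are divided by a reference — an explicit value in µm or
the median ONL thickness over the attached central region — and the ONL band
is painted by its nearest station's relative value through a perceptually
uniform colour ramp, clipped to a display window.  The display
is qualitative; the serialized map is lossless.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

from .errors import ZeroReferenceError
from .morphometry import ThicknessProfile
from .regions import RegionOfInterest

DEFAULT_CLIM = (0.4, 1.2)


@dataclass
class RelativeThicknessMap:
    """Per-station relative ONL thickness keyed by arc position."""

    arc_um: np.ndarray
    relative: np.ndarray
    reference_um: float
    cmap: str = "viridis"
    clim: tuple[float, float] = DEFAULT_CLIM

    def __post_init__(self) -> None:
        self.arc_um = np.asarray(self.arc_um, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)
        if self.reference_um <= 0:
            raise ZeroReferenceError("reference must be positive")
        if np.any(self.relative <= 0):
            raise ValueError("relative values must be positive")

    def to_csv(self, path) -> None:
        """Lossless serialization: full-precision decimal floats."""
        arr = np.stack([self.arc_um, self.relative], axis=1)
        header = (
            f"reference_um={self.reference_um!r},cmap={self.cmap},"
            f"clim={self.clim[0]!r}:{self.clim[1]!r}\narc_um,relative"
        )
        np.savetxt(path, arr, fmt="%.17g", delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path) -> "RelativeThicknessMap":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").strip()
        fields = dict(kv.split("=", 1) for kv in meta.split(","))
        lo, hi = fields["clim"].split(":")
        arr = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
        return cls(
            arc_um=arr[:, 0],
            relative=arr[:, 1],
            reference_um=float(fields["reference_um"]),
            cmap=fields["cmap"],
            clim=(float(lo), float(hi)),
        )


def resolve_reference(
    onl: ThicknessProfile,
    reference: float | str,
    attached_central: RegionOfInterest | tuple[float, float] | None = None,
) -> float:
    if isinstance(reference, (int, float)):
        ref = float(reference)
    elif reference == "attached-central-median":
        if attached_central is None:
            raise ValueError(
                "reference 'attached-central-median' needs the attached "
                "central ROI (or its arc interval)"
            )
        interval = (
            attached_central.interval_um
            if isinstance(attached_central, RegionOfInterest)
            else tuple(attached_central)
        )
        vals = onl.select(interval)
        if not len(vals):
            raise ValueError("profile has no stations in the attached central ROI")
        ref = float(np.median(vals))
    else:
        raise ValueError(f"unresolvable reference: {reference!r}")
    if ref == 0:
        raise ZeroReferenceError("reference thickness is zero")
    return ref


def relative_heatmap(
    tile: np.ndarray,
    onl: ThicknessProfile,
    reference: float | str = "attached-central-median",
    attached_central: RegionOfInterest | tuple[float, float] | None = None,
    onl_mask: np.ndarray | None = None,
    cmap: str = "viridis",
    clim: tuple[float, float] = DEFAULT_CLIM,
) -> tuple[RelativeThicknessMap, np.ndarray]:
    """Relative-thickness map plus a rendered RGB overlay.

    The overlay shows the tile in greyscale with ONL pixels coloured by the
    relative thickness of their nearest calliper station.  When no ONL mask
    is given the stations themselves are painted as a thick polyline.
    """
    if not len(onl.arc_um):
        raise ValueError("empty thickness profile")
    ref = resolve_reference(onl, reference, attached_central)
    rel = onl.thickness_um / ref
    m = RelativeThicknessMap(onl.arc_um.copy(), rel, ref, cmap, clim)

    overlay = _render_overlay(tile, onl, m, onl_mask)
    return m, overlay


def _render_overlay(tile, onl, m, onl_mask):
    import matplotlib

    ramp = matplotlib.colormaps[m.cmap]
    lo, hi = m.clim
    norm = np.clip((m.relative - lo) / max(hi - lo, 1e-12), 0, 1)
    colors = ramp(norm)[:, :3]

    g = tile.astype(float)
    span = np.ptp(g)
    g = (g - g.min()) / span if span else np.zeros_like(g)
    rgb = np.stack([g, g, g], axis=-1)

    if onl.station_xy is None:
        return (rgb * 255).astype(np.uint8)
    from scipy.spatial import cKDTree

    tree = cKDTree(onl.station_xy)
    if onl_mask is not None:
        pix = np.argwhere(onl_mask)
    else:
        # paint a 3-px disk around each station
        offs = np.array(
            [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        )
        pix = (
            onl.station_xy[:, None, :].round() + offs[None, :, :]
        ).reshape(-1, 2).astype(int)
        h, w = tile.shape[:2]
        pix = pix[(pix[:, 0] >= 0) & (pix[:, 0] < h) & (pix[:, 1] >= 0) & (pix[:, 1] < w)]
    _, idx = tree.query(pix)
    rgb[pix[:, 0], pix[:, 1]] = colors[idx]
    return (rgb * 255).astype(np.uint8)


def save_overlay_png(path, overlay: np.ndarray, m: RelativeThicknessMap) -> None:
    """Write the overlay with a colour bar for the clipped ramp."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    fig, ax = plt.subplots(figsize=(10, 10 * overlay.shape[0] / overlay.shape[1] + 1))
    ax.imshow(overlay)
    ax.set_axis_off()
    sm = ScalarMappable(
        norm=Normalize(*m.clim), cmap=matplotlib.colormaps[m.cmap]
    )
    fig.colorbar(sm, ax=ax, fraction=0.03, pad=0.02,
                 label="relative ONL thickness")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
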