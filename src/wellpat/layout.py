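"""Microwell-array geometry.

The physical substrate is a fused-silica chip carrying thousands of
cylindrical wells (default 80 um inner / 120 um outer diameter, 20 um
deep) hexagonally packed inside a rectangular footprint.  All positions
are expressed in micrometres with the origin at the top-left corner of
the footprint, x increasing rightward and y downward.  Pixel (i, j) of a
rendered raster covers the half-open square
``[j*s, (j+1)*s) x [i*s, (i+1)*s)`` where ``s`` is the pixel scale, so
the pixel centre sits at ``((j+0.5)*s, (i+0.5)*s)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyLayoutError, GeometryError

#: default pixel scale: 6.5 um sensor pitch of an Orca Flash 4.0 class
#: sCMOS divided by 4x magnification.
DEFAULT_PIXEL_SCALE_UM = 1.625

DEFAULT_INNER_RADIUS_UM = 40.0
DEFAULT_OUTER_RADIUS_UM = 60.0
DEFAULT_DEPTH_UM = 20.0
DEFAULT_PITCH_UM = 120.0
DEFAULT_FOOTPRINT_UM = (9000.0, 9000.0)
#: well count of the reference full-size array
DEFAULT_WELL_COUNT = 2980


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry of one microwell array.

    Attributes
    ----------
    well_centers : ndarray, shape (n, 2)
        Well centre positions ``(x_um, y_um)``.
    inner_radius_um, outer_radius_um : float
        Radii of the well opening and of the outer lip edge.
    depth_um : float
        Well depth; carried for provenance, rendering is 2-D.
    pitch_um : float
        Centre-to-centre spacing of the hexagonal lattice.
    footprint_um : tuple of float
        ``(width, height)`` of the array region.
    pixel_scale_um_per_px : float
        Physical size of one rendered pixel.
    """

    well_centers: np.ndarray
    inner_radius_um: float = DEFAULT_INNER_RADIUS_UM
    outer_radius_um: float = DEFAULT_OUTER_RADIUS_UM
    depth_um: float = DEFAULT_DEPTH_UM
    pitch_um: float = DEFAULT_PITCH_UM
    footprint_um: tuple[float, float] = DEFAULT_FOOTPRINT_UM
    pixel_scale_um_per_px: float = DEFAULT_PIXEL_SCALE_UM

    def __post_init__(self) -> None:
        centers = np.asarray(self.well_centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "well_centers", centers)
        if not 0 < self.inner_radius_um < self.outer_radius_um:
            raise GeometryError("need 0 < inner_radius < outer_radius")
        if self.outer_radius_um > self.pitch_um / 2 + 1e-9:
            raise GeometryError(
                f"outer radius {self.outer_radius_um} exceeds pitch/2 "
                f"({self.pitch_um / 2}); wells would overlap"
            )
        if self.pixel_scale_um_per_px <= 0:
            raise GeometryError("pixel scale must be positive")
        w, h = self.footprint_um
        if centers.size and (
            centers[:, 0].min() < -1e-6
            or centers[:, 1].min() < -1e-6
            or centers[:, 0].max() > w + 1e-6
            or centers[:, 1].max() > h + 1e-6
        ):
            raise GeometryError("well centers outside footprint")

    @property
    def n_wells(self) -> int:
        return len(self.well_centers)

    @property
    def shape_px(self) -> tuple[int, int]:
        """Raster dimensions (rows, cols) covering the footprint."""
        w, h = self.footprint_um
        s = self.pixel_scale_um_per_px
        return (math.ceil(h / s), math.ceil(w / s))

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """Continuous (row, col) pixel coordinates of physical points."""
        xy = np.asarray(xy_um, dtype=float)
        s = self.pixel_scale_um_per_px
        return np.stack([xy[..., 1] / s - 0.5, xy[..., 0] / s - 0.5], axis=-1)

    def px_to_um(self, rc_px: np.ndarray) -> np.ndarray:
        """Physical (x, y) of continuous (row, col) pixel coordinates."""
        rc = np.asarray(rc_px, dtype=float)
        s = self.pixel_scale_um_per_px
        return np.stack([(rc[..., 1] + 0.5) * s, (rc[..., 0] + 0.5) * s], axis=-1)


def hexagonal_lattice(
    footprint_um: tuple[float, float],
    pitch_um: float,
    margin_um: float,
) -> np.ndarray:
    """Row-major hexagonal lattice of points inside a rectangle.

    Rows are spaced ``pitch * sqrt(3)/2`` apart; odd rows are offset by
    ``pitch / 2``.  Points keep a clearance of ``margin_um`` from every
    footprint edge so the full outer well circle fits inside the image;
    an axis shorter than ``2 * margin_um`` degenerates to a single
    centred row/column.
    """
    w, h = footprint_um
    row_spacing = pitch_um * math.sqrt(3.0) / 2.0
    pts: list[tuple[float, float]] = []
    if h < 2 * margin_um:
        ys = [h / 2.0]
    else:
        n_rows = int(math.floor((h - 2 * margin_um) / row_spacing + 1e-9)) + 1
        ys = [margin_um + i * row_spacing for i in range(n_rows)]
    for row, y in enumerate(ys):
        offset = pitch_um / 2.0 if row % 2 else 0.0
        if w < 2 * margin_um:
            pts.append((w / 2.0, y))
            continue
        x = margin_um + offset
        while x <= w - margin_um + 1e-9:
            pts.append((x, y))
            x += pitch_um
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def build_layout(
    footprint_um: tuple[float, float] = DEFAULT_FOOTPRINT_UM,
    pitch_um: float = DEFAULT_PITCH_UM,
    inner_radius_um: float = DEFAULT_INNER_RADIUS_UM,
    outer_radius_um: float = DEFAULT_OUTER_RADIUS_UM,
    pixel_scale_um_per_px: float = DEFAULT_PIXEL_SCALE_UM,
    depth_um: float = DEFAULT_DEPTH_UM,
    target_well_count: int | None = None,
) -> ArrayLayout:
    """Build a hexagonally packed well layout clipped to a footprint.

    Parameters
    ----------
    target_well_count : int, optional
        Keep exactly this many wells, in row-major order from the top of
        the array.  The fabricated reference substrate holds 2980 wells
        in a 9 x 9 mm footprint, fewer than a dense hexagonal fill;
        truncation reproduces a definite count without inventing an
        unknown arrangement.

    Raises
    ------
    GeometryError
        If ``pitch < 2 * outer_radius`` (wells would overlap) or the
        target count exceeds the available lattice.
    EmptyLayoutError
        If the footprint cannot hold a single well.
    """
    if pitch_um < 2 * outer_radius_um:
        raise GeometryError(
            f"pitch {pitch_um} um smaller than well outer diameter "
            f"{2 * outer_radius_um} um"
        )
    if footprint_um[0] <= 0 or footprint_um[1] <= 0:
        raise GeometryError("footprint must be positive")

    # a well "fits" if at least its inner opening does; the outer lip may
    # touch the footprint edge in degenerate single-well layouts
    if (
        footprint_um[0] < 2 * inner_radius_um
        or footprint_um[1] < 2 * inner_radius_um
    ):
        raise EmptyLayoutError(
            f"footprint {footprint_um} um cannot hold one well of inner "
            f"diameter {2 * inner_radius_um} um"
        )
    centers = hexagonal_lattice(footprint_um, pitch_um, margin_um=outer_radius_um)
    if target_well_count is not None:
        if target_well_count < 1:
            raise GeometryError("target_well_count must be >= 1")
        if target_well_count > len(centers):
            raise GeometryError(
                f"target_well_count {target_well_count} exceeds the "
                f"{len(centers)}-point lattice fitting this footprint"
            )
        centers = centers[:target_well_count]
    return ArrayLayout(
        well_centers=centers,
        inner_radius_um=inner_radius_um,
        outer_radius_um=outer_radius_um,
        depth_um=depth_um,
        pitch_um=pitch_um,
        footprint_um=tuple(float(v) for v in footprint_um),
        pixel_scale_um_per_px=pixel_scale_um_per_px,
    )


def default_layout() -> ArrayLayout:
    """The reference 2980-well, 9 x 9 mm array."""
    return build_layout(target_well_count=DEFAULT_WELL_COUNT)
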