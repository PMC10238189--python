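"""Chip geometry: the logical nanowell layout and its projective mapping onto images.

A chip carries ``n_modules`` independent, identical modules.  Each module is a
row-major rectangular grid of nanowells; wells are enumerated
``index = row * grid_cols + col`` and only the first ``wells_per_module``
grid slots carry a well.  Layout-plane coordinates are micrometres with the
well at (row 0, col 0) centred on the origin.

Images are registered by a single 3x3 homography per module, fitted from the
four module corner points a user clicks in the image (TL, TR, BR, BL order).
Pixel coordinates are 0-based ``(x = column, y = row)`` and continuous
coordinates refer to pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from skimage.transform import ProjectiveTransform

from .errors import CapacityError, DegenerateGeometryError, DomainError

__all__ = [
    "ArrayLayout",
    "GeometryMap",
    "build_layout",
    "default_layout",
    "corner_anchors",
    "fit_projective_map",
    "well_centers",
    "layout_to_yaml",
    "layout_from_yaml",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Logical geometry of one chip.

    The default chip holds 4 modules x 10 040 wells of 1 nL arranged as a
    40 x 251 grid (an exact factorization, so no partial rows).
    """

    n_modules: int
    wells_per_module: int
    grid_rows: int
    grid_cols: int
    well_pitch_um: float
    well_diameter_um: float
    well_volume_nl: float = 1.0

    @property
    def total_wells(self) -> int:
        return self.n_modules * self.wells_per_module

    def well_identities(self) -> np.ndarray:
        """(wells_per_module, 3) int array of (index, row, col), row-major."""
        idx = np.arange(self.wells_per_module)
        rows = idx // self.grid_cols
        cols = idx % self.grid_cols
        return np.stack([idx, rows, cols], axis=1)

    def well_centers_layout(self) -> np.ndarray:
        """(wells_per_module, 2) layout-plane (x, y) centers in um."""
        ident = self.well_identities()
        x = ident[:, 2] * self.well_pitch_um
        y = ident[:, 1] * self.well_pitch_um
        return np.stack([x, y], axis=1).astype(float)


def build_layout(
    n_modules: int = 4,
    wells_per_module: int = 10_040,
    grid_rows: int = 40,
    grid_cols: int = 251,
    well_pitch_um: float = 120.0,
    well_diameter_um: float = 90.0,
    well_volume_nl: float = 1.0,
) -> ArrayLayout:
    """Validate and construct an :class:`ArrayLayout`.

    Raises
    ------
    DomainError
        Non-positive counts or dimensions, or pitch <= diameter.
    CapacityError
        ``grid_rows * grid_cols < wells_per_module``.
    """
    for name, v in [
        ("n_modules", n_modules),
        ("wells_per_module", wells_per_module),
        ("grid_rows", grid_rows),
        ("grid_cols", grid_cols),
    ]:
        if int(v) != v or v < 1:
            raise DomainError(f"{name} must be a positive integer, got {v!r}")
    if well_volume_nl <= 0:
        raise DomainError("well_volume_nl must be > 0")
    if not (well_pitch_um > well_diameter_um > 0):
        raise DomainError("need well_pitch_um > well_diameter_um > 0")
    if grid_rows * grid_cols < wells_per_module:
        raise CapacityError(
            f"grid {grid_rows}x{grid_cols} holds {grid_rows * grid_cols} slots "
            f"< wells_per_module={wells_per_module}"
        )
    return ArrayLayout(
        int(n_modules),
        int(wells_per_module),
        int(grid_rows),
        int(grid_cols),
        float(well_pitch_um),
        float(well_diameter_um),
        float(well_volume_nl),
    )


def default_layout() -> ArrayLayout:
    """The production chip: 4 modules, 10 040 wells each, 1 nL wells."""
    return build_layout()


def corner_anchors(layout: ArrayLayout) -> np.ndarray:
    """Layout-plane module corner anchors (TL, TR, BR, BL), shape (4, 2), um.

    The anchors are the grid bounding box expanded by half a pitch, i.e. the
    outline of the module frame a user would click in an image.
    """
    half = layout.well_pitch_um / 2.0
    xmax = (layout.grid_cols - 1) * layout.well_pitch_um + half
    ymax = (layout.grid_rows - 1) * layout.well_pitch_um + half
    return np.array(
        [[-half, -half], [xmax, -half], [xmax, ymax], [-half, ymax]], dtype=float
    )


@dataclass(frozen=True)
class GeometryMap:
    """Projective transform from layout-plane um to image pixel coordinates."""

    homography: np.ndarray  # 3x3, maps (x_um, y_um, 1) -> pixel homogeneous
    module_id: int = 0

    def __post_init__(self):
        H = np.asarray(self.homography, dtype=float)
        if H.shape != (3, 3):
            raise DomainError("homography must be 3x3")
        if abs(np.linalg.det(H)) < 1e-12 * max(1.0, np.abs(H).max() ** 3):
            raise DegenerateGeometryError("homography is singular")
        object.__setattr__(self, "homography", H)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map (N, 2) layout points to (N, 2) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
        out = hom @ self.homography.T
        return out[:, :2] / out[:, 2:3]


def _collinear(p: np.ndarray, q: np.ndarray, r: np.ndarray, scale: float) -> bool:
    area2 = abs((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))
    return area2 <= 1e-9 * scale**2


def fit_projective_map(
    corner_points_px: np.ndarray, layout: ArrayLayout, module_id: int = 0
) -> GeometryMap:
    """Fit the module homography from four clicked corner pixels (TL, TR, BR, BL).

    Four point correspondences determine a projective transform exactly (up to
    scale); the fit is the direct linear transform as implemented by
    :class:`skimage.transform.ProjectiveTransform`.

    Raises
    ------
    DegenerateGeometryError
        If any three of the four points are collinear (includes duplicates).
    """
    dst = np.asarray(corner_points_px, dtype=float)
    if dst.shape != (4, 2):
        raise DomainError("corner_points_px must have shape (4, 2)")
    scale = float(np.ptp(dst, axis=0).max())
    if scale == 0.0:
        raise DegenerateGeometryError("corner points are all identical")
    for i in range(4):
        others = [j for j in range(4) if j != i]
        if _collinear(dst[others[0]], dst[others[1]], dst[others[2]], scale):
            raise DegenerateGeometryError("three corner points are collinear")
    src = corner_anchors(layout)
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise DegenerateGeometryError("projective fit failed for these corners")
    gmap = GeometryMap(tf.params, module_id=module_id)
    resid = np.abs(gmap.apply(src) - dst).max()
    if resid > 1e-6:
        raise DegenerateGeometryError(
            f"fitted map misses a corner by {resid:.3g} px (> 1e-6)"
        )
    return gmap


def well_centers(gmap: GeometryMap, layout: ArrayLayout) -> np.ndarray:
    """Pixel-space (x, y) centers of one module's wells, build order.

    Ordering is identical to :meth:`ArrayLayout.well_identities`.
    """
    return gmap.apply(layout.well_centers_layout())


def layout_to_yaml(layout: ArrayLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(layout), fh, sort_keys=False)


def layout_from_yaml(path) -> ArrayLayout:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return build_layout(**data)
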