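"""Read chip images and extract per-well mean fluorescence via the known mask.

The mask is the logical well layout placed on the image by a module's
:class:`~digiwell.layout.GeometryMap`.  Each well's intensity is the
arithmetic mean of the pixels whose centers lie within a circular aperture
around the mapped well center (pixel-center-in-disk test, no partial-pixel
weighting, so the result is deterministic and exactly translation-equivariant
for integer shifts).  No background subtraction is done here — the constant
background is absorbed by the negative population of the mixture model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import tifffile

from .errors import DomainError, EmptyApertureError, FormatError, OutOfFrameError
from .layout import ArrayLayout, GeometryMap, well_centers

__all__ = [
    "read_chip_image",
    "write_chip_image",
    "default_aperture_radius",
    "extract_well_intensities",
]


def write_chip_image(path, image: np.ndarray, channels) -> None:
    """Write a (channels, H, W) stack as a multi-page 16-bit grayscale TIFF.

    The channel name is recorded in each page's description tag.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise DomainError("image must be (channels, H, W)")
    channels = list(channels)
    if len(channels) != image.shape[0]:
        raise DomainError("one channel name per plane required")
    with tifffile.TiffWriter(path) as tif:
        for plane, name in zip(image, channels):
            tif.write(plane.astype(np.uint16), description=name,
                      photometric="minisblack")


def read_chip_image(path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-page grayscale TIFF into a (channels, H, W) stack.

    Channel names come from the per-page description tag; pages without one
    are named ``ch<i>`` with a warning.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            planes, names = [], []
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                if arr.ndim != 2:
                    raise FormatError(f"page {i} is not grayscale (shape {arr.shape})")
                planes.append(arr)
                desc = (page.description or "").strip()
                if desc.startswith("{"):  # tifffile's own shape metadata
                    desc = ""
                if desc:
                    names.append(desc.splitlines()[0])
                else:
                    warnings.warn(f"page {i} has no channel metadata; using ch{i}")
                    names.append(f"ch{i}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable / not a TIFF
        raise FormatError(f"cannot read chip image {path!r}: {exc}") from exc
    if not planes:
        raise FormatError(f"{path!r} contains no image pages")
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise FormatError(f"pages have mismatched dimensions: {sorted(shapes)}")
    return np.stack(planes), names


def default_aperture_radius(layout: ArrayLayout, gmap: GeometryMap) -> float:
    """Default aperture: 0.35 x well pitch, expressed in pixels.

    Stays inside the well at moderate registration error.
    """
    c = layout.well_centers_layout().mean(axis=0)
    p = gmap.apply(np.array([c, c + [0.35 * layout.well_pitch_um, 0.0]]))
    return float(np.hypot(*(p[1] - p[0])))


def extract_well_intensities(
    image: np.ndarray,
    gmap: GeometryMap,
    layout: ArrayLayout,
    aperture_radius_px: float | None = None,
    channels=None,
) -> pd.DataFrame:
    """Per-well, per-channel mean fluorescence of one module.

    Parameters
    ----------
    image
        (channels, H, W) array or a single (H, W) plane.
    aperture_radius_px
        Radius of the circular averaging aperture in pixels; default
        0.35 x pitch at the map's local scale.
    channels
        Channel names for the output columns (default ``ch<i>``).

    Returns a DataFrame with columns module, well_index, row, col, x_px,
    y_px, aperture_pixels and one mean-intensity column per channel, in
    layout enumeration order.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise DomainError("image must be 2-D or (channels, H, W)")
    n_chan, height, width = image.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_chan)]
    channels = list(channels)
    if len(channels) != n_chan:
        raise DomainError("number of channel names must match image planes")
    if aperture_radius_px is None:
        aperture_radius_px = default_aperture_radius(layout, gmap)
    r = float(aperture_radius_px)
    if r <= 0:
        raise DomainError("aperture_radius_px must be > 0")

    centers = well_centers(gmap, layout)
    x, y = centers[:, 0], centers[:, 1]
    out_of_frame = np.flatnonzero(
        (x - r < -0.5) | (y - r < -0.5) | (x + r > width - 0.5) | (y + r > height - 0.5)
    )
    if out_of_frame.size:
        raise OutOfFrameError(out_of_frame, "aperture clipped by the image edge")

    # Candidate pixel grid per well: integer offsets around the floored center.
    r_int = int(np.ceil(r)) + 1
    offs = np.arange(-r_int, r_int + 1)
    base_x = np.floor(x).astype(np.int64)
    base_y = np.floor(y).astype(np.int64)
    px = base_x[:, None] + offs[None, :]  # (wells, K) candidate columns
    py = base_y[:, None] + offs[None, :]  # (wells, K) candidate rows
    dx = px - x[:, None]
    dy = py - y[:, None]
    # (wells, K, K) pixel-center-in-disk mask; rows index y, cols index x
    mask = (dy[:, :, None] ** 2 + dx[:, None, :] ** 2) <= r * r
    counts = mask.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise EmptyApertureError(
            f"aperture radius {r} px contains no pixel centers for some wells"
        )
    pxc = np.clip(px, 0, width - 1)
    pyc = np.clip(py, 0, height - 1)
    flat = pyc[:, :, None] * width + pxc[:, None, :]  # (wells, K, K)

    ident = layout.well_identities()
    data = {
        "module": np.full(layout.wells_per_module, gmap.module_id),
        "well_index": ident[:, 0],
        "row": ident[:, 1],
        "col": ident[:, 2],
        "x_px": x,
        "y_px": y,
        "aperture_pixels": counts,
    }
    for c, name in enumerate(channels):
        vals = image[c].ravel()[flat]
        data[name] = (vals * mask).sum(axis=(1, 2)) / counts
    return pd.DataFrame(data)
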