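"""B-scan and PED-segmentation input/output.

Conventions shared by every module in the package:

* images are 2-D arrays indexed ``(row, col)``, 0-based, with row 0 on the
  vitreous side (top of the scan);
* polygon vertices are stored ``(row, col)`` in pixel units, the polygon is
  implicitly closed (last vertex connects to the first);
* a pixel belongs to a rasterized polygon iff its center lies inside or on
  the boundary (boundary ties count as inside).

ImageJ ``.roi`` files store vertices as ``(x, y) = (col, row)``; the reader
swaps them into the internal convention.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from scipy import ndimage
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon as ShapelyPolygon, box as shapely_box

__all__ = [
    "BScan",
    "PedPolygon",
    "PedMask",
    "read_bscan",
    "read_polygon",
    "write_polygon",
    "smooth_polygon",
    "rasterize",
]

DEFAULT_SCALES_UM = (4.0, 7.0)  # (axial, transverse) um per pixel


@dataclass
class BScan:
    """A single OCT B-scan: a 2-D intensity grid plus physical pixel scales."""

    pixels: np.ndarray
    axial_scale_um: float = DEFAULT_SCALES_UM[0]
    transverse_scale_um: float = DEFAULT_SCALES_UM[1]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BScan.pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("BScan.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("BScan.pixels must be non-negative")
        if self.axial_scale_um <= 0 or self.transverse_scale_um <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PedPolygon:
    """Closed polygon outlining a PED, vertices as (row, col) pixel coords."""

    vertices: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")

    def to_shapely(self) -> ShapelyPolygon:
        # shapely works in (x, y) = (col, row)
        return ShapelyPolygon([(c, r) for r, c in self.vertices])


@dataclass
class PedMask:
    """Boolean analysis domain: True inside the PED."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no interior pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


def read_bscan(
    path: str | Path,
    scales: tuple[float, float] | None = None,
    source_id: str | None = None,
) -> BScan:
    """Read a grayscale raster export (PNG/TIFF) into a :class:`BScan`.

    Color images are reduced to luminance; 16-bit values are preserved as
    stored (later normalization maps the image range to [0, 1]).
    ``scales`` is (axial, transverse) um per pixel, defaulting to (4, 7).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
                im = im.convert("L")
            arr = np.asarray(im)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:  # residual channel axis
        arr = arr.mean(axis=2)
    if arr.size == 0:
        raise ValueError(f"image file {path} is empty")
    ax, tr = scales if scales is not None else DEFAULT_SCALES_UM
    return BScan(
        pixels=arr.astype(np.float64),
        axial_scale_um=ax,
        transverse_scale_um=tr,
        source_id=source_id if source_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Polygon dialects: CSV (row,col per line), JSON, ImageJ .roi
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 227
_ROI_TYPE_POLYGON = 0
_ROI_HEADER_SIZE = 64


def _read_imagej_roi(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < _ROI_HEADER_SIZE or data[:4] != _ROI_MAGIC:
        raise ValueError(f"{path} is not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type != _ROI_TYPE_POLYGON:
        raise ValueError(f"{path}: ROI type {roi_type} is not a polygon")
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">h", data[16:18])
    if n < 3:
        raise ValueError(f"{path}: polygon ROI has {n} < 3 vertices")
    coords = struct.unpack(f">{2 * n}h", data[_ROI_HEADER_SIZE : _ROI_HEADER_SIZE + 4 * n])
    xs = np.asarray(coords[:n]) + left
    ys = np.asarray(coords[n:]) + top
    return np.column_stack([ys, xs]).astype(float)  # (row, col)


def _write_imagej_roi(path: Path, vertices: np.ndarray) -> None:
    vr = np.rint(vertices).astype(int)
    ys, xs = vr[:, 0], vr[:, 1]
    top, left = int(ys.min()), int(xs.min())
    header = bytearray(_ROI_HEADER_SIZE)
    header[:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = _ROI_TYPE_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, int(ys.max()), int(xs.max()))
    struct.pack_into(">h", header, 16, len(vr))
    body = struct.pack(f">{len(vr)}h", *(xs - left)) + struct.pack(f">{len(vr)}h", *(ys - top))
    path.write_bytes(bytes(header) + body)


def read_polygon(path: str | Path, dialect: str | None = None) -> PedPolygon:
    """Read a closed PED polygon.

    Dialects: ``"csv"`` (one ``row,col`` pair per line), ``"json"``
    (``{"vertices": [[r, c], ...]}``), ``"imagej-roi"`` (binary .roi,
    polygon type; (x, y) swapped to (row, col)).  Inferred from the file
    suffix when not given.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".json": "json", ".roi": "imagej-roi"}.get(path.suffix.lower())
        if dialect is None:
            raise ValueError(f"cannot infer polygon dialect from suffix of {path}")
    if dialect == "csv":
        rows = []
        for line in path.read_text().strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r, c = line.split(",")[:2]
            rows.append((float(r), float(c)))
        verts = np.asarray(rows, dtype=float)
    elif dialect == "json":
        data = json.loads(path.read_text())
        verts = np.asarray(data["vertices"], dtype=float)
    elif dialect == "imagej-roi":
        verts = _read_imagej_roi(path)
    else:
        raise ValueError(f"unknown polygon dialect {dialect!r}")
    if verts.ndim != 2 or len(verts) < 3:
        raise ValueError(f"{path}: a polygon needs >= 3 vertices, got {len(verts)}")
    return PedPolygon(vertices=verts)


def write_polygon(poly: PedPolygon, path: str | Path, dialect: str | None = None) -> None:
    """Write a polygon in the given dialect (inferred from suffix if absent).

    CSV and JSON round-trip vertices exactly; .roi rounds to integer pixels.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".json": "json", ".roi": "imagej-roi"}.get(path.suffix.lower())
        if dialect is None:
            raise ValueError(f"cannot infer polygon dialect from suffix of {path}")
    if dialect == "csv":
        path.write_text("".join(f"{float(r)!r},{float(c)!r}\n" for r, c in poly.vertices))
    elif dialect == "json":
        path.write_text(json.dumps({"vertices": poly.vertices.tolist()}))
    elif dialect == "imagej-roi":
        _write_imagej_roi(path, poly.vertices)
    else:
        raise ValueError(f"unknown polygon dialect {dialect!r}")


def smooth_polygon(poly: PedPolygon, samples_per_edge: int = 4) -> PedPolygon:
    """Smooth a polygon with a closed periodic interpolating cubic spline.

    The spline passes through every input vertex; each original edge is
    resampled at ``samples_per_edge`` points, so ``samples_per_edge=1``
    returns the input vertices unchanged.  If the smoothed outline
    self-intersects, a warning is issued and the input polygon is returned.
    """
    if len(poly.vertices) < 4:
        raise ValueError("spline smoothing needs >= 4 vertices")
    if samples_per_edge < 1:
        raise ValueError("samples_per_edge must be >= 1")
    n = len(poly.vertices)
    closed = np.vstack([poly.vertices, poly.vertices[:1]])
    t = np.arange(n + 1, dtype=float)
    spline = CubicSpline(t, closed, bc_type="periodic")
    ts = np.arange(n * samples_per_edge, dtype=float) / samples_per_edge
    smoothed = PedPolygon(vertices=spline(ts), smoothed=True)
    if not smoothed.to_shapely().exterior.is_simple:
        warnings.warn("spline smoothing produced a self-intersecting outline; keeping original")
        return poly
    return smoothed


def rasterize(poly: PedPolygon, shape: tuple[int, int]) -> PedMask:
    """Rasterize a closed polygon onto an image grid.

    Pixel (r, c) is inside iff its center (r, c) lies inside or on the
    polygon boundary.  Polygons reaching outside the grid are clipped with
    a warning; an empty interior raises.
    """
    rows, cols = shape
    geom = poly.to_shapely()
    if not geom.is_valid:
        geom = geom.buffer(0)
    frame = shapely_box(-0.5, -0.5, cols - 0.5, rows - 0.5)
    if not frame.covers(geom):
        warnings.warn("polygon extends outside the image; clipping to bounds")
        geom = geom.intersection(frame)
    if geom.is_empty or geom.area == 0 and geom.length == 0:
        raise ValueError("polygon rasterizes to an empty mask")

    minx, miny, maxx, maxy = geom.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(cols - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(rows - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        raise ValueError("polygon rasterizes to an empty mask")
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
    inside = shapely.covers(geom, pts).reshape(rr.shape)

    mask = np.zeros(shape, dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        raise ValueError("polygon rasterizes to an empty mask")
    _, n_comp = ndimage.label(mask)  # 4-connectivity by default
    if n_comp > 1:
        warnings.warn(f"rasterized mask has {n_comp} connected components; expected 1")
    return PedMask(mask=mask)
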