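"""Localization tables, nucleus ROIs and rendering for single-molecule
localization microscopy (SMLM/STORM) data.

A localization table is a tidy :class:`pandas.DataFrame` with one row per
single-molecule emission and canonical columns

``nucleus_id`` (str), ``channel`` (str), ``x`` (nm), ``y`` (nm),
``frame`` (int, optional acquisition index).

Coordinates are continuous nanometres with the origin at the lower-left of
the field; rendering uses half-open pixel bins ``[k*p, (k+1)*p)``.  A
nucleus ROI is either a binary raster mask (with a pixel size in nm) or a
closed polygon in nm; localizations exactly on the boundary count as inside
(the mask value at the floor pixel decides; polygon boundaries are
inclusive).  Rendering is provided for visualization and QC — the
colocalization statistic itself operates on continuous coordinates (see
:mod:`dsbquant.coloc`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.ops
from shapely.geometry import Polygon, shape as _geojson_shape

from .errors import EmptyROIError, FormatError, GeometryError, PlacementError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("nucleus_id", "channel", "x", "y", "frame")


@dataclasses.dataclass(frozen=True)
class CsvDialect:
    """Column mapping for localization CSV files.

    Defaults match ThunderSTORM-style headers (``"x [nm]"``, ``"y [nm]"``,
    ``"frame"``).  When ``pixel_size_nm`` is set, the x/y columns are
    interpreted as camera pixels and multiplied by it on read (and divided
    on write).
    """

    x: str = "x [nm]"
    y: str = "y [nm]"
    frame: str | None = "frame"
    channel: str | None = None
    nucleus_id: str | None = None
    pixel_size_nm: float | None = None


def read_localizations(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    *,
    channel: str | None = None,
    nucleus_id: str | None = None,
) -> pd.DataFrame:
    """Read a localization CSV into the canonical table.

    ``channel`` / ``nucleus_id`` supply constant labels when the file has no
    such columns.  Rows with non-finite or negative coordinates are dropped
    and counted in the log.

    Raises
    ------
    FormatError
        if a mapped column is missing from the file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty localization file", path)
        return _empty_table()
    for attr in ("x", "y"):
        col = getattr(dialect, attr)
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mapped column {col!r} (field {attr!r})")
    out = pd.DataFrame(
        {
            "x": pd.to_numeric(raw[dialect.x], errors="coerce").astype(float),
            "y": pd.to_numeric(raw[dialect.y], errors="coerce").astype(float),
        }
    )
    if dialect.pixel_size_nm is not None:
        out["x"] *= dialect.pixel_size_nm
        out["y"] *= dialect.pixel_size_nm
    if dialect.frame is not None and dialect.frame in raw.columns:
        out["frame"] = pd.to_numeric(raw[dialect.frame], errors="coerce")
    else:
        out["frame"] = np.nan
    if dialect.channel is not None and dialect.channel in raw.columns:
        out["channel"] = raw[dialect.channel].astype(str)
    else:
        out["channel"] = "" if channel is None else str(channel)
    if dialect.nucleus_id is not None and dialect.nucleus_id in raw.columns:
        out["nucleus_id"] = raw[dialect.nucleus_id].astype(str)
    else:
        out["nucleus_id"] = "" if nucleus_id is None else str(nucleus_id)
    ok = np.isfinite(out["x"]) & np.isfinite(out["y"]) & (out["x"] >= 0) & (out["y"] >= 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with non-finite/negative coordinates", path, n_bad)
    out = out.loc[ok].reset_index(drop=True)
    return out[list(CANONICAL_COLUMNS)]


def write_localizations(
    table: pd.DataFrame, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write a canonical table back to CSV under the given dialect.

    Round-trips through :func:`read_localizations` preserve record count,
    coordinates (to well below 1e-6 nm) and channel labels.
    """
    out = pd.DataFrame()
    scale = dialect.pixel_size_nm or 1.0
    out[dialect.x] = table["x"].to_numpy(float) / scale
    out[dialect.y] = table["y"].to_numpy(float) / scale
    if dialect.frame is not None:
        out[dialect.frame] = table.get("frame", np.nan)
    out[dialect.channel or "channel"] = table.get("channel", "")
    out[dialect.nucleus_id or "nucleus_id"] = table.get("nucleus_id", "")
    out.to_csv(path, index=False)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": pd.Series(dtype=str),
            "channel": pd.Series(dtype=str),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "frame": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Nucleus ROIs
# ---------------------------------------------------------------------------


class NucleusROI:
    """A nucleus region of interest in nm coordinates.

    Concrete representations are :class:`PolygonROI` and :class:`MaskROI`.
    Both answer point-in-ROI queries, report an area, and can sample
    uniformly distributed admissible centroid positions for a disc of given
    radius (the domain used by the cluster-randomization null).
    """

    nucleus_id: str

    @property
    def area(self) -> float:  # nm^2
        raise NotImplementedError

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in nm."""
        raise NotImplementedError

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ROI (boundary inclusive)."""
        raise NotImplementedError

    def sample_admissible(
        self, radius: float, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Sample ``n`` centroids uniform over the ROI eroded by ``radius``.

        Returns an (n, 2) array.  Raises :class:`PlacementError` when no
        position admits a disc of that radius.
        """
        raise NotImplementedError

    def filter_table(self, table: pd.DataFrame) -> pd.DataFrame:
        """Drop localizations outside the ROI, logging the count.

        The set of dropped records is a pure function of the coordinates, so
        repeated runs drop exactly the same rows.
        """
        inside = self.contains(table["x"].to_numpy(float), table["y"].to_numpy(float))
        n_out = int((~inside).sum())
        if n_out:
            logger.info("ROI %s: dropped %d out-of-ROI localizations", self.nucleus_id, n_out)
        return table.loc[inside].reset_index(drop=True)


class PolygonROI(NucleusROI):
    """ROI defined by a closed, non-self-intersecting polygon (nm vertices)."""

    def __init__(self, polygon: Polygon, nucleus_id: str = ""):
        if not polygon.is_valid:
            raise GeometryError(f"ROI {nucleus_id!r}: invalid (self-intersecting?) polygon")
        if polygon.area <= 0:
            raise EmptyROIError(f"ROI {nucleus_id!r}: polygon has zero area")
        self.polygon = polygon
        self.nucleus_id = nucleus_id
        self._eroded_cache: dict[float, Polygon] = {}

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return tuple(self.polygon.bounds)  # type: ignore[return-value]

    def contains(self, x, y):
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.polygon, pts)

    def _eroded(self, radius: float) -> Polygon:
        key = round(float(radius), 6)
        if key not in self._eroded_cache:
            self._eroded_cache[key] = self.polygon.buffer(-key)
        return self._eroded_cache[key]

    def sample_admissible(self, radius, n, rng):
        if radius < 0:
            raise ValueError("radius must be >= 0")
        eroded = self._eroded(radius) if radius > 0 else self.polygon
        if eroded.is_empty or eroded.area == 0:
            # Degenerate geometry: at most a single admissible point (e.g. a
            # disc ROI of radius exactly r). Use the pole of inaccessibility.
            pole = shapely.ops.polylabel(self.polygon, tolerance=max(radius, 1.0) * 1e-4)
            clearance = self.polygon.boundary.distance(pole)
            # sub-0.1% slack absorbs polygonal approximation of curved ROIs
            if clearance < radius * (1 - 1e-3):
                raise PlacementError(
                    f"ROI {self.nucleus_id!r}: no placement admits a disc of radius {radius} nm"
                )
            return np.tile([pole.x, pole.y], (n, 1))
        xmin, ymin, xmax, ymax = eroded.bounds
        span = np.array([xmax - xmin, ymax - ymin])
        lo = np.array([xmin, ymin])
        out = np.empty((n, 2))
        filled = 0
        # Batched rejection sampling; candidates are drawn in the unit square
        # and mapped onto the eroded bounding box, so uniformly rescaling the
        # ROI rescales the accepted points exactly (scale invariance).
        while filled < n:
            m = max(2 * (n - filled), 64)
            cand = lo + rng.random((m, 2)) * span
            keep = shapely.covers(eroded, shapely.points(cand[:, 0], cand[:, 1]))
            acc = cand[keep]
            take = min(len(acc), n - filled)
            out[filled : filled + take] = acc[:take]
            filled += take
        return out


class MaskROI(NucleusROI):
    """ROI defined by a binary raster mask.

    ``mask[row, col]`` is indexed as ``[y, x]``; pixel ``(0, 0)`` covers
    ``[origin, origin + pixel_size)`` in both axes.  Erosion for centroid
    sampling uses the Euclidean distance transform of the mask, i.e. it is
    resolved at pixel precision.
    """

    def __init__(
        self,
        mask: np.ndarray,
        pixel_size_nm: float,
        nucleus_id: str = "",
        origin: tuple[float, float] = (0.0, 0.0),
    ):
        mask = np.asarray(mask) > 0
        if pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not mask.any():
            raise EmptyROIError(f"ROI {nucleus_id!r}: all-zero mask")
        self.mask = mask
        self.pixel_size_nm = float(pixel_size_nm)
        self.origin = (float(origin[0]), float(origin[1]))
        self.nucleus_id = nucleus_id
        self._dt_nm: np.ndarray | None = None

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_nm**2

    @property
    def bounds(self):
        ny, nx = self.mask.shape
        ox, oy = self.origin
        p = self.pixel_size_nm
        return (ox, oy, ox + nx * p, oy + ny * p)

    def contains(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ox, oy = self.origin
        p = self.pixel_size_nm
        ix = np.floor((x - ox) / p).astype(int)
        iy = np.floor((y - oy) / p).astype(int)
        ny, nx = self.mask.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        res = np.zeros(x.shape, bool)
        res[ok] = self.mask[iy[ok], ix[ok]]
        return res

    def _distance_nm(self) -> np.ndarray:
        if self._dt_nm is None:
            from scipy.ndimage import distance_transform_edt

            padded = np.pad(self.mask, 1)
            self._dt_nm = distance_transform_edt(padded)[1:-1, 1:-1] * self.pixel_size_nm
        return self._dt_nm

    def sample_admissible(self, radius, n, rng):
        dt = self._distance_nm()
        adm = dt >= radius
        if not adm.any():
            best = np.unravel_index(np.argmax(dt), dt.shape)
            if dt[best] + self.pixel_size_nm < radius:
                raise PlacementError(
                    f"ROI {self.nucleus_id!r}: no placement admits a disc of radius {radius} nm"
                )
            adm = np.zeros_like(dt, bool)
            adm[best] = True
        iy, ix = np.nonzero(adm)
        k = rng.integers(0, len(ix), size=n)
        u = rng.random((n, 2))
        p = self.pixel_size_nm
        ox, oy = self.origin
        return np.column_stack(
            [ox + (ix[k] + u[:, 0]) * p, oy + (iy[k] + u[:, 1]) * p]
        )


def roi_from_polygon(vertices: Sequence[Sequence[float]], nucleus_id: str = "") -> PolygonROI:
    """Build a polygon ROI from an (n, 2) vertex list in nm."""
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise GeometryError(f"ROI {nucleus_id!r}: self-intersecting polygon")
    return PolygonROI(poly, nucleus_id)


def roi_from_convex_hull(table: pd.DataFrame, nucleus_id: str = "") -> PolygonROI:
    """Fallback ROI: convex hull of the localizations themselves.

    Flagged non-canonical — a hull drawn from the signal is not an
    independently delineated nucleus boundary; use it only when no ROI file
    is available.
    """
    pts = shapely.MultiPoint(np.column_stack([table["x"], table["y"]]))
    hull = pts.convex_hull
    if hull.area <= 0:
        raise EmptyROIError(f"ROI {nucleus_id!r}: degenerate convex hull")
    roi = PolygonROI(hull, nucleus_id)
    roi.non_canonical = True  # type: ignore[attr-defined]
    logger.warning("ROI %s: using convex-hull fallback (non-canonical)", nucleus_id)
    return roi


def load_roi(
    path: str | Path, pixel_size_nm: float | None = None, nucleus_id: str | None = None
) -> NucleusROI:
    """Load a nucleus ROI from a raster (TIFF/PNG) or polygon (GeoJSON) file.

    Rasters require ``pixel_size_nm``; any strictly positive pixel value is
    treated as foreground, provided the image is binary-interpretable (at
    most two distinct values).
    """
    path = Path(path)
    nid = nucleus_id if nucleus_id is not None else path.stem
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff", ".png"}:
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm is required for raster ROIs")
        if suffix == ".png":
            from PIL import Image

            arr = np.asarray(Image.open(path).convert("L"))
        else:
            import tifffile

            arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise FormatError(f"{path}: ROI raster must be single-plane 2-D")
        if len(np.unique(arr)) > 2:
            raise FormatError(f"{path}: ROI raster is not binary-interpretable")
        return MaskROI(arr, pixel_size_nm, nucleus_id=nid)
    if suffix in {".json", ".geojson"}:
        data = json.loads(path.read_text())
        geom = data.get("geometry", data)
        poly = _geojson_shape(geom)
        if not isinstance(poly, Polygon):
            raise GeometryError(f"{path}: expected a Polygon geometry")
        if not poly.is_valid:
            raise GeometryError(f"{path}: self-intersecting polygon")
        return PolygonROI(poly, nucleus_id=nid)
    raise FormatError(f"{path}: unsupported ROI format {suffix!r}")


def save_roi(roi: NucleusROI, path: str | Path) -> None:
    """Write a polygon ROI to GeoJSON or a mask ROI to TIFF."""
    path = Path(path)
    if isinstance(roi, PolygonROI):
        path.write_text(json.dumps(shapely.geometry.mapping(roi.polygon)))
    elif isinstance(roi, MaskROI):
        import tifffile

        tifffile.imwrite(path, roi.mask.astype(np.uint8))
    else:  # pragma: no cover
        raise TypeError(type(roi))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RenderedImage:
    """A 2-D histogram of localization counts on a fixed-pixel grid."""

    nucleus_id: str
    channel: str
    pixel_size_nm: float
    grid: np.ndarray  # [row=y, col=x] counts
    origin: tuple[float, float]  # nm offset of pixel (0, 0)


def render(
    table: pd.DataFrame,
    roi: NucleusROI,
    pixel_size_nm: float = 20.0,
    *,
    channel: str | None = None,
) -> RenderedImage:
    """Render in-ROI localizations to a count image (default 20-nm pixels).

    The grid covers the ROI bounding box with half-open pixel bins; the sum
    of the grid equals the number of in-ROI localizations exactly.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if channel is not None:
        table = table[table["channel"] == channel]
    table = roi.filter_table(table)
    xmin, ymin, xmax, ymax = roi.bounds
    nx = max(1, math.ceil((xmax - xmin) / pixel_size_nm))
    ny = max(1, math.ceil((ymax - ymin) / pixel_size_nm))
    grid = np.zeros((ny, nx), dtype=np.int64)
    if len(table):
        ix = np.floor((table["x"].to_numpy(float) - xmin) / pixel_size_nm).astype(int)
        iy = np.floor((table["y"].to_numpy(float) - ymin) / pixel_size_nm).astype(int)
        # points exactly on the upper bound of the box land in the last pixel
        np.clip(ix, 0, nx - 1, out=ix)
        np.clip(iy, 0, ny - 1, out=iy)
        np.add.at(grid, (iy, ix), 1)
    return RenderedImage(
        nucleus_id=roi.nucleus_id,
        channel="" if channel is None else channel,
        pixel_size_nm=float(pixel_size_nm),
        grid=grid,
        origin=(xmin, ymin),
    )


def save_rendered_image(image: RenderedImage, path: str | Path) -> None:
    """Write a rendered image as 16-bit TIFF (counts clipped at 65535)."""
    import tifffile

    tifffile.imwrite(Path(path), np.clip(image.grid, 0, 65535).astype(np.uint16))
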