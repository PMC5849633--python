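"""Tile-based spatial maps of tumor stroma: subsets, distances, immune counts.

A stained tumor section, once serial markers are aligned, is summarised on a
grid of square tiles of 225 um^2 (15 um side, roughly one cell).  Each tile
carries the mean intensity of every marker channel, a compartment flag
(epithelial when more than half of its pixels fall inside the epithelial
mask, stromal otherwise) and, for stromal tiles, a CAF subset label from the
quartile decision tree.

On top of the tile map this module computes the windowed distance from each
stromal tile to the nearest epithelial tile (Euclidean, in tile units,
restricted to a Chebyshev window of 5 tiles by default — tiles farther than
the window from any epithelium have *undefined* distance rather than a
clamped one), renders the classic red-to-yellow distance heatmap, and
quantifies immune-cell colocalization: points (e.g. CD3+ T cells) are binned
into the tile containing them and counted per compartment/subset, with
densities expressed per mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import stats as cohort_stats

#: Side of a tile in micrometers; 15 um squares have an area of 225 um^2.
TILE_SIDE_UM = 15.0

#: Area of one tile in mm^2.
TILE_AREA_MM2 = (TILE_SIDE_UM / 1000.0) ** 2

#: Rendering colors (RGB), linear ramp red -> yellow over defined distances.
_COLOR_MIN = np.array([255, 0, 0], dtype=float)
_COLOR_MAX = np.array([255, 255, 0], dtype=float)
_COLOR_UNDEFINED = np.array([128, 128, 128], dtype=np.uint8)
_COLOR_EPITHELIAL = np.array([0, 0, 0], dtype=np.uint8)


@dataclass
class TileMap:
    """Grid of 225 um^2 tiles with per-channel intensities and compartments.

    ``intensities`` maps channel name to a (rows, cols) float array;
    ``epithelial`` flags epithelial tiles; ``labels`` holds a subset label
    per stromal tile (``None`` elsewhere) once :func:`assign_subsets` has
    run.  Indices are 0-based and row-major; tile (x, y) covers the
    half-open square [x*15, (x+1)*15) x [y*15, (y+1)*15) in um.
    """

    intensities: dict[str, np.ndarray]
    epithelial: np.ndarray
    labels: np.ndarray | None = None
    tile_side_um: float = TILE_SIDE_UM

    def __post_init__(self) -> None:
        self.epithelial = np.asarray(self.epithelial, dtype=bool)
        shape = self.epithelial.shape
        if len(shape) != 2:
            raise ValueError("tile grid must be 2-D")
        for name, grid in self.intensities.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != shape:
                raise ValueError(f"channel {name!r} has shape {grid.shape}, expected {shape}")
            self.intensities[name] = grid
        if self.labels is None:
            self.labels = np.full(shape, None, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != shape:
                raise ValueError("labels grid shape mismatch")
        if (self.labels[self.epithelial] != None).any():  # noqa: E711 - object array
            raise ValueError("epithelial tiles must not carry a subset label")
        if self.tile_side_um <= 0:
            raise ValueError("tile_side_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.epithelial.shape

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.intensities)

    @property
    def stromal(self) -> np.ndarray:
        return ~self.epithelial

    def stromal_frame(self) -> pd.DataFrame:
        """One row per stromal tile: row, col, channel intensities, label."""
        rows, cols = np.nonzero(self.stromal)
        data = {"row": rows, "col": cols}
        for name, grid in self.intensities.items():
            data[name] = grid[rows, cols]
        data["label"] = self.labels[rows, cols]
        return pd.DataFrame(data)

    def compartment_areas_mm2(self) -> dict[str, float]:
        n_epith = int(self.epithelial.sum())
        n_total = self.epithelial.size
        area = (self.tile_side_um / 1000.0) ** 2
        return {"epithelial": n_epith * area, "stromal": (n_total - n_epith) * area}


@dataclass(frozen=True)
class DistanceMap:
    """Per-tile distance to the nearest epithelial tile within a window.

    ``distances`` is NaN on epithelial tiles and on stromal tiles with no
    epithelial tile inside the Chebyshev window (undefined, not zero).
    Values are in tile units; multiply by :data:`TILE_SIDE_UM` for um.
    """

    distances: np.ndarray
    window_radius: int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.distances)

    def distances_um(self, tile_side_um: float = TILE_SIDE_UM) -> np.ndarray:
        return self.distances * tile_side_um


def build_tile_map(
    marker_rasters: Mapping[str, np.ndarray],
    epithelial_mask: np.ndarray,
    pixel_size_um: float,
    tile_side_um: float = TILE_SIDE_UM,
) -> TileMap:
    """Average pre-aligned single-channel rasters into a tile map.

    All rasters and the mask must share one shape and pixel size.  When the
    pixel size does not divide the tile side the rasters are resampled to
    the nearest pixel grid that does.  Per-tile intensity is the mean pixel
    value; a tile is epithelial when more than 50% of its pixels are
    mask-positive.  Partial tiles at the right/bottom edges are dropped.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not marker_rasters:
        raise ValueError("no marker rasters supplied")
    mask = np.asarray(epithelial_mask).astype(bool)
    shapes = {np.asarray(r).shape for r in marker_rasters.values()} | {mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"rasters/mask have mismatched shapes: {sorted(shapes)}")

    ratio = tile_side_um / pixel_size_um
    ppt = int(round(ratio))
    if ppt < 1:
        raise ValueError("pixel size exceeds the tile side; nothing to average")
    rasters = {k: np.asarray(v, dtype=float) for k, v in marker_rasters.items()}
    if abs(ratio - ppt) > 1e-9:
        # resample so an integer number of pixels covers each tile
        from skimage.transform import resize

        h, w = mask.shape
        scale = ppt / ratio
        new_shape = (max(1, int(round(h * scale))), max(1, int(round(w * scale))))
        rasters = {
            k: resize(v, new_shape, order=1, preserve_range=True, anti_aliasing=False)
            for k, v in rasters.items()
        }
        mask = resize(mask.astype(float), new_shape, order=0, preserve_range=True) > 0.5

    h, w = mask.shape
    rows, cols = h // ppt, w // ppt
    if rows < 1 or cols < 1:
        raise ValueError("raster smaller than a single tile")

    def tiled_mean(arr: np.ndarray) -> np.ndarray:
        a = arr[: rows * ppt, : cols * ppt]
        return a.reshape(rows, ppt, cols, ppt).mean(axis=(1, 3))

    intensities = {k: tiled_mean(v) for k, v in rasters.items()}
    coverage = tiled_mean(mask.astype(float))
    return TileMap(intensities=intensities, epithelial=coverage > 0.5, tile_side_um=tile_side_um)


def assign_subsets(tiles: TileMap, thresholds) -> TileMap:
    """Label every stromal tile with a CAF subset; epithelial tiles untouched.

    ``thresholds`` is a :class:`~caftools.classifier.ThresholdSet` covering
    the map's marker channels.  Idempotent: relabeling an already labeled
    map yields the same labels.
    """
    from .classifier import classify_frame

    frame = tiles.stromal_frame()
    labels = np.full(tiles.shape, None, dtype=object)
    if len(frame):
        predicted = classify_frame(frame[list(tiles.channels)], thresholds)
        labels[frame["row"].to_numpy(), frame["col"].to_numpy()] = predicted.to_numpy()
    return TileMap(
        intensities={k: v.copy() for k, v in tiles.intensities.items()},
        epithelial=tiles.epithelial.copy(),
        labels=labels,
        tile_side_um=tiles.tile_side_um,
    )


def distance_to_epithelium(tiles: TileMap, window_radius: int = 5) -> DistanceMap:
    """Windowed Euclidean distance from each stromal tile to the epithelium.

    For a stromal tile at (x, y) the distance is
    ``min sqrt((xe-x)^2 + (ye-y)^2)`` over epithelial tiles (xe, ye) with
    ``|xe-x| <= window_radius`` and ``|ye-y| <= window_radius``; tiles with
    no epithelial tile in that window get NaN (undefined).
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    rows, cols = tiles.shape
    epith = tiles.epithelial
    best = np.full((rows, cols), np.inf)
    for dy in range(-window_radius, window_radius + 1):
        for dx in range(-window_radius, window_radius + 1):
            if dy == 0 and dx == 0:
                continue
            if abs(dy) >= rows or abs(dx) >= cols:
                continue
            d = float(np.hypot(dx, dy))
            # shift the epithelial mask by (dy, dx) onto the candidate tiles
            if dy >= 0:
                src_r, dst_r = slice(dy, rows), slice(0, rows - dy)
            else:
                src_r, dst_r = slice(0, rows + dy), slice(-dy, rows)
            if dx >= 0:
                src_c, dst_c = slice(dx, cols), slice(0, cols - dx)
            else:
                src_c, dst_c = slice(0, cols + dx), slice(-dx, cols)
            hit = np.zeros((rows, cols), dtype=bool)
            hit[dst_r, dst_c] = epith[src_r, src_c]
            np.minimum(best, np.where(hit, d, np.inf), out=best)
    best[epith] = np.nan
    best[np.isinf(best)] = np.nan
    return DistanceMap(distances=best, window_radius=int(window_radius))


@dataclass(frozen=True)
class DistanceBySubset:
    """Per-label distance summaries plus a two-sample comparison."""

    summary: pd.DataFrame
    comparisons: dict


def summarize_distance_by_subset(
    tiles: TileMap,
    dmap: DistanceMap,
    compare: tuple[str, str] | None = None,
) -> DistanceBySubset:
    """Mean +/- SEM distance per subset label, and label-vs-rest comparisons.

    Undefined distances are excluded from the summaries but counted.  A
    label with no defined distance is flagged absent (NaN mean) rather than
    zero.  ``comparisons`` holds the test chosen by the normality-driven
    selection rule for each label against the pooled remaining labels; pass
    ``compare=(a, b)`` to also test one specific label pair.
    """
    if tiles.labels is None or not (tiles.labels != None).any():  # noqa: E711
        raise ValueError("tile map has no subset labels; run assign_subsets first")
    stromal = tiles.stromal
    labels = tiles.labels[stromal]
    dists = dmap.distances[stromal]
    present = sorted({l for l in labels if l is not None})

    rows = []
    groups: dict[str, np.ndarray] = {}
    for label in present:
        sel = labels == label
        d = dists[sel]
        defined = d[np.isfinite(d)]
        groups[label] = defined
        rows.append(
            {
                "label": label,
                "n_tiles": int(sel.sum()),
                "n_defined": int(defined.size),
                "n_undefined": int(sel.sum() - defined.size),
                "mean": float(defined.mean()) if defined.size else np.nan,
                "sem": float(defined.std(ddof=1) / np.sqrt(defined.size))
                if defined.size > 1
                else np.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("label")

    comparisons: dict = {}
    for label in present:
        rest = np.concatenate([groups[o] for o in present if o != label]) if len(present) > 1 else np.array([])
        if groups[label].size >= 3 and rest.size >= 3:
            comparisons[(label, "rest")] = cohort_stats.select_and_test(groups[label], rest)
    if compare is not None:
        a, b = compare
        if groups.get(a) is None or groups.get(b) is None:
            raise ValueError(f"labels {compare} not both present on the map")
        comparisons[(a, b)] = cohort_stats.select_and_test(groups[a], groups[b])
    return DistanceBySubset(summary=summary, comparisons=comparisons)


def render_distance_heatmap(
    dmap: DistanceMap,
    tiles: TileMap,
    out_image=None,
) -> np.ndarray:
    """Render distances as an RGB image: red (near) to yellow (far).

    The ramp is linear over [min, max] of the defined distances; undefined
    stromal tiles are neutral gray and epithelial tiles black.  Returns the
    (rows, cols, 3) uint8 array and optionally writes it (PNG and friends).
    """
    d = dmap.distances
    defined = np.isfinite(d)
    if not defined.any():
        raise ValueError("cannot render a heatmap: no defined distances")
    dmin, dmax = float(np.nanmin(d)), float(np.nanmax(d))
    span = dmax - dmin
    t = np.zeros_like(d)
    if span > 0:
        t[defined] = (d[defined] - dmin) / span
    img = np.empty(d.shape + (3,), dtype=np.uint8)
    img[...] = _COLOR_UNDEFINED
    ramp = _COLOR_MIN[None, :] + t[defined][:, None] * (_COLOR_MAX - _COLOR_MIN)[None, :]
    img[defined] = np.round(ramp).astype(np.uint8)
    img[tiles.epithelial] = _COLOR_EPITHELIAL
    if out_image is not None:
        iio.imwrite(out_image, img)
    return img


def count_immune_per_label(tiles: TileMap, cells: pd.DataFrame) -> dict[str, int]:
    """Count points per compartment: epithelial tiles and each subset label.

    ``cells`` needs columns ``x_um``/``y_um``.  Each point is assigned to
    the tile whose half-open interval [k*15, (k+1)*15) contains it, so a
    point on a shared edge belongs to the tile on its right/bottom side.
    Points outside the tiled area raise an error naming the coordinates.
    """
    rows, cols = tiles.shape
    side = tiles.tile_side_um
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    cx = np.floor(x / side).astype(int)
    cy = np.floor(y / side).astype(int)
    bad = (cx < 0) | (cx >= cols) | (cy < 0) | (cy >= rows)
    if bad.any():
        offenders = list(zip(x[bad][:5], y[bad][:5]))
        raise ValueError(
            f"{int(bad.sum())} point(s) outside the {rows}x{cols} tile grid, e.g. {offenders}"
        )
    counts: dict[str, int] = {"epithelial": 0}
    from .classifier import SUBSETS

    for s in SUBSETS:
        counts[s] = 0
    for xi, yi in zip(cx, cy):
        if tiles.epithelial[yi, xi]:
            counts["epithelial"] += 1
        else:
            label = tiles.labels[yi, xi]
            key = label if label is not None else "unlabeled"
            counts[key] = counts.get(key, 0) + 1
    return counts


def density_per_compartment(
    counts: Mapping[str, float], areas_mm2: Mapping[str, float]
) -> pd.DataFrame:
    """Cell densities (per mm^2) per compartment, plus stroma-normalized values.

    ``areas_mm2`` must be positive; from a :class:`TileMap` use
    :meth:`TileMap.compartment_areas_mm2` (n_tiles x 2.25e-4 mm^2).  The
    ``relative_to_stroma`` column divides each density by the stromal one
    when a ``"stromal"`` compartment is present.
    """
    rows = []
    for comp, count in counts.items():
        if comp not in areas_mm2:
            raise ValueError(f"no area supplied for compartment {comp!r}")
        area = float(areas_mm2[comp])
        if area <= 0:
            raise ValueError(f"area for compartment {comp!r} must be positive; got {area}")
        rows.append({"compartment": comp, "count": count, "area_mm2": area,
                     "density_per_mm2": count / area})
    table = pd.DataFrame(rows).set_index("compartment")
    if "stromal" in table.index and table.loc["stromal", "density_per_mm2"] > 0:
        table["relative_to_stroma"] = (
            table["density_per_mm2"] / table.loc["stromal", "density_per_mm2"]
        )
    return table
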