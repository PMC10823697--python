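"""Densitometry on colony-array plate images.

Reproduces the image-quantification chain of the overlay screen: invert the
grayscale photograph so more oxidized substrate means more signal, build a
background illumination function from blank membrane images, subtract it, and
average the pixel intensities inside a fixed circle at every grid site.

The background function follows the flat-field recipe used for the screen:
the minimum pixel intensity of every 5x5 block of each blank image, combined
across blanks by elementwise minimum, upsampled back to pixel resolution by
block replication, and smoothed with a median filter that removes bright or
dim features that are imaging artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import BackgroundField, GridSpec, PlateImage, PlateLayout, SiteIntensity


def preprocess_image(raw: PlateImage) -> PlateImage:
    """Invert a raw grayscale image: output = 1 - normalized intensity."""
    if raw.stage != "raw":
        raise ValueError(f"expected a raw-stage image, got {raw.stage!r}")
    if np.any(raw.pixels > 1.0):
        raise ValueError("raw image must be normalized to [0, 1] before inversion")
    return PlateImage(
        1.0 - raw.pixels,
        plate_id=raw.plate_id,
        replicate_id=raw.replicate_id,
        stage="inverted",
    )


def _block_minima(pixels: np.ndarray, block_size: int) -> np.ndarray:
    """Per-block minimum with truncated (possibly smaller) edge blocks."""
    h, w = pixels.shape
    row_idx = np.arange(0, h, block_size)
    col_idx = np.arange(0, w, block_size)
    tmp = np.minimum.reduceat(pixels, row_idx, axis=0)
    return np.minimum.reduceat(tmp, col_idx, axis=1)


def estimate_background(
    blanks: list[PlateImage], block_size: int = 5, filter_radius: int = 7
) -> BackgroundField:
    """Background illumination function from one or more blank plates.

    Per blank, the minimum intensity of each ``block_size`` x ``block_size``
    section is taken (edge blocks may be truncated); the block fields are
    combined across blanks by elementwise minimum, replicated back to pixel
    resolution, and median-filtered with a square window of side
    ``2 * filter_radius + 1``.
    """
    if not blanks:
        raise ValueError("need at least one blank image")
    shape = blanks[0].pixels.shape
    for b in blanks:
        if b.stage != "inverted":
            raise ValueError("blank images must be inverted before background estimation")
        if b.pixels.shape != shape:
            raise ValueError("blank images have mismatched dimensions")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    block_field = _block_minima(blanks[0].pixels, block_size)
    for b in blanks[1:]:
        block_field = np.minimum(block_field, _block_minima(b.pixels, block_size))
    field = np.repeat(np.repeat(block_field, block_size, axis=0), block_size, axis=1)
    field = field[: shape[0], : shape[1]]
    if filter_radius > 0:
        field = ndimage.median_filter(field, size=2 * filter_radius + 1, mode="nearest")
    return BackgroundField(field, block_size=block_size, filter_radius=filter_radius)


def subtract_background(image: PlateImage, background: BackgroundField) -> PlateImage:
    """Subtract the illumination function, clamping negatives to zero."""
    if image.stage != "inverted":
        raise ValueError(f"expected an inverted-stage image, got {image.stage!r}")
    if image.pixels.shape != background.pixels.shape:
        raise ValueError("image and background field have mismatched dimensions")
    return PlateImage(
        np.maximum(image.pixels - background.pixels, 0.0),
        plate_id=image.plate_id,
        replicate_id=image.replicate_id,
        stage="background_subtracted",
    )


def circle_mask(shape: tuple[int, int], cy: float, cx: float, diameter: float):
    """Pixel-membership mask of a measurement circle, with its bounding slice.

    A pixel belongs to the circle when its center lies within ``diameter/2``
    (Euclidean) of the circle center. Raises if any member pixel would fall
    outside the image.
    """
    r = diameter / 2.0
    lo_r, hi_r = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    lo_c, hi_c = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    yy = np.arange(lo_r, hi_r)[:, None] - cy
    xx = np.arange(lo_c, hi_c)[None, :] - cx
    mask = (yy**2 + xx**2) <= r**2
    rows, cols = np.nonzero(mask)
    abs_rows, abs_cols = rows + lo_r, cols + lo_c
    if (
        abs_rows.min() < 0
        or abs_cols.min() < 0
        or abs_rows.max() >= shape[0]
        or abs_cols.max() >= shape[1]
    ):
        raise ValueError(
            f"measurement circle at ({cy:.1f}, {cx:.1f}) extends outside the image"
        )
    return abs_rows, abs_cols


def measure_sites(
    image: PlateImage, grid: GridSpec, layout: PlateLayout | None = None
) -> list[SiteIntensity]:
    """Mean intensity inside the measurement circle at every grid site.

    Sites are returned in row-major order. Strain IDs come from ``layout``
    when given, otherwise a positional placeholder is used. All growth flags
    start at 1 (normal); apply ``apply_growth_flags`` afterwards.
    """
    if image.stage != "background_subtracted":
        raise ValueError(
            f"expected a background-subtracted image, got {image.stage!r}"
        )
    if layout is not None and (layout.n_rows, layout.n_cols) != (grid.n_rows, grid.n_cols):
        raise ValueError("layout grid does not match GridSpec")
    sites = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            cy, cx = grid.site_center(row, col)
            rr, cc = circle_mask(image.pixels.shape, cy, cx, grid.circle_diameter)
            mean = float(image.pixels[rr, cc].mean())
            strain = layout.strain_at(row, col) if layout else f"site_r{row:02d}c{col:02d}"
            sites.append(
                SiteIntensity(
                    plate_id=image.plate_id,
                    replicate_id=image.replicate_id,
                    row=row,
                    col=col,
                    strain_id=strain,
                    mean_intensity=mean,
                )
            )
    return sites


def apply_growth_flags(
    sites: list[SiteIntensity], flags: pd.DataFrame | dict[tuple[int, int], int]
) -> list[SiteIntensity]:
    """Set manual growth flags (1 = normal, 0 = no/abnormal growth).

    ``flags`` maps (row, col) to 0/1, either as a dict or a DataFrame with
    columns ``row, col, growth_flag``. Positions absent from the table keep
    the default flag of 1; positions not on the plate, or flag values outside
    {0, 1}, are errors. Intensities are never modified.
    """
    if isinstance(flags, pd.DataFrame):
        table = {
            (int(r), int(c)): v
            for r, c, v in zip(flags["row"], flags["col"], flags["growth_flag"])
        }
    else:
        table = dict(flags)
    known = {(s.row, s.col) for s in sites}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"growth flags for unknown positions: {sorted(unknown)}")
    for value in table.values():
        if value not in (0, 1):
            raise ValueError(f"growth flag must be 0 or 1, got {value!r}")
    out = []
    for s in sites:
        flag = int(table.get((s.row, s.col), s.growth_flag))
        out.append(
            SiteIntensity(
                plate_id=s.plate_id,
                replicate_id=s.replicate_id,
                row=s.row,
                col=s.col,
                strain_id=s.strain_id,
                mean_intensity=s.mean_intensity,
                growth_flag=flag,
            )
        )
    return out


def sites_to_frame(sites: list[SiteIntensity]) -> pd.DataFrame:
    """Long DataFrame in the layout the scoring stage expects."""
    return pd.DataFrame(
        {
            "plate_id": [s.plate_id for s in sites],
            "replicate": [s.replicate_id for s in sites],
            "row": [s.row for s in sites],
            "col": [s.col for s in sites],
            "position": [s.position for s in sites],
            "strain_id": [s.strain_id for s in sites],
            "raw_mean": [s.mean_intensity for s in sites],
            "growth_flag": [s.growth_flag for s in sites],
        }
    )
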