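"""File I/O: plate images (TIFF/PNG), layouts, flags, traces, result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import GridSpec, PlateImage, PlateLayout


def write_plate_image(image: PlateImage, path: str | Path) -> None:
    """Write a plate image as 16-bit grayscale TIFF (or PNG via pillow)."""
    path = Path(path)
    scaled = np.clip(np.round(image.pixels * 65535.0), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, scaled)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(scaled, mode="I;16").save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_plate_image(
    path: str | Path, plate_id: str | None = None, replicate_id: int = 1
) -> PlateImage:
    """Read an 8/16-bit grayscale TIFF or PNG, normalized to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        pixels = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if pixels.ndim == 3:  # RGB -> luminance grayscale
        pixels = pixels[..., :3].mean(axis=-1)
    pixels = pixels.astype(float)
    if pixels.max() > 1.0:
        full_scale = 65535.0 if pixels.max() > 255 else 255.0
        pixels = pixels / full_scale
    return PlateImage(
        pixels, plate_id=plate_id or path.stem, replicate_id=replicate_id, stage="raw"
    )


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    """Layout as long CSV: row, col, position, strain_id, is_empty, effect."""
    from .types import well_label

    rows = []
    empties = set(layout.empty_positions)
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            strain = layout.strain_at(r, c)
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "position": well_label(r, c),
                    "strain_id": strain,
                    "is_empty": int((r, c) in empties),
                    "effect": layout.planted_effects.get(strain, 1.0),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_layout(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path)
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    grid = [[None] * n_cols for _ in range(n_rows)]
    empties, effects = [], {}
    for rec in df.itertuples():
        grid[rec.row][rec.col] = str(rec.strain_id)
        if getattr(rec, "is_empty", 0):
            empties.append((int(rec.row), int(rec.col)))
        eff = float(getattr(rec, "effect", 1.0))
        if eff != 1.0:
            effects[str(rec.strain_id)] = eff
    if any(s is None for row in grid for s in row):
        raise ValueError("layout CSV does not cover every grid position")
    return PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        strain_ids=grid,
        planted_effects=effects,
        empty_positions=empties,
    )


def read_growth_flags(path: str | Path) -> pd.DataFrame:
    """CSV with columns row, col, growth_flag (0/1)."""
    df = pd.read_csv(path)
    required = {"row", "col", "growth_flag"}
    if not required <= set(df.columns):
        raise ValueError(f"flags CSV needs columns {sorted(required)}")
    return df


def read_traces(path: str | Path) -> pd.DataFrame:
    """Long-format kinetic traces CSV: well, strain, time_min, a420."""
    df = pd.read_csv(path)
    required = {"well", "strain", "time_min", "a420"}
    if not required <= set(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(required)}")
    return df


def read_grid_spec(path: str | Path) -> GridSpec:
    with open(path) as fh:
        return GridSpec(**yaml.safe_load(fh))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with stable column order, no index."""
    df.to_csv(path, sep="\t", index=False)
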