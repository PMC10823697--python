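"""Shared domain containers for plate images, grids and layouts.

Conventions
-----------
* Images are 2D ``float64`` arrays with intensities in ``[0, 1]``; axis 0 is
  the image row (y), axis 1 the column (x). Pixel centers sit at integer
  coordinates.
* Grid positions are 0-based ``(row, col)`` internally; user-facing files use
  1-based A1-style labels (``A1`` .. ``P24`` for a 16x24 array).
* ``stage`` tracks where an image sits in the processing chain:
  ``raw`` -> ``inverted`` -> ``background_subtracted``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES = ("raw", "inverted", "background_subtracted")

GROWTH_NORMAL = "normal"
GROWTH_NONE = "none"
GROWTH_ABNORMAL = "abnormal"


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> plate-style label, e.g. (0, 0) -> 'A1'."""
    if row < 0 or col < 0:
        raise ValueError(f"negative grid position ({row}, {col})")
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


@dataclass
class PlateImage:
    """A single grayscale plate photograph (or a processed version of one)."""

    pixels: np.ndarray
    plate_id: str = "plate"
    replicate_id: int = 1
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("plate image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("plate image contains non-finite pixels")
        if np.any(self.pixels < 0):
            raise ValueError("plate image contains negative pixels")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BackgroundField:
    """Background illumination function estimated from blank plates."""

    pixels: np.ndarray
    block_size: int = 5
    filter_radius: int = 7

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("background field must be 2D")
        if np.any(self.pixels < 0):
            raise ValueError("background field must be non-negative")


@dataclass
class GridSpec:
    """Geometry of the colony array on the image.

    ``origin_x``/``origin_y`` are the pixel coordinates of the center of the
    top-left (row 0, col 0) site; sites are then spaced by ``pitch_x`` along
    columns and ``pitch_y`` along rows. ``circle_diameter`` is the diameter in
    pixels of the measurement circle centered on each site (101 px for the
    reference imaging setup).
    """

    n_rows: int = 16
    n_cols: int = 24
    origin_x: float = 0.0
    origin_y: float = 0.0
    pitch_x: float = 0.0
    pitch_y: float = 0.0
    circle_diameter: float = 101.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have positive dimensions")
        if self.circle_diameter <= 0:
            raise ValueError("circle_diameter must be positive")
        if self.pitch_x > 0 and self.pitch_y > 0:
            if self.circle_diameter > min(self.pitch_x, self.pitch_y):
                raise ValueError(
                    "measurement circle larger than grid pitch: circles overlap"
                )

    def site_center(self, row: int, col: int) -> tuple[float, float]:
        """(y, x) pixel coordinates of a site center."""
        return (self.origin_y + row * self.pitch_y, self.origin_x + col * self.pitch_x)


@dataclass
class PlateLayout:
    """Mapping from grid positions to strain identities.

    ``strain_ids`` is an ``n_rows x n_cols`` nested list (row-major).
    ``planted_effects`` assigns a multiplicative expression effect to strains
    (1.0 = reference-like); it is only consulted by the simulator.
    """

    n_rows: int = 16
    n_cols: int = 24
    strain_ids: list[list[str]] = field(default_factory=list)
    reference_positions: list[tuple[int, int]] = field(default_factory=list)
    planted_effects: dict[str, float] = field(default_factory=dict)
    empty_positions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strain_ids:
            self.strain_ids = [
                [f"strain_{well_label(r, c)}" for c in range(self.n_cols)]
                for r in range(self.n_rows)
            ]
        if len(self.strain_ids) != self.n_rows or any(
            len(row) != self.n_cols for row in self.strain_ids
        ):
            raise ValueError("strain_ids grid does not match n_rows x n_cols")
        known = {s for row in self.strain_ids for s in row}
        unknown = set(self.planted_effects) - known
        if unknown:
            raise ValueError(f"planted effects for unknown strains: {sorted(unknown)}")
        for eff in self.planted_effects.values():
            if not eff > 0:
                raise ValueError("planted effects must be positive")
        for r, c in list(self.reference_positions) + list(self.empty_positions):
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"position ({r}, {c}) outside grid")
        if set(self.reference_positions) & set(self.empty_positions):
            raise ValueError("reference and empty positions must be disjoint")

    def strain_at(self, row: int, col: int) -> str:
        return self.strain_ids[row][col]

    def effect_at(self, row: int, col: int) -> float:
        return self.planted_effects.get(self.strain_at(row, col), 1.0)


@dataclass
class SiteIntensity:
    """Background-corrected mean intensity for one grid site."""

    plate_id: str
    replicate_id: int
    row: int
    col: int
    strain_id: str
    mean_intensity: float
    growth_flag: int = 1

    def __post_init__(self) -> None:
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be >= 0")
        if self.growth_flag not in (0, 1):
            raise ValueError("growth_flag must be 0 or 1")

    @property
    def position(self) -> str:
        return well_label(self.row, self.col)
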