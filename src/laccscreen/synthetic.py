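"""Synthetic plate images, blank plates, kinetic traces and activity tables.

The raw screen photographs and plate-reader exports behind a colony-overlay
laccase screen are rarely shareable, so this module generates stand-ins with
known ground truth. It emulates the features the downstream pipeline must
handle:

* a 24x16 colony array whose per-site signal is proportional to the secreted
  laccase activity of the strain at that site;
* a spatial artifact that increases signal toward the plate periphery,
  shaped as concentric rectangular rings (the geometry the zone correction
  targets);
* a smooth background illumination field contributed by the nitrocellulose
  membrane, shared by all plates of an imaging session;
* per-site biological variability (multiplicative, lognormal) and per-pixel
  camera noise (additive Gaussian);
* kinetic absorbance traces with an initial linear phase that rolls over
  into substrate-depletion saturation.

Images are emitted at the ``raw`` stage — dark colonies on a light membrane,
exactly as a photograph of the colorimetric reaction — so that the
quantification chain (inversion, background subtraction, densitometry) can be
exercised end to end. Every generator is a pure function of its parameters
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .screen import assign_zones, n_zones
from .types import (
    GROWTH_NONE,
    GROWTH_NORMAL,
    GridSpec,
    PlateImage,
    PlateLayout,
)


@dataclass
class SimulationConfig:
    """Knobs of the plate-image simulator.

    Intensities are in the inverted (signal) space, fractions of full scale.
    ``base_signal`` is the mean disk intensity of a reference-like colony at
    the plate center; an edge colony is brighter by up to
    ``1 + edge_amplitude``. ``site_cv`` is the coefficient of variation of
    multiplicative per-site biological noise; ``noise_sd`` is additive
    per-pixel camera noise. The clipping invariant
    ``base_signal * max_effect * (1 + edge_amplitude) + background < 1``
    should hold for planted effects to stay measurable.
    """

    image_width: int = 960
    image_height: int = 640
    colony_radius: float = 13.0
    colony_blur_sigma: float = 1.0
    base_signal: float = 0.15
    edge_amplitude: float = 0.25
    background_field_scale: float = 0.05
    noise_sd: float = 0.01
    site_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "colony_radius",
            "base_signal",
            "edge_amplitude",
            "background_field_scale",
            "noise_sd",
            "site_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass
class GroundTruth:
    """What the simulator actually put on the plate."""

    expression: np.ndarray  # (n_rows, n_cols) true per-site expression level
    growth: list[list[str]]  # {normal, none, abnormal} per site
    true_positives: set[str] = field(default_factory=set)
    true_negatives: set[str] = field(default_factory=set)


def default_grid(layout: PlateLayout, config: SimulationConfig,
                 circle_diameter: float | None = None) -> GridSpec:
    """Grid geometry matching the simulated images.

    Sites are pitched uniformly so the array fills the image; the
    measurement circle defaults to the colony diameter plus a 5 px margin
    (it must stay inside the pitch, unlike the 101 px real-image default).
    """
    pitch_x = config.image_width / layout.n_cols
    pitch_y = config.image_height / layout.n_rows
    if circle_diameter is None:
        # strictly inside the pitch so edge-site circles stay on the image
        circle_diameter = min(2 * config.colony_radius + 5, pitch_x - 1, pitch_y - 1)
    return GridSpec(
        n_rows=layout.n_rows,
        n_cols=layout.n_cols,
        origin_x=pitch_x / 2,
        origin_y=pitch_y / 2,
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        circle_diameter=circle_diameter,
    )


def background_field(config: SimulationConfig) -> np.ndarray:
    """Smooth, deterministic membrane illumination field (no noise)."""
    h, w = config.image_height, config.image_width
    y = np.linspace(0.0, np.pi, h)[:, None]
    x = np.linspace(0.0, np.pi, w)[None, :]
    shape = 0.55 + 0.30 * np.sin(y) * np.sin(x) + 0.15 * np.cos(2 * x) * np.cos(y)
    return config.background_field_scale * shape


def zone_factors(n_rows: int, n_cols: int) -> np.ndarray:
    """Per-site edge-artifact weight: 1 on the outermost ring, 0 at center,
    decreasing monotonically ring by ring."""
    zones = assign_zones(n_rows, n_cols, zone_width=1)
    nz = n_zones(n_rows, n_cols, zone_width=1)
    if nz == 1:
        return np.ones_like(zones, dtype=float)
    return (nz - zones) / (nz - 1)


def _render_signal(layout: PlateLayout, config: SimulationConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, GroundTruth]:
    grid = default_grid(layout, config)
    colonies = np.zeros((config.image_height, config.image_width))
    zf = zone_factors(layout.n_rows, layout.n_cols)
    empties = set(layout.empty_positions)
    expression = np.zeros((layout.n_rows, layout.n_cols))
    growth = [[GROWTH_NORMAL] * layout.n_cols for _ in range(layout.n_rows)]
    # lognormal multiplier with unit mean and the requested CV
    if config.site_cv > 0:
        sigma = np.sqrt(np.log1p(config.site_cv**2))
        site_noise = rng.lognormal(-0.5 * sigma**2, sigma, size=expression.shape)
    else:
        site_noise = np.ones_like(expression)
    r = config.colony_radius
    for row in range(layout.n_rows):
        for col in range(layout.n_cols):
            if (row, col) in empties:
                growth[row][col] = GROWTH_NONE
                continue
            level = layout.effect_at(row, col) * site_noise[row, col]
            expression[row, col] = level
            amp = config.base_signal * level * (1 + config.edge_amplitude * zf[row, col])
            cy, cx = grid.site_center(row, col)
            lo_r, hi_r = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
            lo_c, hi_c = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
            yy = np.arange(lo_r, hi_r)[:, None] - cy
            xx = np.arange(lo_c, hi_c)[None, :] - cx
            disk = (yy**2 + xx**2) <= r**2
            colonies[lo_r:hi_r, lo_c:hi_c] += amp * disk
    if config.colony_blur_sigma > 0:
        colonies = ndimage.gaussian_filter(colonies, config.colony_blur_sigma)
    truth = GroundTruth(
        expression=expression,
        growth=growth,
        true_positives={s for s, e in layout.planted_effects.items() if e > 1},
        true_negatives={s for s, e in layout.planted_effects.items() if e < 1},
    )
    return colonies, truth


def simulate_plate_image(
    layout: PlateLayout,
    config: SimulationConfig,
    seed: int,
    plate_id: str = "plate",
    replicate_id: int = 1,
) -> tuple[PlateImage, GroundTruth]:
    """Render one colony-overlay photograph with known ground truth.

    In the inverted (signal) space, each colony disk has mean intensity
    ``base_signal * effect * site_noise * (1 + edge_amplitude * zone_factor)``
    on top of the shared background field and per-pixel noise; the emitted
    image is the raw-stage complement (dark colonies on light membrane).
    """
    rng = np.random.default_rng(seed)
    colonies, truth = _render_signal(layout, config, rng)
    signal = colonies + background_field(config)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, 1.0)
    image = PlateImage(1.0 - signal, plate_id=plate_id, replicate_id=replicate_id, stage="raw")
    return image, truth


def simulate_blank_plate(
    config: SimulationConfig, seed: int, plate_id: str = "blank", replicate_id: int = 1
) -> PlateImage:
    """A colony-free membrane photograph: background field plus pixel noise."""
    rng = np.random.default_rng(seed)
    signal = background_field(config)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, 1.0)
    return PlateImage(1.0 - signal, plate_id=plate_id, replicate_id=replicate_id, stage="raw")


def simulate_kinetic_trace(
    true_slope: float,
    intercept: float,
    linear_until: float,
    total_time: float,
    read_interval: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    saturation_tau: float = 15.0,
    well_id: str = "A1",
    strain_id: str = "strain",
) -> "pd.DataFrame":
    """Absorbance-vs-time trace: linear phase, then exponential saturation.

    ``A(t) = intercept + true_slope * t`` for ``t <= linear_until``; beyond
    that the curve approaches a plateau exponentially with time constant
    ``saturation_tau`` (minutes), with a continuous first derivative at the
    breakpoint — emulating substrate depletion. Oxidized ABTS accumulates, so
    a negative slope is rejected. Returns a long-format frame with columns
    ``well, strain, time_min, a420``.
    """
    if true_slope < 0:
        raise ValueError("true_slope must be >= 0: oxidized ABTS accumulates")
    if linear_until > total_time:
        raise ValueError("linear_until must not exceed total_time")
    if read_interval <= 0:
        raise ValueError("read_interval must be positive")
    if saturation_tau <= 0:
        raise ValueError("saturation_tau must be positive")
    t = np.arange(0.0, total_time + read_interval / 2, read_interval)
    a = intercept + true_slope * np.minimum(t, linear_until)
    late = t > linear_until
    # plateau = A(linear_until) + slope*tau, so dA/dt is continuous at the break
    a[late] += true_slope * saturation_tau * (
        1.0 - np.exp(-(t[late] - linear_until) / saturation_tau)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return pd.DataFrame(
        {"well": well_id, "strain": strain_id, "time_min": t, "a420": a}
    )


def simulate_activity_study(
    n_strains: int,
    effects: dict[str, float],
    n_replicates: int = 3,
    cv: float = 0.10,
    seed: int = 0,
    reference_strain: str = "reference",
    reference_mean: float = 3.0e-4,
    od600_mean: float = 10.0,
    od600_cv: float = 0.05,
) -> pd.DataFrame:
    """Per-replicate activity/OD600 table with planted fold effects.

    Each strain's OD600-normalized activity is drawn around
    ``effect * reference_mean`` with coefficient of variation ``cv``; the raw
    ``activity`` column is the normalized value times an independently drawn
    culture density, so the normalization step downstream has real work to
    do. Strains beyond ``effects`` are filled in as reference-like
    (effect 1.0). The reference strain is always included.
    """
    if n_replicates < 2:
        raise ValueError("need at least two replicates per strain")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    strains: dict[str, float] = {reference_strain: 1.0}
    strains.update(effects)
    filler = 1
    while len(strains) < n_strains + 1:  # +1 for the reference
        name = f"strain_{filler:03d}"
        if name not in strains:
            strains[name] = 1.0
        filler += 1
    rows = []
    for strain, effect in strains.items():
        mean_norm = effect * reference_mean
        for rep in range(1, n_replicates + 1):
            norm = mean_norm * max(1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0), 1e-9)
            od = od600_mean * max(
                1.0 + (rng.normal(0.0, od600_cv) if od600_cv > 0 else 0.0), 1e-9
            )
            rows.append(
                {
                    "strain_id": strain,
                    "replicate": rep,
                    "activity": norm * od,
                    "od600": od,
                }
            )
    return pd.DataFrame(rows)


def make_screen_layouts(
    n_plates: int,
    n_positives_per_plate: int = 6,
    effect: float = 3.0,
    n_rows: int = 16,
    n_cols: int = 24,
    n_empty_per_plate: int = 4,
    seed: int = 0,
) -> list[PlateLayout]:
    """Layouts for a multi-plate screen with planted positive strains.

    Strain IDs are unique across plates; planted positives and empty sites
    are placed uniformly at random (disjointly) on each plate.
    """
    rng = np.random.default_rng(seed)
    layouts = []
    for p in range(n_plates):
        strain_ids = [
            [f"p{p + 1:02d}_r{r:02d}c{c:02d}" for c in range(n_cols)]
            for r in range(n_rows)
        ]
        all_pos = [(r, c) for r in range(n_rows) for c in range(n_cols)]
        picked = rng.choice(len(all_pos), size=n_positives_per_plate + n_empty_per_plate,
                            replace=False)
        hot = [all_pos[i] for i in picked[:n_positives_per_plate]]
        empty = [all_pos[i] for i in picked[n_positives_per_plate:]]
        effects = {strain_ids[r][c]: effect for r, c in hot}
        layouts.append(
            PlateLayout(
                n_rows=n_rows,
                n_cols=n_cols,
                strain_ids=strain_ids,
                planted_effects=effects,
                empty_positions=empty,
            )
        )
    return layouts


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
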