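"""End-to-end runs: images -> scores -> hits, and traces -> activity -> stats.

``run_screen`` quantifies every plate/replicate image against the shared
background field, scores sites, and calls hits; ``run_liquid`` fits kinetic
traces, converts slopes to activities, normalizes by OD600 and runs the
Dunnett comparison against the reference strain. Both write TSV outputs plus
a provenance-stamped report and are deterministic for a given configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, imagequant, io, kinetics, screen
from .types import GridSpec, PlateLayout

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, geometry and thresholds for a pipeline run."""

    image_paths: list[str] = dc_field(default_factory=list)  # plate images
    blank_paths: list[str] = dc_field(default_factory=list)
    layout_path: str | None = None
    flags_paths: dict[str, str] = dc_field(default_factory=dict)  # "plate:rep" -> csv
    traces_path: str | None = None
    od_path: str | None = None
    out_dir: str = "results"
    grid: GridSpec = dc_field(default_factory=GridSpec)
    zone_width: int = 1
    z_threshold: float = 2.5
    min_replicates: int = 2
    r_min: float = 0.999
    min_points: int = 5
    activity: kinetics.ActivitySpec = dc_field(default_factory=kinetics.ActivitySpec)
    reference_strain: str = "reference"
    block_size: int = 5
    filter_radius: int = 7
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = GridSpec(**raw["grid"])
        if "activity" in raw:
            raw["activity"] = kinetics.ActivitySpec(**raw["activity"])
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in outputs."""
        def default(o):
            return vars(o)

        blob = json.dumps(vars(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "version": __version__}


def quantify_plates(
    images,
    blanks,
    grid: GridSpec,
    layout: PlateLayout | None = None,
    flags: dict[tuple[str, int], pd.DataFrame] | None = None,
    block_size: int = 5,
    filter_radius: int = 7,
) -> pd.DataFrame:
    """Images + blanks -> long per-site intensity frame.

    ``flags`` optionally maps (plate_id, replicate) to a growth-flag table.
    """
    if not blanks:
        raise ValueError("no blank images supplied: cannot estimate background")
    inverted_blanks = [imagequant.preprocess_image(b) for b in blanks]
    background = imagequant.estimate_background(
        inverted_blanks, block_size=block_size, filter_radius=filter_radius
    )
    frames = []
    for image in images:
        corrected = imagequant.subtract_background(
            imagequant.preprocess_image(image), background
        )
        sites = imagequant.measure_sites(corrected, grid, layout)
        key = (image.plate_id, image.replicate_id)
        if flags and key in flags:
            sites = imagequant.apply_growth_flags(sites, flags[key])
        frames.append(imagequant.sites_to_frame(sites))
    return pd.concat(frames, ignore_index=True)


def run_screen(config: RunConfig) -> dict:
    """Full overlay-screen analysis from image files; returns the report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.blank_paths:
        raise ValueError("config lists no blank images")
    blanks = [io.read_plate_image(p) for p in config.blank_paths]
    images = []
    for p in config.image_paths:
        img = io.read_plate_image(p)
        # filenames end in _r<replicate>, e.g. plate01_r2.tif
        stem = Path(p).stem
        if "_r" in stem:
            plate, _, rep = stem.rpartition("_r")
            img.plate_id, img.replicate_id = plate, int(rep)
        images.append(img)
    layout = io.read_layout(config.layout_path) if config.layout_path else None
    flags = {}
    for key, path in config.flags_paths.items():
        plate, _, rep = key.rpartition(":")
        flags[(plate, int(rep))] = io.read_growth_flags(path)
    sites = quantify_plates(
        images, blanks, config.grid, layout, flags,
        block_size=config.block_size, filter_radius=config.filter_radius,
    )
    scores, hits = screen.score_screen(
        sites,
        zone_width=config.zone_width,
        threshold=config.z_threshold,
        min_replicates=config.min_replicates,
    )
    io.write_table(scores, out / "scores.tsv")
    io.write_table(hits, out / "hits.tsv")
    qc = (
        scores.groupby(["plate_id", "replicate"])
        .agg(
            median_raw=("raw_mean", "median"),
            n_flagged=("growth_flag", lambda f: int((f == 0).sum())),
            n_sites=("raw_mean", "size"),
        )
        .reset_index()
    )
    report = {
        **_provenance(config),
        "n_plates": int(scores["plate_id"].nunique()),
        "n_strains": int(hits.shape[0]),
        "n_positive": int((hits["call"] == "positive").sum()),
        "n_negative": int((hits["call"] == "negative").sum()),
        "plate_qc": qc.to_dict(orient="records"),
    }
    with open(out / "screen_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info(
        "screen: %d strains, %d positive, %d negative hits",
        report["n_strains"], report["n_positive"], report["n_negative"],
    )
    return report


def fit_traces(
    traces: pd.DataFrame,
    spec: kinetics.ActivitySpec,
    r_min: float = 0.999,
    min_points: int = 5,
) -> pd.DataFrame:
    """Per-well linear fits and activities from a long trace frame."""
    rows = []
    for (well, strain), sub in traces.groupby(["well", "strain"], sort=False):
        trace = kinetics.KineticTrace.from_frame(sub)
        fit = kinetics.fit_linear_range(trace, r_min=r_min, min_points=min_points)
        rows.append(
            {
                "well": well,
                "strain_id": strain,
                "slope": fit.slope,
                "r": fit.r,
                "n_used": fit.n_used,
                "activity": kinetics.activity_from_slope(fit, spec),
            }
        )
    return pd.DataFrame(rows)


def run_liquid(config: RunConfig) -> pd.DataFrame:
    """Liquid-assay analysis: traces + OD table -> activity and stats TSVs."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.traces_path is None or config.od_path is None:
        raise ValueError("config must give traces_path and od_path")
    traces = io.read_traces(config.traces_path)
    od = pd.read_csv(config.od_path)  # columns: well, od600 (+ optional replicate)
    fits = fit_traces(traces, config.activity, config.r_min, config.min_points)
    merged = fits.merge(od, on="well", how="left", validate="one_to_one")
    if merged["od600"].isna().any():
        missing = merged.loc[merged["od600"].isna(), "well"].tolist()
        raise ValueError(f"missing OD600 for wells: {missing}")
    if "replicate" not in merged.columns:
        merged["replicate"] = merged.groupby("strain_id").cumcount() + 1
    per_rep, per_strain = kinetics.normalize_and_fold(merged, config.reference_strain)
    stats_df = kinetics.anova_dunnett(
        per_rep[["strain_id", "normalized_activity"]], config.reference_strain
    )
    result = per_strain.merge(stats_df[["strain_id", "p_adj", "stars"]],
                              on="strain_id", how="left")
    result["config_hash"] = config.digest()
    io.write_table(per_rep, out / "activities.tsv")
    io.write_table(result, out / "activity_stats.tsv")
    return result
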