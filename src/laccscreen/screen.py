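"""Plate normalization, zone correction, modified Z-scores and hit calling.

The scoring chain for a colony-overlay screen plate is:

1. divide every site's mean intensity by the plate median, computed over
   sites with normal growth only (flag 1), so the flag-1 median becomes 1.0;
2. partition the array into concentric rectangular rings ("zones", ring 1 at
   the periphery) and, for every zone whose flag-1 median exceeds 1.0, divide
   all values in that zone by the zone median — this removes the systematic
   signal increase toward the plate edges;
3. convert the corrected values into modified Z-scores,
   z = (x - median) / MAD with MAD = 1.4826 * median(|x - median|),
   median and MAD taken over flag-1 sites of the plate;
4. call a strain a positive hit when z >= threshold in at least
   ``min_replicates`` replicates (default 2.5 and 2), a negative hit with the
   mirrored rule on the negative side.

All functions operate on pandas DataFrames with columns
``plate_id, replicate, row, col, strain_id, raw_mean, growth_flag``; each
stage adds its output column (``normalized``, ``zone_index``,
``zone_corrected``, ``modified_z``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes the MAD consistent with sigma under normality

SITE_COLUMNS = ["plate_id", "replicate", "row", "col", "strain_id", "raw_mean", "growth_flag"]


def normalize_to_plate_median(sites: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide raw site means by the plate median over flag-1 sites.

    Returns the updated frame (new column ``normalized``) and the plate
    median. Flag-0 sites are excluded from the median but still receive a
    normalized value.
    """
    flags = sites["growth_flag"].to_numpy()
    raws = sites["raw_mean"].to_numpy(dtype=float)
    grown = raws[flags == 1]
    if grown.size == 0:
        raise ValueError("cannot normalize: every site is flagged as no/abnormal growth")
    plate_median = float(np.median(grown))
    if plate_median <= 0:
        raise ValueError("cannot normalize: plate median intensity is zero")
    out = sites.copy()
    out["normalized"] = raws / plate_median
    return out, plate_median


def assign_zones(n_rows: int, n_cols: int, zone_width: int = 1) -> np.ndarray:
    """Zone index per grid site: concentric rectangular rings, 1 = outermost.

    ``zone_index = 1 + floor(ring / zone_width)`` where ``ring`` is the
    Chebyshev-like distance to the nearest grid border,
    ``min(row, col, n_rows-1-row, n_cols-1-col)``.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("zone assignment needs a grid of at least 2x2")
    if zone_width < 1:
        raise ValueError("zone_width must be >= 1")
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    ring = np.minimum(
        np.minimum(rows, n_rows - 1 - rows), np.minimum(cols, n_cols - 1 - cols)
    )
    return 1 + ring // zone_width


def n_zones(n_rows: int, n_cols: int, zone_width: int = 1) -> int:
    max_ring = (min(n_rows, n_cols) - 1) // 2
    return 1 + max_ring // zone_width


def zone_correct(sites: pd.DataFrame, zone_width: int = 1) -> pd.DataFrame:
    """Apply the concentric-rectangle edge correction to normalized values.

    A zone is corrected only when its flag-1 median of ``normalized`` exceeds
    the plate median (1.0 by construction, strict inequality); correction
    divides every value in the zone — including flag-0 sites — by the zone
    median, so a corrected zone's flag-1 median becomes exactly 1.0. Zones
    with no flag-1 sites are left unchanged with a warning.
    """
    if "normalized" not in sites.columns:
        raise ValueError("sites must be normalized before zone correction")
    out = sites.copy()
    n_rows = int(out["row"].max()) + 1
    n_cols = int(out["col"].max()) + 1
    zone_map = assign_zones(n_rows, n_cols, zone_width)
    out["zone_index"] = zone_map[out["row"].to_numpy(), out["col"].to_numpy()]
    corrected = out["normalized"].to_numpy(dtype=float).copy()
    for zone, idx in out.groupby("zone_index").groups.items():
        sub = out.loc[idx]
        grown = sub.loc[sub["growth_flag"] == 1, "normalized"]
        if grown.empty:
            logger.warning("zone %d has no normally-grown sites; left uncorrected", zone)
            continue
        zone_median = float(grown.median())
        if zone_median > 1.0:
            corrected[out.index.get_indexer(idx)] = sub["normalized"].to_numpy() / zone_median
    out["zone_corrected"] = corrected
    return out


def modified_zscore(values, flags=None) -> np.ndarray:
    """Modified Z-scores: (x - median) / MAD, MAD = 1.4826 * median(|x - median|).

    Median and MAD are computed over flag-1 entries only, but a score is
    returned for every entry. Raises for degenerate plates (fewer than two
    flag-1 values, or MAD of zero).
    """
    x = np.asarray(values, dtype=float)
    if flags is None:
        flags = np.ones(x.shape, dtype=int)
    flags = np.asarray(flags)
    grown = x[flags == 1]
    if grown.size < 2:
        raise ValueError("modified Z-score needs at least two normally-grown sites")
    med = np.median(grown)
    mad = MAD_SCALE * np.median(np.abs(grown - med))
    if mad == 0:
        raise ValueError("MAD is zero: degenerate plate (no spread among grown sites)")
    return (x - med) / mad


def score_plate(sites: pd.DataFrame, zone_width: int = 1) -> pd.DataFrame:
    """Run the full per-plate chain: normalize -> zone-correct -> modified Z."""
    scored, _ = normalize_to_plate_median(sites)
    scored = zone_correct(scored, zone_width=zone_width)
    scored["modified_z"] = modified_zscore(
        scored["zone_corrected"].to_numpy(), scored["growth_flag"].to_numpy()
    )
    return scored


def call_hits(
    replicate_z: dict[str, list[float]] | pd.DataFrame,
    threshold: float = 2.5,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Classify strains from their per-replicate modified Z-scores.

    ``positive`` when z >= +threshold in >= min_replicates replicates,
    ``negative`` with the mirrored rule, else ``none``. A strain qualifying on
    both sides (inconsistent replicates) is demoted to ``none`` with a
    warning. Accepts a mapping strain -> z list or a long DataFrame with
    columns ``strain_id`` and ``modified_z``.
    """
    if isinstance(replicate_z, pd.DataFrame):
        grouped = {
            strain: sub["modified_z"].dropna().tolist()
            for strain, sub in replicate_z.groupby("strain_id", sort=False)
        }
    else:
        grouped = {k: list(v) for k, v in replicate_z.items()}
    if not grouped:
        raise ValueError("no strains to call")
    records = []
    for strain, zs in grouped.items():
        if len(zs) == 0:
            logger.warning("strain %s has no replicate scores; excluded", strain)
            continue
        z = np.asarray(zs, dtype=float)
        n_pos = int(np.sum(z >= threshold))
        n_neg = int(np.sum(z <= -threshold))
        pos = n_pos >= min_replicates
        neg = n_neg >= min_replicates
        if pos and neg:
            logger.warning("strain %s qualifies as both positive and negative; called none", strain)
            call = "none"
        elif pos:
            call = "positive"
        elif neg:
            call = "negative"
        else:
            call = "none"
        records.append(
            {
                "strain_id": strain,
                "n_replicates": len(zs),
                "z_scores": ";".join(f"{v:.4g}" for v in z),
                "mean_modified_z": float(z.mean()),
                "n_pos_passing": n_pos,
                "n_neg_passing": n_neg,
                "call": call,
            }
        )
    if not records:
        raise ValueError("no strains with any replicate scores")
    return pd.DataFrame.from_records(records)


def score_screen(
    sites: pd.DataFrame,
    zone_width: int = 1,
    threshold: float = 2.5,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (plate, replicate) and call hits across replicates.

    ``sites`` holds all plates and replicates of the screen in one long
    frame. Flag-0 sites are scored (their z is reported) but excluded from
    hit calling, mirroring their exclusion from plate medians. Returns
    ``(scores, hits)``.
    """
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"sites frame is missing columns: {missing}")
    scored_parts = []
    for (plate, rep), sub in sites.groupby(["plate_id", "replicate"], sort=False):
        try:
            scored_parts.append(score_plate(sub, zone_width=zone_width))
        except ValueError as exc:
            raise ValueError(f"plate {plate!r} replicate {rep}: {exc}") from exc
    scores = pd.concat(scored_parts, ignore_index=True)
    callable_sites = scores[scores["growth_flag"] == 1]
    hits = call_hits(
        callable_sites[["strain_id", "modified_z"]],
        threshold=threshold,
        min_replicates=min_replicates,
    )
    return scores, hits
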