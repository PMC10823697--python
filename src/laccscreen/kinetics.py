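"""Liquid ABTS assay: linear-range fitting, Beer-Lambert activity, statistics.

A laccase-containing supernatant oxidizes ABTS; the radical cation product
absorbs at 420 nm, so the initial slope of an A420-vs-time trace is
proportional to enzyme activity. The analysis chain is:

1. trim points from the trace until an ordinary least-squares fit of the
   retained points reaches a Pearson correlation of at least ``r_min``
   (default 0.999) — isolating the initial linear phase from substrate
   depletion (late saturation) or mixing lag (early curvature);
2. convert the slope (AU/min) to a molar rate with the Beer-Lambert law and
   scale by the reaction volume to get µmol oxidized ABTS per minute;
3. normalize activity by culture OD600 and express each strain as a fold
   change versus a reference strain measured on the same plate;
4. compare strains by one-way ANOVA with Dunnett's many-to-one correction
   (versus the reference) or Tukey's correction (all pairs).

A ΔΔCt helper for qPCR relative expression is included because screen
follow-up typically pairs activity with transcript measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KineticTrace:
    """One well's A420 time series."""

    well_id: str
    strain_id: str
    time: np.ndarray  # minutes, strictly increasing
    a420: np.ndarray  # absorbance units
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a420 = np.asarray(self.a420, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.a420.shape:
            raise ValueError("time and a420 must be 1D arrays of equal length")
        if self.time.size < 3:
            raise ValueError("a kinetic trace needs at least three points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.a420))):
            raise ValueError("trace contains non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KineticTrace":
        """Build from a long-format frame (columns well, strain, time_min, a420)."""
        well = str(df["well"].iloc[0])
        strain = str(df["strain"].iloc[0])
        df = df.sort_values("time_min")
        return cls(well, strain, df["time_min"].to_numpy(), df["a420"].to_numpy())


@dataclass
class LinearFit:
    """OLS fit over the retained linear range of a trace."""

    slope: float
    intercept: float
    r: float
    n_used: int
    retained_mask: np.ndarray
    trimmed_points: list[int] = field(default_factory=list)


def _pearson_fit(t: np.ndarray, a: np.ndarray):
    res = stats.linregress(t, a)
    return res.slope, res.intercept, res.rvalue


def fit_linear_range(
    trace: KineticTrace,
    r_min: float = 0.999,
    min_points: int = 5,
    strategy: str = "trailing_first",
) -> LinearFit:
    """Trim trace ends until the OLS fit reaches ``r >= r_min``.

    Points are removed one at a time from the ends of the series (curvature
    in these assays lives at the ends: substrate-depletion saturation late,
    mixing lag early), so the retained range is always contiguous.
    ``trailing_first`` drops the last point whenever doing so improves r and
    falls back to the leading point otherwise; ``best_improvement`` always
    drops whichever end yields the larger r, preferring the trailing end on
    ties.

    A trace that already satisfies ``r >= r_min`` is returned untrimmed.
    Otherwise points are eliminated until the threshold is reached, and then
    for as long as a further removal still strictly increases r — so on
    noiseless data the retained range is exactly the linear segment rather
    than the first window that scrapes past the threshold. Fails once fewer
    than ``min_points`` points would remain, reporting the best correlation
    achieved.
    """
    if strategy not in ("trailing_first", "best_improvement"):
        raise ValueError(f"unknown trimming strategy {strategy!r}")
    t, a = trace.time, trace.a420
    n = t.size
    if min_points < 3:
        raise ValueError("min_points must be at least 3")
    lo, hi = 0, n  # retained window [lo, hi)

    def fit(lo_: int, hi_: int):
        if np.ptp(a[lo_:hi_]) == 0:
            return 0.0, float(a[lo_]), np.nan  # constant absorbance: r undefined
        return _pearson_fit(t[lo_:hi_], a[lo_:hi_])

    slope, icept, r = fit(lo, hi)
    best_r = r
    trimmed_any = False
    while True:
        reached = np.isfinite(r) and r >= r_min
        if reached and not trimmed_any:
            break  # already acceptable without any elimination
        if hi - lo <= min_points:
            if reached:
                break
            raise ValueError(
                f"could not reach r >= {r_min} with >= {min_points} points "
                f"(best r = {best_r if np.isfinite(best_r) else float('nan'):.6f})"
            )
        _, _, r_trail = fit(lo, hi - 1)
        _, _, r_lead = fit(lo + 1, hi)
        r_trail = -np.inf if not np.isfinite(r_trail) else r_trail
        r_lead = -np.inf if not np.isfinite(r_lead) else r_lead
        if strategy == "trailing_first":
            drop_trailing = r_trail > r or r_trail >= r_lead
        else:
            drop_trailing = r_trail >= r_lead
        candidate_r = r_trail if drop_trailing else r_lead
        # improvements at float resolution do not count: without the tolerance
        # the polish phase could nibble exactly-linear points on r ~ 1 ties
        if reached and not (np.isfinite(r) and candidate_r > r + 1e-12):
            break  # local optimum of linearity at or past the threshold
        if drop_trailing:
            hi -= 1
        else:
            lo += 1
        trimmed_any = True
        slope, icept, r = fit(lo, hi)
        if np.isfinite(r):
            best_r = max(best_r, r)
    mask = np.zeros(n, dtype=bool)
    mask[lo:hi] = True
    trace.retained_mask = mask
    return LinearFit(
        slope=float(slope),
        intercept=float(icept),
        r=float(r),
        n_used=hi - lo,
        retained_mask=mask,
        trimmed_points=list(range(0, lo)) + list(range(hi, n)),
    )


@dataclass
class ActivitySpec:
    """Physical constants converting an absorbance slope to µmol/min.

    ``epsilon``: molar extinction coefficient of the oxidized ABTS radical at
    420 nm (M^-1 cm^-1, literature value 36,000). ``path_length``: optical
    path of 200 µL in a flat-bottom 96-well plate (cm). ``reaction_volume``
    and ``supernatant_volume`` in liters (200 µL reaction containing 20 µL
    culture supernatant).
    """

    epsilon: float = 36_000.0
    path_length: float = 0.58
    reaction_volume: float = 2.0e-4
    supernatant_volume: float = 2.0e-5

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_length", "reaction_volume", "supernatant_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def activity_from_slope(fit: LinearFit | float, spec: ActivitySpec | None = None,
                        per_supernatant: bool = False) -> float:
    """Beer-Lambert conversion of an A420 slope to µmol oxidized ABTS / min.

    ``slope / (epsilon * path_length)`` is the molar production rate (M/min);
    multiplied by the reaction volume and 1e6 it becomes µmol/min in the
    well. With ``per_supernatant=True`` the value is rescaled by
    ``reaction_volume / supernatant_volume`` to express it per volume of
    undiluted supernatant.
    """
    spec = spec or ActivitySpec()
    slope = fit.slope if isinstance(fit, LinearFit) else float(fit)
    if slope < 0:
        raise ValueError("negative slope: oxidized ABTS cannot disappear")
    activity = slope / (spec.epsilon * spec.path_length) * spec.reaction_volume * 1e6
    if per_supernatant:
        activity *= spec.reaction_volume / spec.supernatant_volume
    return activity


def normalize_and_fold(
    activities: pd.DataFrame, reference_strain: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OD600-normalize per-replicate activities and compute fold changes.

    ``activities`` needs columns ``strain_id, replicate, activity, od600``.
    Returns ``(per_replicate, per_strain)``: the first adds
    ``normalized_activity`` and the second holds each strain's mean, sd and
    ``fold_change`` = mean(strain normalized) / mean(reference normalized).
    """
    required = {"strain_id", "replicate", "activity", "od600"}
    missing = required - set(activities.columns)
    if missing:
        raise ValueError(f"activity table is missing columns: {sorted(missing)}")
    df = activities.copy()
    od = df["od600"].to_numpy(dtype=float)
    if np.any(~np.isfinite(od)) or np.any(od <= 0):
        raise ValueError("every replicate needs a positive, finite OD600")
    df["normalized_activity"] = df["activity"] / df["od600"]
    if reference_strain not in set(df["strain_id"]):
        raise ValueError(f"reference strain {reference_strain!r} not in table")
    ref_mean = df.loc[df["strain_id"] == reference_strain, "normalized_activity"].mean()
    if ref_mean == 0:
        raise ValueError("reference strain has zero mean normalized activity")
    summary = (
        df.groupby("strain_id", sort=False)["normalized_activity"]
        .agg(["count", "mean", "std"])
        .reset_index()
        .rename(columns={"count": "n", "mean": "mean_normalized", "std": "sd_normalized"})
    )
    summary["fold_change"] = summary["mean_normalized"] / ref_mean
    df["fold_change"] = df["strain_id"].map(
        dict(zip(summary["strain_id"], summary["fold_change"]))
    )
    return df, summary


def p_to_stars(p: float) -> str:
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_groups(groups: dict[str, np.ndarray] | pd.DataFrame,
               value_col: str = "normalized_activity") -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        return {
            str(s): sub[value_col].to_numpy(dtype=float)
            for s, sub in groups.groupby("strain_id", sort=False)
        }
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def anova_dunnett(
    groups: dict[str, np.ndarray] | pd.DataFrame, reference: str, seed: int = 0
) -> pd.DataFrame:
    """One-way ANOVA followed by Dunnett many-to-one comparisons.

    Every non-reference group is compared against the reference; p-values are
    adjusted for the family of comparisons (two-sided). Returns one row per
    comparison with the group mean, t statistic, adjusted p and the standard
    significance stars (<0.05 *, <0.01 **, <0.005 ***).
    """
    data = _as_groups(groups)
    if reference not in data:
        raise ValueError(f"reference group {reference!r} missing")
    others = {k: v for k, v in data.items() if k != reference}
    if not others:
        raise ValueError("need at least one non-reference group")
    for name, vals in data.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than two replicates")
    if all(np.ptp(v) == 0 for v in data.values()):
        raise ValueError("zero within-group variance everywhere: test undefined")
    f_stat, f_p = stats.f_oneway(*data.values())
    # the multivariate-t integration is quasi-random; seed it for repeatable p
    res = stats.dunnett(*others.values(), control=data[reference], rng=seed)
    rows = []
    for i, (name, vals) in enumerate(others.items()):
        p = float(res.pvalue[i])
        rows.append(
            {
                "strain_id": name,
                "n": vals.size,
                "mean": float(vals.mean()),
                "statistic": float(res.statistic[i]),
                "p_adj": p,
                "stars": p_to_stars(p),
                "anova_F": float(f_stat),
                "anova_p": float(f_p),
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(groups: dict[str, np.ndarray] | pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey's all-pairs comparisons."""
    data = _as_groups(groups)
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for name, vals in data.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than two replicates")
    if all(np.ptp(v) == 0 for v in data.values()):
        raise ValueError("zero within-group variance everywhere: test undefined")
    f_stat, f_p = stats.f_oneway(*data.values())
    res = stats.tukey_hsd(*data.values())
    names = list(data)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "strain_a": names[i],
                    "strain_b": names[j],
                    "p_adj": p,
                    "stars": p_to_stars(p),
                    "anova_F": float(f_stat),
                    "anova_p": float(f_p),
                }
            )
    return pd.DataFrame(rows)


def delta_delta_ct(
    sample_target_ct: float,
    sample_reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
):
    """qPCR relative expression by the ΔΔCt method: fold = 2^-ΔΔCt.

    ΔΔCt = (Ct_target - Ct_refgene)_sample - (Ct_target - Ct_refgene)_calibrator.
    Accepts scalars or arrays; all Ct values must be finite.
    """
    cts = [np.asarray(v, dtype=float) for v in (
        sample_target_ct, sample_reference_ct, calibrator_target_ct, calibrator_reference_ct
    )]
    if any(not np.all(np.isfinite(c)) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    fold = 2.0 ** (-ddct)
    return float(fold) if np.isscalar(sample_target_ct) or np.ndim(fold) == 0 else fold
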