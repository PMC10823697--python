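"""Self-contained recovery benchmarks on fully synthetic inputs.

These drive the complete pipeline — image rendering, densitometry, scoring,
hit calling, kinetic fitting, fold-change statistics — against planted
ground truth and report recovery metrics. They are what a user runs to
convince themselves the chain works before pointing it at real data.
"""

from __future__ import annotations

import numpy as np

from . import kinetics, screen, synthetic
from .pipeline import quantify_plates


def run_synthetic_screen(
    seed: int = 0,
    n_plates: int = 4,
    n_replicates: int = 3,
    n_positives_per_plate: int = 6,
    effect: float = 3.0,
    site_cv: float = 0.10,
    z_threshold: float = 2.5,
    min_replicates: int = 2,
) -> dict:
    """Simulate a multi-plate colony screen and measure hit recovery.

    Every plate carries ``n_positives_per_plate`` strains with a planted
    expression effect, a few empty (no-growth) sites, the edge artifact, a
    background field, per-site biological noise of CV ``site_cv`` redrawn in
    every replicate, and pixel noise. Growth flags for the empty sites are
    applied as a manual-inspection table would be. Returns sensitivity over
    planted positives and the false-positive rate over null strains.
    """
    rng = np.random.default_rng(seed)
    config = synthetic.SimulationConfig(site_cv=site_cv)
    layouts = synthetic.make_screen_layouts(
        n_plates,
        n_positives_per_plate=n_positives_per_plate,
        effect=effect,
        seed=int(rng.integers(2**31)),
    )
    grid = synthetic.default_grid(layouts[0], config)
    frames = []
    planted: set[str] = set()
    null_strains: set[str] = set()
    for p, layout in enumerate(layouts):
        planted |= set(layout.planted_effects)
        empties = set(layout.empty_positions)
        null_strains |= {
            layout.strain_at(r, c)
            for r in range(layout.n_rows)
            for c in range(layout.n_cols)
            if layout.strain_at(r, c) not in layout.planted_effects
            and (r, c) not in empties
        }
        blanks = [
            synthetic.simulate_blank_plate(config, seed=int(rng.integers(2**31)))
            for _ in range(3)
        ]
        images = [
            synthetic.simulate_plate_image(
                layout,
                config,
                seed=int(rng.integers(2**31)),
                plate_id=f"plate{p + 1:02d}",
                replicate_id=rep,
            )[0]
            for rep in range(1, n_replicates + 1)
        ]
        flags = {
            (f"plate{p + 1:02d}", rep): {pos: 0 for pos in layout.empty_positions}
            for rep in range(1, n_replicates + 1)
        }
        flag_frames = {
            key: _flags_frame(table) for key, table in flags.items()
        }
        frames.append(
            quantify_plates(images, blanks, grid, layout, flag_frames)
        )
    import pandas as pd

    sites = pd.concat(frames, ignore_index=True)
    scores, hits = screen.score_screen(
        sites, threshold=z_threshold, min_replicates=min_replicates
    )
    called_pos = set(hits.loc[hits["call"] == "positive", "strain_id"])
    tp = len(called_pos & planted)
    fp = len(called_pos & null_strains)
    return {
        "n_planted": len(planted),
        "n_null": len(null_strains),
        "n_called_positive": len(called_pos),
        "true_positives": tp,
        "false_positives": fp,
        "sensitivity": tp / len(planted),
        "false_positive_rate": fp / len(null_strains),
        "scores": scores,
        "hits": hits,
    }


def _flags_frame(table: dict):
    import pandas as pd

    return pd.DataFrame(
        {
            "row": [r for r, _ in table],
            "col": [c for _, c in table],
            "growth_flag": list(table.values()),
        }
    )


def run_fold_recovery(
    effects: dict[str, float],
    n_seeds: int = 100,
    n_replicates: int = 3,
    cv: float = 0.10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean recovered fold change per strain over ``n_seeds`` simulated studies."""
    rng = np.random.default_rng(seed)
    sums = {k: 0.0 for k in effects}
    for _ in range(n_seeds):
        study = synthetic.simulate_activity_study(
            len(effects), effects, n_replicates=n_replicates, cv=cv,
            seed=int(rng.integers(2**31)),
        )
        _, summary = kinetics.normalize_and_fold(study, "reference")
        idx = summary.set_index("strain_id")
        for k in effects:
            sums[k] += float(idx.loc[k, "fold_change"])
    return {k: v / n_seeds for k, v in sums.items()}
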