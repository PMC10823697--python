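"""Linear-range fitting, Beer-Lambert activity, fold changes and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laccscreen import (
    ActivitySpec,
    KineticTrace,
    activity_from_slope,
    anova_dunnett,
    anova_tukey,
    delta_delta_ct,
    fit_linear_range,
    normalize_and_fold,
    simulate_activity_study,
    simulate_kinetic_trace,
)


def trace_from(slope, intercept, linear_until, total, noise=0.0, seed=0):
    df = simulate_kinetic_trace(slope, intercept, linear_until, total,
                                noise_sd=noise, seed=seed)
    return KineticTrace.from_frame(df)


class TestFitLinearRange:
    def test_perfect_line_untrimmed(self):
        fit = fit_linear_range(trace_from(0.02, 0.05, 120, 120))
        assert fit.trimmed_points == []
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.02, abs=1e-12)

    def test_plateau_trimmed_from_trailing_end(self):
        """Saturation after 60 min: trailing points go, slope exact to 1e-9."""
        fit = fit_linear_range(trace_from(0.02, 0.05, 60, 120))
        assert fit.slope == pytest.approx(0.02, abs=1e-9)
        assert fit.r >= 0.999
        assert all(i > 60 for i in fit.trimmed_points)  # only trailing removals
        assert fit.retained_mask[:5].all()

    def test_constant_trace_is_degenerate(self):
        tr = KineticTrace("w", "s", np.arange(10.0), np.full(10, 0.3))
        with pytest.raises(ValueError, match="could not reach"):
            fit_linear_range(tr)

    def test_unreachable_r_reports_best(self):
        rng = np.random.default_rng(0)
        tr = KineticTrace("w", "s", np.arange(12.0), rng.uniform(0, 1, 12))
        with pytest.raises(ValueError, match="best r"):
            fit_linear_range(tr, r_min=0.99999)

    def test_min_points_floor_respected(self):
        fit = fit_linear_range(trace_from(0.02, 0.05, 60, 120), min_points=5)
        assert fit.n_used >= 5

    def test_strategy_validation(self):
        with pytest.raises(ValueError, match="strategy"):
            fit_linear_range(trace_from(0.02, 0.05, 120, 120), strategy="nope")

    def test_noisy_linear_slope_within_three_se(self):
        """On data linear within noise, the estimate stays within 3 SE of
        truth in essentially all of 1000 simulations."""
        hits = 0
        for seed in range(1000):
            tr = trace_from(0.02, 0.05, 120, 120, noise=0.003, seed=seed)
            fit = fit_linear_range(tr)
            res = stats.linregress(tr.time[fit.retained_mask], tr.a420[fit.retained_mask])
            if abs(fit.slope - 0.02) <= 3 * res.stderr:
                hits += 1
        assert hits / 1000 >= 0.985

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            KineticTrace("w", "s", np.array([0.0, 2.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError, match="three"):
            KineticTrace("w", "s", np.array([0.0, 1.0]), np.zeros(2))


class TestActivityFromSlope:
    def test_worked_beer_lambert_example(self):
        """0.036 AU/min, eps 36000, l 0.58 cm, 200 uL -> 3.448e-4 umol/min."""
        activity = activity_from_slope(0.0360, ActivitySpec())
        assert activity == pytest.approx(0.036 / 20880 * 2e-4 * 1e6, rel=1e-12)
        assert activity == pytest.approx(3.448e-4, rel=1e-3)

    def test_zero_slope_zero_activity(self):
        assert activity_from_slope(0.0) == 0.0

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            activity_from_slope(-0.01)

    def test_homogeneity_in_slope_epsilon_and_path(self):
        base = activity_from_slope(0.02, ActivitySpec())
        assert activity_from_slope(0.04, ActivitySpec()) == pytest.approx(2 * base)
        assert activity_from_slope(0.02, ActivitySpec(epsilon=72000)) == pytest.approx(base / 2)
        assert activity_from_slope(0.02, ActivitySpec(path_length=1.16)) == pytest.approx(base / 2)

    def test_per_supernatant_rescaling(self):
        spec = ActivitySpec()
        ratio = spec.reaction_volume / spec.supernatant_volume
        assert activity_from_slope(0.02, spec, per_supernatant=True) == pytest.approx(
            ratio * activity_from_slope(0.02, spec)
        )


class TestNormalizeAndFold:
    def table(self):
        return pd.DataFrame(
            {
                "strain_id": ["ref"] * 3 + ["a"] * 3,
                "replicate": [1, 2, 3] * 2,
                "activity": [1.0, 1.2, 0.8, 2.0, 2.4, 1.6],
                "od600": [1.0] * 6,
            }
        )

    def test_equal_means_fold_one(self):
        df = self.table()
        df.loc[df["strain_id"] == "a", "activity"] = [1.0, 1.2, 0.8]
        _, summary = normalize_and_fold(df, "ref")
        assert summary.set_index("strain_id").loc["a", "fold_change"] == pytest.approx(1.0)

    def test_fold_change_ratio_of_means(self):
        _, summary = normalize_and_fold(self.table(), "ref")
        assert summary.set_index("strain_id").loc["a", "fold_change"] == pytest.approx(2.0)

    def test_od_scaling_cancels(self):
        df = self.table()
        doubled = df.copy()
        doubled["activity"] *= 2
        doubled["od600"] *= 2
        _, s1 = normalize_and_fold(df, "ref")
        _, s2 = normalize_and_fold(doubled, "ref")
        pd.testing.assert_frame_equal(s1, s2)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_and_fold(self.table(), "nope")

    def test_bad_od_rejected(self):
        df = self.table()
        df.loc[0, "od600"] = 0.0
        with pytest.raises(ValueError, match="OD600"):
            normalize_and_fold(df, "ref")

    def test_planted_folds_recovered_from_simulated_study(self):
        """Simulation oracle: planted effects come back within sampling error."""
        effects = {"ski3": 5.3, "arv1": 5.0, "pmt2": 4.3, "flat": 1.0}
        folds = {k: [] for k in effects}
        for seed in range(20):
            study = simulate_activity_study(4, effects, n_replicates=3, cv=0.1, seed=seed)
            _, summary = normalize_and_fold(study, "reference")
            for k in effects:
                folds[k].append(summary.set_index("strain_id").loc[k, "fold_change"])
        for k, planted in effects.items():
            assert np.mean(folds[k]) == pytest.approx(planted, rel=0.10)


def mc_dunnett_pvalues(groups, control, n_draws=100_000, seed=0):
    """Monte-Carlo max-|t| null for Dunnett comparisons (independent oracle)."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    n_c = len(control)
    n_total = sum(sizes) + n_c
    df = n_total - len(sizes) - 1

    def tstats(samples, ctrl):
        means = [s.mean(axis=-1) for s in samples]
        cmean = ctrl.mean(axis=-1)
        ss = sum(((s - m[..., None]) ** 2).sum(axis=-1) for s, m in zip(samples, means))
        ss = ss + ((ctrl - cmean[..., None]) ** 2).sum(axis=-1)
        sp = np.sqrt(ss / df)
        return np.stack(
            [
                (m - cmean) / (sp * np.sqrt(1 / n + 1 / n_c))
                for m, n in zip(means, sizes)
            ],
            axis=-1,
        )

    obs = tstats([np.asarray(g)[None, :] for g in groups],
                 np.asarray(control)[None, :])[0]
    null = tstats([rng.normal(size=(n_draws, n)) for n in sizes],
                  rng.normal(size=(n_draws, n_c)))
    max_null = np.abs(null).max(axis=1)
    return np.array([(max_null >= abs(t)).mean() for t in obs])


class TestAnovaDunnett:
    def test_identical_groups_nonsignificant(self):
        g = np.array([1.0, 1.1, 0.9, 1.05])
        res = anova_dunnett({"ref": g, "a": g, "b": g}, "ref")
        assert np.all(res["p_adj"] >= 0.999)

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(1)
        a, ref = rng.normal(1.4, 0.2, 4), rng.normal(1.0, 0.2, 4)
        res = anova_dunnett({"ref": ref, "a": a}, "ref")
        t = stats.ttest_ind(a, ref, equal_var=True)
        # scipy evaluates the k=1 multivariate-t tail by quasi-random
        # integration, so agreement is to quadrature precision
        assert res.loc[0, "p_adj"] == pytest.approx(t.pvalue, abs=1e-3)

    def test_matches_monte_carlo_max_t_oracle(self):
        """Adjusted p agrees with a 1e5-draw max-|t| null within 0.005."""
        groups = {
            "ref": np.array([1.00, 0.92, 1.05]),
            "a": np.array([1.35, 1.18, 1.28]),
            "b": np.array([1.05, 0.98, 1.22]),
            "c": np.array([0.80, 0.95, 0.88]),
        }
        res = anova_dunnett(groups, "ref")
        mc = mc_dunnett_pvalues(
            [groups["a"], groups["b"], groups["c"]], groups["ref"], seed=11
        )
        assert np.allclose(res["p_adj"], mc, atol=0.005)

    def test_adjusted_p_at_least_unadjusted_and_monotone(self):
        rng = np.random.default_rng(2)
        groups = {"ref": rng.normal(1, 0.1, 4)}
        for i, shift in enumerate([0.0, 0.1, 0.2, 0.3]):
            groups[f"g{i}"] = rng.normal(1 + shift, 0.1, 4)
        res = anova_dunnett(groups, "ref")
        df = sum(len(v) for v in groups.values()) - len(groups)
        unadjusted = 2 * stats.t.sf(np.abs(res["statistic"]), df)
        assert np.all(res["p_adj"] >= unadjusted - 1e-12)
        order = res.sort_values("statistic", key=np.abs)["p_adj"].to_numpy()
        assert np.all(np.diff(order) <= 1e-12)

    def test_stars_at_standard_cutpoints(self):
        from laccscreen.kinetics import p_to_stars

        assert p_to_stars(0.04) == "*"
        assert p_to_stars(0.009) == "**"
        assert p_to_stars(0.004) == "***"
        assert p_to_stars(0.5) == "ns"

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_dunnett({"ref": np.ones(3), "a": np.full(3, 2.0)}, "ref")


class TestAnovaTukey:
    def test_identical_groups_nonsignificant(self):
        g = np.array([1.0, 1.1, 0.9, 1.05])
        res = anova_tukey({"a": g, "b": g, "c": g})
        assert np.all(res["p_adj"] >= 0.999)

    def test_two_groups_match_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1.4, 0.2, 5), rng.normal(1.0, 0.2, 5)
        res = anova_tukey({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.loc[0, "p_adj"] == pytest.approx(t.pvalue, abs=1e-6)

    def test_matches_studentized_range_monte_carlo(self):
        """Pairwise adjusted p agrees with a max-range null within 0.005."""
        groups = {
            "a": np.array([1.00, 0.92, 1.05, 0.97]),
            "b": np.array([1.30, 1.18, 1.28, 1.22]),
            "c": np.array([1.05, 0.98, 1.22, 1.10]),
        }
        res = anova_tukey(groups)
        arrays = list(groups.values())
        n = 4
        k = 3
        df = k * (n - 1)
        rng = np.random.default_rng(7)
        draws = rng.normal(size=(100_000, k, n))
        means = draws.mean(axis=2)
        sp = np.sqrt(((draws - means[..., None]) ** 2).sum(axis=(1, 2)) / df)
        qmax = (means.max(axis=1) - means.min(axis=1)) / (sp / np.sqrt(n))
        obs_sp = np.sqrt(sum(((g - g.mean()) ** 2).sum() for g in arrays) / df)
        for rec in res.itertuples():
            qa = abs(groups[rec.strain_a].mean() - groups[rec.strain_b].mean())
            q_obs = qa / (obs_sp / np.sqrt(n))
            p_mc = float((qmax >= q_obs).mean())
            assert rec.p_adj == pytest.approx(p_mc, abs=0.005)


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "sample,calibrator,expected",
        [
            ((20.0, 15.0), (20.0, 15.0), 1.0),  # ddCt = 0
            ((19.0, 15.0), (20.0, 15.0), 2.0),  # ddCt = -1
            ((20.0, 15.0), (22.0, 15.0), 4.0),  # ddCt = -2
        ],
    )
    def test_fold_from_ct_values(self, sample, calibrator, expected):
        fold = delta_delta_ct(sample[0], sample[1], calibrator[0], calibrator[1])
        assert fold == pytest.approx(expected, rel=1e-12)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            delta_delta_ct(np.nan, 15.0, 20.0, 15.0)
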