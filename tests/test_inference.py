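import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import probene as pb
from probene import DesignError, DomainError

from conftest import MC_SEED, make_records


def _per_group_ols(records, group, scale="raw"):
    """Independent oracle: plain least squares on one group's points."""
    df = pb.ExperimentRecord  # noqa: F841 (documentation only)
    xs, ys = [], []
    for r in records:
        if r.strain == group:
            xs.append(pb.to_analysis_scale(r.density, scale))
            ys.append(r.outcome)
    X = np.column_stack([np.ones(len(xs)), xs])
    coef, *_ = np.linalg.lstsq(X, np.array(ys), rcond=None)
    return coef  # (a, b)


class TestDensityVariation:
    def test_identical_groups_show_no_variation(self):
        recs = make_records(
            {"A": [(d, 0) for d in (1, 2, 3, 4)], "B": [(d, 0) for d in (1, 2, 3, 4)]}
        )
        fit = pb.test_density_variation(recs, "strain", scale="raw")
        assert fit.term_tests["strain"].pvalue == pytest.approx(1.0)
        assert fit.property_label == "proliferation"

    def test_separated_groups_show_proliferation_variation(self, rng):
        a = 2 + rng.normal(0, 1e-3, 4)
        b = 6 + rng.normal(0, 1e-3, 4)
        recs = make_records(
            {"A": [(d, 0) for d in a], "B": [(d, 0) for d in b]}
        )
        fit = pb.test_density_variation(recs, "strain", scale="raw")
        assert fit.term_tests["strain"].pvalue < 1e-6
        assert fit.summary_for("B").c_bar > fit.summary_for("A").c_bar

    def test_matches_hand_rolled_sums_of_squares(self, rng):
        # 3 host types, n=10 each, mean densities {2, 4, 8}, sd 0.5
        groups = {"hA": 2.0, "hB": 4.0, "hC": 8.0}
        recs = []
        data = {}
        for h, mu in groups.items():
            d = mu + 0.5 * rng.standard_normal(10)
            d = np.abs(d)
            data[h] = d
            recs += [pb.ExperimentRecord(h, "s", float(x), 0.0) for x in d]
        fit = pb.test_density_variation(recs, "host_type", scale="raw")

        # oracle: one-way decomposition of sums of squares by hand
        allv = np.concatenate(list(data.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in data.values())
        F = (ssb / 2) / (ssw / (30 - 3))
        p = stats.f.sf(F, 2, 27)
        t = fit.term_tests["host_type"]
        assert t.statistic == pytest.approx(F, rel=1e-10)
        assert t.pvalue == pytest.approx(p, rel=1e-10)
        assert fit.property_label == "resistance"

    def test_single_group_is_design_error(self):
        recs = make_records({"A": [(1, 0), (2, 0)]})
        with pytest.raises(DesignError):
            pb.test_density_variation(recs, "strain", scale="raw")

    def test_zero_within_group_variance_flagged(self):
        recs = make_records({"A": [(2, 0)] * 4, "B": [(6, 0)] * 4})
        fit = pb.test_density_variation(recs, "strain", scale="raw")
        assert "zero_within_group_variance" in fit.flags
        assert math.isnan(fit.term_tests["strain"].pvalue)


class TestSlopeVariation:
    def test_exact_fixture_recovers_per_group_lines(self, exact_two_strain):
        fit = pb.test_slope_variation(exact_two_strain, "strain", scale="raw")
        a_line, b_line = fit.line_for("A"), fit.line_for("B")
        assert a_line.b == pytest.approx(-1.0, abs=1e-10)
        assert a_line.a == pytest.approx(10.0, abs=1e-10)
        assert b_line.b == pytest.approx(0.0, abs=1e-10)
        assert b_line.a == pytest.approx(10.0, abs=1e-10)
        # saturated-model lines equal independent per-group least squares
        for g in ("A", "B"):
            a_o, b_o = _per_group_ols(exact_two_strain, g)
            line = fit.line_for(g)
            assert line.a == pytest.approx(a_o, abs=1e-9)
            assert line.b == pytest.approx(b_o, abs=1e-9)

    def test_equal_slopes_zero_noise_degenerate_p(self):
        recs = make_records(
            {
                "A": [(d, 10 - d) for d in (1, 2, 3, 4)],
                "B": [(d, 12 - d) for d in (1, 2, 3, 4)],
            }
        )
        fit = pb.test_slope_variation(recs, "strain", scale="raw")
        assert fit.line_for("A").b == pytest.approx(fit.line_for("B").b, abs=1e-10)
        assert math.isnan(fit.interaction_p)
        assert "degenerate_p_zero_residual_variance" in fit.flags

    def test_interaction_p_matches_separate_fit_contrast_oracle(self, rng):
        # 2 strains, true slope difference 1, n=50/strain, sigma=1
        n = 50
        recs = []
        parts = {}
        for strain, b in (("A", -1.0), ("B", 0.0)):
            d = rng.normal(4, 1, n)
            h = 10 + b * d + rng.standard_normal(n)
            parts[strain] = (d, h)
            recs += [
                pb.ExperimentRecord("h", strain, float(x), float(y))
                for x, y in zip(np.abs(d), h)
            ]
        fit = pb.test_slope_variation(recs, "strain", scale="raw")

        # oracle: separate per-group OLS, pooled variance, slope contrast t
        slopes, sxx, ssr = {}, {}, {}
        for g, (d, h) in parts.items():
            X = np.column_stack([np.ones(n), d])
            coef, res, *_ = np.linalg.lstsq(X, h, rcond=None)
            slopes[g] = coef[1]
            sxx[g] = ((d - d.mean()) ** 2).sum()
            ssr[g] = float(res[0])
        s2 = (ssr["A"] + ssr["B"]) / (2 * n - 4)
        se = math.sqrt(s2 * (1 / sxx["A"] + 1 / sxx["B"]))
        t = (slopes["A"] - slopes["B"]) / se
        p_oracle = 2 * stats.t.sf(abs(t), 2 * n - 4)
        assert fit.interaction_p == pytest.approx(p_oracle, rel=1e-9)

    def test_health_shift_changes_only_intercepts(self, rng):
        recs = pb.simulate_experiment(pb.make_preset("fig2_strains", seed=MC_SEED))
        shifted = [
            pb.ExperimentRecord(r.host_type, r.strain, r.density, r.outcome + 100.0)
            for r in recs
        ]
        f0 = pb.test_slope_variation(recs, "strain")
        f1 = pb.test_slope_variation(shifted, "strain")
        assert f1.interaction_p == pytest.approx(f0.interaction_p, rel=1e-9)
        for g in ("benevolent", "neutral", "malevolent"):
            assert f1.line_for(g).b == pytest.approx(f0.line_for(g).b, abs=1e-9)
            assert f1.line_for(g).a == pytest.approx(f0.line_for(g).a + 100.0, abs=1e-7)
            assert f1.summary_for(g).c_bar == pytest.approx(f0.summary_for(g).c_bar)

    def test_invariant_to_relabelling_and_row_order(self, rng):
        recs = pb.simulate_experiment(pb.make_preset("null", seed=MC_SEED + 1))
        f0 = pb.test_slope_variation(recs, "strain")
        relabel = {"wt": "zzz", "ko": "aaa"}
        perm = rng.permutation(len(recs))
        recs2 = [
            pb.ExperimentRecord(
                recs[i].host_type, relabel[recs[i].strain], recs[i].density, recs[i].outcome
            )
            for i in perm
        ]
        f1 = pb.test_slope_variation(recs2, "strain")
        assert f1.interaction_p == pytest.approx(f0.interaction_p, rel=1e-9)
        assert f1.line_for("zzz").b == pytest.approx(f0.line_for("wt").b, abs=1e-9)

    def test_constant_density_in_group_names_group(self):
        recs = make_records(
            {"A": [(1, 9), (2, 8), (3, 7)], "B": [(2, 10), (2, 9), (2, 11)]}
        )
        with pytest.raises(DesignError, match="B"):
            pb.test_slope_variation(recs, "strain", scale="raw")

    def test_poor_overlap_downgrades_result(self):
        recs = make_records(
            {
                "A": [(1, 9), (1.5, 8.6), (2, 8)],
                "B": [(5, 10), (5.5, 10.1), (6, 10)],
            }
        )
        fit = pb.test_slope_variation(recs, "strain", scale="raw")
        assert any(f.startswith("unreliable_slope_comparison") for f in fit.flags)

    def test_missing_values_excluded_and_counted(self):
        df = pd.DataFrame(
            {
                "host_type": ["h"] * 8,
                "strain": ["A"] * 4 + ["B"] * 4,
                "density": [1, 2, 3, np.nan, 1, 2, 3, 4],
                "outcome": [9, 8, 7, 6, 10, np.nan, 10, 10],
                "outcome_kind": ["continuous"] * 8,
            }
        )
        fit = pb.test_slope_variation(df, "strain", scale="raw")
        assert fit.n_obs == 6
        assert fit.n_excluded == 2


class TestBinaryOutcome:
    def test_all_survivors_is_degenerate(self):
        recs = make_records(
            {"A": [(1, 1), (2, 1), (3, 1)], "B": [(1, 1), (2, 1), (3, 1)]},
            outcome_kind="binary",
        )
        with pytest.raises(DesignError):
            pb.fit_binary_outcome(recs, "strain", scale="raw")

    def test_slopes_reported_on_log_odds_scale(self, rng):
        cells = tuple(
            pb.CellParams("h", s, a=5.0, b=-1.5, mu_density=3.5, sd_density=1.0, n=200)
            for s in ("A", "B")
        )
        sc = pb.SimulationScenario(
            cells=cells, sigma_health=1.0, outcome_kind="binary", seed=MC_SEED
        )
        fit = pb.fit_binary_outcome(pb.simulate_experiment(sc), "strain")
        assert "log-odds" in fit.property_label
        for g in ("A", "B"):
            line = fit.line_for(g)
            assert abs(line.b - (-1.5)) < 2.5 * line.se_b  # recovers truth

    def test_complete_separation_flagged_with_fallback(self):
        # survival perfectly determined by density: monotone likelihood
        recs = make_records(
            {
                "A": [(d, 1 if d < 3 else 0) for d in (1, 1.5, 2, 2.5, 3.5, 4, 4.5, 5)],
                "B": [(d, 1 if d < 3 else 0) for d in (1.2, 1.7, 2.2, 2.7, 3.6, 4.1, 4.6, 5.1)],
            },
            outcome_kind="binary",
        )
        fit = pb.fit_binary_outcome(recs, "strain", scale="raw")
        assert "complete_separation" in fit.flags
        assert "penalized_fallback" in fit.flags
        assert math.isnan(fit.interaction_p)

    def test_continuous_records_rejected(self, exact_two_strain):
        with pytest.raises(DomainError):
            pb.fit_binary_outcome(exact_two_strain, "strain", scale="raw")


class TestQuadraticExtension:
    def test_exact_parabola_recovered(self):
        # h = 10 - (c - 3)^2 on c in 1..5, zero noise, two identical strains
        pts = [(c, 10 - (c - 3) ** 2) for c in (1, 2, 3, 4, 5)]
        recs = make_records({"A": pts, "B": pts})
        fit = pb.fit_quadratic_extension(recs, "strain", scale="raw")
        assert fit.group_quadratic["A"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.group_quadratic["B"] == pytest.approx(-1.0, abs=1e-9)

    def test_exact_line_has_zero_curvature(self):
        recs = make_records(
            {
                "A": [(c, 10 - c) for c in (1, 2, 3, 4, 5)],
                "B": [(c, 8 - 2 * c) for c in (1, 2, 3, 4, 5)],
            }
        )
        fit = pb.fit_quadratic_extension(recs, "strain", scale="raw")
        assert fit.group_quadratic["A"] == pytest.approx(0.0, abs=1e-8)
        assert fit.group_quadratic["B"] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_distinct_densities_is_design_error(self):
        recs = make_records(
            {"A": [(1, 9), (2, 8), (1, 9.1), (2, 8.1)], "B": [(1, 9), (2, 8), (3, 7)]}
        )
        with pytest.raises(DesignError, match="A"):
            pb.fit_quadratic_extension(recs, "strain", scale="raw")

    def test_curvature_detected_on_simulated_quadratic(self, rng):
        cells = tuple(
            pb.CellParams("h", s, a=10, b=0.0, quad=-0.5, mu_density=4, sd_density=1, n=60)
            for s in ("A", "B")
        )
        sc = pb.SimulationScenario(cells=cells, sigma_health=1.0, seed=MC_SEED)
        fit = pb.fit_quadratic_extension(pb.simulate_experiment(sc), "strain")
        assert fit.term_tests["curvature"].pvalue < 0.01


class TestCombinedFactorial:
    def _scenario(self, hs_effect=0.0, n=30, seed=MC_SEED):
        cells = []
        for h in ("hA", "hB"):
            for s in ("s1", "s2"):
                mu = 4.0 + (hs_effect if (h, s) == ("hB", "s2") else 0.0)
                cells.append(
                    pb.CellParams(h, s, a=10, b=-1, mu_density=mu, sd_density=1, n=n)
                )
        return pb.SimulationScenario(cells=tuple(cells), sigma_health=1.0, seed=seed)

    def test_additive_data_drops_screen_interaction(self):
        res = pb.fit_combined_factorial(pb.simulate_experiment(self._scenario()))
        assert not res.interaction_retained
        assert "host_type:strain" in res.density_model.term_tests
        assert res.health_model.term_tests["strain:density"].pvalue > 0  # present

    def test_strong_cell_effect_retains_screen_interaction(self):
        res = pb.fit_combined_factorial(
            pb.simulate_experiment(self._scenario(hs_effect=2.0))
        )
        assert res.interaction_retained
        assert "outcome_depends_on_host_strain_combination" in res.flags

    def test_single_strain_is_design_error(self):
        cells = tuple(
            pb.CellParams(h, "s1", a=10, b=-1, mu_density=4, sd_density=1, n=10)
            for h in ("hA", "hB")
        )
        sc = pb.SimulationScenario(cells=cells, sigma_health=1.0, seed=1)
        with pytest.raises(DesignError):
            pb.fit_combined_factorial(pb.simulate_experiment(sc))

    def test_empty_cell_is_design_error_listing_cell(self):
        sc = self._scenario()
        cells = tuple(c for c in sc.cells if not (c.host_type == "hB" and c.strain == "s2"))
        sc2 = pb.SimulationScenario(cells=cells, sigma_health=1.0, seed=2)
        with pytest.raises(DesignError, match="hB"):
            pb.fit_combined_factorial(pb.simulate_experiment(sc2))

    def test_serializes_to_json(self):
        res = pb.fit_combined_factorial(pb.simulate_experiment(self._scenario()))
        import json

        doc = json.loads(res.to_json())
        assert doc["schema_version"] == 1
        assert "density_model" in doc and "health_model" in doc


def test_mixed_outcome_kinds_rejected():
    recs = make_records({"A": [(1, 9), (2, 8)]}) + make_records(
        {"B": [(1, 1), (2, 0)]}, outcome_kind="binary"
    )
    with pytest.raises(DomainError):
        pb.test_density_variation(recs, "strain", scale="raw")
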