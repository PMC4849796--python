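import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seapatch.errors import SchemaError, ValidationError
from seapatch.hierarchy_path import (
    DEFAULT_LEVELS,
    Hierarchy,
    assign_tier,
    between_level_edges,
    fit_path_model,
    render_edge_list,
    to_dot,
    within_level_edges,
)
from seapatch.synthetic_data import simulate_path_system


def _default_table(rng, n=41):
    names = [v for _, vs in DEFAULT_LEVELS for v in vs]
    return pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)


class TestTiers:
    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.0005, "strong"),
            (0.005, "mid"),
            (0.03, "weak"),
            (0.05, "weak"),
            (0.07, "marginal"),
            (0.1, "ns"),
            (0.8, "ns"),
        ],
    )
    def test_band_boundaries(self, p, tier):
        assert assign_tier(p) == tier


class TestWithinLevelEdges:
    def test_single_variable_level_has_no_edges(self, rng):
        table = _default_table(rng)
        assert within_level_edges(["wind_modulus"], table) == []

    def test_perfect_negative_pair(self, rng):
        x = rng.normal(size=41)
        table = pd.DataFrame({"x": x, "y": -x})
        (edge,) = within_level_edges(["x", "y"], table)
        assert edge.coefficient == pytest.approx(-1.0)
        assert edge.tier == "strong" and edge.sign == "negative"

    def test_direction_symmetric(self, rng):
        table = _default_table(rng)
        (ab,) = within_level_edges(["mean_sst_c", "mean_sss"], table)
        (ba,) = within_level_edges(["mean_sss", "mean_sst_c"], table)
        assert ab.coefficient == pytest.approx(ba.coefficient)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_builtin_correlation_recovered_within_sampling_band(self, rng):
        # r = -0.4 at n = 41: Fisher-z 95% band is about +/- 0.25
        cov = np.array([[1.0, -0.4], [-0.4, 1.0]])
        draws = rng.multivariate_normal([0, 0], cov, size=41)
        table = pd.DataFrame(draws, columns=["sst", "sss"])
        (edge,) = within_level_edges(["sst", "sss"], table)
        assert edge.coefficient == pytest.approx(-0.4, abs=0.25)

    def test_missing_variable_is_schema_error(self, rng):
        with pytest.raises(SchemaError):
            within_level_edges(["nope", "gx"], _default_table(rng))


class TestBetweenLevelEdges:
    def test_exact_copy_gives_unit_coefficient(self, rng):
        u = rng.normal(size=41)
        table = pd.DataFrame({"u": u, "y": u.copy()})
        (edge,) = between_level_edges(["y"], ["u"], table)
        assert edge.coefficient == pytest.approx(1.0, abs=1e-10)
        assert edge.tier == "strong"
        assert edge.from_var == "u" and edge.to_var == "y"

    def test_single_predictor_equals_pearson_r(self, rng):
        table = _default_table(rng)
        (edge,) = between_level_edges(["wind_modulus"], ["delta_atm_pressure_mb"], table)
        r = stats.pearsonr(table["wind_modulus"], table["delta_atm_pressure_mb"])
        assert edge.coefficient == pytest.approx(r.statistic, abs=1e-10)

    def test_signal_and_noise_predictors_separate(self, rng):
        hits_signal, hits_noise_ns = 0, 0
        reps = 40
        for _ in range(reps):
            n = 500
            u1, u2 = rng.normal(size=n), rng.normal(size=n)
            y = 0.8 * u1 + 0.6 * rng.normal(size=n)
            table = pd.DataFrame({"u1": u1, "u2": u2, "y": y})
            edges = {e.from_var: e for e in between_level_edges(["y"], ["u1", "u2"], table)}
            hits_signal += abs(edges["u1"].coefficient - 0.8) <= 0.1
            hits_noise_ns += edges["u2"].tier == "ns"
        assert hits_signal >= 0.95 * reps
        assert hits_noise_ns >= 0.8 * reps

    def test_too_few_rows_rejected(self, rng):
        table = _default_table(rng, n=3)
        with pytest.raises(ValidationError):
            between_level_edges(["gx"], ["mean_sst_c", "mean_sss"], table)

    def test_collinear_upper_set_warns_but_reports(self, rng):
        u = rng.normal(size=41)
        table = pd.DataFrame({"u1": u, "u2": u + 1e-9 * rng.normal(size=41),
                              "y": u + rng.normal(size=41)})
        edges = between_level_edges(["y"], ["u1", "u2"], table)
        assert len(edges) == 2
        assert all("collinear" in e.warning for e in edges)


class TestFitPathModel:
    def test_default_structure_edge_counts(self, rng):
        model = fit_path_model(Hierarchy(), _default_table(rng))
        # within-level pairs: C(3,2) at level I plus one pair at II, III, IV, VI, IX
        assert len(model.within_edges()) == 3 + 5
        # between-level: sum of |lower| x |adjacent upper| over the 8 level gaps
        sizes = [len(vs) for _, vs in DEFAULT_LEVELS]
        expected = sum(a * b for a, b in zip(sizes, sizes[1:]))
        assert len(model.between_edges()) == expected == 23

    def test_two_level_toy(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 2)), columns=["y", "u"])
        model = fit_path_model(Hierarchy((("I", ("y",)), ("II", ("u",)))), table)
        assert len(model.edges) == 1
        assert model.edges[0].kind == "between_level"

    def test_deterministic(self, rng):
        table = _default_table(rng)
        m1 = fit_path_model(Hierarchy(), table)
        m2 = fit_path_model(Hierarchy(), table)
        assert [e.coefficient for e in m1.edges] == [e.coefficient for e in m2.edges]

    def test_duplicate_variable_rejected(self):
        with pytest.raises(ValidationError):
            Hierarchy((("I", ("x", "y")), ("II", ("x",))))


class TestPathRecovery:
    WEIGHTS = {
        ("mean_sst_c", "gx"): 0.4,
        ("mean_sss", "moran_i"): -0.5,
        ("uw6_36", "mean_sst_c"): -0.6,
        ("uw6_39", "mean_sss"): 0.5,
        ("uwm_36", "uw6_36"): 0.5,
        ("uwm_39", "uw6_39"): 0.5,
        ("wind_modulus", "uwm_36"): 0.4,
        ("zonal_wind", "wind_modulus"): 0.6,
        ("meridional_wind", "wind_modulus"): -0.5,
        ("delta_atm_pressure_mb", "zonal_wind"): 0.3,
        ("atm_pressure_mb", "delta_atm_pressure_mb"): 0.4,
        ("pdo", "atm_pressure_mb"): 0.5,
        ("npgo", "atm_pressure_mb"): -0.3,
    }

    def test_population_partials_match_unit_variance_weights(self, rng):
        # with independent unit parents and one parent per child, the
        # standardized partial is w * sd(parent)/sd(child)
        table, truth = simulate_path_system(
            Hierarchy((("I", ("y",)), ("II", ("u",)))), {("u", "y"): 0.8},
            n=10, rng=rng, noise_sd=0.6,
        )
        assert truth[("u", "y")] == pytest.approx(0.8 / np.hypot(0.8, 0.6))

    def test_recovers_generating_partials_at_n500(self, rng):
        table, truth = simulate_path_system(
            Hierarchy(), self.WEIGHTS, n=500, rng=rng, noise_sd=0.8
        )
        model = fit_path_model(Hierarchy(), table)
        n = len(table)
        # compare each fitted coefficient to the population partial within
        # a generous sampling band ~ 3.5/sqrt(n)
        for e in model.between_edges():
            assert e.coefficient == pytest.approx(
                truth[(e.from_var, e.to_var)], abs=3.5 / np.sqrt(n)
            )

    def test_skip_level_dependency_produces_no_skip_edge(self, rng):
        weights = dict(self.WEIGHTS)
        weights[("pdo", "gx")] = 0.7  # level IX feeding level I directly
        table, _ = simulate_path_system(Hierarchy(), weights, n=300, rng=rng)
        model = fit_path_model(Hierarchy(), table)
        level_of = {v: i for i, (_, vs) in enumerate(Hierarchy().levels) for v in vs}
        for e in model.between_edges():
            assert level_of[e.from_var] - level_of[e.to_var] == 1


class TestRendering:
    def test_edge_list_round_trip(self, tmp_path, rng):
        model = fit_path_model(Hierarchy(), _default_table(rng))
        path = tmp_path / "edges.csv"
        render_edge_list(model, path)
        df = pd.read_csv(path)
        assert len(df) == len(model.edges)
        assert set(df.columns) >= {"from", "to", "kind", "coefficient", "p_value", "tier", "sign"}
        ns_rows = df[df["p_value"] >= 0.1]
        assert (ns_rows["tier"] == "ns").all()

    def test_empty_model_header_only(self, tmp_path, rng):
        table = pd.DataFrame({"y": rng.normal(size=10)})
        model = fit_path_model(Hierarchy((("I", ("y",)),)), table)
        path = tmp_path / "edges.csv"
        render_edge_list(model, path)
        assert pd.read_csv(path).empty

    def test_dot_marks_ns_dashed_and_negative_grey(self, rng):
        x = rng.normal(size=41)
        table = pd.DataFrame({"y": -x + 0.01 * rng.normal(size=41), "u": x})
        model = fit_path_model(Hierarchy((("I", ("y",)), ("II", ("u",)))), table)
        dot = to_dot(model)
        assert "color=grey" in dot
        assert "digraph" in dot
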