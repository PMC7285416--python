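import warnings

import numpy as np
import pytest

from megax import (
    MulticollinearityError,
    SimulationTruth,
    StudyEffect,
    ValidationError,
    default_study_grid,
    fit_mlr,
    simulate_effect_table,
)


def effects_from_lfcs(grid, lfcs, gene="G"):
    return [
        StudyEffect(study_id=s.study_id, gene=gene, lfc=float(l), se=0.2,
                    n_control=s.n_control, n_case=s.n_case)
        for s, l in zip(grid, lfcs)
    ]


class TestFitMLR:
    def test_noiseless_numeric_factor_recovered(self):
        grid = default_study_grid(8)
        effects = effects_from_lfcs(grid, [0.1 * s.study_age_years for s in grid])
        res = fit_mlr(effects, grid, ["study_age"])
        assert res.coefficients["study_age"] == pytest.approx(0.1, abs=1e-10)
        assert res.factor_p["study_age"] < 1e-10
        assert res.r2 == pytest.approx(1.0)

    def test_categorical_factor_gets_joint_p(self):
        grid = default_study_grid(9, country=["A", "A", "A", "B", "B", "B", "C", "C", "C"])
        shifts = {"A": 0.0, "B": -1.0, "C": 1.0}
        effects = effects_from_lfcs(grid, [shifts[s.country] for s in grid])
        res = fit_mlr(effects, grid, ["country"])
        assert set(res.factor_p) == {"country"}
        assert res.factor_p["country"] < 1e-8
        assert res.coefficients["country_B"] == pytest.approx(-1.0, abs=1e-10)

    def test_study_order_permutation_invariant(self):
        grid = default_study_grid(10, country=["A", "B"] * 5)
        rng = np.random.default_rng(1)
        effects = effects_from_lfcs(grid, rng.normal(0, 1, 10))
        a = fit_mlr(effects, grid, ["study_age", "country"])
        b = fit_mlr(effects[::-1], list(reversed(grid)), ["study_age", "country"])
        assert a == b

    def test_coefficients_match_normal_equations(self):
        """Independent oracle: solve (X'X) beta = X'y directly."""
        from megax import StudyMetadata

        rng0 = np.random.default_rng(0)
        grid = [
            StudyMetadata(
                study_id=f"SIM{i + 1:03d}",
                n_control=int(rng0.integers(5, 60)),
                n_case=int(rng0.integers(5, 60)),
                country=["A", "B", "C"][i % 3],
                study_age_years=float(i + 1),
            )
            for i in range(12)
        ]
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 12)
        effects = effects_from_lfcs(grid, y)
        res = fit_mlr(effects, grid, ["n_total", "study_age", "country"])
        order = np.argsort([s.study_id for s in grid])
        X = []
        for i in order:
            s = grid[i]
            X.append([1.0, s.n_total, s.study_age_years,
                      1.0 * (s.country == "B"), 1.0 * (s.country == "C")])
        X = np.array(X)
        beta = np.linalg.solve(X.T @ X, X.T @ y[order])
        got = [res.coefficients[c] for c in ("const", "n_total", "study_age", "country_B", "country_C")]
        np.testing.assert_allclose(got, beta, atol=1e-10)

    def test_aliased_terms_reported(self):
        grid = default_study_grid(8)
        effects = effects_from_lfcs(grid, np.linspace(0, 1, 8))
        with pytest.raises(MulticollinearityError) as exc:
            fit_mlr(effects, grid, ["n_total", "n_control"])  # n_case constant => aliased
        assert exc.value.aliased

    def test_saturated_design_refused(self):
        grid = default_study_grid(4, country=["A", "B", "C", "D"])
        effects = effects_from_lfcs(grid, [0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            fit_mlr(effects, grid, ["country", "study_age"])

    def test_low_residual_df_warns(self):
        grid = default_study_grid(5, country=["A", "B", "A", "B", "A"])
        effects = effects_from_lfcs(grid, [0.1, -0.2, 0.3, 0.0, -0.1])
        with pytest.warns(UserWarning, match="residual df"):
            fit_mlr(effects, grid, ["study_age", "country"])

    def test_unknown_factor_rejected(self):
        grid = default_study_grid(6)
        with pytest.raises(ValidationError, match="unknown factor"):
            fit_mlr(effects_from_lfcs(grid, np.zeros(6)), grid, ["smoking"])


class TestCalibration:
    GRID = default_study_grid(11, 30, 30, country=["B" if i in (0, 5, 10) else "A" for i in range(11)])

    def test_null_type_i_error_near_nominal(self):
        """No covariate effects: per-factor rejection at alpha=0.05 should sit
        in [0.03, 0.07] over 500 replicates."""
        rej = {"study_age": 0, "country": 0}
        reps = 500
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(reps):
                truth = SimulationTruth(gene_truth={"G": -0.5}, tau2=0.2, seed=300_000 + rep)
                effects = simulate_effect_table(truth, self.GRID)
                res = fit_mlr(effects, self.GRID, ["study_age", "country"])
                for f in rej:
                    rej[f] += res.factor_p[f] < 0.05
        for f, count in rej.items():
            assert 0.03 <= count / reps <= 0.07, f

    def test_injected_country_shift_detected(self):
        """Country shift of -1.0 on 3 of 11 studies, tau2=0.05: joint country
        p < 0.05 in at least 80% of replicates."""
        hits = 0
        reps = 500
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(reps):
                truth = SimulationTruth(
                    gene_truth={"G": 0.0}, tau2=0.05,
                    covariate_effects={"country": {"B": -1.0}}, seed=400_000 + rep,
                )
                effects = simulate_effect_table(truth, self.GRID)
                res = fit_mlr(effects, self.GRID, ["study_age", "country"])
                hits += res.factor_p["country"] < 0.05
        assert hits / reps >= 0.80
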