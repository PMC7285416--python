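import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megax import (
    InsufficientStudiesError,
    MegaAnalysis,
    SimulationTruth,
    ValidationError,
    default_study_grid,
    heterogeneity,
    mega_analyze,
    partial_mega_analyze,
    pool,
    select_top_datasets,
    simulate_effect_table,
)
from conftest import make_effects


class TestHeterogeneity:
    def test_hand_worked_example(self, two_study_effects):
        h = heterogeneity(two_study_effects)
        assert h.Q == pytest.approx(8.0, abs=1e-10)
        assert h.df == 1
        assert h.ISq_pct == pytest.approx(87.5, abs=1e-10)
        assert h.tau2 == pytest.approx(1.75, abs=1e-10)

    def test_equal_effects_have_zero_dispersion(self):
        h = heterogeneity(make_effects([2.0, 2.0, 2.0]))
        assert h.Q == 0.0 and h.ISq_pct == 0.0 and h.tau2 == 0.0

    def test_q_below_df_truncates_to_zero(self):
        h = heterogeneity(make_effects([1.0, 1.1], [2.0, 2.0]))
        assert h.Q < h.df
        assert h.ISq_pct == 0.0 and h.tau2 == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            heterogeneity(make_effects([1.0]))

    def test_nonpositive_se_rejected(self):
        effects = make_effects([1.0, 2.0])
        bad = [effects[0], effects[1].__class__(**{**effects[1].__dict__, "se": 0.0, "degenerate": True})]
        with pytest.raises(ValidationError):
            heterogeneity(bad)


class TestPooling:
    def test_fixed_inverse_variance_example(self, two_study_effects):
        res = pool(two_study_effects, "fixed")
        assert res.pooled_lfc == pytest.approx(2.0, abs=1e-12)
        assert res.se == pytest.approx(1 / math.sqrt(8.0), abs=1e-12)
        assert res.ci95[0] == pytest.approx(2.0 - 1.959964 * res.se, abs=1e-5)

    def test_repeated_effect_pools_to_itself_under_both_models(self):
        effects = make_effects([2.0, 2.0, 2.0])
        for model in ("fixed", "random"):
            assert pool(effects, model).pooled_lfc == pytest.approx(2.0)

    def test_random_with_zero_tau2_equals_fixed(self):
        effects = make_effects([1.0, 1.05, 0.95], [1.0, 1.0, 1.0])
        assert heterogeneity(effects).tau2 == 0.0
        f, r = pool(effects, "fixed"), pool(effects, "random")
        assert r.pooled_lfc == pytest.approx(f.pooled_lfc, abs=1e-14)
        assert r.se == pytest.approx(f.se, abs=1e-14)

    def test_weights_normalized_to_max_one(self, two_study_effects):
        res = pool(two_study_effects, "fixed")
        assert max(res.weights.values()) == 1.0
        assert all(w > 0 for w in res.weights.values())

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.05, 3)),
            min_size=2, max_size=4,
        )
    )
    def test_matches_brute_force_weighted_mean(self, pairs):
        """Independent oracle: explicit weighted mean over per-study terms."""
        effects = make_effects([p[0] for p in pairs], [p[1] for p in pairs])
        for model in ("fixed", "random"):
            res = pool(effects, model)
            tau2 = res.het.tau2 if model == "random" else 0.0
            w = [1.0 / (se**2 + tau2) for _, se in pairs]
            oracle = sum(wi * y for wi, (y, _) in zip(w, pairs)) / sum(w)
            assert res.pooled_lfc == pytest.approx(oracle, abs=1e-12)
            assert res.se == pytest.approx(1.0 / math.sqrt(sum(w)), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.tuples(st.floats(-3, 3), st.floats(0.1, 2)), min_size=3, max_size=6),
        st.floats(0.1, 10),
    )
    def test_scale_equivariance(self, pairs, c):
        """Scaling all effects and SEs by c scales the estimate; p unchanged."""
        effects = make_effects([p[0] for p in pairs], [p[1] for p in pairs])
        scaled = make_effects([c * p[0] for p in pairs], [c * p[1] for p in pairs])
        a, b = mega_analyze(effects), mega_analyze(scaled)
        assert b.model == a.model
        assert b.pooled_lfc == pytest.approx(c * a.pooled_lfc, rel=1e-9, abs=1e-12)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-6, abs=1e-12)

    def test_random_effects_matches_metafor(self):
        """Cross-check DL pooling against the r-metafor reference."""
        lfc = [0.3, -0.5, 1.2, 0.8, -0.1]
        se = [0.2, 0.3, 0.25, 0.4, 0.15]
        res = pool(make_effects(lfc, se), "random")
        rcode = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, lfc))}), sei=c({','.join(map(str, se))}),"
            " method='DL', test='z');"
            "cat(sprintf('%.12g', c(r$b, r$se, r$tau2, r$QE, r$pval)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        ).stdout.split()
        b, s, tau2, Q, p = map(float, out)
        assert res.pooled_lfc == pytest.approx(b, abs=1e-6)
        assert res.se == pytest.approx(s, abs=1e-6)
        assert res.het.tau2 == pytest.approx(tau2, abs=1e-6)
        assert res.het.Q == pytest.approx(Q, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)


class TestModelSelection:
    def test_heterogeneous_input_selects_random(self, two_study_effects):
        assert mega_analyze(two_study_effects).model == "random"

    def test_homogeneous_input_selects_fixed(self):
        effects = make_effects([1.0, 1.1], [2.0, 2.0])
        assert mega_analyze(effects).model == "fixed"

    def test_high_tau2_usually_selects_random(self):
        grid = default_study_grid(11, 30, 30)
        chosen = 0
        reps = 500
        for rep in range(reps):
            truth = SimulationTruth(gene_truth={"G": 0.0}, tau2=0.6, seed=700_000 + rep)
            chosen += mega_analyze(simulate_effect_table(truth, grid)).model == "random"
        assert chosen / reps >= 0.95


class TestTopDatasetSelection:
    def test_eleven_studies_at_half_keeps_five(self):
        effects = make_effects(list(np.linspace(-2, 2, 11)))
        assert len(select_top_datasets(effects, 0.5)) == 5

    def test_largest_absolute_effects_kept(self):
        effects = make_effects([3.0, 1.0, -2.0, 0.5])
        kept = select_top_datasets(effects, 0.5)
        assert [e.lfc for e in kept] == [3.0, -2.0]

    def test_tie_keeps_earlier_study(self):
        effects = make_effects([3.0, 2.0, -2.0, 0.5])
        kept = select_top_datasets(effects, 0.5)
        assert [e.study_id for e in kept] == ["S1", "S2"]

    def test_too_small_subset_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            select_top_datasets(make_effects([1.0, 2.0, 3.0]), 0.5)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            select_top_datasets(make_effects([1.0, 2.0]), 0.0)


class TestPartialMegaAnalysis:
    def test_homogeneous_top_subset_selects_fixed(self):
        # top half identical and strong; the rest scattered
        effects = make_effects([-2.0, -2.0, -2.0, 0.1, -0.3, 0.2])
        res = partial_mega_analyze(effects, 0.5)
        assert res.het.Q == pytest.approx(0.0, abs=1e-12)
        assert res.model == "fixed"
        assert set(res.studies_used) == {"S1", "S2", "S3"}

    def test_fraction_one_is_identity(self):
        effects = make_effects([1.0, -0.5, 0.3, 2.0])
        assert partial_mega_analyze(effects, 1.0) == mega_analyze(effects)

    def test_subset_signal_sharpens_pooled_effect(self):
        """5 strongly negative + 6 null studies: the top-half pool is more
        negative than the full pool."""
        grid = default_study_grid(11, 30, 30, country=["B"] * 5 + ["A"] * 6)
        truth = SimulationTruth(
            gene_truth={"G": 0.0}, tau2=0.01,
            covariate_effects={"country": {"B": -1.5}}, seed=11,
        )
        effects = simulate_effect_table(truth, grid)
        full = mega_analyze(effects)
        part = partial_mega_analyze(effects, 0.5)
        assert part.pooled_lfc < full.pooled_lfc < 0.1

    def test_null_selection_inflates_magnitude(self):
        """Documented selection bias: under delta=0 with heterogeneity, the
        partial pool's |LFC| is stochastically larger than the full pool's."""
        grid = default_study_grid(11, 30, 30)
        wins = 0
        reps = 2000
        for rep in range(reps):
            truth = SimulationTruth(gene_truth={"G": 0.0}, tau2=0.3, seed=800_000 + rep)
            effects = simulate_effect_table(truth, grid)
            wins += abs(partial_mega_analyze(effects, 0.5).pooled_lfc) > abs(
                mega_analyze(effects).pooled_lfc
            )
        # stochastically larger: the partial |LFC| exceeds the full |LFC| in
        # a clear majority of null replicates
        assert wins / reps > 0.6


class TestParameterRecovery:
    def test_tau2_estimate_unbiased_at_k50(self):
        grid = default_study_grid(50, 30, 30)
        estimates = []
        for rep in range(2000):
            truth = SimulationTruth(gene_truth={"G": 0.5}, tau2=0.2, seed=200_000 + rep)
            estimates.append(heterogeneity(simulate_effect_table(truth, grid)).tau2)
        assert np.mean(estimates) == pytest.approx(0.2, rel=0.10)


class TestModelObject:
    def test_from_dataframe_round_trip(self, two_study_effects):
        import pandas as pd

        df = pd.DataFrame(
            {
                "study_id": [e.study_id for e in two_study_effects],
                "gene": [e.gene for e in two_study_effects],
                "lfc": [e.lfc for e in two_study_effects],
                "se": [e.se for e in two_study_effects],
                "n_control": [e.n_control for e in two_study_effects],
                "n_case": [e.n_case for e in two_study_effects],
            }
        )
        model = MegaAnalysis.from_dataframe(df, gene="G")
        assert model.fit("fixed") == pool(two_study_effects, "fixed")

    def test_summary_and_forest_frame(self, two_study_effects):
        res = MegaAnalysis(two_study_effects).fit()
        assert "random-effects" in res.summary()
        frame = res.forest_frame()
        assert list(frame["study_id"]) == ["S1", "S2"]
        assert (frame["ci_high"] > frame["ci_low"]).all()
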