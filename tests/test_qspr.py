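"""Simple-OLS QSPR layer: fit statistics and model ranking."""

import io

import numpy as np
import pytest

from mpolytop.qspr import (
    DegeneratePredictorError,
    PropertyTable,
    fit_simple,
    model_report,
    rank_models,
)
from mpolytop.synthetic_data import noisy_linear_table


class TestFitSimple:
    def test_exact_line(self):
        x = np.arange(1.0, 8.0)
        fit = fit_simple(x, 2 * x + 1)
        assert fit.R == pytest.approx(1.0)
        assert fit.R2 == pytest.approx(1.0)
        assert fit.RMSE == pytest.approx(0.0, abs=1e-10)
        assert fit.adjR2 == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # hand-computed OLS on (0,0), (1,1), (2,1)
        fit = fit_simple([0, 1, 2], [0, 1, 1])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1 / 6)
        assert fit.R2 == pytest.approx(3 / 4)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        fit = fit_simple(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.R2 == pytest.approx(r**2, rel=1e-12)
        assert fit.R == pytest.approx(abs(r), rel=1e-12)

    def test_rmse_is_residual_standard_error(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 1.0])
        fit = fit_simple(x, y)
        # SSE = 1/6 on this triple; RSE = sqrt(SSE / (n-2))
        assert fit.RMSE == pytest.approx(np.sqrt((1 / 6) / 1))
        pop = fit_simple(x, y, population_rmse=True)
        assert pop.RMSE == pytest.approx(np.sqrt((1 / 6) / 3))

    def test_negative_slope_reports_positive_R(self):
        x = np.arange(1.0, 10.0)
        fit = fit_simple(x, -3 * x + 2)
        assert fit.slope < 0 and fit.R == pytest.approx(1.0)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            fit = fit_simple(x, y)
            assert fit.adjR2 <= fit.R2 + 1e-12

    def test_shuffling_rows_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(size=12)
        fit = fit_simple(x, y)
        perm = rng.permutation(12)
        shuffled = fit_simple(x[perm], y[perm])
        for fieldname in ("slope", "intercept", "R", "R2", "RMSE", "adjR2"):
            assert getattr(fit, fieldname) == pytest.approx(
                getattr(shuffled, fieldname), rel=1e-10
            )

    def test_constant_x_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_simple([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_simple([1, 2, 3], [1, 2])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_simple([1, 2], [1, 2])


class TestParameterRecovery:
    def test_noiseless_table_recovers_exactly(self):
        table = noisy_linear_table(8, 93.33, 3.098, 0.0, seed=1)
        x, y = table.complete_pairs("Y", "X")
        fit = fit_simple(x, y)
        assert fit.intercept == pytest.approx(93.33)
        assert fit.slope == pytest.approx(3.098)
        assert fit.R == pytest.approx(1.0)
        assert fit.RMSE == pytest.approx(0.0, abs=1e-9)

    def test_noisy_table_recovers_within_three_se(self):
        beta1 = 3.0
        table = noisy_linear_table(8, 10.0, beta1, 0.5, seed=7)
        x, y = table.complete_pairs("Y", "X")
        fit = fit_simple(x, y)
        se = fit.RMSE / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - beta1) < 3 * se


class TestPropertyTable:
    def test_duplicate_compounds_rejected(self):
        csv = "compound,Y,X\na,1,1\na,2,2\nb,3,3\n"
        with pytest.raises(ValueError):
            PropertyTable.from_csv(io.StringIO(csv), ["Y"])

    def test_missing_cells_dropped_per_pair(self):
        csv = "compound,Y,X\na,1,1\nb,,2\nc,3,3\nd,4,4\n"
        table = PropertyTable.from_csv(io.StringIO(csv), ["Y"])
        x, y = table.complete_pairs("Y", "X")
        assert len(x) == 3


class TestModelReport:
    def test_perfect_pair_equation(self):
        table = noisy_linear_table(6, 1.0, 2.0, 0.0, seed=0)
        row = model_report(table, "Y", "X")
        assert not row.skipped
        assert row.equation == "Y = 1 + 2*X"
        assert row.fit.R == pytest.approx(1.0)

    def test_all_missing_descriptor_skipped(self):
        csv = "compound,Y,X\na,1,\nb,2,\nc,3,\n"
        table = PropertyTable.from_csv(io.StringIO(csv), ["Y"])
        row = model_report(table, "Y", "X")
        assert row.skipped and "complete pairs" in row.reason


class TestRankModels:
    @staticmethod
    def _two_relation_table(seed=0):
        rng = np.random.default_rng(seed)
        import pandas as pd

        x = np.arange(1.0, 11.0)
        df = pd.DataFrame(
            {
                "D1": x,
                "D2": rng.permutation(x),  # scrambled: near-null relation
                "P": 2 * x + 1,
            },
            index=pd.Index([f"c{i}" for i in range(10)], name="compound"),
        )
        return PropertyTable(data=df, properties=("P",), descriptors=("D1", "D2"))

    def test_threshold_filters(self):
        table = self._two_relation_table()
        kept = rank_models(table, threshold_R=0.85)
        assert [r.descriptor for r in kept] == ["D1"]

    def test_impossible_threshold_empty(self):
        assert rank_models(self._two_relation_table(), threshold_R=1.1) == []

    def test_ranking_follows_noise_level(self):
        import pandas as pd

        rng = np.random.default_rng(21)
        x = np.arange(1.0, 13.0)
        df = pd.DataFrame(
            {
                "X": x,
                "tight": 3 * x + rng.normal(0, 0.1, 12),
                "loose": 3 * x + rng.normal(0, 2.0, 12),
            },
            index=pd.Index([f"c{i}" for i in range(12)], name="compound"),
        )
        table = PropertyTable(
            data=df, properties=("tight", "loose"), descriptors=("X",)
        )
        ranked = rank_models(table, threshold_R=0.0)
        assert [r.property for r in ranked] == ["tight", "loose"]
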