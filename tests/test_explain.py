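"""Kernel SHAP and the cohort-level explanation summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecgscar.explain import (
    Explanation,
    kernel_shap,
    summarize_components,
    top_feature_frequency,
    welch_compare,
)
from ecgscar.registry import VECTOR_COLUMNS


def exact_shapley(f, background, x):
    """Brute-force Shapley values with background-mean imputation (d <= 12)."""
    d = x.size
    phi = np.zeros(d)

    def v(subset):
        m = np.zeros(d)
        m[list(subset)] = 1.0
        blend = m * x + (1 - m) * background
        return float(np.mean(f(blend)))

    for j in range(d):
        others = [i for i in range(d) if i != j]
        for r in range(d):
            for S in itertools.combinations(others, r):
                w = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
                phi[j] += w * (v(S + (j,)) - v(S))
    return phi


class TestKernelShap:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.d = 8
        self.bg = rng.normal(size=(20, self.d))
        self.w = rng.normal(size=self.d)
        self.x = rng.normal(size=self.d)

    def test_linear_model_closed_form(self):
        f = lambda X: X @ self.w + 0.5
        e = kernel_shap(f, self.bg, self.x, n_coalitions=2048, seed=0)
        expected = self.w * (self.x - self.bg.mean(axis=0))
        assert np.abs(e.phi - expected).max() < 1e-6
        assert e.local_accuracy_gap() < 1e-9

    def test_enumeration_matches_exact_shapley_on_nonlinear_model(self):
        f = lambda X: X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + X @ self.w
        e = kernel_shap(f, self.bg, self.x, n_coalitions=2048, seed=0)
        assert np.abs(e.phi - exact_shapley(f, self.bg, self.x)).max() < 1e-9

    def test_sampled_coalitions_match_exact_within_tolerance(self):
        f = lambda X: X[:, 0] * X[:, 1] + np.sin(X[:, 2]) + X @ self.w
        e = kernel_shap(
            f, self.bg, self.x, n_coalitions=200_000, seed=0, force_sampling=True
        )
        assert np.abs(e.phi - exact_shapley(f, self.bg, self.x)).max() <= 1e-3

    def test_ignored_feature_gets_zero_attribution(self):
        f = lambda X: 2.0 * X[:, 0]
        e = kernel_shap(f, self.bg, self.x, n_coalitions=2048, seed=0)
        assert np.abs(e.phi[1:]).max() < 1e-9

    def test_local_accuracy_holds_for_arbitrary_model(self):
        f = lambda X: np.tanh(X).sum(axis=1) ** 2
        e = kernel_shap(f, self.bg, self.x, n_coalitions=500, seed=3)
        assert e.local_accuracy_gap() < 1e-9

    def test_symmetric_features_get_equal_attribution(self):
        bg = np.zeros((10, 4))
        x = np.array([1.0, 1.0, 0.3, -0.2])
        f = lambda X: X[:, 0] + X[:, 1] + 0.5 * X[:, 2] * X[:, 3]
        e = kernel_shap(f, bg, x, n_coalitions=2048, seed=0)
        assert e.phi[0] == pytest.approx(e.phi[1], abs=1e-9)

    def test_too_few_coalitions_rejected(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="n_coalitions"):
            kernel_shap(f, self.bg, self.x, n_coalitions=self.d)

    def test_empty_background_rejected(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="background"):
            kernel_shap(f, np.zeros((0, 8)), self.x)


def _explanation(phi, names=None):
    phi = np.asarray(phi, float)
    return Explanation(
        phi=phi, base_value=0.0, output_value=float(phi.sum()),
        feature_names=tuple(names) if names else tuple(VECTOR_COLUMNS[: phi.size]),
    )


class TestSummaries:
    def test_single_support_explanation_tops_component_ranking(self):
        phi = np.zeros(276)
        phi[VECTOR_COLUMNS.index("aVR_q_amplitude")] = 0.4
        df = summarize_components([_explanation(phi)])
        assert df.iloc[0]["component"] == "Q"
        assert df.iloc[0]["lead"] == "aVR"

    def test_duplicating_explanations_leaves_summary_unchanged(self):
        rng = np.random.default_rng(0)
        exps = [_explanation(rng.normal(size=276)) for _ in range(5)]
        a = summarize_components(exps)
        b = summarize_components(exps + exps)
        pd.testing.assert_frame_equal(a, b)

    def test_mixed_registries_rejected(self):
        e1 = _explanation(np.ones(276))
        e2 = Explanation(
            phi=np.ones(276), base_value=0, output_value=276,
            feature_names=tuple(reversed(VECTOR_COLUMNS)),
        )
        with pytest.raises(ValueError, match="registries"):
            summarize_components([e1, e2])

    def test_top20_marks_56_of_276_features(self):
        rng = np.random.default_rng(1)
        freq = top_feature_frequency([_explanation(rng.normal(size=276))])
        assert math.ceil(0.2 * 276) == 56
        assert (freq > 0).sum() == 56
        assert set(freq.unique()) <= {0.0, 1.0}

    def test_frequencies_average_over_predictions(self):
        phi1 = np.zeros(276); phi1[0] = 1.0
        phi2 = np.zeros(276); phi2[1] = 1.0
        freq = top_feature_frequency([_explanation(phi1), _explanation(phi2)])
        assert freq.iloc[0] == 1.0  # index 0 is top in one, tie-broken in other
        assert 0.0 <= freq.min() and freq.max() <= 1.0

    def test_magnitude_ties_break_by_registry_index(self):
        phi = np.ones(10)
        freq = top_feature_frequency([_explanation(phi, names=[f"f{i}" for i in range(10)])],
                                     quantile=0.2)
        assert freq.to_numpy().tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            top_feature_frequency([_explanation(np.ones(4))], quantile=1.0)


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        x = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array([1, 1, 1, 0, 0, 0])
        out = welch_compare(x, y)
        assert out.loc["f", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["f", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"f": np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])})
        y = np.concatenate([np.zeros(200), np.ones(200)])
        out = welch_compare(x, y)
        assert out.loc["f", "p"] < 1e-10

    def test_group_means_and_sds_reported(self):
        x = pd.DataFrame({"f": [0.0, 2.0, 10.0, 12.0]})
        y = np.array([0, 0, 1, 1])
        out = welch_compare(x, y)
        assert out.loc["f", "scar_mean"] == 11.0
        assert out.loc["f", "noscar_mean"] == 1.0

    def test_undersized_class_reports_nan(self):
        x = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        y = np.array([1, 0, 0])
        out = welch_compare(x, y)
        assert np.isnan(out.loc["f", "p"])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            welch_compare(pd.DataFrame({"f": [1.0, 2.0]}), np.array([0, 2]))
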