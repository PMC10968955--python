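"""Synthetic cohorts and the mixed-graphical-model Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exponet.exposome import score_cohort
from exponet.synthetic import (CohortSpec, GraphModelError,
                               GraphValidationError, TrueGraph,
                               generate_cohort, inject_dependence, sample_mgm)

BIG_N = 50_000


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(CohortSpec(n_respondents=BIG_N, seed=11))


def _vectorized_prevalences(df: pd.DataFrame) -> dict[str, float]:
    """Independent re-derivation of binarized prevalences from raw columns."""
    out = {}
    out["winter_birth"] = df["month"].isin([12, 1, 2]).mean()
    oc = df[["oc_csection", "oc_low_weight", "oc_preterm"]]
    any_yes = (oc == "yes").any(axis=1)
    any_dk = (oc == "dont_know").any(axis=1)
    observed = any_yes | ~any_dk
    out["obstetric_complications"] = any_yes[observed].mean()
    pa = df["paternal_age"].dropna()
    out["advanced_paternal_age"] = (pa >= 35).mean()
    out["non_right_handedness"] = (df["handedness"] != "right").mean()
    for comp in ("emotional_neglect", "emotional_abuse", "bullying", "sexual_abuse"):
        out[comp] = (df[comp] == "yes").mean()
    cpq = df[[f"cpq_{i:02d}" for i in range(1, 12)]]
    out["cannabis_use"] = (cpq == "yes").any(axis=1).mean()
    out["urban_upbringing"] = (df["residence"] != "rural").mean()
    return out


class TestCohortGeneration:
    def test_reproducible_given_seed(self):
        spec = CohortSpec(n_respondents=300, seed=5)
        pd.testing.assert_frame_equal(generate_cohort(spec), generate_cohort(spec))

    def test_different_seed_differs(self):
        a = generate_cohort(CohortSpec(n_respondents=300, seed=5))
        b = generate_cohort(CohortSpec(n_respondents=300, seed=6))
        assert not a.equals(b)

    def test_range_safety(self, big_cohort):
        df = big_cohort
        assert df["month"].between(1, 12).all()
        for scale, (lo, hi) in {"pq16": (0, 16), "gad7": (0, 21),
                                "phq9": (0, 27), "mdq": (0, 13),
                                "ocir": (0, 72), "asrs5": (0, 24)}.items():
            assert df[scale].between(lo, hi).all()
            assert (df[scale] == df[scale].round()).all()
        assert df["handedness"].isin(["right", "left", "mixed"]).all()
        assert df["residence"].isin(
            ["rural", "city_le_100k", "city_200k_500k", "city_gt_500k"]).all()
        assert df["age"].between(18, 35).all()

    def test_marginal_calibration_prevalences(self, big_cohort):
        spec = CohortSpec()
        prev = _vectorized_prevalences(big_cohort)
        for comp, target in spec.exposure_prevalences.items():
            assert prev[comp] == pytest.approx(target, abs=0.01), comp

    def test_marginal_calibration_symptom_means(self, big_cohort):
        for scale, (mean, sd, *_rng) in CohortSpec().symptom_marginals.items():
            assert big_cohort[scale].mean() == pytest.approx(mean, abs=0.2), scale
            assert big_cohort[scale].std() == pytest.approx(sd, rel=0.15), scale

    def test_missingness_rates(self, big_cohort):
        oc_all_unknown = (
            big_cohort[["oc_csection", "oc_low_weight", "oc_preterm"]]
            == "dont_know").all(axis=1).mean()
        assert oc_all_unknown == pytest.approx(0.215, abs=0.01)
        assert big_cohort["paternal_age"].isna().mean() == pytest.approx(0.182, abs=0.01)

    def test_mean_out_of_instrument_range_rejected(self):
        marg = dict(CohortSpec().symptom_marginals)
        marg["phq9"] = (30.0, 6.2, 0, 27)
        with pytest.raises(ValueError, match="phq9"):
            CohortSpec(symptom_marginals=marg)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(exposure_prevalences={**CohortSpec().exposure_prevalences,
                                             "bullying": 1.2})


class TestMGMSampler:
    def test_empty_graph_independence(self):
        g = TrueGraph([("a", "binary"), ("b", "binary")], np.zeros((2, 2)))
        ds = sample_mgm(g, BIG_N, burn_in=50, thin=5, seed=0)
        X = ds.values
        for j in range(2):
            assert X[:, j].mean() == pytest.approx(0.5, abs=0.01)
        assert abs(np.corrcoef(X.T)[0, 1]) < 0.02

    @pytest.mark.parametrize("theta", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_two_node_binary_matches_exact_enumeration(self, theta):
        # exact 4-state Boltzmann distribution: p(x1,x2) ∝ exp(theta x1 x2)
        g = TrueGraph([("a", "binary"), ("b", "binary")],
                      np.array([[0, theta], [theta, 0]]))
        ds = sample_mgm(g, BIG_N, burn_in=60, thin=5, seed=42)
        X = ds.values.astype(int)
        counts = np.bincount(X[:, 0] * 2 + X[:, 1], minlength=4)
        w = np.array([1.0, 1.0, 1.0, np.exp(theta)])
        expected = BIG_N * w / w.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=3)

    @pytest.mark.parametrize("rho", [-0.6, 0.3, 0.5])
    def test_two_continuous_matches_bivariate_normal(self, rho):
        # unit conditional variances: joint precision [[1,-rho],[-rho,1]],
        # hence marginal correlation exactly rho
        g = TrueGraph([("x", "continuous"), ("y", "continuous")],
                      np.array([[0, rho], [rho, 0]]))
        ds = sample_mgm(g, BIG_N, burn_in=60, thin=5, seed=7)
        assert np.corrcoef(ds.values.T)[0, 1] == pytest.approx(rho, abs=0.02)

    def test_deterministic_given_seed(self):
        g = TrueGraph([("x", "continuous"), ("b", "binary")],
                      np.array([[0, 0.4], [0.4, 0]]))
        a = sample_mgm(g, 500, burn_in=50, thin=2, seed=3)
        b = sample_mgm(g, 500, burn_in=50, thin=2, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_column_types_match_declaration(self):
        g = TrueGraph([("x", "continuous"), ("b", "binary")],
                      np.array([[0, 0.4], [0.4, 0]]))
        ds = sample_mgm(g, 500, burn_in=50, thin=2, seed=3)
        assert set(np.unique(ds.values[:, 1])) <= {0.0, 1.0}
        assert len(np.unique(ds.values[:, 0])) > 100

    def test_asymmetric_matrix_rejected(self):
        J = np.array([[0, 0.5], [0.2, 0]])
        with pytest.raises(GraphValidationError, match="symmetric"):
            TrueGraph([("a", "binary"), ("b", "binary")], J)

    def test_improper_continuous_block_names_a_node(self):
        # coupling 1.2 with unit variances makes the Gaussian block indefinite
        J = np.array([[0, 1.2], [1.2, 0]])
        with pytest.raises(GraphModelError, match="y"):
            TrueGraph([("x", "continuous"), ("y", "continuous")], J)

    def test_json_round_trip(self, tmp_path):
        g = TrueGraph([("x", "continuous"), ("b", "binary")],
                      np.array([[0, 0.4], [0.4, 0]]),
                      node_thresholds=np.array([0.1, -0.2]))
        path = tmp_path / "graph.json"
        g.to_json(str(path))
        g2 = TrueGraph.from_json(str(path))
        assert g2.node_specs == g.node_specs
        np.testing.assert_allclose(g2.interaction_matrix, g.interaction_matrix)
        np.testing.assert_allclose(g2.node_thresholds, g.node_thresholds)


class TestInjectDependence:
    def test_node_column_mismatch_rejected(self):
        cohort = pd.DataFrame({"pq16": [1.0, 2.0]})
        g = TrueGraph([("pq16", "continuous"), ("nope", "continuous")],
                      np.zeros((2, 2)))
        with pytest.raises(GraphValidationError, match="nope"):
            inject_dependence(cohort, g)

    def test_empty_graph_preserves_marginals(self):
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame({
            "a": rng.normal(10, 2, 4000),
            "b": (rng.random(4000) < 0.3).astype(float),
        })
        g = TrueGraph([("a", "continuous"), ("b", "binary")], np.zeros((2, 2)))
        out = inject_dependence(cohort, g, seed=1)
        # continuous marginals are affine-matched to the input sample exactly
        assert out["a"].mean() == pytest.approx(cohort["a"].mean(), abs=1e-9)
        assert out["a"].std(ddof=0) == pytest.approx(cohort["a"].std(ddof=0), abs=1e-9)
        assert out["b"].mean() == pytest.approx(cohort["b"].mean(), abs=0.02)

    def test_positive_coupling_gives_positive_association(self):
        cohort = generate_cohort(CohortSpec(n_respondents=4000, seed=2))
        scored = score_cohort(cohort)
        cohort = cohort.assign(es=scored["es"].to_numpy())
        J = np.array([[0, 0.3], [0.3, 0]])
        g = TrueGraph([("es", "continuous"), ("pq16", "continuous")], J)
        out = inject_dependence(cohort, g, seed=3)
        r = np.corrcoef(out["es"], out["pq16"])[0, 1]
        assert r > 0.15
        # marginal drift stays small
        assert out["es"].mean() == pytest.approx(cohort["es"].mean(), abs=1e-9)
        assert out["pq16"].mean() == pytest.approx(cohort["pq16"].mean(), abs=1e-9)

    def test_binary_marginal_drift_under_coupling(self):
        rng = np.random.default_rng(4)
        cohort = pd.DataFrame({
            "u": (rng.random(5000) < 0.4).astype(float),
            "v": rng.normal(0, 1, 5000),
        })
        J = np.array([[0, 0.5], [0.5, 0]])
        g = TrueGraph([("u", "binary"), ("v", "continuous")], J)
        out = inject_dependence(cohort, g, seed=5)
        assert out["u"].mean() == pytest.approx(0.4, abs=0.02)
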