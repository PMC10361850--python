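"""Federation core: IRLS partials, federated fit, score release, privacy."""

import json

import numpy as np
import pytest
from scipy.special import expit

import fedqi as fq
from fedqi.federation import (
    FederatedLogisticRegression,
    RegistryNode,
    federated_fit,
    local_irls_partial,
    release_scores,
)
from fedqi.pipeline import pooled_logistic_fit

from conftest import toy_frame


def _two_by_two_nodes(a, b, c, d):
    """Country A/B nodes over a single binary covariate (HER2): a/c records
    with HER2 positive/negative in A, b/d in B."""
    def rows(country, pos, neg):
        return ([{"country": country, "her2": "positive"}] * pos
                + [{"country": country, "her2": "negative"}] * neg)

    node_a = RegistryNode("A", toy_frame(rows("A", a, c)), ["her2"])
    node_b = RegistryNode("B", toy_frame(rows("B", b, d)), ["her2"])
    return [node_a, node_b]


class TestIRLSPartial:
    def test_beta_zero_weights_are_one_quarter(self, small_nodes):
        node = small_nodes[0]
        p = len(node.column_names)
        partial = local_irls_partial(node, np.zeros(p), "NL")
        X = node._design.values
        np.testing.assert_allclose(partial.xtwx, 0.25 * X.T @ X, rtol=1e-12)
        assert partial.n == node.n_records

    def test_partials_add_over_any_split(self, small_scenario, rng):
        frame = small_scenario[0].frame.head(40)
        beta = rng.normal(scale=0.3, size=24)
        whole = RegistryNode("w", frame)
        half1 = RegistryNode("h1", frame.iloc[:17])
        half2 = RegistryNode("h2", frame.iloc[17:])
        pw = local_irls_partial(whole, beta, "NL")
        p1 = local_irls_partial(half1, beta, "NL")
        p2 = local_irls_partial(half2, beta, "NL")
        np.testing.assert_allclose(pw.xtwx, p1.xtwx + p2.xtwx, rtol=1e-12)
        np.testing.assert_allclose(pw.xtwz, p1.xtwz + p2.xtwz, rtol=1e-12)
        assert pw.n == p1.n + p2.n

    def test_matches_per_record_brute_force(self, small_scenario, rng):
        frame = small_scenario[1].frame.head(50)
        node = RegistryNode("n", frame)
        beta = rng.normal(scale=0.5, size=24)
        partial = local_irls_partial(node, beta, "NO")
        X = node._design.values
        y = (frame["country"] == "NO").to_numpy(float)
        xtwx = np.zeros((24, 24))
        xtwz = np.zeros(24)
        dev = 0.0
        for i in range(len(frame)):
            mu = expit(X[i] @ beta)
            w = mu * (1 - mu)
            z = X[i] @ beta + (y[i] - mu) / w
            xtwx += w * np.outer(X[i], X[i])
            xtwz += w * X[i] * z
            dev += -2 * (y[i] * np.log(mu) + (1 - y[i]) * np.log(1 - mu))
        np.testing.assert_allclose(partial.xtwx, xtwx, rtol=1e-10)
        np.testing.assert_allclose(partial.xtwz, xtwz, rtol=1e-10)
        assert partial.deviance == pytest.approx(dev, rel=1e-10)


class TestFederatedFit:
    def test_matches_centralized_pooled_fit(self, small_scenario,
                                            small_nodes, small_model):
        frames = {"NL": small_scenario[0].frame,
                  "NO": small_scenario[1].frame}
        names, pooled = pooled_logistic_fit(
            frames, "NL", fq.COVARIATES, small_model.dropped_columns_
        )
        fed = np.array([
            small_model.coef_[small_model.column_names_.index(c)]
            for c in names
        ])
        assert np.abs(fed - pooled).max() < 1e-6

    def test_two_by_two_slope_is_log_cross_product(self):
        a, b, c, d = 30, 10, 20, 40
        with pytest.warns(UserWarning):  # her2=unknown column is all-zero
            model = federated_fit(_two_by_two_nodes(a, b, c, d), "A")
        slope = model.coef_[model.column_names_.index("her2=positive")]
        assert slope == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
        assert "her2=unknown" in model.dropped_columns_

    def test_separation_flagged_with_finite_coefficients(self):
        # country A exclusively HER2-positive: perfectly separated
        with pytest.warns(UserWarning):
            model = federated_fit(_two_by_two_nodes(25, 0, 0, 25), "A")
        assert not model.converged_
        assert np.isfinite(model.coef_).all()

    def test_partition_invariance(self, small_scenario, small_model):
        nl, no = small_scenario[0].frame, small_scenario[1].frame
        nodes = [
            RegistryNode("NL-a", nl.iloc[:1000]),
            RegistryNode("NL-b", nl.iloc[1000:1800]),
            RegistryNode("NL-c", nl.iloc[1800:]),
            RegistryNode("NO", no),
        ]
        split = federated_fit(nodes, "NL")
        assert np.abs(split.coef_ - small_model.coef_).max() < 1e-8

    def test_single_membership_class_is_an_error(self, small_scenario):
        frame = small_scenario[0].frame
        nodes = [RegistryNode("a", frame.iloc[:50]),
                 RegistryNode("b", frame.iloc[50:100])]
        with pytest.raises(ValueError, match="membership"):
            federated_fit(nodes, "NL")


class TestScoreRelease:
    def test_beta_zero_scores_are_half(self, small_nodes):
        model = FederatedLogisticRegression()
        model.coef_ = np.zeros(len(small_nodes[0].column_names))
        model.column_names_ = small_nodes[0].column_names
        scores, countries = release_scores(small_nodes[0], model)
        assert np.all(scores == 0.5)
        assert set(countries) == {"NL"}

    def test_scores_match_brute_force_and_stay_in_unit_interval(
        self, small_nodes, small_model
    ):
        node = small_nodes[1]
        scores, _ = release_scores(node, small_model)
        expected = expit(node._design.values @ small_model.coef_)
        np.testing.assert_allclose(scores, expected, rtol=1e-12)
        assert np.all((scores > 0) & (scores < 1))


class TestPrivacyContract:
    def test_audit_payloads_scale_free_except_score_release(
        self, small_scenario
    ):
        frame = small_scenario[0].frame
        node_big = RegistryNode("big", frame)
        node_small = RegistryNode("small", frame.head(60))
        for node in (node_big, node_small):
            local_irls_partial(node, np.zeros(24), "NL")
            node.level_counts()
        # identical payload dimensions despite a 50x size difference
        assert ([e["payload_dim"] for e in node_big.audit_log]
                == [e["payload_dim"] for e in node_small.audit_log])

    def test_score_release_is_logged_with_score_and_country_only(
        self, small_nodes, small_model
    ):
        node = small_nodes[0]
        node.audit_log.clear()
        release_scores(node, small_model)
        (entry,) = node.audit_log
        assert entry["operation"] == "release_scores"
        assert entry["fields"] == ["score", "country"]


def test_model_json_round_trip(small_model, tmp_path):
    path = tmp_path / "model.json"
    small_model.to_json(path)
    back = FederatedLogisticRegression.from_json(path.read_text())
    np.testing.assert_allclose(back.coef_, small_model.coef_)
    assert back.column_names_ == small_model.column_names_
    assert back.converged_ == small_model.converged_
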