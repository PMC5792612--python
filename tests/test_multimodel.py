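"""Candidate enumeration, weighting, pruning, averaging, tree aggregation."""

import numpy as np
import pandas as pd
import pytest

import ovensong as ov
from ovensong.multimodel import all_parameter_weights
from ovensong.pgls import FitResult, ModelSpec


def stub_fit(terms, aicc, coefs=None, family="BM", interaction=False,
             response="y"):
    """Hand-built FitResult for testing ranking logic in isolation."""
    spec = ModelSpec(response, tuple(terms), interaction=interaction,
                     family=family)
    names = ["Intercept"] + list((coefs or {}).keys())
    values = [0.0] + list((coefs or {}).values())
    return FitResult(spec=spec, param_names=tuple(names),
                     coefficients=np.array(values), sigma2=1.0,
                     transform_estimate=None, loglik=-aicc / 2, k=2, n=50,
                     aicc=aicc)


class TestBuildModelSet:
    def test_default_enumeration(self):
        specs = ov.build_model_set("y")
        assert len(specs) == 75
        structures = {(s.terms, s.interaction) for s in specs}
        assert len(structures) == 15
        constants = [s for s in specs if not s.terms]
        assert len(constants) == 5
        assert {s.family for s in constants} == set(ov.FAMILIES)

    def test_interaction_models_use_categorical_habitat_only(self):
        specs = ov.build_model_set("y")
        for s in specs:
            if s.interaction:
                assert "Habitat" in s.terms and "EnvPC1" not in s.terms

    def test_envpc1_interaction_request_rejected(self):
        with pytest.raises(ValueError, match="categorical"):
            ModelSpec("y", ("BodySize", "EnvPC1"), interaction=True)


class TestWeights:
    def test_equal_aicc_splits_evenly(self):
        w = ov.akaike_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_delta_two_example(self):
        w = ov.akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_normalized_and_shift_invariant(self, rng):
        a = rng.uniform(100, 200, 20)
        w1 = ov.akaike_weights(a)
        w2 = ov.akaike_weights(a + 1234.5)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w1, w2, atol=1e-12)

    def test_all_infinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ov.akaike_weights([np.inf, np.inf])


class TestRanking:
    def test_delta_and_constant_weight(self):
        fits = [stub_fit(("BodySize",), 100.0, {"Body Size": 1.0}),
                stub_fit((), 103.0),
                stub_fit(("Habitat",), 101.0,
                         {"Habitat (semi-open)": 0.1, "Habitat (open)": 0.2})]
        ms = ov.rank_models(fits)
        assert ms.delta_aicc[0] == 0.0
        assert (ms.delta_aicc >= 0).all()
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-12)
        # evidence ratio of the top model relative to the constant model
        assert ms.evidence_ratio[0] == pytest.approx(
            ms.weights[0] / ms.w_constant)


class TestPruning:
    def test_superset_within_two_pruned(self):
        ms = ov.rank_models([
            stub_fit(("BodySize",), 100.0, {"Body Size": 1.0}),
            stub_fit(("BodySize", "Habitat"), 101.5,
                     {"Body Size": 1.0, "Habitat (semi-open)": 0.0,
                      "Habitat (open)": 0.0}),
        ])
        retained, log = ov.prune_uninformative(ms)
        assert len(retained) == 1
        assert retained[0].spec.terms == ("BodySize",)
        assert "pruned" in log[0]

    def test_non_nested_both_retained(self):
        ms = ov.rank_models([
            stub_fit(("BodySize",), 100.0, {"Body Size": 1.0}),
            stub_fit(("BeakSize",), 101.0, {"Beak Size": 1.0}),
        ])
        retained, _ = ov.prune_uninformative(ms)
        assert len(retained) == 2

    def test_chain_of_supersets_all_pruned(self):
        ms = ov.rank_models([
            stub_fit(("BodySize",), 100.0, {"Body Size": 1.0}),
            stub_fit(("BodySize", "Habitat"), 101.0,
                     {"Body Size": 1.0, "Habitat (semi-open)": 0.0,
                      "Habitat (open)": 0.0}),
            stub_fit(("BodySize", "Habitat"), 101.9,
                     {"Body Size": 1.0, "Habitat (semi-open)": 0.0,
                      "Habitat (open)": 0.0, "Body Size × Habitat (semi-open)": 0.0,
                      "Body Size × Habitat (open)": 0.0}, interaction=True),
        ])
        retained, _ = ov.prune_uninformative(ms)
        assert len(retained) == 1

    def test_top_model_never_pruned(self, rng):
        fits = [stub_fit(("BodySize", "Habitat"), 100.0,
                         {"Body Size": 1.0, "Habitat (semi-open)": 0.0,
                          "Habitat (open)": 0.0})]
        fits += [stub_fit((), 100.0 + d) for d in rng.uniform(0, 5, 10)]
        retained, _ = ov.prune_uninformative(ov.rank_models(fits))
        assert retained[0].spec.terms == ("BodySize", "Habitat")


class TestCumulativeSet:
    def test_prefix_until_threshold(self):
        fits = [stub_fit((), a) for a in [0.0, 1.578, 4.8, 5.6]]
        ms = ov.rank_models(fits)
        # engineered weights ~ {0.60, 0.27, 0.054, 0.036}: need three models
        idx = ov.cumulative_weight_set(ms, threshold=0.95)
        assert len(idx) == 3

    def test_single_model(self):
        ms = ov.rank_models([stub_fit((), 10.0)])
        assert ov.cumulative_weight_set(ms) == [0]

    def test_uniform_weights_over_twenty(self):
        ms = ov.rank_models([stub_fit((), 50.0) for _ in range(20)])
        assert len(ov.cumulative_weight_set(ms, threshold=0.95)) == 19


class TestParameterWeights:
    def test_hand_computed_total(self):
        fits = [stub_fit(("BodySize",), 0, {"Body Size": 1.0}),
                stub_fit(("BodySize", "Habitat"), 0,
                         {"Body Size": 1.0, "Habitat (semi-open)": 0.0,
                          "Habitat (open)": 0.0}),
                stub_fit((), 0)]
        w = [0.6, 0.2, 0.2]
        assert ov.parameter_total_weight(fits, w, "Body Size") == \
            pytest.approx(0.8)

    def test_absent_parameter_warns_and_is_zero(self):
        fits = [stub_fit((), 0)]
        with pytest.warns(UserWarning, match="no model"):
            assert ov.parameter_total_weight(fits, [1.0], "Body Size") == 0.0

    def test_everywhere_present_is_one(self):
        fits = [stub_fit(("BodySize",), 0, {"Body Size": 1.0})] * 3
        w = [0.5, 0.3, 0.2]
        assert ov.parameter_total_weight(fits, w, "Body Size") == \
            pytest.approx(1.0)


class TestAveraging:
    def test_zero_substitution(self):
        fits = [stub_fit(("BodySize",), 0, {"Body Size": 1.0}),
                stub_fit((), 0)]
        avg = ov.model_average(fits, [0.5, 0.5])
        assert avg.averaged_beta["Body Size"] == pytest.approx(0.5)
        assert avg.averaged_beta["Beak Size"] == 0.0

    def test_shared_coefficient_is_convex(self):
        fits = [stub_fit(("BodySize",), 0, {"Body Size": 3.3}),
                stub_fit(("BodySize", "Habitat"), 0,
                         {"Body Size": 3.3, "Habitat (semi-open)": 0.1,
                          "Habitat (open)": 0.2})]
        avg = ov.model_average(fits, [0.25, 0.75])
        assert avg.averaged_beta["Body Size"] == pytest.approx(3.3)

    def test_weights_renormalized(self):
        fits = [stub_fit(("BodySize",), 0, {"Body Size": 2.0}),
                stub_fit((), 0)]
        avg = ov.model_average(fits, [0.3, 0.3])  # sums to 0.6
        assert avg.averaged_beta["Body Size"] == pytest.approx(1.0)
        assert avg.parameter_total_weight["Body Size"] == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ov.model_average([], [])


class TestAcrossTrees:
    def test_identical_trees_equal_single_tree_result(self, small_bundle,
                                                      species_table):
        tree = small_bundle.tree
        trees = ov.TreeSet([tree, tree, tree])
        data = species_table
        single_fits = ov.fit_model_set("log_pace_hz", data, tree,
                                       families=("BM", "lambda"))
        ms = ov.rank_models(single_fits)
        idx = ov.cumulative_weight_set(ms)
        single = ov.model_average([ms.fits[i] for i in idx], ms.weights[idx])
        multi = ov.average_across_trees(trees, "log_pace_hz", data,
                                        families=("BM", "lambda"))
        assert multi.tree_count == 3
        assert np.allclose(multi.averaged_beta.to_numpy(),
                           single.averaged_beta.to_numpy(), atol=1e-10)

    def test_mean_of_per_tree_averages(self, small_bundle, species_table):
        trees = ov.TreeSet(list(small_bundle.tree_set.trees[:2]))
        result, per_tree = ov.average_across_trees(
            trees, "log_pace_hz", species_table, families=("BM", "lambda"),
            return_per_tree=True)
        manual = np.mean([a.averaged_beta.to_numpy() for a in per_tree],
                         axis=0)
        assert np.allclose(result.averaged_beta.to_numpy(), manual)

    def test_tree_data_mismatch(self, small_bundle):
        trees = small_bundle.tree_set
        data = pd.DataFrame({"log_pace_hz": [1.0]}, index=["not_a_species"])
        with pytest.raises(ValueError, match="overlap"):
            ov.average_across_trees(trees, "log_pace_hz", data)

    def test_posterior_sample_dimension_check(self, small_bundle,
                                              species_table):
        """Across-tree averaging yields one value per report parameter."""
        trees = ov.TreeSet(list(small_bundle.tree_set.trees[:3]))
        avg = ov.average_across_trees(trees, "vocal_deviation"
                                      if "vocal_deviation" in species_table
                                      else "log_pace_hz",
                                      species_table, families=("lambda",))
        assert tuple(avg.averaged_beta.index) == ov.ALL_PARAMETERS


class TestFullParameterWeights:
    def test_report_order_and_range(self, species_table, small_bundle):
        fits = ov.fit_model_set("log_max_freq_hz", species_table,
                                small_bundle.tree, families=("BM", "lambda"))
        ms = ov.rank_models(fits)
        w = all_parameter_weights(ms.fits, ms.weights)
        assert list(w.index) == [p for p in ov.ALL_PARAMETERS
                                 if p != "Intercept"]
        assert ((w >= 0) & (w <= 1 + 1e-12)).all()
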