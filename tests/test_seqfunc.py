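import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htfunclib.epinnet import SiteNeighborhood
from htfunclib.genotypes import Genotype
from htfunclib.profiles import Alignment, build_pssm
from htfunclib.seqfunc import (
    AA_CATEGORIES,
    CountTable,
    build_features,
    call_hits,
    enrichment,
    fit_decline,
    functional_fraction_by_n,
    logistic_logo,
    pocket_filter,
    two_stage_classify,
)


def make_counts(data):
    return CountTable(pd.DataFrame(data))


class TestEnrichment:
    def test_frequency_ratio_arithmetic(self):
        ct = make_counts(
            {"sorted": {"g1": 10, "g2": 90}, "presorted": {"g1": 5, "g2": 995}}
        )
        e = enrichment(ct, "sorted", "presorted")
        assert e["g1"] == pytest.approx((10 / 100) / (5 / 1000))  # 20

    def test_absent_in_sorted_is_zero(self):
        ct = make_counts(
            {"sorted": {"g1": 0, "g2": 10}, "presorted": {"g1": 5, "g2": 5}}
        )
        assert enrichment(ct, "sorted", "presorted")["g1"] == 0.0

    def test_sorted_only_genotype_is_infinitely_enriched(self):
        ct = make_counts(
            {"sorted": {"g1": 3, "g2": 10}, "presorted": {"g1": 0, "g2": 5}}
        )
        e = enrichment(ct, "sorted", "presorted")
        assert math.isinf(e["g1"])
        calls = call_hits({"GFP": e}, threshold=1.0)
        assert calls.loc["g1", "label"] == "GFP"

    def test_zero_total_rejected(self):
        ct = make_counts({"sorted": {"g1": 0}, "presorted": {"g1": 5}})
        with pytest.raises(ValueError, match="zero total"):
            enrichment(ct, "sorted", "presorted")

    @given(scale=st.integers(min_value=1, max_value=1000))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_rescaling_one_sample(self, scale):
        base = {"sorted": {"g1": 10, "g2": 90}, "presorted": {"g1": 5, "g2": 995}}
        scaled = {
            "sorted": {k: v * scale for k, v in base["sorted"].items()},
            "presorted": base["presorted"],
        }
        e1 = enrichment(make_counts(base), "sorted", "presorted")
        e2 = enrichment(make_counts(scaled), "sorted", "presorted")
        assert np.allclose(e1.values, e2.values)


class TestCallHits:
    @pytest.mark.parametrize(
        "gfp,amcyan,expected",
        [
            (2.0, 0.5, "GFP"),
            (0.5, 2.0, "AmCyan"),
            (2.0, 2.0, "both"),
            (1.0, 0.5, "nonfunctional"),  # strict inequality at the threshold
        ],
    )
    def test_gate_combinations(self, gfp, amcyan, expected):
        calls = call_hits(
            {
                "GFP": pd.Series({"g": gfp}),
                "AmCyan": pd.Series({"g": amcyan}),
            },
            threshold=1.0,
        )
        assert calls.loc["g", "label"] == expected


class TestPocketFilter:
    REF = "ACDEFGH"

    def test_pocket_only_variant_kept(self):
        kept = pocket_filter([("ACDWFGH", "x")], self.REF, pocket={4})
        assert len(kept) == 1

    def test_extra_pocket_mutation_dropped(self):
        kept = pocket_filter([("WCDWFGH", "x")], self.REF, pocket={4})
        assert kept == []

    def test_reference_itself_kept(self):
        assert len(pocket_filter([(self.REF, "x")], self.REF, pocket=set())) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pocket_filter([("AC", "x")], self.REF, pocket={1})


class TestFunctionalFraction:
    def test_partition_and_fractions(self):
        table = functional_fraction_by_n(
            [1, 1, 2, 2, 2, 5], [True, True, True, False, False, False]
        )
        assert table.loc[table["n"] == 1, "fraction"].item() == 1.0
        assert table.loc[table["n"] == 2, "fraction"].item() == pytest.approx(1 / 3)
        assert 3 not in set(table["n"])  # empty bins omitted
        assert table["count"].sum() == 6


class TestFitDecline:
    def test_noiseless_parameter_recovery(self):
        A, B = 0.5, 0.1
        n = np.arange(0, 9)
        F = np.exp(-A * n - B * n * (n - 1) / 2)
        fit = fit_decline(n, F)
        assert fit.A == pytest.approx(A, abs=1e-6)
        assert fit.B == pytest.approx(B, abs=1e-6)

    def test_prediction_at_zero_is_one(self):
        fit = fit_decline([1, 2, 3], [0.5, 0.2, 0.05])
        assert fit.predict(0) == pytest.approx(1.0)

    def test_quadratic_and_pairwise_forms_agree(self):
        # exp(-alpha n - beta n^2) == exp(-A n - B n(n-1)/2) with
        # alpha = A - B/2, beta = B/2, checked on a grid
        fit = fit_decline([1, 2, 3, 4], [0.6, 0.3, 0.1, 0.02])
        n = np.linspace(0, 10, 50)
        lhs = np.exp(-fit.alpha * n - fit.beta * n**2)
        assert np.allclose(lhs, fit.predict(n))

    def test_pure_exponential_data_gives_zero_epistasis(self):
        n = np.arange(0, 8)
        F = np.exp(-0.4 * n)
        fit = fit_decline(n, F)
        assert fit.B <= 1e-6

    def test_all_zero_fractions_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_decline([1, 2], [0.0, 0.0])


@pytest.fixture
def feature_inputs():
    reference = {1: "A", 2: "C", 3: "Y"}
    aln = Alignment(("ACY", "ACY", "GCY", "AWY"), ("ref", "a", "b", "c"), 0)
    pssm = build_pssm(aln)
    nbhds = [SiteNeighborhood(1, (1, 2)), SiteNeighborhood(3, (3,))]
    return reference, pssm, nbhds


class TestBuildFeatures:
    def test_reference_row_is_all_zero(self, feature_inputs):
        reference, pssm, nbhds = feature_inputs
        feats = build_features([Genotype.from_mapping(reference)], reference, pssm, nbhds)
        numeric = feats.select_dtypes("number")
        assert (numeric.iloc[0] == 0).all()

    def test_neighborhood_mutation_counts(self, feature_inputs):
        reference, pssm, nbhds = feature_inputs
        g = Genotype.from_mapping({1: "G", 2: "W", 3: "Y"})
        feats = build_features([g], reference, pssm, nbhds)
        assert feats.loc[0, "nbhd_1"] == 2
        assert feats.loc[0, "nbhd_3"] == 0
        assert feats.loc[0, "n_mutations"] == 2

    def test_category_change_flag(self, feature_inputs):
        reference, pssm, nbhds = feature_inputs
        assert AA_CATEGORIES["Y"] == "aromatic" and AA_CATEGORIES["M"] == "aliphatic"
        g = Genotype.from_mapping({1: "A", 2: "C", 3: "M"})
        feats = build_features([g], reference, pssm, nbhds)
        assert feats.loc[0, "catchange_3"] == 1.0

    def test_column_count_is_fixed_function_of_inputs(self, feature_inputs):
        reference, pssm, nbhds = feature_inputs
        g = Genotype.from_mapping(reference)
        feats = build_features([g, g], reference, pssm, nbhds, areas={"core": {1}})
        n_pos, n_nbhd, n_areas = len(reference), len(nbhds), 1
        expected = n_pos + 1 + n_nbhd + n_areas + 3 * n_pos + 6
        assert feats.shape[1] == expected


def _classification_fixture(seed=0, n=600):
    """Labels fully determined by position-1 identity: G -> nonfunctional,
    A -> GFP, S -> AmCyan."""
    rng = np.random.default_rng(seed)
    reference = {1: "A", 2: "C", 3: "Y"}
    aln = Alignment(("ACY", "ACY", "GCY", "AWY", "SCY"), tuple("rabcd"), 0)
    pssm = build_pssm(aln)
    nbhds = [SiteNeighborhood(1, (1, 2)), SiteNeighborhood(3, (3,))]
    genos, labels = [], []
    label_map = {"G": "nonfunctional", "A": "GFP", "S": "AmCyan"}
    for _ in range(n):
        ids = {
            1: rng.choice(["A", "G", "S"]),
            2: rng.choice(["C", "W"]),
            3: rng.choice(["Y", "M"]),
        }
        genos.append(Genotype.from_mapping(ids))
        labels.append(label_map[ids[1]])
    feats = build_features(genos, reference, pssm, nbhds)
    return feats, labels


class TestTwoStageClassifier:
    def test_separable_labels_reach_perfect_balanced_accuracy(self):
        feats, labels = _classification_fixture()
        result = two_stage_classify(feats, labels, seed=0)
        assert result.stage1_balanced_accuracy == 1.0
        assert result.stage2_accuracy == 1.0

    def test_permuted_labels_score_near_chance(self):
        feats, labels = _classification_fixture(seed=2)
        rng = np.random.default_rng(2)
        shuffled = list(rng.permutation(labels))
        result = two_stage_classify(feats, shuffled, seed=2)
        assert 0.3 < result.stage1_balanced_accuracy < 0.7

    def test_predict_pipeline_routes_through_both_stages(self):
        feats, labels = _classification_fixture(seed=3)
        result = two_stage_classify(feats, labels, seed=3)
        preds = result.predict(feats)
        assert set(preds) <= {"nonfunctional", "GFP", "AmCyan"}
        assert (preds == np.array(labels)).mean() > 0.95

    def test_missing_class_rejected(self):
        feats, labels = _classification_fixture()
        with pytest.raises(ValueError, match="non-functional"):
            two_stage_classify(feats, ["GFP"] * len(labels))


class TestLogisticLogo:
    def _genotypes(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        genos, labels = [], []
        for _ in range(n):
            ids = {
                1: rng.choice(["A", "G"]),
                5: rng.choice(["T", "S"]),
                9: rng.choice(["Y", "M"]),
            }
            genos.append(Genotype.from_mapping(ids))
            labels.append(int(ids[5] == "S"))  # label depends on position 5 only
        return genos, labels

    def test_signal_concentrates_at_causal_position(self):
        genos, labels = self._genotypes()
        logo = logistic_logo(genos, labels, l2_C=0.5)
        causal = logo.loc[5].abs().max()
        assert causal > logo.loc[1].abs().max()
        assert causal > logo.loc[9].abs().max()
        # brute-force contingency log-odds agrees in sign
        assert logo.loc[5, "S"] > 0 > logo.loc[5, "T"]

    def test_mean_centered_by_site(self):
        genos, labels = self._genotypes(seed=1)
        logo = logistic_logo(genos, labels)
        assert np.allclose(logo.sum(axis=1).values, 0.0, atol=1e-9)

    def test_hamming_radius_filter_keeps_exact_ball(self):
        from htfunclib.seqfunc import hamming_ball

        genos, _ = self._genotypes(seed=2, n=200)
        center = genos[0]
        kept = hamming_ball(genos, [center], radius=2)
        # independent brute-force enumeration of the radius-2 ball
        expected = [
            i
            for i, g in enumerate(genos)
            if sum(a != b for (_, a), (_, b) in zip(g.identities, center.identities)) <= 2
        ]
        assert kept == expected
        assert all(genos[i].hamming(center) <= 2 for i in kept)

    def test_degenerate_filter_rejected(self):
        genos, labels = self._genotypes(n=50)
        with pytest.raises(ValueError):
            logistic_logo(genos, [1] * len(genos))
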