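"""Similarity-aggregation (SAM) consensus pipeline."""

import numpy as np
import pytest

from fuzzyslim import (
    DEFAULT_OPINION_SCALE,
    ExpertProfile,
    OpinionSet,
    aggregate,
    average_agreement,
    consensus_coefficients,
    expert_weights,
    make_fuzzy,
    psf_weights,
    relative_agreement,
    sam_aggregate,
)
from fuzzyslim.consensus import UNIFORM_SCHEME


def panel_of(n, scheme="uniform"):
    profiles = [
        ExpertProfile(f"E{i+1}", 12.0, "master", "high") for i in range(n)
    ]
    return expert_weights(profiles, scheme)


class TestExpertWeights:
    def test_identical_profiles_share_weight_equally(self):
        panel = expert_weights(
            [
                ExpertProfile("a", 8, "bachelor", "medium"),
                ExpertProfile("b", 8, "bachelor", "medium"),
            ]
        )
        assert [p.weight for p in panel] == [0.5, 0.5]

    def test_uniform_scheme_overrides_credentials(self):
        panel = expert_weights(
            [
                ExpertProfile("a", 30, "phd", "high"),
                ExpertProfile("b", 1, "diploma", "low"),
                ExpertProfile("c", 1, "diploma", "low"),
            ],
            "uniform",
        )
        assert [p.weight for p in panel] == pytest.approx([1 / 3] * 3)

    def test_default_score_table_normalization(self):
        # 25y/phd/high scores 4+4+3=11; 2y/diploma/low scores 1+1+1=3
        panel = expert_weights(
            [
                ExpertProfile("senior", 25, "phd", "high"),
                ExpertProfile("junior", 2, "diploma", "low"),
            ]
        )
        assert [p.weight for p in panel] == pytest.approx([11 / 14, 3 / 14])

    def test_unknown_attribute_level_rejected(self):
        with pytest.raises(ValueError, match="education"):
            expert_weights([ExpertProfile("a", 5, "wizard", "high")])


class TestAgreementChain:
    def test_unanimous_panel_agrees_fully(self):
        s = np.ones((4, 4))
        assert average_agreement(s) == pytest.approx([1.0] * 4)

    def test_average_agreement_hand_value(self):
        s = np.array([[1, 0.9, 0.9], [0.9, 1, 0.8], [0.9, 0.8, 1]])
        assert average_agreement(s) == pytest.approx([0.9, 0.85, 0.85])

    def test_single_expert_is_an_error(self):
        with pytest.raises(ValueError, match="panel too small"):
            average_agreement(np.ones((1, 1)))

    def test_relative_agreement_normalizes(self):
        assert relative_agreement([1, 1, 1]) == pytest.approx([1 / 3] * 3)
        ra = relative_agreement([0.9, 0.85, 0.85])
        assert ra == pytest.approx([0.34615, 0.32692, 0.32692], abs=1e-5)
        assert ra.sum() == pytest.approx(1.0)

    def test_total_disagreement_rejected(self):
        with pytest.raises(ValueError):
            relative_agreement([0.0, 0.0])


class TestConsensusCoefficients:
    def test_beta_zero_reduces_to_relative_agreement(self):
        ra, w = np.array([0.7, 0.3]), np.array([0.5, 0.5])
        assert consensus_coefficients(ra, w, 0.0) == pytest.approx(ra)

    def test_beta_one_reduces_to_expert_weights(self):
        ra, w = np.array([0.7, 0.3]), np.array([0.5, 0.5])
        assert consensus_coefficients(ra, w, 1.0) == pytest.approx(w)

    def test_hand_blend(self):
        cc = consensus_coefficients(
            np.array([0.5, 0.5]), np.array([0.6, 0.4]), 0.4
        )
        assert cc == pytest.approx([0.54, 0.46])

    @pytest.mark.parametrize("beta", [0.0, 0.25, 0.4, 1.0])
    def test_sums_to_one_for_any_beta(self, beta, rng):
        ra = rng.dirichlet(np.ones(7))
        w = rng.dirichlet(np.ones(7))
        assert consensus_coefficients(ra, w, beta).sum() == pytest.approx(
            1.0, abs=1e-9
        )

    @pytest.mark.parametrize("beta", [-0.1, 1.5])
    def test_beta_outside_unit_interval_rejected(self, beta):
        with pytest.raises(ValueError):
            consensus_coefficients([0.5, 0.5], [0.5, 0.5], beta)


class TestAggregate:
    def test_identical_opinions_aggregate_to_themselves(self):
        f = make_fuzzy((0.3, 0.5, 0.7))
        assert aggregate([f, f, f], [0.2, 0.3, 0.5]).points == pytest.approx(
            f.points
        )

    def test_equal_weights_give_midpoint(self):
        g = aggregate(
            [make_fuzzy((0.2, 0.3, 0.4)), make_fuzzy((0.4, 0.5, 0.6))],
            [0.5, 0.5],
        )
        assert g.points == pytest.approx((0.3, 0.4, 0.5))

    def test_weighted_pointwise_sum(self):
        g = aggregate(
            [make_fuzzy((0, 0.1, 0.2)), make_fuzzy((0.5, 0.6, 0.7))],
            [0.54, 0.46],
        )
        assert g.points == pytest.approx((0.23, 0.33, 0.43))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate([make_fuzzy((0, 0.1, 0.2))], [0.5, 0.5])

    def test_aggregate_stays_in_panel_envelope(self, rng):
        for _ in range(50):
            ops = [make_fuzzy(np.sort(rng.random(3))) for _ in range(5)]
            cc = rng.dirichlet(np.ones(5))
            g = aggregate(ops, cc)
            pts = np.array([f.points for f in ops])
            assert (g.points >= pts.min(axis=0) - 1e-12).all()
            assert (g.points <= pts.max(axis=0) + 1e-12).all()


class TestPsfWeights:
    def opinion_sets(self, terms_by_item, experts):
        return [
            OpinionSet(
                item,
                {e: DEFAULT_OPINION_SCALE[t] for e, t in zip(experts, terms)},
            )
            for item, terms in terms_by_item.items()
        ]

    def test_identically_judged_items_share_weight(self):
        panel = panel_of(3)
        experts = [p.id for p in panel]
        sets = self.opinion_sets(
            {k: ["medium", "high", "medium"] for k in "abcd"}, experts
        )
        weights, _ = psf_weights(panel, sets)
        assert list(weights.values()) == pytest.approx([0.25] * 4)

    def test_unanimous_top_item_outweighs_unanimous_bottom(self):
        panel = panel_of(4)
        experts = [p.id for p in panel]
        sets = self.opinion_sets(
            {
                "first": ["very high"] * 4,
                "second": ["very low"] * 4,
                "third": ["very low"] * 4,
            },
            experts,
        )
        weights, traces = psf_weights(panel, sets)
        assert weights["first"] > weights["second"]
        assert weights["second"] == pytest.approx(weights["third"])
        # unanimous panels aggregate to the common opinion exactly
        assert traces["first"].aggregate.points == pytest.approx(
            DEFAULT_OPINION_SCALE["very high"].points
        )

    def test_weights_nonnegative_and_sum_to_one(self, rng):
        panel = panel_of(5, "default")
        experts = [p.id for p in panel]
        terms = list(DEFAULT_OPINION_SCALE)
        sets = self.opinion_sets(
            {
                f"item{i}": [terms[int(k)] for k in rng.integers(0, 7, 5)]
                for i in range(6)
            },
            experts,
        )
        weights, _ = psf_weights(panel, sets)
        assert all(w >= 0 for w in weights.values())
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_permuting_experts_leaves_weights_unchanged(self, rng):
        profiles = [
            ExpertProfile("a", 25, "phd", "high"),
            ExpertProfile("b", 2, "diploma", "low"),
            ExpertProfile("c", 8, "master", "medium"),
        ]
        terms = {"x": ["low", "high", "medium"], "y": ["medium", "medium", "high"]}
        forward = expert_weights(profiles)
        backward = expert_weights(profiles[::-1])
        w1, _ = psf_weights(
            forward, self.opinion_sets(terms, [p.id for p in forward])
        )
        terms_rev = {k: v[::-1] for k, v in terms.items()}
        w2, _ = psf_weights(
            backward, self.opinion_sets(terms_rev, [p.id for p in backward])
        )
        for item in terms:
            assert w1[item] == pytest.approx(w2[item], abs=1e-12)

    def test_trace_invariants(self):
        panel = panel_of(3, "default")
        sets = self.opinion_sets(
            {"only": ["low", "medium", "high"]}, [p.id for p in panel]
        )
        trace = sam_aggregate(sets[0], panel, beta=0.4)
        assert np.allclose(trace.agreement, trace.agreement.T)
        assert np.allclose(np.diag(trace.agreement), 1.0)
        assert trace.relative_agreement.sum() == pytest.approx(1.0, abs=1e-9)
        assert trace.consensus.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_opinion_detected(self):
        panel = panel_of(3)
        bad = OpinionSet(
            "x",
            {
                "E1": DEFAULT_OPINION_SCALE["medium"],
                "E2": DEFAULT_OPINION_SCALE["medium"],
            },
        )
        with pytest.raises(ValueError, match="missing opinions"):
            sam_aggregate(bad, panel)
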