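"""Perturbation operations: set identities, paired effects, greedy search oracle."""

import numpy as np
import pytest

import histomil as hm
from histomil import (
    RegionMask,
    append_patches,
    cohens_d_paired,
    greedy_sufficiency_search,
    keep_only,
    necessity_test,
    remove_patches,
    sufficiency_test,
    transfer_test,
)
from histomil.perturb import SearchTrace


def mean_coord0(bag):
    """Stub bag scorer: mean of feature column 0 (permutation invariant)."""
    return float(bag.features[:, 0].mean())


@pytest.fixture
def bag(small_cohort):
    return small_cohort["bags"][0]


class TestSetOperations:
    def test_remove_empty_is_identity(self, bag):
        out = remove_patches(bag, [])
        np.testing.assert_array_equal(out.features, bag.features)

    def test_remove_preserves_order(self, bag):
        n = bag.n_patches
        out = remove_patches(bag, [0, n - 1])
        np.testing.assert_array_equal(out.features, bag.features[1 : n - 1])

    def test_remove_complement_equals_keep_only(self, bag):
        keep = {1, 3, 5}
        comp = set(range(bag.n_patches)) - keep
        a = keep_only(bag, keep)
        b = remove_patches(bag, comp)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_remove_composes_over_disjoint_sets(self, bag):
        s, t = {0, 2}, {4, 6}
        step = remove_patches(remove_patches(bag, s), [i - sum(1 for j in s if j < i) for i in t])
        joint = remove_patches(bag, s | t)
        np.testing.assert_array_equal(step.features, joint.features)

    def test_remove_all_rejected(self, bag):
        with pytest.raises(ValueError):
            remove_patches(bag, range(bag.n_patches))
        with pytest.raises(ValueError):
            keep_only(bag, [])

    def test_original_untouched(self, bag):
        before = bag.features.copy()
        remove_patches(bag, [0])
        np.testing.assert_array_equal(bag.features, before)

    def test_append_extends_geometry_and_is_valid(self, bag):
        extra = np.ones((7, bag.dim), dtype=np.float32)
        out = append_patches(bag, extra)
        assert out.n_patches == bag.n_patches + 7
        assert out.geometry.height_px > bag.geometry.height_px
        np.testing.assert_array_equal(out.features[-7:], extra)


class TestCohensD:
    def test_hand_computed(self):
        assert cohens_d_paired([-1, -2, 0]) == pytest.approx(-1.0)  # mean -1, sd 1

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(cohens_d_paired([0.5, 0.5, 0.5]))

    def test_scale_invariance(self, rng):
        d = rng.normal(size=10)
        assert cohens_d_paired(d) == pytest.approx(cohens_d_paired(7.3 * d))


class TestNecessitySufficiency:
    def test_empty_masks_degenerate(self, small_cohort):
        bags = small_cohort["bags"][:5]
        masks = {b.slide_id: RegionMask(b.slide_id, patch_indices=frozenset()) for b in bags}
        res = necessity_test(lambda b: 1.0, bags, masks, inclusion_threshold=0.5)
        assert res.degenerate and np.all(res.table["delta"] == 0)

    def test_full_mask_sufficiency_is_identity(self, small_cohort):
        bags = small_cohort["bags"][:5]
        masks = {
            b.slide_id: RegionMask(b.slide_id, patch_indices=frozenset(range(b.n_patches)))
            for b in bags
        }
        res = sufficiency_test(lambda b: 1.0 + mean_coord0(b) * 0, bags, masks, inclusion_threshold=0.5)
        assert np.all(res.table["delta"] == 0)

    def test_inclusion_rule_strictly_greater(self, small_cohort):
        bags = small_cohort["bags"][:4]
        masks = {b.slide_id: RegionMask(b.slide_id, patch_indices=frozenset({0})) for b in bags}
        with pytest.raises(ValueError, match="eligible"):
            necessity_test(lambda b: 0.5, bags, masks, inclusion_threshold=0.5)

    def test_mask_and_complement_predictions_coincide(self, bag):
        mask_idx = set(range(0, bag.n_patches, 2))
        comp = set(range(bag.n_patches)) - mask_idx
        kept = keep_only(bag, mask_idx)
        removed = remove_patches(bag, comp)
        assert mean_coord0(kept) == pytest.approx(mean_coord0(removed))


class TestGreedySearch:
    def test_recipient_already_high_stops_immediately(self, small_cohort):
        donor, recipient = small_cohort["bags"][:2]
        trace = greedy_sufficiency_search(lambda b: 100.0, donor, recipient, high_threshold=52.94118)
        assert trace.selected == [] and trace.stop_reason == "reached_threshold"

    def test_first_pick_is_best_single_patch(self, small_cohort):
        donor, recipient = small_cohort["bags"][:2]
        trace = greedy_sufficiency_search(
            mean_coord0, donor, recipient, high_threshold=np.inf, stop_on_no_improvement=False
        )
        best_first = max(
            range(donor.n_patches),
            key=lambda j: mean_coord0(append_patches(recipient, donor.features[j])),
        )
        assert trace.selected[0] == best_first

    def test_budget_is_quarter_of_donor(self, small_cohort):
        donor, recipient = small_cohort["bags"][:2]
        trace = greedy_sufficiency_search(
            mean_coord0, donor, recipient, high_threshold=np.inf, stop_on_no_improvement=False
        )
        assert trace.budget == donor.n_patches // 4
        assert len(trace.selected) == trace.budget
        assert trace.stop_reason == "exhausted_budget"

    def test_exhaustive_per_iteration_oracle(self, rng, small_cohort):
        """Full greedy trace equals an independently coded exhaustive search."""
        template = small_cohort["bags"][0]
        for _ in range(100):
            nd, nr = int(rng.integers(4, 13)), int(rng.integers(2, 8))
            donor = template.subset(np.arange(nd))
            donor = hm.EmbeddingBag(
                donor.slide_id, donor.encoder_id,
                rng.integers(-3, 4, size=(nd, donor.dim)).astype(np.float32),
                donor.coords, donor.geometry,
            )
            recipient = template.subset(np.arange(nr))
            threshold = float(rng.normal(scale=2))
            trace = greedy_sufficiency_search(
                mean_coord0, donor, recipient, high_threshold=threshold
            )
            oracle = oracle_greedy(donor, recipient, threshold)
            assert trace.selected == oracle.selected
            assert trace.predictions == pytest.approx(oracle.predictions)
            assert trace.stop_reason == oracle.stop_reason

    def test_no_improvement_stop(self, small_cohort):
        donor, recipient = small_cohort["bags"][:2]
        # strictly decreasing score in bag size: every insertion hurts
        trace = greedy_sufficiency_search(
            lambda b: -b.n_patches, donor, recipient, high_threshold=np.inf
        )
        assert trace.selected == [] and trace.stop_reason == "no_improvement"

    def test_tiny_donor_budget_floor(self, small_cohort):
        donor = small_cohort["bags"][0].subset(np.arange(3))
        recipient = small_cohort["bags"][1]
        trace = greedy_sufficiency_search(
            mean_coord0, donor, recipient, high_threshold=np.inf, stop_on_no_improvement=False
        )
        assert trace.budget == 1


def oracle_greedy(donor, recipient, threshold):
    """Independent exhaustive-argmax greedy implementation (pure python)."""
    selected, preds = [], []
    feats = [list(map(float, row)) for row in recipient.features[:, :1]]
    donor_col = [float(v) for v in donor.features[:, 0]]
    current = [v[0] for v in feats]
    pred = sum(current) / len(current)
    budget = max(1, donor.n_patches // 4)
    if pred >= threshold:
        return SearchTrace(selected, preds, pred, "reached_threshold", budget)
    unused = list(range(donor.n_patches))
    while True:
        best_j, best_s = None, -float("inf")
        for j in unused:
            cand = current + [donor_col[j]]
            s = sum(cand) / len(cand)
            if s > best_s:
                best_j, best_s = j, s
        if best_s <= pred:
            return SearchTrace(selected, preds, None, "no_improvement", budget)
        unused.remove(best_j)
        current.append(donor_col[best_j])
        pred = best_s
        selected.append(best_j)
        preds.append(pred)
        if pred >= threshold:
            return SearchTrace(selected, preds, None, "reached_threshold", budget)
        if len(selected) >= budget:
            return SearchTrace(selected, preds, None, "exhausted_budget", budget)


class TestTransfer:
    def test_empty_recipients_empty_report(self):
        out = transfer_test(mean_coord0, np.ones((2, 32)), [])
        assert out.empty

    def test_self_insertion_of_mean_is_neutral(self, bag):
        # inserting a patch equal to the bag's own column-0 mean leaves the stub unchanged
        patch = np.full((1, bag.dim), mean_coord0(bag), dtype=np.float32)
        out = transfer_test(mean_coord0, patch, [bag])
        assert out["delta"].iloc[0] == pytest.approx(0.0, abs=1e-5)

    def test_empty_patch_set_rejected(self, bag):
        with pytest.raises(ValueError):
            transfer_test(mean_coord0, np.empty((0, bag.dim)), [bag])
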