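import numpy as np
import pytest

from mvfuse.dataset_io import ViewTriplet
from mvfuse.interpretability import (ActivationMask, AssignmentRecord, Heatmap,
                                     activation_rates, assign_regions,
                                     cohens_kappa, compute_cam,
                                     extract_components, postprocess_cam,
                                     select_top_fraction)
from mvfuse.multiview_model import ModelConfig, build_model
from mvfuse.synthetic_specimens import REGION_IDS
from mvfuse.trainer import set_global_seed


def _baseline_model(seed, n_classes=4):
    set_global_seed(seed)
    return build_model(ModelConfig(variant="baseline", views=("dorsal",),
                                   n_classes=n_classes, backbone="tinycnn",
                                   input_size=32, dropout_p=0.0))


def _triplet(rng, size=32):
    img = rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
    return ViewTriplet(images={"dorsal": img},
                       availability=(True, False, False), label=0, subfamily=0)


class TestComputeCam:
    def test_linear_gap_oracle_closed_form(self, rng):
        """The head is linear on GAP features, so y_c = sum_k w_ck GAP(A^k)
        and Grad-CAM must equal ReLU(sum_k (w_ck / Z) A^k) elementwise."""
        for trial in range(20):
            model = _baseline_model(seed=trial)
            model.head.bias.data[:] = rng.normal(0, 1, 4)
            model.head.weight.data[:] = rng.normal(0, 1, model.head.weight.shape)
            triplet = _triplet(rng)
            c = int(rng.integers(0, 4))
            heat, cw = compute_cam(model, triplet, "dorsal", c)
            A = model.last_maps["image"].data[0]
            Z = A.shape[1] * A.shape[2]
            expected = np.maximum(
                (model.head.weight.data[c][:, None, None] / Z * A).sum(0), 0.0)
            np.testing.assert_allclose(heat.values, expected, rtol=1e-6,
                                       atol=1e-6 * max(1.0, expected.max()))
            np.testing.assert_allclose(cw.alpha, model.head.weight.data[c] / Z,
                                       rtol=1e-5, atol=1e-8)

    def test_everywhere_negative_combination_clamps_to_zero(self, rng):
        model = _baseline_model(seed=1)
        # negative weights over nonnegative (post-ReLU) activations
        model.head.weight.data[:] = -1.0
        heat, _ = compute_cam(model, _triplet(rng), "dorsal", 0)
        assert np.all(heat.values == 0.0)

    def test_predicted_class_is_default(self, rng):
        model = _baseline_model(seed=2)
        triplet = _triplet(rng)
        heat, _ = compute_cam(model, triplet, "dorsal")
        logits = model.forward_images(
            np.asarray(triplet.images["dorsal"], np.float32)
            .transpose(2, 0, 1)[None] / 127.5 - 1.0).data
        assert heat.class_index == int(logits[0].argmax())

    def test_unavailable_view_rejected(self, rng):
        model = _baseline_model(seed=3)
        with pytest.raises(ValueError, match="not available"):
            compute_cam(model, _triplet(rng), "ventral", 0)

    def test_attention_model_produces_per_view_maps(self, rng):
        set_global_seed(5)
        model = build_model(ModelConfig(variant="attention", n_classes=4,
                                        backbone="tinycnn", input_size=32,
                                        dropout_p=0.0))
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        t = ViewTriplet(images={"dorsal": img, "ventral": img.copy()},
                        availability=(True, False, True), label=0, subfamily=0)
        for view in ("dorsal", "ventral"):
            heat, _ = compute_cam(model, t, view, 1)
            assert heat.values.shape == (8, 8)
            assert np.all(heat.values >= 0.0)


class TestPostprocessing:
    def test_all_distinct_values_retain_exactly_20_percent(self, rng):
        values = rng.permutation(100).reshape(10, 10).astype(float)
        mask, degenerate = select_top_fraction(values, 0.2)
        assert mask.sum() == 20 and not degenerate

    def test_value_threshold_mode(self):
        values = np.linspace(0.0, 1.0, 101)
        mask, _ = select_top_fraction(values, 0.2, mode="value_threshold")
        assert mask.sum() == 21  # values >= 0.8, ties retained
        with pytest.raises(ValueError, match="mode"):
            select_top_fraction(values, 0.2, mode="quantile")

    def test_constant_map_retains_all_and_flags_degeneracy(self):
        mask, degenerate = select_top_fraction(np.ones((5, 5)), 0.2)
        assert mask.all() and degenerate

    def test_all_zero_heatmap_gives_empty_mask(self):
        act = postprocess_cam(Heatmap(np.zeros((8, 8)), 0, "dorsal"), (64, 64))
        assert not act.mask.any() and act.components == []

    def test_postprocess_upsamples_to_input_resolution(self, rng):
        heat = Heatmap(rng.random((8, 8)), 0, "dorsal")
        act = postprocess_cam(heat, (96, 96))
        assert act.mask.shape == (96, 96)
        assert act.mask.sum() > 0

    def test_heatmap_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            Heatmap(np.array([[-1.0, 0.0]]), 0, "dorsal")


class TestComponents:
    def test_two_separate_blobs(self):
        mask = np.zeros((30, 30), bool)
        mask[2:7, 2:7] = True
        mask[20:25, 20:25] = True
        comps = extract_components(mask, min_area_frac=0.001)
        assert len(comps) == 2
        assert sorted(c.area for c in comps) == [25, 25]
        boxes = sorted(c.bbox for c in comps)
        assert boxes == [(2, 2, 7, 7), (20, 20, 25, 25)]

    def test_diagonal_touch_is_one_component_under_8_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only at the corner (3,3)-(4,4)
        comps = extract_components(mask, min_area_frac=0.0)
        assert len(comps) == 1

    def test_small_components_dropped(self):
        mask = np.zeros((100, 100), bool)
        mask[0, 0] = True  # 1 px < 0.1% of 10000
        mask[50:60, 50:60] = True
        comps = extract_components(mask, min_area_frac=0.001)
        assert len(comps) == 1 and comps[0].area == 100

    def test_empty_mask(self):
        assert extract_components(np.zeros((5, 5), bool)) == []

    def test_mask_equals_union_of_components(self, rng):
        raw = rng.random((40, 40)) > 0.7
        act = postprocess_cam(Heatmap(rng.random((8, 8)), 0, "d"), (40, 40))
        union = np.zeros_like(act.mask)
        for c in act.components:
            assert act.mask[c.pixels].all()
            union |= c.pixels
        np.testing.assert_array_equal(union, act.mask)


class TestAssignRegions:
    def _annotation(self):
        ann = np.zeros((20, 20), np.uint8)
        ann[:, :10] = REGION_IDS["legs"]
        ann[:, 10:] = REGION_IDS["thorax"]
        return ann

    def test_full_containment(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 2:8] = True
        assert assign_regions(mask, self._annotation()) == {"legs"}

    def test_split_activation_records_both(self):
        mask = np.zeros((20, 20), bool)
        mask[0, :10] = True  # 10 px legs (50%)
        mask[1, 10:20] = True  # 10 px thorax (50%)
        assert assign_regions(mask, self._annotation(), tau=0.15) == \
            {"legs", "thorax"}

    def test_minority_region_below_tau_excluded(self):
        mask = np.zeros((20, 20), bool)
        mask[0, :9] = True
        mask[0, 10] = True  # 10% thorax < tau
        assert assign_regions(mask, self._annotation(), tau=0.15) == {"legs"}

    def test_background_never_recorded(self):
        ann = np.zeros((20, 20), np.uint8)
        mask = np.ones((20, 20), bool)
        assert assign_regions(mask, ann) == set()

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_regions(np.zeros((10, 10), bool), np.zeros((20, 20)))

    def test_centroid_rule_records_component_centers(self):
        mask = np.zeros((20, 20), bool)
        mask[4:9, 2:7] = True  # centroid (6, 4) -> legs half
        mask[4:9, 13:18] = True  # centroid (6, 15) -> thorax half
        regions = assign_regions(mask, self._annotation(), rule="centroid")
        assert regions == {"legs", "thorax"}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            assign_regions(np.ones((20, 20), bool), self._annotation(),
                           rule="area")


class TestActivationRates:
    def _records(self):
        mk = lambda i, regions: AssignmentRecord(f"s{i}", "A", "lateral",
                                                 set(regions))
        return [mk(0, ["legs"]), mk(1, ["legs"]), mk(2, ["legs", "thorax"]),
                mk(3, ["thorax"])]

    def test_direct_ratio(self):
        table = activation_rates(self._records())
        assert table.rate("A", "lateral", "legs") == pytest.approx(0.75)

    def test_unrecorded_region_is_zero(self):
        table = activation_rates(self._records())
        assert table.rate("A", "lateral", "antennae") == 0.0

    def test_multi_label_rates_sum_above_one(self):
        recs = [AssignmentRecord(f"s{i}", "B", "dorsal", {"legs", "antennae"})
                for i in range(4)]
        table = activation_rates(recs)
        frame = table.to_frame()
        assert frame[frame.subfamily == "B"]["rate"].sum() == pytest.approx(2.0)

    def test_order_invariance(self):
        a = activation_rates(self._records())
        b = activation_rates(list(reversed(self._records())))
        assert a.rates == b.rates

    def test_empty_subset_raises_on_lookup(self):
        table = activation_rates(self._records())
        with pytest.raises(KeyError):
            table.rate("B", "dorsal", "legs")


class TestCohensKappa:
    def test_perfect_agreement(self):
        labels = np.array(["legs", "thorax", "legs", "head"])
        assert cohens_kappa(labels, labels).kappa == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # table (20, 5; 10, 15): p_o = 0.7, p_e = 0.5, kappa = 0.4
        a = np.array([0] * 25 + [1] * 25)
        b = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        res = cohens_kappa(a, b)
        assert res.p_observed == pytest.approx(0.7)
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.4)

    def test_independent_labelings_near_zero(self, rng):
        n = 10_000
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert abs(cohens_kappa(a, b).kappa) < 0.05

    def test_single_shared_category_is_degenerate(self):
        res = cohens_kappa(np.zeros(5, int), np.zeros(5, int))
        assert res.degenerate and np.isnan(res.kappa)

    def test_agreement_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, 200))
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)
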