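"""Singular-value profiles, prototypes and (constrained) soft labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scaleformer as sf
from scaleformer import pipeline
from scaleformer.soft_labeling import assign_slice_labels


class TestSingularProfile:
    def test_rank_one_matrix_has_single_nonzero_value(self):
        u = np.linspace(0.1, 1.0, 64)[:, None]
        v = np.linspace(1.0, 0.2, 64)[None, :]
        profile = sf.slice_singular_profile(u * v, d=10, canonical_size=(64, 64))
        assert profile.values[0] > 0
        np.testing.assert_allclose(profile.values[1:], 0, atol=1e-10)

    def test_matches_dense_svd_oracle_without_resize(self, rng):
        mat = rng.uniform(0, 1, (64, 64))
        profile = sf.slice_singular_profile(mat, d=50, canonical_size=(64, 64))
        oracle = np.linalg.svd(mat, compute_uv=False)[:50]
        np.testing.assert_allclose(profile.values, oracle, rtol=1e-10)

    def test_contract_descending_length_d(self, rng):
        crop = rng.integers(0, 255, (120, 90, 3)).astype(np.uint8)
        profile = sf.slice_singular_profile(crop)
        assert profile.d == 50
        assert np.all(np.diff(profile.values) <= 1e-9)
        assert np.all(profile.values >= 0)

    def test_zero_padding_when_rank_below_d(self):
        mat = np.outer(np.ones(16), np.ones(16))
        profile = sf.slice_singular_profile(mat, d=20, canonical_size=(16, 16))
        assert profile.d == 20
        # one dominant value; the rest is numerical noise, padding exactly 0
        assert np.count_nonzero(profile.values > 1e-8) == 1
        np.testing.assert_array_equal(profile.values[16:], 0.0)

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            sf.slice_singular_profile(np.ones((8, 8)), d=0)


class TestClassPrototypes:
    def test_single_slice_per_class_gives_those_profiles(self):
        profiles = [
            (sf.SingularProfile(np.array([float(4 - i), 1.0, 0.0])), i + 1)
            for i in range(4)
        ]
        protos = sf.fit_class_prototypes(profiles)
        for (p, c) in profiles:
            np.testing.assert_array_equal(protos.s_bar[c - 1], p.values)

    def test_mean_is_idempotent_on_identical_profiles(self):
        p = sf.SingularProfile(np.array([3.0, 2.0, 1.0]))
        others = [(sf.SingularProfile(np.array([1.0, 0.5, 0.1])), c) for c in (2, 3, 4)]
        protos = sf.fit_class_prototypes([(p, 1), (p, 1)] + others)
        np.testing.assert_array_equal(protos.s_bar[0], p.values)

    def test_missing_class_error_names_it(self):
        with pytest.raises(ValueError, match="pT1b"):
            sf.fit_class_prototypes(
                [(sf.SingularProfile(np.array([1.0])), c) for c in (1, 2, 3)]
            )

    def test_synthetic_class_prototypes_are_distinguishable(
        self, dataset, slices_by_slide
    ):
        classes = dataset.slide_classes()
        roi = []
        for sid, slices in slices_by_slide.items():
            for sl in slices:
                if sl.has_roi:
                    roi.append(
                        (sf.slice_singular_profile(sl.crops["10x"]), classes[sid])
                    )
        protos = sf.fit_class_prototypes(roi)
        unit = protos.s_bar / np.linalg.norm(protos.s_bar, axis=1, keepdims=True)
        cosines = unit @ unit.T
        off_diag = cosines[~np.eye(4, dtype=bool)]
        assert off_diag.max() < 1 - 1e-4


class TestSoftLabel:
    def test_profile_equal_to_a_prototype_wins(self):
        # cosine similarity of a profile with itself is maximal, so a slice
        # whose profile coincides with prototype i must be labeled class i
        rows = np.array(
            [
                [4.0, 1.0, 0.5, 0.1],
                [4.0, 3.0, 0.5, 0.1],
                [4.0, 3.0, 2.5, 0.1],
                [4.0, 3.0, 2.5, 2.0],
            ]
        )
        protos = sf.ClassPrototypes(rows)
        for i in range(4):
            y = sf.soft_label(sf.SingularProfile(rows[i]), protos)
            assert y.argmax_class() == i + 1

    def test_identical_prototypes_give_uniform(self):
        protos = sf.ClassPrototypes(np.tile([2.0, 1.0, 0.5], (4, 1)))
        y = sf.soft_label(sf.SingularProfile(np.array([3.0, 1.0, 0.2])), protos)
        np.testing.assert_allclose(y.probs, 0.25)

    def test_probabilities_sum_to_one(self, rng):
        protos = sf.ClassPrototypes(np.sort(rng.uniform(0, 5, (4, 10)))[:, ::-1])
        values = np.sort(rng.uniform(0, 5, 10))[::-1]
        y = sf.soft_label(sf.SingularProfile(values), protos)
        assert y.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        protos = sf.ClassPrototypes(np.ones((4, 5)))
        with pytest.raises(ValueError, match="different d"):
            sf.soft_label(sf.SingularProfile(np.ones(4)), protos)


class TestConstrainLabel:
    def test_worked_examples_match_to_two_decimals(self):
        y1 = sf.constrain_label(
            sf.LabelVector(np.array([0.46, 0.39, 0.08, 0.07]), "soft"), k=3
        )
        np.testing.assert_array_equal(np.round(y1.probs, 2), [0.54, 0.46, 0, 0])
        y2 = sf.constrain_label(
            sf.LabelVector(np.array([0.21, 0.54, 0.10, 0.15]), "soft"), k=3
        )
        np.testing.assert_array_equal(np.round(y2.probs, 2), [0.28, 0.72, 0, 0])

    def test_single_allowed_category_collapses_to_one_hot(self):
        y = sf.constrain_label(sf.LabelVector(np.array([0.5, 0.0, 0.25, 0.25]), "soft"), k=2)
        np.testing.assert_array_equal(y.probs, [1, 0, 0, 0])

    def test_idempotent_on_constrained_vectors(self):
        y = sf.constrain_label(
            sf.LabelVector(np.array([0.46, 0.39, 0.08, 0.07]), "soft"), k=3
        )
        again = sf.constrain_label(y, k=3)
        np.testing.assert_allclose(again.probs, y.probs)

    def test_k_one_refused(self):
        with pytest.raises(ValueError, match="hard"):
            sf.constrain_label(sf.LabelVector(np.full(4, 0.25), "soft"), k=1)

    def test_zero_mass_below_k_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            sf.constrain_label(sf.LabelVector(np.array([0.0, 0.0, 0.5, 0.5]), "soft"), k=3)

    @settings(deadline=None, max_examples=50)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        k=st.integers(2, 4),
    )
    def test_output_on_simplex_with_exact_zeros(self, raw, k):
        probs = np.array(raw) / np.sum(raw)
        y = sf.constrain_label(sf.LabelVector(probs, "soft"), k)
        assert y.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(y.probs[k - 1 :] == 0.0)
        assert y.kind == "constrained_soft"


class TestBaselineLabels:
    def test_smoothed_class3_example(self):
        y = sf.baseline_labels(3, "smoothed", epsilon=0.1)
        np.testing.assert_array_equal(np.round(y.probs, 3), [0.033, 0.033, 0.9, 0.033])

    def test_constrained_smoothing_non_roi_pt1a(self):
        y = sf.baseline_labels(3, "constrained_smoothed", has_roi=False)
        np.testing.assert_array_equal(y.probs, [0.5, 0.5, 0, 0])

    def test_hard_one_hot(self):
        np.testing.assert_array_equal(sf.baseline_labels(1, "hard").probs, [1, 0, 0, 0])

    def test_roi_slice_keeps_hard_label_under_constrained_smoothing(self):
        y = sf.baseline_labels(3, "constrained_smoothed", has_roi=True)
        np.testing.assert_array_equal(y.probs, [0, 0, 1, 0])

    def test_class1_non_roi_falls_back_to_hard(self):
        y = sf.baseline_labels(1, "constrained_smoothed", has_roi=False)
        np.testing.assert_array_equal(y.probs, [1, 0, 0, 0])

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            sf.baseline_labels(2, "smoothed", epsilon=1.0)


def test_constrained_soft_labels_recover_true_lower_class(
    dataset, slices_by_slide
):
    """On synthetic slides, the constrained soft label's argmax should point
    at the texture class the non-ROI slice was actually generated with, for
    the clear majority of slices whose true class is below the slide's."""
    classes = dataset.slide_classes()
    assign_slice_labels(slices_by_slide, classes, scheme="constrained_soft")
    hits = total = 0
    for sid, slices in slices_by_slide.items():
        k = classes[sid]
        if k == 1:
            continue
        truth = pipeline.match_slices_to_blobs(slices, dataset.registry[sid])
        for sl in slices:
            if sl.has_roi or truth[sl.slice_id] >= k:
                continue
            total += 1
            hits += sl.label.argmax_class() == truth[sl.slice_id]
    assert total >= 10
    assert hits / total >= 0.7
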