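"""Bias correction, probability maps, kNN segmentation and volumetry."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from clinmri.dicom_io import BACKGROUND, CSF, GM, WM, ImageVolume, LabelVolume
from clinmri.phantom import (
    AtlasJitter,
    PhantomSpec,
    generate_atlas_set,
    generate_phantom,
)
from clinmri.segmentation import (
    BiasConfig,
    KnnConfig,
    KnnModel,
    ProbabilityMap,
    build_probability_map,
    compute_volumes,
    correct_bias,
    knn_segment,
    majority_mask,
    sample_training_set,
)


def brute_force_knn(features, classes, query, k):
    """Independent oracle: exhaustive inclusive-shell nearest-neighbour vote."""
    out = np.empty(len(query), dtype=np.int16)
    for qi, q in enumerate(query):
        d = np.sqrt(((features - q) ** 2).sum(axis=1))
        kth = np.sort(d)[k - 1]
        shell = d <= kth
        best = None
        for cls in (CSF, GM, WM):
            sel = shell & (classes == cls)
            count = sel.sum()
            mean = d[sel].mean() if count else np.inf
            key = (-count, mean, cls)
            if best is None or key < best[0]:
                best = (key, cls)
        out[qi] = best[1]
    return out


class TestCorrectBias:
    def test_bias_free_phantom_gives_unit_field(self, default_phantom):
        volume, _, _ = default_phantom
        _, field = correct_bias(volume)
        assert np.max(np.abs(field - 1.0)) < 0.02

    def test_known_quadratic_field_reduces_wm_variation(self):
        spec = PhantomSpec(seed=6, bias_amplitude=0.2, class_noise_sd=0.0)
        volume, labels, _ = generate_phantom(spec)
        wm = labels.data == WM
        cv_before = volume.data[wm].std() / volume.data[wm].mean()
        corrected, _ = correct_bias(volume)
        cv_after = corrected.data[wm].std() / corrected.data[wm].mean()
        assert cv_after <= 0.5 * cv_before

    def test_field_strictly_positive_and_mean_preserved(self, default_phantom):
        volume, _, _ = default_phantom
        corrected, field = correct_bias(volume)
        assert np.all(field > 0)
        fg = volume.data > 50
        assert corrected.data[fg].mean() == pytest.approx(
            volume.data[fg].mean(), rel=1e-6
        )

    def test_all_zero_image_is_error(self):
        with pytest.raises(ValueError):
            correct_bias(ImageVolume(np.zeros((8, 8, 8)), (3, 3, 3)))


@pytest.fixture(scope="module")
def identity_pmap(noise_free_phantom):
    """Six identical identity-posed atlases registered to themselves."""
    spec = PhantomSpec(seed=2, class_noise_sd=0.0)
    atlases = generate_atlas_set(spec, n=6, jitter=AtlasJitter.none())
    volume, labels, _ = noise_free_phantom
    pmap, masks = build_probability_map(atlases, volume)
    return pmap, masks, labels


@pytest.fixture(scope="module")
def unanimous(noise_free_phantom):
    volume, labels, _ = noise_free_phantom
    votes = np.zeros((4,) + labels.shape)
    for cls in (BACKGROUND, CSF, GM, WM):
        votes[cls] = labels.data == cls
    return volume, labels, ProbabilityMap(votes, 6, volume)


class TestProbabilityMap:
    def test_identical_atlases_give_binary_probabilities(self, identity_pmap):
        pmap, _, labels = identity_pmap
        probs = pmap.probabilities
        assert set(np.unique(probs)) <= {0.0, 1.0}
        recovered = probs.argmax(axis=0)
        agreement = (recovered == labels.data).mean()
        assert agreement > 0.999

    def test_probabilities_sum_to_one(self, identity_pmap):
        pmap, _, _ = identity_pmap
        assert np.allclose(pmap.probabilities.sum(axis=0), 1.0, atol=1e-9)

    def test_quantized_to_atlas_count(self, atlas_set6, posed_subject):
        _, (volume, _, _) = posed_subject
        pmap, _ = build_probability_map(atlas_set6, volume)
        scaled = pmap.probabilities * pmap.n_atlases
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)

    def test_half_votes_average_to_half(self):
        votes = np.zeros((4, 2, 2, 2))
        votes[GM] = 0.5
        votes[WM] = 0.5
        pmap = ProbabilityMap(votes, 6, None)
        assert pmap.class_probability(GM)[0, 0, 0] == 0.5


class TestMajorityMask:
    @pytest.mark.parametrize("votes, included", [(5, True), (4, False), (6, True)])
    def test_vote_thresholds_of_six(self, votes, included):
        masks = [np.ones((2, 2, 2), dtype=np.uint8)] * votes + [
            np.zeros((2, 2, 2), dtype=np.uint8)
        ] * (6 - votes)
        out = majority_mask(masks, threshold=0.8)
        assert bool(out[0, 0, 0]) is included

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            majority_mask([])


class TestSampleTrainingSet:
    def test_unanimous_samples_match_ground_truth(self, unanimous):
        volume, labels, pmap = unanimous
        model = sample_training_set(volume, pmap, KnnConfig(seed=3))
        means = {CSF: 450.0, GM: 620.0, WM: 800.0}
        for cls in (CSF, GM, WM):
            sel = model.classes == cls
            assert sel.sum() <= 2000
            assert np.all(model.features[sel, 0] == means[cls])

    def test_seeded_resampling_is_identical(self, unanimous):
        volume, _, pmap = unanimous
        m1 = sample_training_set(volume, pmap, KnnConfig(seed=5))
        m2 = sample_training_set(volume, pmap, KnnConfig(seed=5))
        assert np.array_equal(m1.features, m2.features)
        assert np.array_equal(m1.classes, m2.classes)

    def test_threshold_fallback_warns_then_errors(self, unanimous):
        volume, labels, pmap = unanimous
        # knock CSF below unanimity everywhere: threshold must step down
        probs = pmap.probabilities.copy()
        probs[CSF] *= 5 / 6
        probs[BACKGROUND] += pmap.probabilities[CSF] / 6
        lowered = ProbabilityMap(probs, 6, volume)
        with pytest.warns(UserWarning):
            model = sample_training_set(volume, lowered, KnnConfig(seed=3))
        assert (model.classes == CSF).sum() >= 45
        # zero out a class entirely: no threshold can save it
        probs2 = pmap.probabilities.copy()
        probs2[BACKGROUND] += probs2[WM]
        probs2[WM] = 0.0
        dead = ProbabilityMap(probs2, 6, volume)
        with pytest.raises(ValueError, match="3"), pytest.warns(UserWarning):
            sample_training_set(volume, dead, KnnConfig(seed=3))


class TestKnnSegment:
    def test_separated_intensities_recover_truth_with_k1(self,
                                                         noise_free_phantom):
        volume, labels, _ = noise_free_phantom
        features = np.array([[450.0], [620.0], [800.0]] * 45)
        classes = np.array([CSF, GM, WM] * 45)
        model = KnnModel(features, classes, k=1)
        icv = labels.data > 0
        out = knn_segment(volume, model, icv)
        assert np.array_equal(out.data[icv], labels.data[icv])

    def test_outside_mask_is_background(self, noise_free_phantom):
        volume, labels, _ = noise_free_phantom
        model = KnnModel(
            np.array([[450.0], [620.0], [800.0]] * 45),
            np.array([CSF, GM, WM] * 45),
            k=1,
        )
        icv = labels.data > 0
        out = knn_segment(volume, model, icv)
        assert np.all(out.data[~icv] == BACKGROUND)

    def test_matches_brute_force_oracle_small_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n_train, n_query = 300, 500
            feats = np.round(rng.normal(600, 120, (n_train, 1)))
            classes = rng.choice([CSF, GM, WM], n_train)
            model = KnnModel(feats, classes, k=45)
            grid = np.round(rng.normal(600, 150, (8, 8, 8)))
            vol = ImageVolume(grid, (3, 3, 3))
            mask = rng.random((8, 8, 8)) < 0.98
            out = knn_segment(vol, model, mask.astype(np.uint8))
            expected = brute_force_knn(
                feats, classes, grid.reshape(-1, 1)[mask.ravel()], 45
            )
            assert np.array_equal(out.data.ravel()[mask.ravel()], expected)

    def test_rescaling_invariance(self, noise_free_phantom):
        # training and query intensities scale together: labels unchanged
        volume, labels, _ = noise_free_phantom
        icv = labels.data > 0
        votes = np.zeros((4,) + labels.shape)
        for cls in (BACKGROUND, CSF, GM, WM):
            votes[cls] = labels.data == cls
        pmap = ProbabilityMap(votes, 6, volume)
        model = sample_training_set(volume, pmap, KnnConfig(seed=9))
        out1 = knn_segment(volume, model, icv)

        scaled = volume.with_data(volume.data * 2.5)
        pmap2 = ProbabilityMap(votes, 6, scaled)
        model2 = sample_training_set(scaled, pmap2, KnnConfig(seed=9))
        out2 = knn_segment(scaled, model2, icv)
        assert np.array_equal(out1.data, out2.data)

    def test_determinism(self, noise_free_phantom):
        volume, labels, _ = noise_free_phantom
        model = KnnModel(
            np.array([[450.0], [620.0], [800.0]] * 45),
            np.array([CSF, GM, WM] * 45),
            k=5,
        )
        icv = labels.data > 0
        out1 = knn_segment(volume, model, icv)
        out2 = knn_segment(volume, model, icv)
        assert np.array_equal(out1.data, out2.data)

    def test_too_few_samples_per_class_is_training_error(self):
        with pytest.raises(ValueError):
            KnnModel(np.array([[1.0], [2.0], [3.0]]),
                     np.array([CSF, GM, WM]), k=2)


class TestComputeVolumes:
    def test_thousand_gm_voxels_at_one_mm3_is_one_ml(self):
        data = np.zeros((10, 10, 10), dtype=np.int16)
        data.ravel()[:1000] = GM
        labels = LabelVolume(data, (1.0, 1.0, 1.0))
        record = compute_volumes(labels)
        assert record.gm_ml == pytest.approx(1.0)

    def test_sum_identities_hold_exactly(self, default_phantom):
        _, labels, _ = default_phantom
        record = compute_volumes(labels)
        assert record.icv_ml - (record.csf_ml + record.gm_ml + record.wm_ml) == 0.0
        assert record.brain_ml - (record.gm_ml + record.wm_ml) == 0.0

    def test_noise_free_phantom_volumes_near_analytic_truth(
        self, noise_free_spec, noise_free_phantom
    ):
        from clinmri.phantom import analytic_volumes_ml

        _, labels, _ = noise_free_phantom
        record = compute_volumes(labels)
        truth = analytic_volumes_ml(noise_free_spec)
        for key in ("csf_ml", "gm_ml", "wm_ml"):
            assert getattr(record, key) == pytest.approx(truth[key], rel=0.05)

    def test_cerebrum_restricted_volume(self, default_phantom):
        _, labels, _ = default_phantom
        cerebrum = np.isin(labels.data, [GM, WM]).astype(np.uint8)
        record = compute_volumes(labels, cerebrum_mask=cerebrum)
        assert record.cerebrum_brain_ml == pytest.approx(record.brain_ml)
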