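"""Mutual information, pose recovery and transform application."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from clinmri.dicom_io import ImageVolume, LabelVolume
from clinmri.phantom import Ellipsoid, PhantomSpec, Pose, generate_phantom
from clinmri.registration import (
    AffineTransform,
    RegistrationConfig,
    affine_register,
    apply_transform,
    entropy,
    mutual_information,
    nonrigid_register,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def _pose_error_mm(transform: AffineTransform, pose: Pose) -> float:
    """Max discrepancy between recovered and true fixed->moving map."""
    rot = pose.rotation_matrix()
    t = np.array(pose.translation_mm)
    probes = np.array(
        [[0, 0, 0], [30, 0, 0], [0, 40, 0], [0, 0, 30], [-30, -30, -20.0]]
    )
    true = ((probes - t) @ rot) / pose.scale
    return float(np.linalg.norm(transform.apply(probes) - true, axis=1).max())


class TestMutualInformation:
    def test_self_information_equals_entropy(self, default_phantom):
        volume, _, _ = default_phantom
        mi = mutual_information(volume, volume, bins=32)
        assert mi == pytest.approx(entropy(volume, bins=32), abs=1e-9)

    def test_symmetric(self, default_phantom, noise_free_phantom):
        a = default_phantom[0]
        b = noise_free_phantom[0]
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-12
        )

    def test_permuted_voxels_carry_almost_no_information(self, default_phantom):
        volume, _, _ = default_phantom
        rng = np.random.default_rng(0)
        replicates = [
            mutual_information(
                volume.data, rng.permutation(volume.data.ravel()), bins=32
            )
            for _ in range(5)
        ]
        # permutation destroys spatial correspondence; MI should sit at the
        # finite-sample floor, far below the self-information
        self_mi = mutual_information(volume, volume)
        assert max(replicates) < 0.05 * self_mi
        assert np.mean(replicates) + 3 * np.std(replicates) < 0.05 * self_mi

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            mutual_information(np.zeros(10), np.zeros(11))
        with pytest.raises(ValueError):
            mutual_information(np.zeros(10), np.zeros(10), bins=1)


class TestAffineRegister:
    def test_identical_volumes_give_identity(self, default_phantom):
        volume, _, _ = default_phantom
        transform, mi = affine_register(volume, volume)
        # recovered map should move points by well under 0.1 voxel (0.3 mm)
        probes = np.array([[0, 0, 0], [30, 20, 10], [-40, 10, -20.0]])
        drift = np.linalg.norm(transform.apply(probes) - probes, axis=1).max()
        assert drift < 0.3
        assert mi == pytest.approx(mutual_information(volume, volume), rel=0.05)

    @pytest.mark.parametrize("shift", [(6.0, 0.0, 0.0), (10.0, -8.0, 6.0)])
    def test_translation_recovery_within_half_voxel(self, default_phantom,
                                                    shift):
        moving, _, _ = default_phantom
        pose = Pose(translation_mm=shift)
        spec = dataclasses.replace(PhantomSpec(seed=1), pose=pose, seed=31)
        fixed, _, _ = generate_phantom(spec)
        transform, _ = affine_register(moving, fixed)
        assert _pose_error_mm(transform, pose) < 1.5  # 0.5 voxel at 3 mm

    @pytest.mark.parametrize("angles", [(5.0, 0.0, 0.0), (0.0, 0.0, 10.0)])
    def test_rotation_recovery_within_one_degree(self, default_phantom, angles):
        moving, _, _ = default_phantom
        pose = Pose(rotation_deg=angles)
        spec = dataclasses.replace(PhantomSpec(seed=1), pose=pose, seed=32)
        fixed, _, _ = generate_phantom(spec)
        transform, _ = affine_register(moving, fixed)
        rot = pose.rotation_matrix()
        u, _, vt = np.linalg.svd(transform.matrix)
        recovered = u @ vt
        cos = (np.trace(recovered @ rot) - 1.0) / 2.0
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_deterministic(self, default_phantom, noise_free_phantom):
        moving = default_phantom[0]
        fixed = noise_free_phantom[0]
        t1, mi1 = affine_register(moving, fixed)
        t2, mi2 = affine_register(moving, fixed)
        assert np.array_equal(t1.matrix, t2.matrix)
        assert np.array_equal(t1.translation, t2.translation)
        assert mi1 == mi2

    def test_serialization_round_trip(self):
        t = AffineTransform(np.eye(3) * 1.1, [1.0, -2.0, 3.0], [0.5, 0, 0])
        back = AffineTransform.deserialize(t.serialize())
        assert np.allclose(back.matrix, t.matrix)
        assert np.allclose(back.translation, t.translation)

    def test_inverse_composes_to_identity(self):
        t = AffineTransform(
            np.array([[1.1, 0.02, 0], [0, 0.95, 0.01], [0.03, 0, 1.0]]),
            [4.0, -2.0, 1.0],
        )
        points = np.array([[10.0, -5.0, 3.0], [0, 0, 0]])
        assert np.allclose(t.inverse().apply(t.apply(points)), points,
                           atol=1e-6)


class TestNonrigid:
    def test_identical_volumes_near_zero_displacement(self, default_phantom):
        volume, _, _ = default_phantom
        field, _ = nonrigid_register(
            volume, volume, AffineTransform.identity()
        )
        assert field.max_displacement() < 0.75  # 0.25 voxel at 3 mm

    def test_displacement_cap_respected(self, default_phantom,
                                        noise_free_phantom):
        config = RegistrationConfig(displacement_cap_mm=2.0)
        field, _ = nonrigid_register(
            default_phantom[0],
            noise_free_phantom[0],
            AffineTransform.identity(),
            config,
        )
        assert np.max(np.abs(field.coefficients)) <= 2.0

    def test_refines_structure_no_affine_can_express(self, default_phantom):
        # subject whose inner shells are shifted relative to the outer ones:
        # a global affine cannot align both, a coarse warp can do better
        geometry = dict(PhantomSpec().tissue_geometry)
        for name in ("gm", "wm"):
            e = geometry[name]
            geometry[name] = Ellipsoid(
                (e.center[0], e.center[1] + 7.0, e.center[2]), e.semi_axes
            )
        spec = dataclasses.replace(
            PhantomSpec(seed=33), tissue_geometry=geometry
        )
        subject, subject_labels, _ = generate_phantom(spec)
        moving, moving_labels, _ = default_phantom

        affine, _ = affine_register(moving, subject)
        field, _ = nonrigid_register(moving, subject, affine)
        after_affine = apply_transform(moving_labels, affine, subject, "nearest")
        after_warp = apply_transform(moving_labels, field, subject, "nearest")
        dice_affine = dice(after_affine.data == 3, subject_labels.data == 3)
        dice_warp = dice(after_warp.data == 3, subject_labels.data == 3)
        assert dice_warp >= dice_affine


class TestApplyTransform:
    def test_identity_transform_is_identity(self, default_phantom):
        volume, labels, _ = default_phantom
        out = apply_transform(volume, AffineTransform.identity(), volume)
        assert np.allclose(out.data, volume.data)
        lout = apply_transform(labels, AffineTransform.identity(), labels,
                               "nearest")
        assert np.array_equal(lout.data, labels.data)

    def test_labels_with_linear_interpolation_rejected(self, default_phantom):
        _, labels, _ = default_phantom
        with pytest.raises(ValueError):
            apply_transform(labels, AffineTransform.identity(), labels,
                            "linear")

    def test_labels_only_take_input_values(self, default_phantom):
        _, labels, _ = default_phantom
        shift = AffineTransform(np.eye(3), [4.4, -2.7, 1.3])
        out = apply_transform(labels, shift, labels, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))

    def test_translate_inverse_translate_mask_round_trip(self, default_phantom):
        _, labels, _ = default_phantom
        mask = labels.data > 0
        vol = ImageVolume(mask.astype(float), labels.spacing, labels.origin)
        shift = AffineTransform(np.eye(3), [4.0, 5.0, -3.0])
        there = apply_transform(vol, shift, vol, "nearest")
        back = apply_transform(there, shift.inverse(), vol, "nearest")
        assert dice(back.data > 0.5, mask) >= 0.95
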