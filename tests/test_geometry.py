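import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymmorph import (
    LandmarkConfiguration,
    TpsModel,
    align_mirrored,
    estimate_missing,
    fit_symmetry_plane,
    gpa,
    mirror_fill,
)
from asymmorph.geometry import (
    GeometryError,
    centroid_size,
    procrustes_distance,
)
from asymmorph.synthetic import AsymmetrySpec, apply_asymmetry


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestSymmetryPlane:
    def test_symmetric_template_midline_on_plane(self, template, scheme):
        plane = fit_symmetry_plane(template, scheme)
        for m in scheme.midline:
            d = abs((template.coords[m] - plane.point) @ plane.normal)
            assert d < 1e-9

    def test_coplanar_anchors_zero_residual(self):
        from asymmorph import LandmarkScheme

        scheme = LandmarkScheme(
            n_total=5, pairs=((0, 4),), midline=(1, 2, 3),
            regions=dict.fromkeys(range(5), "other"),
        )
        # pair symmetric about y = 0 and three midline points in that plane
        coords = np.array(
            [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 1.0], [3.0, 0.0, 0.5],
             [0.0, -1.0, 0.0]]
        )
        cfg = LandmarkConfiguration("A", coords, np.zeros(5, bool))
        plane = fit_symmetry_plane(cfg, scheme, use_pair_midpoints=True)
        for p in [coords[1], coords[2], coords[3], (coords[0] + coords[4]) / 2]:
            assert abs((p - plane.point) @ plane.normal) < 1e-12

    def test_matches_eigen_oracle(self, scheme):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(123, 3)) * [5, 1, 2]
        cfg = LandmarkConfiguration("A", coords, np.zeros(123, bool))
        plane = fit_symmetry_plane(cfg, scheme, use_pair_midpoints=True)
        # oracle: eigen-decomposition of the anchor scatter
        anchors = [coords[m] for m in scheme.midline]
        anchors += [(coords[l] + coords[r]) / 2 for l, r in scheme.pairs]
        A = np.asarray(anchors)
        A = A - A.mean(axis=0)
        w, v = np.linalg.eigh(A.T @ A)
        oracle_normal = v[:, 0]
        assert min(
            np.linalg.norm(plane.normal - oracle_normal),
            np.linalg.norm(plane.normal + oracle_normal),
        ) < 1e-10

    def test_too_few_anchors(self, tiny_scheme):
        coords = np.zeros((3, 3))
        cfg = LandmarkConfiguration("A", coords, np.array([True, True, True]))
        with pytest.raises(GeometryError, match="cannot fit plane"):
            fit_symmetry_plane(cfg, tiny_scheme)

    def test_reflection_involution(self, template, scheme):
        plane = fit_symmetry_plane(template, scheme)
        pts = np.random.default_rng(0).normal(size=(20, 3)) * 100
        assert np.allclose(plane.reflect(plane.reflect(pts)), pts, atol=1e-12)


class TestMirrorFill:
    def test_symmetric_template_fixed_point(self, template, scheme):
        rn = mirror_fill(template, scheme)
        assert np.abs(rn.coords - template.coords).max() < 1e-9

    def test_planted_displacement_recovered(self, template, scheme):
        # displace one right nasal landmark 2 mm leftward (+y)
        nasal_right = [
            i for i in scheme.region_indices("nasal") if i in scheme.right_indices
        ]
        r = nasal_right[0]
        cfg = template.copy()
        cfg.coords[r] += np.array([0.0, 2.0, 0.0])
        rn = mirror_fill(cfg, scheme)
        assert np.linalg.norm(cfg.coords[r] - rn.coords[r]) == pytest.approx(2.0, abs=1e-9)

    def test_left_and_midline_copied(self, template, scheme):
        rn = mirror_fill(template, scheme)
        for i in list(scheme.left_indices) + list(scheme.midline):
            assert np.array_equal(rn.coords[i], template.coords[i])

    def test_missing_left_propagates(self, template, scheme):
        jugal_left = [
            i for i in scheme.region_indices("jugal") if i in scheme.left_indices
        ]
        l = jugal_left[0]
        r = scheme.partner(l)
        cfg = template.copy()
        cfg.missing[l] = True
        rn = mirror_fill(cfg, scheme)
        assert rn.missing[r]


class TestTps:
    def test_interpolates_control_points(self):
        rng = np.random.default_rng(1)
        src = rng.normal(size=(20, 3))
        tgt = src + rng.normal(0, 0.3, size=(20, 3))
        tps = TpsModel.fit(src, tgt)
        assert np.abs(tps.transform(src) - tgt).max() < 1e-8

    def test_affine_map_zero_bending(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(15, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        tgt = src @ A.T + b
        tps = TpsModel.fit(src, tgt)
        assert tps.bending_energy == pytest.approx(0.0, abs=1e-6)
        probe = rng.normal(size=(10, 3)) * 2
        assert np.abs(tps.transform(probe) - (probe @ A.T + b)).max() < 1e-8

    def test_coplanar_rejected(self):
        src = np.random.default_rng(0).normal(size=(10, 3))
        src[:, 2] = 0.0
        with pytest.raises(GeometryError, match="coplanar"):
            TpsModel.fit(src, src)


class TestEstimateMissing:
    def test_complete_config_unchanged(self, template):
        out = estimate_missing(template, template)
        assert np.array_equal(out.coords, template.coords)
        assert out.estimated == ()

    def test_identity_warp_restores_exactly(self, template):
        cfg = template.copy()
        cfg.missing[40] = True
        cfg.coords[40] = np.nan
        out = estimate_missing(cfg, template)
        assert np.linalg.norm(out.coords[40] - template.coords[40]) < 1e-6
        assert out.estimated == (40,)
        assert not out.missing.any()

    def test_affine_deformation_oracle(self, template):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3)) * 0.1 + np.eye(3)
        b = rng.normal(size=3) * 10
        target = LandmarkConfiguration(
            "warped", template.coords @ A.T + b, np.zeros(template.n_landmarks, bool)
        )
        cfg = target.copy()
        for i in (5, 70, 100):
            cfg.missing[i] = True
            cfg.coords[i] = np.nan
        out = estimate_missing(cfg, template)
        scale = centroid_size(target.coords)
        for i in (5, 70, 100):
            expected = template.coords[i] @ A.T + b
            assert np.linalg.norm(out.coords[i] - expected) < 1e-8 * scale

    def test_incomplete_reference_rejected(self, template):
        ref = template.copy()
        ref.missing[0] = True
        cfg = template.copy()
        cfg.missing[1] = True
        with pytest.raises(GeometryError, match="complete"):
            estimate_missing(cfg, ref)


class TestGpa:
    def _rigid_copies(self, template, n, seed=0, scale_spread=True):
        rng = np.random.default_rng(seed)
        configs = []
        for i in range(n):
            R = _random_rotation(rng)
            s = rng.uniform(0.5, 2.0) if scale_spread else 1.0
            t = rng.normal(size=3) * 50
            configs.append(
                LandmarkConfiguration(
                    f"c{i}", template.coords @ R.T * s + t, np.zeros(template.n_landmarks, bool)
                )
            )
        return configs

    def test_rigid_motion_superimposes_exactly(self, template):
        configs = self._rigid_copies(template, 2, seed=4)
        aligned = gpa(configs)
        d = np.sqrt(((aligned.coords[0] - aligned.coords[1]) ** 2).sum())
        assert d < 1e-10

    def test_unit_centroid_sizes(self, template):
        configs = self._rigid_copies(template, 5, seed=5)
        aligned = gpa(configs)
        for shape in aligned.coords:
            assert centroid_size(shape) == pytest.approx(1.0, abs=1e-12)

    def test_rotations_proper(self, template):
        configs = self._rigid_copies(template, 4, seed=6)
        aligned = gpa(configs)
        for tr in aligned.transforms:
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_objective_non_increasing(self, template):
        rng = np.random.default_rng(8)
        configs = []
        for i in range(6):
            noisy = template.coords + rng.normal(0, 5, template.coords.shape)
            configs.append(
                LandmarkConfiguration(f"c{i}", noisy, np.zeros(template.n_landmarks, bool))
            )
        aligned = gpa(configs)
        hist = aligned.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_reflection_not_absorbed(self, template):
        mirror = template.coords * np.array([1.0, -1.0, 1.0])
        d_proper = procrustes_distance(template.coords, mirror, allow_reflection=False)
        d_improper = procrustes_distance(template.coords, mirror, allow_reflection=True)
        assert d_improper < 1e-10
        assert d_proper > 1e-3

    def test_single_configuration_centered_scaled(self, template):
        aligned = gpa([template])
        assert centroid_size(aligned.coords[0]) == pytest.approx(1.0, abs=1e-12)
        assert np.abs(aligned.coords[0].mean(axis=0)).max() < 1e-12

    def test_incomplete_rejected(self, template):
        cfg = template.copy()
        cfg.missing[0] = True
        with pytest.raises(GeometryError, match="incomplete"):
            gpa([cfg])


class TestAlignMirrored:
    def test_symmetric_template_coincides(self, template, scheme):
        aligned = gpa([template])
        rn = mirror_fill(template, scheme)
        out = align_mirrored(aligned, rn)
        assert np.abs(out - aligned.coords[0]).max() < 1e-9

    def test_displacement_scales_by_centroid_size(self, template, scheme):
        spec = AsymmetrySpec(regions=("nasal",), magnitude=2.0, side="right")
        cfg = apply_asymmetry(template.copy(), spec, scheme)
        s = centroid_size(cfg.coords)
        aligned = gpa([cfg])
        rn = mirror_fill(cfg, scheme)
        out = align_mirrored(aligned, rn)
        from asymmorph.synthetic import affected_landmarks

        for i in affected_landmarks(spec, scheme):
            d = np.linalg.norm(aligned.coords[0][i] - out[i])
            assert d == pytest.approx(2.0 / s, rel=1e-6)

    def test_transform_not_idempotent(self, template, scheme):
        cfg = template.copy()
        cfg.coords = cfg.coords * 2.0 + 10.0  # non-trivial transform
        aligned = gpa([cfg])
        rn = mirror_fill(cfg, scheme)
        once = align_mirrored(aligned, rn)
        tr = aligned.transform_for(cfg.specimen_id)
        twice = tr.apply(once)
        assert not np.allclose(once, twice)

    def test_unknown_source_rejected(self, template, scheme):
        aligned = gpa([template])
        rn = mirror_fill(template, scheme)
        rn.source = "nope"
        with pytest.raises(GeometryError, match="nope"):
            align_mirrored(aligned, rn)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_reflection_involution_property(seed):
    from asymmorph.geometry import SymmetryPlane

    rng = np.random.default_rng(seed)
    n = rng.normal(size=3)
    n = n / np.linalg.norm(n)
    plane = SymmetryPlane(point=rng.normal(size=3), normal=n)
    pts = rng.normal(size=(5, 3)) * 10
    assert np.allclose(plane.reflect(plane.reflect(pts)), pts, atol=1e-12)
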