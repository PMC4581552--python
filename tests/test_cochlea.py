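"""Cochlea model: mesh slicing, plane projection, size metric, generator."""

import numpy as np
import pytest

from cisim.cochlea import (
    CochleaContour2D,
    LumenWidthProfile,
    ModiolarAxis,
    measure_distance_A,
    project_to_plane,
    sample_cross_sections,
    synthesize_cochlea,
)
from cisim.errors import (
    DegeneratePlaneError,
    InsufficientCoverageError,
    InvalidConfigError,
    InvalidInputError,
)

from helpers import helical_tube_mesh


AXIS = ModiolarAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


class TestCrossSections:
    def test_tube_width_matches_diameter(self):
        mesh = helical_tube_mesh(tube_radius=0.5, helix_radius=4.0, turns=2.0)
        samples = sample_cross_sections(mesh, AXIS, step_deg=5.0)
        widths = np.array(
            [np.linalg.norm(s.outer_point - s.inner_point) for s in samples]
        )
        assert np.all(np.abs(widths - 1.0) / 1.0 < 0.05)

    def test_two_turns_at_five_degrees_gives_144_samples(self):
        mesh = helical_tube_mesh(turns=2.0, pitch_per_turn=1.5)
        samples = sample_cross_sections(mesh, AXIS, step_deg=5.0)
        assert len(samples) == 144

    def test_reversed_axis_gives_same_sample_set(self):
        mesh = helical_tube_mesh(turns=1.5)
        fwd = sample_cross_sections(mesh, AXIS, step_deg=15.0)
        rev = sample_cross_sections(
            mesh,
            ModiolarAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, -1.0])),
            step_deg=15.0,
        )

        def key(s):
            return tuple(np.round(np.concatenate([s.inner_point, s.outer_point]), 5))

        assert sorted(map(key, fwd)) == sorted(map(key, rev))


class TestPlaneProjection:
    def _coplanar_samples(self, n=24, normal=None, noise=0.0, rng=None):
        from cisim.cochlea import CrossSectionSample

        rng = rng or np.random.default_rng(7)
        normal = np.array([0.0, 0.0, 1.0]) if normal is None else normal
        normal = normal / np.linalg.norm(normal)
        # orthonormal basis of the plane
        helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(normal, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        ang = np.deg2rad(np.linspace(0, 400, n))
        r_out = 5.0 * np.exp(-0.1 * np.deg2rad(np.linspace(0, 400, n)))
        samples = []
        for a, ro in zip(ang, r_out):
            for r, which in ((ro - 1.5, "inner"), (ro, "outer")):
                pass
            inner3 = (ro - 1.5) * (np.cos(a) * e1 + np.sin(a) * e2)
            outer3 = ro * (np.cos(a) * e1 + np.sin(a) * e2)
            if noise:
                inner3 = inner3 + rng.normal(0, noise, 3)
                outer3 = outer3 + rng.normal(0, noise, 3)
            samples.append(
                CrossSectionSample(
                    plane_angle=np.degrees(a), inner_point=inner3, outer_point=outer3
                )
            )
        return samples, normal

    def test_coplanar_samples_recovered_exactly(self):
        samples, _ = self._coplanar_samples()
        contour = project_to_plane(samples, canonicalize=False)
        # all points must be in the fitted plane: 2D embedding is lossless,
        # so pairwise distances survive the projection
        inner3 = np.array([s.inner_point for s in samples])
        d3 = np.linalg.norm(np.diff(inner3, axis=0), axis=1)
        d2 = np.linalg.norm(np.diff(contour.inner_contour, axis=0), axis=1)
        assert np.allclose(d3, d2, atol=1e-9)

    def test_noisy_plane_normal_within_two_degrees_of_svd_oracle(self):
        samples, true_normal = self._coplanar_samples(
            normal=np.array([0.2, -0.1, 1.0]), noise=0.05
        )
        pts = np.vstack(
            [[s.inner_point for s in samples], [s.outer_point for s in samples]]
        )
        c = pts.mean(axis=0)
        oracle_normal = np.linalg.svd(pts - c)[2][2]
        from cisim.cochlea import fit_odr_plane

        _, _, _, normal = fit_odr_plane(pts)
        cosang = abs(np.dot(normal, oracle_normal))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1e-9  # same SVD
        cos_truth = abs(np.dot(normal, true_normal / np.linalg.norm(true_normal)))
        assert np.degrees(np.arccos(np.clip(cos_truth, -1, 1))) < 2.0

    def test_too_few_samples_rejected(self):
        samples, _ = self._coplanar_samples()
        with pytest.raises(InvalidInputError):
            project_to_plane(samples[:5])

    def test_collinear_points_degenerate(self):
        from cisim.cochlea import CrossSectionSample

        samples = [
            CrossSectionSample(
                plane_angle=10.0 * i,
                inner_point=np.array([float(i), 0.0, 0.0]),
                outer_point=np.array([float(i) + 0.5, 0.0, 0.0]),
            )
            for i in range(8)
        ]
        with pytest.raises(DegeneratePlaneError):
            project_to_plane(samples)

    def test_projection_idempotent_on_projected_samples(self):
        from cisim.cochlea import CrossSectionSample

        samples, _ = self._coplanar_samples()
        first = project_to_plane(samples)
        rebuilt = [
            CrossSectionSample(
                plane_angle=s.plane_angle,
                inner_point=np.append(p_in, 0.0),
                outer_point=np.append(p_out, 0.0),
            )
            for s, p_in, p_out in zip(
                samples, first.inner_contour, first.outer_contour
            )
        ]
        second = project_to_plane(rebuilt)
        assert np.allclose(second.inner_contour, first.inner_contour, atol=1e-9)
        assert np.allclose(second.outer_contour, first.outer_contour, atol=1e-9)


class TestDistanceA:
    def test_generator_roundtrip(self):
        contour = synthesize_cochlea(A_mm=9.0)
        assert abs(measure_distance_A(contour) - 9.0) <= 0.05

    def test_similarity_invariance(self, cm_cochlea):
        scaled = cm_cochlea.scaled(1.1)
        assert np.isclose(
            measure_distance_A(scaled), 1.1 * measure_distance_A(cm_cochlea)
        )

    def test_circle_annulus_gives_diameter(self):
        th = np.linspace(0, 2.05 * np.pi, 300)
        outer = 4.5 * np.column_stack([np.cos(th), np.sin(th)])
        inner = 3.5 * np.column_stack([np.cos(th), np.sin(th)])
        contour = CochleaContour2D(
            inner_contour=inner,
            outer_contour=outer,
            cochleostomy_point=0.5 * (inner[0] + outer[0]),
            entry_direction=np.array([-1.0, 0.0]),
        )
        assert abs(measure_distance_A(contour) - 9.0) < 1e-3

    def test_insufficient_coverage_rejected(self, cm_cochlea):
        n = len(cm_cochlea.outer_contour)
        partial = CochleaContour2D(
            inner_contour=cm_cochlea.inner_contour[: n // 4],
            outer_contour=cm_cochlea.outer_contour[: n // 4],
            cochleostomy_point=cm_cochlea.cochleostomy_point,
            entry_direction=cm_cochlea.entry_direction,
        )
        with pytest.raises(InsufficientCoverageError):
            measure_distance_A(partial)


class TestSynthesizeCochlea:
    def test_distance_b_smaller_than_a(self, cm_cochlea):
        from cisim.cochlea import measure_distance_B

        b = measure_distance_B(cm_cochlea)
        assert 0 < b < measure_distance_A(cm_cochlea)

    def test_size_presets_strictly_increasing(self):
        a = [measure_distance_A(synthesize_cochlea(size=s)) for s in ("CS", "CM", "CL")]
        assert a[0] < a[1] < a[2]

    def test_lumen_everywhere_positive(self):
        for s in ("CS", "CM", "CL"):
            contour = synthesize_cochlea(size=s)
            assert contour.lumen_width.min() > 0

    def test_walls_do_not_cross(self, cm_cochlea):
        assert not cm_cochlea.inner_line.crosses(cm_cochlea.outer_line)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidConfigError):
            synthesize_cochlea(A_mm=9.0, turns=1.0)
        with pytest.raises(InvalidConfigError):
            synthesize_cochlea(A_mm=12.0)
        with pytest.raises(InvalidInputError):
            synthesize_cochlea()

    def test_narrow_lumen_warns(self):
        with pytest.warns(UserWarning):
            contour = synthesize_cochlea(
                A_mm=8.0,
                lumen_width_profile=LumenWidthProfile(fraction=0.2, floor=0.1, cap=0.5),
            )
        assert contour.narrow_lumen_warning

    def test_scale_equivariance_of_geometry(self, cm_cochlea):
        scaled = cm_cochlea.scaled(1.25)
        assert np.isclose(scaled.lumen_polygon.area, 1.25**2 * cm_cochlea.lumen_polygon.area, rtol=1e-9)
        assert np.isclose(scaled.mouth_width, 1.25 * cm_cochlea.mouth_width)
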