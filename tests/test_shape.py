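"""Nuclear shape statistics: profiles, irregularity, curvature, events."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from nucleostress.segmentation import NucleusMask, segment_nuclei
from nucleostress.shape import (
    BoundaryContour,
    classic_descriptors,
    curvature_profile,
    detect_indentations,
    extract_boundary,
    indentation_histogram,
    irregularity,
    radial_profile,
)
from nucleostress.synthetic import (
    ChromatinTextureSpec,
    NucleusSpec,
    make_polar_boundary,
    oracle_irregularity,
    simulate_bundle,
)

from conftest import random_nucleus_specs


def ellipse_contour(a, b, n=2048):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BoundaryContour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


def pipeline_contour(spec, seed=0):
    """render -> segment -> extract, the full measurement chain."""
    bundle = simulate_bundle(
        spec, ChromatinTextureSpec(noise_sd=2.0, blob_count=0, seed=seed))
    mask = segment_nuclei(bundle.dapi, spec.pixel_size)
    assert mask.n_labels == 1
    return extract_boundary(mask, 1)


class TestBoundaryContour:
    def test_cw_input_is_reoriented(self):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        cw = np.column_stack([np.cos(-t), np.sin(-t)])
        b = BoundaryContour(cw)
        x, y = b.vertices[:, 0], b.vertices[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0

    def test_too_few_vertices_rejected(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        with pytest.raises(ValueError):
            BoundaryContour(np.column_stack([np.cos(t), np.sin(t)]))


class TestExtractBoundary:
    def test_raster_disk_radius(self):
        yy, xx = np.mgrid[0:101, 0:101]
        disk = ((xx - 50) ** 2 + (yy - 50) ** 2 <= 40**2).astype(int)
        c = extract_boundary(disk, 1, pixel_size=1.0)
        r = np.hypot(c.vertices[:, 0] - 50, c.vertices[:, 1] - 50)
        assert np.all(np.abs(r - 40) <= 0.5)

    def test_border_touching_region_raises(self):
        m = np.zeros((40, 40), dtype=int)
        m[0:20, 5:25] = 1
        with pytest.raises(ValueError):
            extract_boundary(m, 1, pixel_size=1.0)


class TestRadialProfile:
    def test_circle_profile_is_unity(self):
        prof = radial_profile(make_polar_boundary(NucleusSpec(base_radius=8.0)))
        assert np.allclose(prof.r_hat, 1.0, atol=1e-6)
        assert prof.star_convex

    def test_single_mode_pointwise(self):
        spec = NucleusSpec(base_radius=8.0, fourier_modes=((3, 0.1, 0.0),))
        prof = radial_profile(make_polar_boundary(spec))
        assert np.abs(prof.r_hat - (1 + 0.1 * np.cos(3 * prof.theta))).max() < 1e-3

    def test_mean_normalization_invariant(self):
        for spec in random_nucleus_specs(5, seed=3):
            prof = radial_profile(make_polar_boundary(spec))
            assert abs(prof.r_hat.mean() - 1.0) < 1e-9

    def test_folded_polygon_flagged_not_star_convex(self):
        # square with an off-centre L-shaped (bent) slot: rays from the
        # centroid cross the boundary more than once near the slot elbow
        outline = [(0, 0), (10, 0), (10, 10), (7.5, 10), (7.5, 2),
                   (3, 2), (3, 3), (6.5, 3), (6.5, 10), (0, 10)]
        pts = []
        for p, q in zip(outline, outline[1:] + outline[:1]):
            p, q = np.array(p, float), np.array(q, float)
            n = max(8, int(np.hypot(*(q - p)) * 4))
            pts.extend(p + (q - p) * s for s in np.linspace(0, 1, n, endpoint=False))
        prof = radial_profile(BoundaryContour(np.array(pts)[::-1]))
        assert not prof.star_convex


class TestIrregularity:
    def test_circle_near_zero_through_raster_pipeline(self):
        # noiseless raster round-trip: the statistic's floor is set by
        # the extraction pipeline, not by the generative shape
        bundle = simulate_bundle(
            NucleusSpec(base_radius=8.0),
            ChromatinTextureSpec(noise_sd=0.0, blob_count=0))
        mask = segment_nuclei(bundle.dapi, 0.25)
        contour = extract_boundary(mask, 1)
        assert irregularity(radial_profile(contour)) < 1e-3

    @pytest.mark.parametrize("a", [0.05, 0.1, 0.15])
    def test_mode_analytic_4a(self, a):
        spec = NucleusSpec(base_radius=8.0, fourier_modes=((4, a, 0.7),))
        v = irregularity(radial_profile(make_polar_boundary(spec)))
        assert v == pytest.approx(4 * a, rel=0.01)

    def test_matches_oracle_after_image_roundtrip(self):
        spec = NucleusSpec(base_radius=8.0,
                           fourier_modes=((3, 0.06, 0.4), (5, 0.03, 1.1)),
                           dents=((2.2, 2.0, 1.0),))
        v = irregularity(radial_profile(pipeline_contour(spec)))
        assert v == pytest.approx(oracle_irregularity(spec), rel=0.03)

    @given(scale=st.floats(0.5, 3.0))
    def test_scale_invariance_is_exact(self, scale):
        spec = NucleusSpec(base_radius=8.0,
                           fourier_modes=((3, 0.07, 0.2), (4, 0.04, 1.0)))
        base = make_polar_boundary(spec)
        v0 = irregularity(radial_profile(base))
        v1 = irregularity(radial_profile(BoundaryContour(scale * base.vertices)))
        assert v1 == pytest.approx(v0, rel=1e-9)

    @pytest.mark.parametrize("angle", np.linspace(0, 2 * math.pi, 12, endpoint=False))
    def test_rotation_invariance(self, angle):
        spec = NucleusSpec(base_radius=8.0,
                           fourier_modes=((3, 0.07, 0.2), (4, 0.04, 1.0)))
        base = make_polar_boundary(spec)
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        v0 = irregularity(radial_profile(base))
        v1 = irregularity(radial_profile(BoundaryContour(base.vertices @ rot.T)))
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_adding_a_dent_never_decreases(self):
        # holds on near-circular baselines (the hepatocyte case); with
        # strong Fourier lobes the centroid shift of a dent can cancel
        # part of the mode signal, so lobed baselines are out of scope
        rng = np.random.default_rng(19)
        for i in range(20):
            n_prior = int(rng.integers(0, 3))
            dents = tuple((rng.uniform(0, 2 * np.pi), rng.uniform(1.5, 4.0),
                           rng.uniform(0.8, 1.5)) for _ in range(n_prior))
            spec = NucleusSpec(base_radius=8.0, dents=dents, seed=i)
            v0 = oracle_irregularity(spec)
            extra = (rng.uniform(0, 2 * np.pi), rng.uniform(1.5, 4.0),
                     rng.uniform(0.8, 1.5))
            spec_d = NucleusSpec(base_radius=8.0, dents=dents + (extra,), seed=i)
            assert oracle_irregularity(spec_d) >= v0

    def test_dented_population_more_irregular_than_circles(self):
        dented, plain = [], []
        for i in range(5):
            rng = np.random.default_rng(100 + i)
            spec_d = NucleusSpec(base_radius=8.0, dents=(
                (rng.uniform(0, 2 * np.pi), 2.0, 1.2),
                (rng.uniform(0, 2 * np.pi), 3.0, 1.0)), seed=i)
            spec_p = NucleusSpec(base_radius=8.0,
                                 fourier_modes=((3, 0.01, 0.0),), seed=i)
            dented.append(irregularity(radial_profile(pipeline_contour(spec_d, i))))
            plain.append(irregularity(radial_profile(pipeline_contour(spec_p, i))))
        assert np.mean(dented) > np.mean(plain)
        assert min(dented) > max(plain)


class TestClassicDescriptors:
    def test_disk(self):
        m = classic_descriptors(ellipse_contour(8, 8))
        assert m.circularity == pytest.approx(1.0, rel=0.03)
        assert m.aspect_ratio == pytest.approx(1.0, rel=0.03)
        assert m.roundness == pytest.approx(1.0, rel=0.03)
        assert m.solidity == pytest.approx(1.0, rel=0.03)

    def test_two_to_one_ellipse(self):
        m = classic_descriptors(ellipse_contour(10, 5))
        assert m.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert m.roundness == pytest.approx(0.5, rel=0.03)

    def test_star_solidity_matches_hull_oracle(self):
        t = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
        r = 8 + 2.4 * np.cos(5 * t)
        star = BoundaryContour(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        m = classic_descriptors(star)
        hull = ConvexHull(star.vertices)
        assert m.solidity < 1
        assert m.solidity == pytest.approx(star.area / hull.volume, rel=1e-6)


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        cp = curvature_profile(make_polar_boundary(NucleusSpec(base_radius=5.0)))
        assert np.allclose(cp.kappa, 0.2, rtol=0.02)

    def test_ellipse_tip_curvature(self):
        cp = curvature_profile(ellipse_contour(10, 5))
        assert cp.kappa.max() == pytest.approx(10 / 25, rel=0.03)

    def test_turning_number_on_assorted_contours(self):
        contours = [make_polar_boundary(s) for s in random_nucleus_specs(5, seed=5)]
        contours.append(ellipse_contour(10, 5))
        for c in contours:
            cp = curvature_profile(c)
            total = np.sum(cp.kappa) * cp.perimeter / len(cp.kappa)
            assert total == pytest.approx(2 * np.pi, rel=0.02)

    def test_tiny_contour_raises(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        tiny = BoundaryContour(0.05 * np.column_stack([np.cos(t), np.sin(t)]))
        with pytest.raises(ValueError):
            curvature_profile(tiny, smoothing_sigma=0.4)


class TestIndentationEvents:
    def test_circle_has_no_events(self):
        cp = curvature_profile(pipeline_contour(NucleusSpec(base_radius=8.0)))
        assert detect_indentations(cp) == []

    def test_single_dent_recovered_as_one_negative_event(self):
        spec = NucleusSpec(base_radius=8.0, dents=((0.9, 2.0, 1.5),), seed=1)
        events = detect_indentations(curvature_profile(pipeline_contour(spec, 1)))
        assert len(events) == 1
        assert events[0].signed_radius == pytest.approx(-2.0, rel=0.2)

    def test_pinch_recovered_as_positive_event(self):
        spec = NucleusSpec(base_radius=8.0, pinches=((2.0, 1.5),), seed=2)
        events = detect_indentations(curvature_profile(pipeline_contour(spec, 2)))
        pos = [e for e in events if e.signed_radius > 0]
        assert len(pos) == 1
        assert pos[0].signed_radius == pytest.approx(1.5, rel=0.2)

    def test_event_location_points_at_the_dent(self):
        spec = NucleusSpec(base_radius=8.0, dents=((0.9, 2.0, 1.5),), seed=1)
        events = detect_indentations(curvature_profile(pipeline_contour(spec, 1)))
        # y grows downward in image coordinates, so the angle is mirrored
        assert min(abs(events[0].theta_location - 0.9),
                   abs(2 * np.pi - events[0].theta_location - 0.9)) < 0.2


class TestIndentationHistogram:
    def test_empty(self):
        h = indentation_histogram([], bin_width=0.5)
        assert h.counts.sum() == 0 and h.asymmetry == 0.0

    def test_counts_conserved_and_binned(self):
        from nucleostress.shape import IndentationEvent
        events = [IndentationEvent(-2.0, 0.0, 1.0)] * 10
        h = indentation_histogram(events, bin_width=0.5)
        assert h.counts.sum() == 10
        assert h.counts.max() == 10  # all in one bin

    @given(st.lists(st.floats(-5, 5).filter(lambda x: abs(x) > 0.01),
                    min_size=0, max_size=40))
    def test_asymmetry_bounds_and_conservation(self, radii):
        from nucleostress.shape import IndentationEvent
        events = [IndentationEvent(r, 0.0, 1.0) for r in radii]
        h = indentation_histogram(events, bin_width=0.5)
        assert h.counts.sum() == len(radii)
        assert -1.0 <= h.asymmetry <= 1.0

    def test_symmetric_events_have_zero_asymmetry(self):
        from nucleostress.shape import IndentationEvent
        events = ([IndentationEvent(2.0, 0.0, 1.0)] * 4
                  + [IndentationEvent(-2.0, 0.0, 1.0)] * 4)
        assert indentation_histogram(events, 0.5).asymmetry == 0.0
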