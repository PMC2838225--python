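"""The six measuring functions on split lesion halves."""

import math

import numpy as np
import pytest

from lesionsf.config import PipelineConfig
from lesionsf.imaging import LesionSegmentation, luminance, segment_lesion
from lesionsf.measuring import (
    DegenerateHalfError,
    SplittingLine,
    boundary_mf,
    color_mf,
    half_graphs,
    joint_normalize,
    mass_mf,
    negate_mf,
)
from lesionsf.sfcore import (
    compute_size_function,
    matching_distance,
    prune_diagram,
)
from lesionsf.synthlesion import LesionSpec, generate_lesion


def make_disk(size=160, radius=50, rgb=(90, 60, 50), bg=(205, 175, 155)):
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = bg
    c = (size / 2 - 0.5, size / 2 - 0.5)
    rr, cc = np.mgrid[0:size, 0:size]
    img[np.hypot(rr - c[0], cc - c[1]) <= radius] = rgb
    return img


@pytest.fixture(scope="module")
def disk():
    img = make_disk()
    seg = segment_lesion(img)
    return img, seg


def line_at(seg, angle):
    return SplittingLine(angle=angle, center=seg.center)


class TestBoundaryMF:
    def test_circle_halves_are_single_arcs(self, disk):
        _, seg = disk
        for ang in (0.0, math.pi / 3):
            for side in (+1, -1):
                g = boundary_mf(seg, line_at(seg, ang), side)
                d = compute_size_function(g)
                assert len(d.cornerlines) == 1
                assert d.cornerlines[0] < 1.0  # arc reaches the line
                assert max(g.phi.values()) == pytest.approx(50, abs=1.5)
                # distance-to-line on an arc has minima at both ends, so
                # exactly one essential cornerpoint ~ (0, R) survives
                d = prune_diagram(d, 1.0)
                assert len(d.proper) == 1
                (x, y) = d.proper[0]
                assert x < 1.5 and y == pytest.approx(50, abs=1.5)

    def test_mirror_symmetric_halves_match(self, disk):
        img, seg = disk
        g1, g2 = half_graphs(img, luminance(img), seg, line_at(seg, 0.0), "boundary")
        dist = matching_distance(
            prune_diagram(compute_size_function(g1), 0.005),
            prune_diagram(compute_size_function(g2), 0.005),
            cornerline_penalty=2.0,
        )
        assert dist <= 0.05

    def test_crossing_arcs_give_one_cornerline_each(self):
        # hand-built closed polyline crossing the horizontal center line
        # 6 times: three runs above, three below (cyclically)
        top, bot = 10.0, -10.0
        pts = [(bot, c) for c in np.linspace(-30, 30, 20)]  # bottom run
        pts += [(top, 28), (-2.0, 20), (top, 12), (-2.0, 0), (top, -12), (top, -28)]
        boundary = np.array(pts) + 100.0
        seg = LesionSegmentation(
            mask=None, boundary=boundary, center=(100.0, 100.0), area=0, perimeter=0
        )
        line = SplittingLine(angle=0.0, center=seg.center)
        # side +1 has signed distance > 0 under normal (cos0, -sin0) = rows
        dplus = compute_size_function(boundary_mf(seg, line, +1))
        dminus = compute_size_function(boundary_mf(seg, line, -1))
        assert len(dplus.cornerlines) == 3
        assert len(dminus.cornerlines) == 3

    def test_degenerate_half_rejected(self):
        boundary = np.array([(1.0, 0.0), (2.0, 1.0), (1.5, 2.0)]) + 100.0
        seg = LesionSegmentation(
            mask=None, boundary=boundary, center=(100.0, 100.0), area=0, perimeter=0
        )
        with pytest.raises(DegenerateHalfError, match="degenerate half"):
            boundary_mf(seg, SplittingLine(angle=0.0, center=(100.0, 100.0)), -1)


class TestMassColorMF:
    def test_uniform_half_disk_profile_unimodal(self, disk):
        img, seg = disk
        g = mass_mf(luminance(img), seg, line_at(seg, 0.0), +1)
        top = max(g.phi.values())
        d = prune_diagram(compute_size_function(g), top * 0.02)
        assert len(d.cornerlines) == 1
        # chord-length profile: single interior maximum, minima at the two
        # ends -> exactly one essential cornerpoint (~min, ~max)
        assert len(d.proper) == 1
        (x, y) = d.proper[0]
        assert x == pytest.approx(min(g.phi.values()), rel=0.05)
        assert y == pytest.approx(top, rel=0.05)

    def test_mirror_symmetric_mass_matches(self, disk):
        img, seg = disk
        gp, gm = half_graphs(img, luminance(img), seg, line_at(seg, 0.0), "mass")
        dist = matching_distance(
            prune_diagram(compute_size_function(gp), 0.005),
            prune_diagram(compute_size_function(gm), 0.005),
            cornerline_penalty=2.0,
        )
        assert dist <= 0.05

    def test_doubling_grey_doubles_phi(self, disk):
        img, seg = disk
        gray = luminance(img)
        g1 = mass_mf(gray, seg, line_at(seg, 0.5), +1)
        g2 = mass_mf(2.0 * gray, seg, line_at(seg, 0.5), +1)
        for v in g1.vertices:
            assert g2.phi[v] == pytest.approx(2 * g1.phi[v], rel=1e-12)

    @staticmethod
    def _manual_disk_seg(size=160, radius=50):
        c = (size / 2 - 0.5, size / 2 - 0.5)
        rr, cc = np.mgrid[0:size, 0:size]
        mask = np.hypot(rr - c[0], cc - c[1]) <= radius
        th = np.linspace(0, 2 * math.pi, 300, endpoint=False)
        boundary = np.stack(
            [radius * np.sin(th) + c[0], radius * np.cos(th) + c[1]], axis=1
        )
        return LesionSegmentation(
            mask=mask, boundary=boundary, center=c, area=int(mask.sum()), perimeter=0
        )

    def test_constant_color_gives_zero_distance(self):
        seg = self._manual_disk_seg()
        img = np.full((160, 160, 3), 120, dtype=np.uint8)
        line = SplittingLine(1.0, seg.center)
        gp, gm = color_mf(img, seg, line, +1), color_mf(img, seg, line, -1)
        assert max(gp.phi.values()) <= 1e-9
        assert max(gm.phi.values()) <= 1e-9
        dist = matching_distance(
            compute_size_function(gp),
            compute_size_function(gm),
            cornerline_penalty=2.0,
        )
        assert dist <= 1e-9

    def test_color_varying_parallel_to_line_gives_zero(self):
        seg = self._manual_disk_seg()
        img = np.empty((160, 160, 3), dtype=np.uint8)
        img[:] = np.linspace(40, 200, 160)[None, :, None]  # varies along columns
        line = SplittingLine(0.0, seg.center)  # tangent along columns
        g = color_mf(img, seg, line, +1)
        assert max(g.phi.values()) <= 1e-9

    def test_color_blob_asymmetry_detected(self):
        base = make_disk(size=180, radius=60)
        blob = base.copy()
        rr, cc = np.mgrid[0:180, 0:180]
        inside = np.hypot(rr - 60.0, cc - 89.5) <= 12  # blob in one half
        blob[inside] = (40, 110, 140)
        cfg = PipelineConfig()

        def color_dist(img):
            seg = segment_lesion(img)
            gp, gm = half_graphs(
                img, luminance(img), seg, SplittingLine(0.0, seg.center), "color"
            )
            return matching_distance(
                prune_diagram(compute_size_function(gp), cfg.min_persistence),
                prune_diagram(compute_size_function(gm), cfg.min_persistence),
                cornerline_penalty=cfg.cornerline_penalty,
            )

        assert color_dist(blob) >= 5 * max(color_dist(base), 1e-6)


class TestNegateAndNormalize:
    def test_negate_twice_is_identity(self, disk):
        img, seg = disk
        g = boundary_mf(seg, line_at(seg, 0.3), +1)
        gg = negate_mf(negate_mf(g))
        assert gg.phi == g.phi and gg.edges == g.edges

    def test_negated_cornerlines_at_minus_component_maxima(self):
        from lesionsf.sfcore import SizeGraph

        g = SizeGraph(
            vertices=[0, 1, 2, 3],
            edges={(0, 1), (2, 3)},
            phi={0: 1.0, 1: 4.0, 2: -2.0, 3: 0.5},
        )
        d = compute_size_function(negate_mf(g))
        assert sorted(d.cornerlines) == [-4.0, -0.5]

    def test_joint_normalize_max_is_one(self, disk):
        img, seg = disk
        gp = boundary_mf(seg, line_at(seg, 0.0), +1)
        gm = boundary_mf(seg, line_at(seg, 0.0), -1)
        np_, nm = joint_normalize(gp, gm)
        m = max(
            max(abs(v) for v in np_.phi.values()),
            max(abs(v) for v in nm.phi.values()),
        )
        assert m == pytest.approx(1.0, abs=1e-12)

    def test_zero_scale_is_noop(self):
        from lesionsf.sfcore import SizeGraph

        g = SizeGraph(vertices=[0], phi={0: 0.0})
        a, b = joint_normalize(g, g)
        assert a.phi == {0: 0.0}

    def test_scale_invariance_of_normalized_boundary_distances(self):
        cfg = PipelineConfig()

        def bdist(img, angle):
            seg = segment_lesion(img)
            gp, gm = half_graphs(
                img, luminance(img), seg, SplittingLine(angle, seg.center), "boundary"
            )
            return matching_distance(
                prune_diagram(compute_size_function(gp), cfg.min_persistence),
                prune_diagram(compute_size_function(gm), cfg.min_persistence),
                cornerline_penalty=cfg.cornerline_penalty,
            )

        spec_small = LesionSpec(
            image_size=160,
            base_radius=40,
            boundary_harmonics=[(3, 0.15, 0.4)],
            boundary_asym=1.0,
        )
        spec_big = LesionSpec(
            image_size=320,
            base_radius=80,
            boundary_harmonics=[(3, 0.15, 0.4)],
            boundary_asym=1.0,
        )
        img_s, _ = generate_lesion(spec_small)
        img_b, _ = generate_lesion(spec_big)
        for ang in (0.0, 1.2):
            a, b = bdist(img_s, ang), bdist(img_b, ang)
            assert b == pytest.approx(a, abs=0.02 * max(a, 1.0))


def test_reflection_swaps_halves_and_preserves_distance(disk_image, config):
    """Mirroring the image across the splitting line must leave the
    half-versus-half comparison unchanged for every measuring function."""
    from lesionsf.asymmetry import asymmetry_curves

    spec = LesionSpec(
        boundary_harmonics=[(3, 0.12, 0.0), (2, 0.05, 0.0)],
        boundary_asym=1.0,
        color_asym=0.5,
        seed=5,
    )
    img, _ = generate_lesion(spec)
    seg = segment_lesion(img)
    mirrored = img[::-1].copy()  # reflection across the horizontal center line
    segm = segment_lesion(mirrored)
    c = asymmetry_curves(img, seg, config)
    cm = asymmetry_curves(mirrored, segm, config)
    for mf in c:
        assert cm[mf].values[0] == pytest.approx(c[mf].values[0], abs=0.05)
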