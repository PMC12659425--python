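"""Cavity construction: clipping, auxiliary spheres, areas/volumes, merging."""

import numpy as np
import pytest

from cosmosol.cavity import (
    AUXILIARY,
    CavityParams,
    Segment,
    Sphere,
    build_cavity,
    build_ses_cavity,
    build_vdw_cavity,
    compute_area_volume,
    compute_d_min,
    gepol_add_spheres,
    merge_segments,
)
from cosmosol.solute import make_fixture


def unit_sphere(center=(0, 0, 0), radius=1.0, origin=0):
    return Sphere(np.asarray(center, dtype=float), radius, origin)


class TestVdwCavity:
    def test_single_sphere_nothing_clipped(self):
        cav = build_vdw_cavity([unit_sphere()], "fine")
        assert len(cav.segments) == 240
        assert cav.area == pytest.approx(4 * np.pi, rel=0.005)

    def test_disjoint_spheres_are_union_of_tessellations(self):
        sp = [unit_sphere(), unit_sphere(center=(5, 0, 0), origin=1)]
        cav = build_vdw_cavity(sp, "fine")
        assert len(cav.segments) == 480
        assert cav.area == pytest.approx(8 * np.pi, rel=0.005)

    def test_two_overlapping_spheres_cap_area(self):
        # unit spheres 1 Å apart: each loses a cap of height 0.5 (area π),
        # exposed area = 2·4π − 2π = 6π
        sp = [unit_sphere(), unit_sphere(center=(1, 0, 0), origin=1)]
        cav = build_vdw_cavity(sp, "fine")
        assert cav.area == pytest.approx(6 * np.pi, rel=0.02)

    def test_empty_sphere_list_rejected(self):
        with pytest.raises(ValueError):
            build_vdw_cavity([], "fine")

    def test_clipping_monotonicity(self):
        """Adding a sphere never increases any existing sphere's exposure."""
        sp = [unit_sphere(), unit_sphere(center=(1.2, 0, 0), origin=1)]
        before = build_vdw_cavity(sp, "fine")
        extra = sp + [unit_sphere(center=(0.6, 0.8, 0), origin=2)]
        after = build_vdw_cavity(extra, "fine")

        def per_sphere(cav, sid):
            return sum(s.area for s in cav.segments if s.sphere_id == sid)

        for sid in (0, 1):
            assert per_sphere(after, sid) <= per_sphere(before, sid) + 1e-12


class TestAreaVolume:
    def test_single_sphere_formulas(self):
        cav = build_vdw_cavity([unit_sphere()], "fine")
        area, volume = compute_area_volume(cav)
        assert area == pytest.approx(4 * np.pi, rel=0.01)
        assert volume == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_scaling(self):
        sp = [unit_sphere(), unit_sphere(center=(1.0, 0.2, 0), origin=1)]
        a1, v1 = compute_area_volume(build_vdw_cavity(sp, "fine"))
        doubled = [
            Sphere(2.0 * s.center, 2.0 * s.radius, s.origin) for s in sp
        ]
        a2, v2 = compute_area_volume(build_vdw_cavity(doubled, "fine"))
        assert a2 == pytest.approx(4 * a1, rel=1e-10)
        assert v2 == pytest.approx(8 * v1, rel=1e-10)

    def test_volume_against_monte_carlo(self, rng):
        """Divergence-theorem volume vs a direct inside-test MC estimate."""
        for _ in range(3):
            c2 = rng.uniform(-1.0, 1.0, size=3)
            r1, r2 = rng.uniform(0.8, 1.5, size=2)
            sp = [unit_sphere(radius=r1), Sphere(c2, r2, 1)]
            cav = build_vdw_cavity(sp, "fine")
            lo = np.minimum(-r1 * np.ones(3), c2 - r2) - 0.01
            hi = np.maximum(r1 * np.ones(3), c2 + r2) + 0.01
            pts = rng.uniform(lo, hi, size=(1_000_000, 3))
            inside = (np.einsum("ij,ij->i", pts, pts) < r1**2) | (
                np.einsum("ij,ij->i", pts - c2, pts - c2) < r2**2
            )
            box = np.prod(hi - lo)
            p = inside.mean()
            mc_vol = box * p
            mc_err = box * np.sqrt(p * (1 - p) / len(pts))
            # allow 3σ MC noise plus the O(h²) discretization bias
            assert abs(cav.volume - mc_vol) < 3 * mc_err + 0.01 * mc_vol


class TestGepolSpheres:
    def test_single_sphere_unchanged(self):
        sp = [unit_sphere(radius=2.0)]
        assert gepol_add_spheres(sp, rsolv=1.3) == sp

    def test_wide_gap_probe_fits(self):
        sp = [unit_sphere(radius=1.0), Sphere(np.array([5.0, 0, 0]), 1.0, 1)]
        # surface gap 3.0 > 2·1.3: the probe passes, no fillers
        assert len(gepol_add_spheres(sp, rsolv=1.3)) == 2

    def test_narrow_gap_tangency_construction(self):
        # two R=2 spheres, centers 5 Å apart, probe 1.3 Å: probe tangent to
        # both has center at x=2.5, height h=√(3.3²−2.5²); the auxiliary
        # sphere is tangent to it: radius h − 1.3
        sp = [unit_sphere(radius=2.0), Sphere(np.array([5.0, 0, 0]), 2.0, 1)]
        aug = gepol_add_spheres(sp, rsolv=1.3)
        aux = [s for s in aug if s.origin == AUXILIARY]
        assert len(aux) >= 1
        h = np.sqrt(3.3**2 - 2.5**2)
        assert aux[0].center == pytest.approx([2.5, 0.0, 0.0], abs=1e-12)
        assert aux[0].radius == pytest.approx(h - 1.3, abs=1e-12)

    def test_small_or_engulfed_candidates_discarded(self):
        # heavily fused spheres (overlap beyond ofac) get no filler
        sp = [unit_sphere(radius=2.0), Sphere(np.array([0.5, 0, 0]), 2.0, 1)]
        assert len(gepol_add_spheres(sp, rsolv=1.3)) == 2


class TestSesCavity:
    def test_single_atom_matches_vdw(self):
        params = CavityParams(cavity_type="ses", level="fine")
        ses = build_ses_cavity([unit_sphere(radius=2.0)], params)
        vdw = build_cavity([unit_sphere(radius=2.0)], CavityParams(level="fine"))
        assert ses.area == pytest.approx(vdw.area, rel=1e-12)
        assert len(ses.segments) == len(vdw.segments)

    def test_chain_ses_area_below_vdw(self):
        """Overlapping colinear chain: fillers bury the inter-sphere crevices,
        so the approximate SES exposes less area than the vdW surface."""
        _, spheres = make_fixture("chain9", 0)
        ses = build_ses_cavity(spheres, CavityParams(cavity_type="ses", level="fine"))
        vdw = build_cavity(spheres, CavityParams(level="fine"))
        assert any(s.origin == AUXILIARY for s in ses.spheres)
        assert ses.area <= vdw.area

    def test_post_merge_distances_respect_d_min(self):
        _, spheres = make_fixture("chain9", 0)
        params = CavityParams(cavity_type="ses", level="fine")
        cav = build_ses_cavity(spheres, params)
        d_min = compute_d_min(params.level, params.rsolv, params.mfactor)
        centers = cav.centers
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(centers, k=2)
        assert d[:, 1].min() >= d_min - 1e-12


class TestDmin:
    def test_zero_mfactor_disables(self):
        assert compute_d_min("fine", 1.3, 0.0) == 0.0

    def test_linear_in_mfactor(self):
        d1 = compute_d_min("fine", 1.3, 1.0)
        d2 = compute_d_min("fine", 1.3, 2.0)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_monotone_in_level(self):
        ds = [compute_d_min(lvl, 1.3, 1.0) for lvl in ("coarse", "fine", "xfine")]
        assert ds[0] > ds[1] > ds[2] > 0


def _segment(center, area, normal=(0, 0, 1.0)):
    n = np.asarray(normal, dtype=float)
    return Segment(np.asarray(center, dtype=float), area, n / np.linalg.norm(n), 0)


class TestMergeSegments:
    def test_coincident_pair_sums_areas(self):
        segs = [_segment((0, 0, 0), 0.3), _segment((0, 0, 0), 0.5)]
        out = merge_segments(segs, 0.1)
        assert len(out) == 1
        assert out[0].area == pytest.approx(0.8, abs=1e-15)
        assert np.allclose(out[0].center, 0.0)
        assert out[0].merged_count == 2

    def test_far_apart_is_identity(self):
        segs = [_segment((0, 0, 0), 0.3), _segment((1, 0, 0), 0.5)]
        assert merge_segments(segs, 0.1) == segs

    def test_transitive_chain_collapses_and_conserves_area(self):
        # a–b and b–c are close, a–c is not: closure merges all three
        segs = [
            _segment((0.00, 0, 0), 0.2),
            _segment((0.08, 0, 0), 0.3),
            _segment((0.16, 0, 0), 0.4),
        ]
        out = merge_segments(segs, 0.1)
        assert len(out) == 1
        assert out[0].area == pytest.approx(0.9, abs=1e-12)
        # independent connected-components oracle
        import networkx as g

        G = g.Graph()
        G.add_nodes_from(range(3))
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(segs[i].center - segs[j].center) < 0.1:
                    G.add_edge(i, j)
        assert len(list(g.connected_components(G))) == len(out)
        expected_center = np.average(
            [s.center for s in segs], axis=0, weights=[s.area for s in segs]
        )
        assert np.allclose(out[0].center, expected_center, atol=1e-12)

    def test_random_merge_conserves_area_exactly(self, rng):
        segs = [
            _segment(rng.uniform(0, 1, 3), rng.uniform(0.01, 0.2), rng.normal(size=3))
            for _ in range(120)
        ]
        total = sum(s.area for s in segs)
        out = merge_segments(segs, 0.25)
        assert sum(s.area for s in out) == pytest.approx(total, rel=1e-12)
        centers = np.array([s.center for s in out])
        from scipy.spatial import cKDTree

        if len(out) > 1:
            d, _ = cKDTree(centers).query(centers, k=2)
            assert d[:, 1].min() >= 0.25 - 1e-12

    def test_negative_d_min_rejected(self):
        with pytest.raises(ValueError):
            merge_segments([_segment((0, 0, 0), 1.0)], -0.1)
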