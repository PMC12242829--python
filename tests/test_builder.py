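"""Spheroid construction from the periodic random Voronoi tessellation."""

import numpy as np
import pytest

from spherofiber.builder import (box_edge_for, build_spheroid, radius_for_count,
                                 sample_seed_points, spheroid_complex,
                                 spheroid_radius)
from spherofiber.cellcomplex import REAL
from spherofiber.mechanics import cell_volumes_areas


def test_sample_seed_points_count_and_determinism():
    box = box_edge_for(64)
    a = sample_seed_points(64, box, np.random.default_rng(7), lloyd_sweeps=1)
    b = sample_seed_points(64, box, np.random.default_rng(7), lloyd_sweeps=1)
    assert a.shape == (64, 3)
    assert (a >= 0).all() and (a < box).all()
    np.testing.assert_array_equal(a, b)


def test_mean_voronoi_volume_is_box_cubed_over_n():
    # n points in a periodic box of edge n^(1/3): mean cell volume exactly 1
    assert box_edge_for(8) ** 3 / 8 == pytest.approx(1.0)


def test_lloyd_relaxation_reduces_cell_volume_variance():
    stds = {0: [], 5: []}
    for seed in range(3):
        for sweeps in (0, 5):
            cc = spheroid_complex(40, np.random.default_rng(seed),
                                  lloyd_sweeps=sweeps)
            _, V, _ = cell_volumes_areas(cc)
            stds[sweeps].append(V.std())
    assert np.mean(stds[5]) < np.mean(stds[0])


def test_degenerate_radius_raises():
    rng = np.random.default_rng(0)
    box = box_edge_for(64)
    pts = sample_seed_points(64, box, rng, lloyd_sweeps=0)
    with pytest.raises(ValueError, match="no generator"):
        build_spheroid(pts, 0.0, box)


def test_radius_for_count_is_exact():
    rng = np.random.default_rng(1)
    box = box_edge_for(216)
    pts = sample_seed_points(216, box, rng, lloyd_sweeps=0)
    r = radius_for_count(pts, box, 20)
    center = np.full(3, box / 2)
    assert (np.linalg.norm(pts - center, axis=1) < r).sum() == 20
    with pytest.raises(ValueError, match="cannot cut"):
        radius_for_count(pts, box, 216)


def test_spheroid_structure_invariants(small_spheroid):
    cc = small_spheroid
    assert len(cc.real_cells()) == 60
    # clean audit: faces doubly incident, cells closed with Euler char 2,
    # no doubly-shared cell pairs, interface faces real|empty
    assert cc.audit(confluent=True) == []
    # the interface surface is a single closed component
    assert cc.interface_surface_components() == 1
    # every interface face has exactly one real incident cell
    fc = cc.face_cells()
    for fid in cc.interface_faces():
        labs = [cc.cell_label[c] for c, _ in fc[fid]]
        assert sorted(labs) == ["empty", "real"]
    # boundary cells are exactly the real cells touching an empty cell
    nm_all = {}
    for fid, inc in fc.items():
        if len(inc) == 2:
            (c1, _), (c2, _) = inc
            nm_all.setdefault(c1, set()).add(c2)
            nm_all.setdefault(c2, set()).add(c1)
    for c in cc.real_cells():
        touches_empty = any(cc.cell_label[o] == "empty" for o in nm_all[c])
        assert (c in cc.boundary_cells()) == touches_empty


def test_total_real_volume_near_target(small_spheroid):
    _, V, _ = cell_volumes_areas(small_spheroid)
    assert (V > 0).all()
    assert V.sum() == pytest.approx(60.0, rel=0.15)


def test_total_real_volume_within_ten_percent_at_production_size():
    cc = spheroid_complex(100, np.random.default_rng(9))
    _, V, _ = cell_volumes_areas(cc)
    assert V.sum() == pytest.approx(100.0, rel=0.10)


def test_build_determinism():
    a = spheroid_complex(40, np.random.default_rng(5))
    b = spheroid_complex(40, np.random.default_rng(5))
    np.testing.assert_array_equal(a.positions, b.positions)
    assert a.faces == b.faces
    assert a.cells == b.cells
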