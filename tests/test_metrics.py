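import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mvseg.metrics import (
    EvalReport,
    boundary_voxels,
    dice,
    evaluate_case,
    jaccard,
    surface_distances,
)
from mvseg.volume import Volume

from conftest import make_label, random_mask_pair


# -- independent oracles -------------------------------------------------------


def set_dice(a, b):
    """Brute-force Dice from explicit coordinate sets."""
    sa = set(map(tuple, np.argwhere(a)))
    sb = set(map(tuple, np.argwhere(b)))
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def set_jaccard(a, b):
    sa = set(map(tuple, np.argwhere(a)))
    sb = set(map(tuple, np.argwhere(b)))
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def brute_boundary(mask):
    """Boundary via explicit 6-neighbour checks; outside counts as background."""
    mask = mask.astype(bool)
    pts = []
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            inside = (
                0 <= nz < mask.shape[0]
                and 0 <= ny < mask.shape[1]
                and 0 <= nx < mask.shape[2]
            )
            if not inside or not mask[nz, ny, nx]:
                pts.append((z, y, x))
                break
    return np.array(pts, dtype=float)


def brute_surface_distances(a, b, spacing):
    """All-pairs symmetric surface distances in mm."""
    pa = brute_boundary(a) * np.asarray(spacing)
    pb = brute_boundary(b) * np.asarray(spacing)
    d_ab = cdist(pa, pb).min(axis=1)
    d_ba = cdist(pb, pa).min(axis=1)
    d = np.concatenate([d_ab, d_ba])
    return d.mean(), d.std(), d.max()


# -- tests ----------------------------------------------------------------------


class TestOverlap:
    def test_examples(self):
        full = make_label(np.ones((2, 2, 2)))
        assert dice(full, full) == 1.0
        a = np.zeros((2, 2, 2), np.uint8)
        a[0] = 1  # 4 voxels
        b = np.zeros((2, 2, 2), np.uint8)
        b[:, 0] = 1  # 4 voxels, overlap 2
        assert dice(make_label(a), make_label(b)) == 0.5
        assert jaccard(make_label(a), make_label(b)) == pytest.approx(1 / 3)
        disjoint = make_label(1 - a)
        assert dice(make_label(a), disjoint) == 0.0

    def test_empty_conventions(self):
        empty = make_label(np.zeros((2, 2, 2)))
        some = make_label(np.ones((2, 2, 2)))
        assert dice(empty, empty) == 1.0
        assert jaccard(empty, empty) == 1.0
        assert dice(empty, some) == 0.0
        assert jaccard(some, empty) == 0.0

    def test_against_set_oracle(self, rng):
        for _ in range(50):
            g, p = random_mask_pair(rng)
            assert dice(g, p) == set_dice(g.data, p.data)
            assert jaccard(g, p) == set_jaccard(g.data, p.data)

    def test_symmetry_and_identity(self, rng):
        g, p = random_mask_pair(rng)
        assert dice(g, p) == dice(p, g)
        assert jaccard(g, p) == jaccard(p, g)
        j = jaccard(g, p)
        assert dice(g, p) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_growing_pred_never_decreases_dice(self, rng):
        for _ in range(20):
            g, p = random_mask_pair(rng, shape=(8, 8, 8))
            missing = np.argwhere(g.data.astype(bool) & ~p.data.astype(bool))
            if len(missing) == 0:
                continue
            before = dice(g, p)
            grown = p.data.copy()
            grown[tuple(missing[0])] = 1
            assert dice(g, make_label(grown)) >= before

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(make_label(np.zeros((2, 2, 2))), make_label(np.zeros((2, 2, 3))))


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        g, _ = random_mask_pair(rng)
        if not g.data.any():
            pytest.skip("empty draw")
        assert surface_distances(g, g) == (0.0, 0.0, 0.0)

    def test_single_voxels_three_apart(self):
        a = np.zeros((8, 3, 3), np.uint8)
        b = np.zeros((8, 3, 3), np.uint8)
        a[2, 1, 1] = 1
        b[5, 1, 1] = 1
        assert surface_distances(make_label(a), make_label(b)) == (3.0, 0.0, 3.0)

    def test_anisotropic_spacing(self):
        a = np.zeros((8, 3, 3), np.uint8)
        b = np.zeros((8, 3, 3), np.uint8)
        a[2, 1, 1] = 1
        b[5, 1, 1] = 1
        sp = (0.62, 0.73, 0.73)
        mean, std, mx = surface_distances(make_label(a, sp), make_label(b, sp))
        assert mean == pytest.approx(3 * 0.62, abs=1e-12)
        assert mx == pytest.approx(1.86, abs=1e-12)

    def test_against_brute_force(self, rng):
        for _ in range(10):
            g, p = random_mask_pair(rng, shape=(10, 10, 10))
            if not g.data.any() or not p.data.any():
                continue
            got = surface_distances(g, p)
            want = brute_surface_distances(g.data, p.data, (1.0, 1.0, 1.0))
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_symmetry(self, rng):
        g, p = random_mask_pair(rng)
        m1 = surface_distances(g, p)
        m2 = surface_distances(p, g)
        assert m1[0] == pytest.approx(m2[0], abs=1e-12)
        assert m1[2] == pytest.approx(m2[2], abs=1e-12)

    def test_empty_mask_rejected(self):
        empty = make_label(np.zeros((3, 3, 3)))
        some = make_label(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            surface_distances(empty, some)

    def test_boundary_definition_matches_brute_force(self, rng):
        for _ in range(5):
            g, _ = random_mask_pair(rng, shape=(9, 9, 9))
            got = np.argwhere(boundary_voxels(g.data))
            want = brute_boundary(g.data)
            assert got.shape == want.shape
            np.testing.assert_array_equal(got, want.astype(int))


class TestEvaluateCase:
    def test_identical_masks(self, rng):
        g, _ = random_mask_pair(rng)
        rep = evaluate_case(g, g, case_id="x")
        assert rep.dsc == 1.0 and rep.jac == 1.0
        assert rep.mean_sd == rep.std_sd == rep.max_sd == 0.0
        assert rep.case_id == "x"

    def test_dsc_jac_identity_and_ordering(self, rng):
        g, p = random_mask_pair(rng)
        if not p.data.any():
            pytest.skip("empty draw")
        rep = evaluate_case(g, p)
        assert rep.dsc == pytest.approx(2 * rep.jac / (1 + rep.jac), abs=1e-12)
        assert rep.mean_sd <= rep.max_sd

    def test_spacing_mismatch_rejected(self, rng):
        g, p = random_mask_pair(rng)
        p2 = Volume(p.data, (2.0, 1.0, 1.0), role="label")
        with pytest.raises(ValueError):
            evaluate_case(g, p2)

    def test_report_row(self):
        rep = EvalReport("id1", 0.9, 0.8, 0.5, 0.2, 3.0)
        row = rep.as_dict()
        assert row["case_id"] == "id1"
        assert set(row) == {
            "case_id",
            "dsc",
            "jaccard",
            "mean_sd_mm",
            "std_sd_mm",
            "max_sd_mm",
        }
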