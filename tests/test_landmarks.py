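import numpy as np
import pytest
from scipy import stats as sps

import voxmark as vm


@pytest.fixture
def defs12(tmp_path):
    """Twelve landmarks with Bookstein types 1/2/3, four of each."""
    lines = []
    types = [1, 2, 3] * 4
    for n, t in enumerate(types, start=1):
        lines.append(f"{n} landmark number {n} type={t}")
    path = tmp_path / "landmarks.txt"
    path.write_text("\n".join(lines) + "\n")
    return vm.load_landmark_list(path)


def marked_set(defs, coords, specimen_id="spec"):
    s = vm.LandmarkSet(defs=defs, specimen_id=specimen_id)
    for i, n in enumerate(s.numbers):
        s.coords[n] = np.asarray(coords[i], dtype=float)
    return s


class TestLoadLandmarkList:
    def test_single_definition(self, tmp_path):
        p = tmp_path / "lm.txt"
        p.write_text("1 tip of coronoid process\n")
        defs = vm.load_landmark_list(p)
        assert len(defs) == 1
        assert defs[0].number == 1
        assert defs[0].description == "tip of coronoid process"

    def test_twelve_definitions_in_order(self, defs12):
        assert [d.number for d in defs12] == list(range(1, 13))
        assert [d.lm_type for d in defs12] == [1, 2, 3] * 4

    def test_gap_in_numbering_raises_with_line(self, tmp_path):
        p = tmp_path / "lm.txt"
        p.write_text("1 first\n3 third\n")
        with pytest.raises(ValueError, match="lm.txt:2"):
            vm.load_landmark_list(p)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = tmp_path / "lm.txt"
        p.write_text("# header\n\n1 one\n2 two\n")
        assert len(vm.load_landmark_list(p)) == 2

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "lm.txt"
        p.write_text("# nothing here\n")
        with pytest.raises(ValueError, match="empty"):
            vm.load_landmark_list(p)


class TestLoadSymmetryMap:
    def write(self, tmp_path, text):
        p = tmp_path / "sym.txt"
        p.write_text(text)
        return p

    def test_valid_map(self, tmp_path):
        defs = [vm.LandmarkDef(n, f"lm{n}") for n in range(1, 5)]
        p = self.write(tmp_path, "midline 1 2\npair 3 4\n")
        sym = vm.load_symmetry_map(p, defs)
        assert sym.midline == {1, 2}
        assert sym.pairs == [(3, 4)]
        s = marked_set(defs, [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        assert len(sym.linking_lines(s)) == 1

    def test_self_pair_raises(self, tmp_path):
        defs = [vm.LandmarkDef(n, "") for n in range(1, 5)]
        with pytest.raises(ValueError, match="itself"):
            vm.load_symmetry_map(self.write(tmp_path, "pair 3 3\n"), defs)

    def test_unknown_number_raises(self, tmp_path):
        defs = [vm.LandmarkDef(n, "") for n in range(1, 13)]
        with pytest.raises(ValueError, match="unknown landmark number 99"):
            vm.load_symmetry_map(self.write(tmp_path, "pair 1 99\n"), defs)

    def test_midline_and_paired_conflict_raises(self, tmp_path):
        defs = [vm.LandmarkDef(n, "") for n in range(1, 5)]
        with pytest.raises(ValueError, match="both midline and paired"):
            vm.load_symmetry_map(self.write(tmp_path, "midline 1\npair 1 2\n"), defs)


class TestMarkAndJump:
    @pytest.fixture
    def setting(self):
        v = vm.Volume(data=np.zeros((32, 32, 16)))
        cursor = vm.init_cursor(v)
        lm = vm.LandmarkSet(defs=[vm.LandmarkDef(1, "only")])
        return v, cursor, lm

    def test_mark_stores_cursor_coordinates(self, setting):
        _, cursor, lm = setting
        cursor.set_position((10, 12, 8))
        vm.mark_point(lm, 1, cursor)
        np.testing.assert_array_equal(lm.coords[1], [10, 12, 8])

    def test_remark_overwrites(self, setting):
        _, cursor, lm = setting
        vm.mark_point(lm, 1, cursor)
        cursor.set_position((1, 2, 3))
        vm.mark_point(lm, 1, cursor)
        np.testing.assert_array_equal(lm.coords[1], [1, 2, 3])

    def test_unknown_number_raises(self, setting):
        _, cursor, lm = setting
        with pytest.raises(KeyError):
            vm.mark_point(lm, 5, cursor)

    def test_jump_returns_to_marked_point(self, setting):
        _, cursor, lm = setting
        cursor.set_position((10, 12, 8))
        vm.mark_point(lm, 1, cursor)
        vm.move_cursor(cursor, "x", 5)
        vm.jump_stored(lm, 1, cursor)
        np.testing.assert_array_equal(cursor.position, [10, 12, 8])

    def test_jump_to_unmarked_raises(self, setting):
        _, cursor, lm = setting
        with pytest.raises(ValueError, match="not been marked"):
            vm.jump_stored(lm, 1, cursor)

    def test_mark_snapshots_position_not_reference(self, setting):
        _, cursor, lm = setting
        vm.mark_point(lm, 1, cursor)
        stored = lm.coords[1].copy()
        vm.move_cursor(cursor, "y", 3)
        np.testing.assert_array_equal(lm.coords[1], stored)


class TestTpsExport:
    def test_single_landmark_file_layout(self, tmp_path):
        lm = marked_set([vm.LandmarkDef(1, "tip")], [(10.0, 12.0, 8.0)], specimen_id="skull_a")
        path = tmp_path / "out.tps"
        vm.export_tps(lm, path)
        lines = path.read_text().splitlines()
        assert lines == ["LM3=1", "10.000000 12.000000 8.000000", "ID=skull_a"]

    def test_round_trip_of_12_random_landmarks(self, tmp_path, defs12):
        rng = np.random.default_rng(5)
        coords = np.round(rng.uniform(0, 50, size=(12, 3)), 6)
        lm = marked_set(defs12, coords)
        path = tmp_path / "out.tps"
        vm.export_tps(lm, path)
        back, sid = vm.read_tps(path)
        np.testing.assert_array_equal(back, coords)
        assert sid == "spec"

    def test_strict_export_names_unmarked(self, tmp_path, defs12):
        lm = vm.LandmarkSet(defs=defs12)
        for n in lm.numbers:
            if n != 7:
                lm.coords[n] = np.zeros(3)
        with pytest.raises(ValueError, match=r"\[7\]"):
            vm.export_tps(lm, tmp_path / "out.tps")
        vm.export_tps(lm, tmp_path / "out.tps", strict=False)
        back, _ = vm.read_tps(tmp_path / "out.tps")
        assert len(back) == 11

    def test_voxel_unit_export(self, tmp_path):
        lm = marked_set([vm.LandmarkDef(1, "")], [(1.0, 2.0, 4.0)])
        vm.export_tps(lm, tmp_path / "v.tps", spacing=(0.5, 0.5, 2.0))
        back, _ = vm.read_tps(tmp_path / "v.tps")
        np.testing.assert_allclose(back[0], [2.0, 4.0, 2.0])


class TestNtsysExport:
    def test_single_specimen_header(self, tmp_path):
        lm = marked_set([vm.LandmarkDef(1, "")], [(1.0, 2.0, 3.0)])
        path = tmp_path / "o.nts"
        vm.export_ntsys([lm], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "1 1 3 0"
        assert lines[2].split() == ["1.000000", "2.000000", "3.000000"]

    def test_two_specimens_twelve_landmarks_header(self, tmp_path, defs12):
        rng = np.random.default_rng(2)
        sets = [
            marked_set(defs12, rng.uniform(0, 10, (12, 3)), specimen_id=f"s{i}")
            for i in range(2)
        ]
        path = tmp_path / "o.nts"
        vm.export_ntsys(sets, path)
        assert path.read_text().splitlines()[0] == "1 2 36 0"
        coords, labels = vm.read_ntsys(path)
        assert coords.shape == (2, 12, 3)
        assert labels == ["s0", "s1"]

    def test_inconsistent_defs_raise(self, tmp_path, defs12):
        a = marked_set(defs12, np.zeros((12, 3)))
        b = marked_set([vm.LandmarkDef(1, "")], [(0, 0, 0)])
        with pytest.raises(ValueError, match="share the same landmark definitions"):
            vm.export_ntsys([a, b], tmp_path / "o.nts")

    def test_tps_and_ntsys_decode_to_identical_matrices(self, tmp_path, defs12):
        rng = np.random.default_rng(9)
        coords = np.round(rng.uniform(0, 30, (12, 3)), 6)
        lm = marked_set(defs12, coords)
        vm.export_tps(lm, tmp_path / "a.tps")
        vm.export_ntsys([lm], tmp_path / "a.nts")
        tps_coords, _ = vm.read_tps(tmp_path / "a.tps")
        nts_coords, _ = vm.read_ntsys(tmp_path / "a.nts")
        np.testing.assert_array_equal(tps_coords, nts_coords[0])


class TestPrecisionStats:
    def test_identical_repeats_have_zero_distances(self, defs12):
        coords = np.arange(36, dtype=float).reshape(12, 3)
        repeats = [marked_set(defs12, coords) for _ in range(4)]
        stats = vm.precision_stats(repeats, spacing=(1, 1, 1))
        for t in (1, 2, 3):
            np.testing.assert_array_equal(stats[t]["distances"], 0.0)

    def test_three_repeat_hand_example(self):
        defs = [vm.LandmarkDef(1, "", lm_type=1)]
        repeats = [marked_set(defs, [(x, 5.0, 5.0)]) for x in (0.0, 0.0, 3.0)]
        stats = vm.precision_stats(repeats, spacing=(1, 1, 1))
        assert sorted(stats[1]["distances"].tolist()) == [0.0, 0.0, 3.0]
        assert stats[1]["median"] == 0.0

    def test_recovers_type_ordered_gaussian_spread(self, defs12):
        # 10 repeats x 12 landmarks; jitter sigma by type: 0.5 / 1 / 2 voxels
        rng = np.random.default_rng(31)
        sigma = {1: 0.5, 2: 1.0, 3: 2.0}
        base = rng.uniform(20, 40, size=(12, 3))
        repeats = []
        for _ in range(10):
            jitter = np.stack([rng.normal(0, sigma[d.lm_type], 3) for d in defs12])
            repeats.append(marked_set(defs12, base + jitter))
        stats = vm.precision_stats(repeats, spacing=(1, 1, 1))
        m1, m2, m3 = (stats[t]["median"] for t in (1, 2, 3))
        assert m1 < m2 < m3
        # theoretical median radial distance of a 3D Gaussian
        radial_median = np.sqrt(sps.chi2.ppf(0.5, df=3))
        for t in (1, 2, 3):
            expected = sigma[t] * radial_median
            assert stats[t]["median"] == pytest.approx(expected, rel=0.25)

    def test_invariant_to_repeat_order_and_joint_translation(self, defs12):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 10, size=(12, 3))
        repeats = [marked_set(defs12, base + rng.normal(0, 1, (12, 3))) for _ in range(5)]
        ref = vm.precision_stats(repeats, spacing=(1, 1, 1))
        perm = [repeats[i] for i in [3, 0, 4, 1, 2]]
        shifted = [
            marked_set(defs12, r.coord_matrix() + np.array([5.0, -3.0, 11.0])) for r in repeats
        ]
        for other in (vm.precision_stats(perm, (1, 1, 1)), vm.precision_stats(shifted, (1, 1, 1))):
            for t in (1, 2, 3):
                np.testing.assert_allclose(
                    np.sort(ref[t]["distances"]), np.sort(other[t]["distances"]), atol=1e-9
                )

    def test_fewer_than_two_repeats_raises(self, defs12):
        with pytest.raises(ValueError, match="two repeats"):
            vm.precision_stats([marked_set(defs12, np.zeros((12, 3)))], (1, 1, 1))


class TestSymmetryDeviation:
    def test_symmetric_marks_map_onto_partners(self, mirror_blobs):
        vol, truth = mirror_blobs
        defs = [
            vm.LandmarkDef(1, "left tip"), vm.LandmarkDef(2, "right tip"),
            vm.LandmarkDef(3, "left top"), vm.LandmarkDef(4, "right top"),
        ]
        lm = marked_set(defs, [truth["left_tip"], truth["right_tip"],
                               truth["left_top"], truth["right_top"]])
        sym = vm.SymmetryMap(midline=set(), pairs=[(1, 2), (3, 4)])
        plane = vm.plane_from_points(*truth["plane_points"])
        dev = vm.symmetry_deviation(lm, sym, plane)
        assert max(dev.values()) < min(vol.spacing)
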