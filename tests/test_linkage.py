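import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from compbias import linkage as lnk
from compbias import simulate as sim


def toy_matrix(calls, scaffolds=None, positions=None):
    calls = np.asarray(calls, dtype=float)
    n = calls.shape[0]
    markers = pd.DataFrame(
        {
            "scaffold": scaffolds if scaffolds is not None else ["s"] * n,
            "pos": positions if positions is not None else np.arange(1, n + 1) * 100,
        },
        index=[f"m{i:02d}" for i in range(n)],
    )
    return lnk.GenotypeMatrix(markers=markers, calls=calls)


class TestFilterMarkers:
    def test_quoted_thresholds(self):
        nan = np.nan
        calls = [
            [0, 1, 0, 1, 0, 1, 0, 1],      # fine
            [nan, nan, 0, 1, 0, 1, 0, 1],  # 25% missing -> removed
            [0, 0, 0, 0, 0, 0, 0, 1],      # MAF 0.125 < 0.15 -> removed
            [0, 0, 0, 0, 0, 1, 1, 1],      # MAF 0.375 -> kept
        ]
        filtered, log = lnk.filter_markers(toy_matrix(calls))
        assert list(filtered.markers.index) == ["m00", "m03"]
        assert set(log["marker"]) == {"m01", "m02"}

    def test_boundaries_inclusive_on_keep_side(self):
        # exactly 20% missing -> kept
        a = np.array([[np.nan, 0, 1, 0, 1]])
        filtered, _ = lnk.filter_markers(toy_matrix(a))
        assert len(filtered.markers) == 1
        # MAF exactly 0.15 (3 of 20) -> kept
        b = np.array([[0] * 17 + [1] * 3], dtype=float)
        filtered, _ = lnk.filter_markers(toy_matrix(b))
        assert len(filtered.markers) == 1

    def test_passing_matrix_unchanged(self, cross_bundle):
        matrix, _ = cross_bundle
        filtered, log = lnk.filter_markers(matrix)
        assert log.empty or set(log["marker"]).isdisjoint(filtered.markers.index)

    def test_all_removed_is_error(self):
        calls = np.zeros((3, 10))
        with pytest.raises(ValueError, match="all markers"):
            lnk.filter_markers(toy_matrix(calls))


class TestMirrorPhase:
    def test_columns_flipped_and_count_doubled(self):
        m = toy_matrix([[0, 0, 1], [1, np.nan, 0]])
        mm = lnk.mirror_phase(m)
        assert mm.n_markers == 4
        assert mm.calls[2].tolist() == [1.0, 1.0, 0.0]
        assert np.isnan(mm.calls[3][1])

    def test_involution(self):
        m = toy_matrix([[0, 1, 1], [1, 0, 0]])
        back = lnk.mirror_phase(lnk.mirror_phase(m))
        assert list(back.markers.index) == list(m.markers.index)
        np.testing.assert_array_equal(back.calls, m.calls)


class TestPairwiseLinkage:
    def test_identical_columns_tight_linkage(self):
        col = np.tile([0.0, 1.0], 45)
        pair = lnk.pairwise_linkage(col, col)
        assert pair.r_hat == 0.0
        assert pair.p_linkage < 1e-20

    def test_complementary_columns_r_one(self):
        col = np.tile([0.0, 1.0], 45)
        pair = lnk.pairwise_linkage(col, 1 - col)
        assert pair.r_hat == 1.0

    def test_independent_table_not_linked(self):
        # 2x2 table [[25,20],[22,23]]
        a = np.array([1.0] * 45 + [0.0] * 45)
        b = np.array([1.0] * 25 + [0.0] * 20 + [1.0] * 22 + [0.0] * 23)
        pair = lnk.pairwise_linkage(a, b)
        ref = stats.fisher_exact([[25, 20], [22, 23]])[1]
        assert pair.p_linkage == pytest.approx(ref, rel=1e-9)
        assert pair.p_linkage > 0.05

    def test_too_few_cotyped_rejected(self):
        with pytest.raises(ValueError, match="co-typed"):
            lnk.pairwise_linkage([0.0, np.nan], [np.nan, 1.0])

    def test_vectorized_fisher_matches_scipy(self, rng):
        for _ in range(200):
            table = rng.integers(0, 30, size=4)
            if table.sum() == 0:
                continue
            ours = lnk._fisher_two_sided(*[[int(x)] for x in table])[0]
            ref = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestKosambi:
    @pytest.mark.parametrize(
        "r, cm",
        [(0.0, 0.0), (0.1, 25 * math.log(1.5)), (0.25, 25 * math.log(3.0))],
    )
    def test_closed_form(self, r, cm):
        assert lnk.kosambi_cm(r) == pytest.approx(cm, abs=1e-12)

    def test_inverse_roundtrip(self):
        grid = np.linspace(0.0, 0.49, 100)
        back = lnk.kosambi_r(lnk.kosambi_cm(grid))
        assert np.max(np.abs(back - grid)) < 1e-12

    def test_r_at_half_undefined(self):
        with pytest.raises(ValueError):
            lnk.kosambi_cm(0.5)


class TestGrouping:
    def test_six_chromosomes_recovered(self, cross_bundle):
        matrix, truth = cross_bundle
        mirrored = lnk.mirror_phase(matrix)
        groups, _ = lnk.group_markers(mirrored)
        assert len(groups) == 6
        for g in groups:
            chroms = truth.loc[[lnk.strip_mirror(m) for m in g], "chromosome"]
            assert chroms.nunique() == 1

    def test_mirror_partner_count_before_dedup(self, cross_bundle):
        # each kept group corresponds to a dropped mirror twin
        matrix, _ = cross_bundle
        mirrored = lnk.mirror_phase(matrix)
        groups, unplaced = lnk.group_markers(mirrored)
        placed = sum(len(g) for g in groups) + len(unplaced)
        assert placed == matrix.n_markers

    def test_unlinked_markers_unplaced(self, rng):
        calls = rng.integers(0, 2, size=(6, 60)).astype(float)
        m = toy_matrix(calls)
        groups, unplaced = lnk.group_markers(lnk.mirror_phase(m))
        assert groups == []
        assert len(unplaced) == 6


class TestOrdering:
    def test_two_markers_trivial(self, cross_bundle):
        matrix, _ = cross_bundle
        sub = lnk.GenotypeMatrix(markers=matrix.markers.iloc[:2], calls=matrix.calls[:2])
        assert lnk.order_markers(list(sub.markers.index), sub) == list(sub.markers.index)

    def test_simulated_line_recovered(self):
        spec = sim.SimulationSpec(seed=8)
        spec.cross.n_chromosomes = 1
        spec.cross.markers_per_chromosome = 20
        spec.cross.n_sons = 200
        spec.cross.missing_rate = 0.0
        spec.cross.error_rate = 0.0
        matrix, truth = sim.sim_cross(spec)
        ordered = lnk.order_markers(list(matrix.markers.index), matrix)
        got = truth.loc[ordered, "order"].tolist()
        assert got == sorted(got) or got == sorted(got, reverse=True)

    def test_equidistant_triple_is_lexicographic(self):
        # three identical columns: every pairwise r is 0
        calls = np.tile(np.array([0, 0, 1, 1, 0, 1], dtype=float), (3, 1))
        m = toy_matrix(calls)
        r, _ = lnk.pairwise_r_matrix(calls)
        assert len(np.unique(r[np.triu_indices(3, 1)])) == 1
        assert lnk.order_markers(list(m.markers.index), m) == ["m00", "m01", "m02"]


class TestSplitGaps:
    def make_map(self, cms):
        g = lnk.LinkageGroup("LG1", [f"m{i}" for i in range(len(cms))], cms)
        return lnk.GeneticMap(groups=[g])

    def test_single_large_gap_splits(self):
        out = lnk.split_gaps(self.make_map([0, 10, 20, 100, 110]), gap_cm=70)
        assert [g.marker_ids for g in out.groups] == [["m0", "m1", "m2"], ["m3", "m4"]]
        assert out.groups[1].positions_cm[0] == 0.0

    def test_no_gap_unchanged(self):
        out = lnk.split_gaps(self.make_map([0, 30, 65]), gap_cm=70)
        assert len(out.groups) == 1

    def test_two_gaps_three_groups(self):
        out = lnk.split_gaps(self.make_map([0, 80, 90, 170]), gap_cm=70)
        assert len(out.groups) == 3


class TestBuildMapProperties:
    def test_phase_invariance(self, cross_bundle):
        matrix, _ = cross_bundle
        base = lnk.build_map(matrix)
        rng = np.random.default_rng(99)
        flip = rng.random(matrix.n_markers) < 0.5
        flipped_calls = matrix.calls.copy()
        flipped_calls[flip] = 1.0 - flipped_calls[flip]
        flipped = lnk.GenotypeMatrix(markers=matrix.markers, calls=flipped_calls)
        alt = lnk.build_map(flipped)
        assert len(base.groups) == len(alt.groups)
        for g1, g2 in zip(base.groups, alt.groups):
            assert g1.marker_ids == g2.marker_ids
            assert g1.positions_cm == pytest.approx(g2.positions_cm, abs=1e-12)

    def test_positions_nondecreasing(self, cross_bundle):
        matrix, _ = cross_bundle
        gmap = lnk.build_map(matrix)
        for g in gmap.groups:
            assert all(b >= a for a, b in zip(g.positions_cm, g.positions_cm[1:]))

    def test_adjacent_r_unbiased(self):
        spec = sim.SimulationSpec(seed=17)
        spec.cross.n_chromosomes = 1
        spec.cross.markers_per_chromosome = 2
        spec.cross.n_sons = 10_000
        spec.cross.missing_rate = 0.0
        spec.cross.error_rate = 0.0
        spec.cross.r_adjacent = 0.1
        matrix, _ = sim.sim_cross(spec)
        pair = lnk.pairwise_linkage(matrix.calls[0], matrix.calls[1])
        r = min(pair.r_hat, 1 - pair.r_hat)  # phase randomized at generation
        se = math.sqrt(0.1 * 0.9 / 10_000)
        assert abs(r - 0.1) <= 3 * se


class TestAnchoring:
    def anchored_map(self, n=12, chimera=False):
        # one scaffold, markers at increasing bp and cM on LG1; optionally a
        # contiguous 5-marker block at the low end belonging to LG2
        ids = [f"m{i:02d}" for i in range(n)]
        pos = [(i + 1) * 1000 for i in range(n)]
        markers = pd.DataFrame({"scaffold": ["sc1"] * n, "pos": pos}, index=ids)
        if chimera:
            g2 = lnk.LinkageGroup("LG2", ids[:5], [float(i) for i in range(5)])
            g1 = lnk.LinkageGroup("LG1", ids[5:], [float(i) for i in range(n - 5)])
            groups = [g1, g2]
        else:
            groups = [lnk.LinkageGroup("LG1", ids, [float(i) for i in range(n)])]
        return lnk.GeneticMap(groups=groups), markers

    def test_simple_anchor_plus_orientation(self):
        gmap, markers = self.anchored_map()
        (anchor,) = lnk.anchor_scaffolds(gmap, markers)
        assert anchor.group == "LG1"
        assert anchor.orientation == "+"
        assert not anchor.chimera_flag

    def test_end_block_flags_chimera_with_split(self):
        gmap, markers = self.anchored_map(chimera=True)
        (anchor,) = lnk.anchor_scaffolds(gmap, markers)
        assert anchor.group == "LG1"
        assert anchor.chimera_flag
        assert anchor.minority_group == "LG2"
        # midpoint between marker 5 (5000 bp) and marker 6 (6000 bp)
        assert anchor.suggested_split_bp == 5500

    def test_two_discordant_markers_orientation_unknown(self):
        ids = ["m00", "m01"]
        markers = pd.DataFrame({"scaffold": ["sc1", "sc1"], "pos": [100, 200]}, index=ids)
        gmap = lnk.GeneticMap(groups=[lnk.LinkageGroup("LG1", ids, [5.0, 0.0])])
        (anchor,) = lnk.anchor_scaffolds(gmap, markers)
        assert anchor.orientation == "unknown"


class TestIo:
    def test_tsv_roundtrip(self, tmp_path, cross_bundle):
        matrix, _ = cross_bundle
        path = tmp_path / "geno.tsv"
        sim.write_genotypes_tsv(matrix, path)
        back = lnk.read_genotypes_tsv(path)
        np.testing.assert_array_equal(
            np.isnan(back.calls), np.isnan(matrix.calls)
        )
        np.testing.assert_array_equal(
            np.nan_to_num(back.calls), np.nan_to_num(matrix.calls)
        )
        assert list(back.markers.index) == list(matrix.markers.index)
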