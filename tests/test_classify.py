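import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gliapipe import (
    LabeledNuclei,
    classify_microglial_nuclei,
    count_high_gr_nuclei,
    nonnuclear_gr_volume,
    nuclear_gr_fraction,
    quartile_bin,
    soma_volume,
)
from gliapipe.errors import ParameterError
from gliapipe.types import CellRecord
from conftest import brute_force_dilate


def make_nuclei(*masks):
    lab = np.zeros(masks[0].shape, dtype=np.int32)
    for i, m in enumerate(masks):
        lab[m] = i + 1
    return LabeledNuclei(lab)


def cube(shape, lo, hi):
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


class TestClassification:
    def test_fully_covered_nucleus_is_microglia(self):
        shape = (10, 10, 10)
        nucleus = cube(shape, (3, 3, 3), (6, 6, 6))
        ox42 = cube(shape, (2, 2, 2), (8, 8, 8))
        assert classify_microglial_nuclei(make_nuclei(nucleus), ox42) == {1}

    def test_single_uncovered_voxel_unclassifies(self):
        shape = (10, 10, 10)
        nucleus = cube(shape, (3, 3, 3), (6, 6, 6))
        ox42 = nucleus.copy()
        ox42[3, 3, 3] = False
        assert classify_microglial_nuclei(make_nuclei(nucleus), ox42) == set()

    @settings(derandomize=True, max_examples=25)
    @given(
        lab=hnp.arrays(np.int32, (6, 6, 6), elements=st.integers(0, 2)),
        ox42=hnp.arrays(bool, (6, 6, 6)),
    )
    def test_matches_brute_force_subset_check(self, lab, ox42):
        # compact labels so the container invariant holds
        present = sorted(set(lab.ravel()) - {0})
        relabel = np.zeros(3, dtype=np.int32)
        for i, p in enumerate(present):
            relabel[p] = i + 1
        lab = relabel[lab]
        nuclei = LabeledNuclei(lab)
        got = classify_microglial_nuclei(nuclei, ox42)
        for label in nuclei.labels:
            subset = all(
                ox42[idx] for idx in zip(*np.nonzero(lab == label))
            )
            assert (label in got) == subset


class TestNuclearGRFraction:
    def test_full_and_disjoint_coverage(self):
        shape = (8, 8, 8)
        nucleus = cube(shape, (2, 2, 2), (6, 6, 6))
        assert nuclear_gr_fraction(nucleus, nucleus) == 1.0
        assert nuclear_gr_fraction(nucleus, ~nucleus) == 0.0

    def test_partial_fraction_by_direct_count(self):
        # 1200-voxel nucleus, 300 GR-positive nucleus voxels -> 0.25
        shape = (12, 20, 20)
        nucleus = cube(shape, (0, 0, 0), (3, 20, 20))  # 1200 voxels
        gr = cube(shape, (0, 0, 0), (3, 5, 20))  # 300 inside
        assert nuclear_gr_fraction(nucleus, gr) == pytest.approx(0.25)

    def test_empty_nucleus_raises(self):
        with pytest.raises(ParameterError):
            nuclear_gr_fraction(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool))


class TestQuartileBin:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, "Q1"),
            (0.25, "Q1"),  # right-closed boundary convention
            (0.251, "Q2"),
            (0.5, "Q2"),
            (0.75, "Q3"),
            (0.751, "Q4"),
            (0.80, "Q4"),  # "greater than 75% GR in the nucleus"
            (1.0, "Q4"),
        ],
    )
    def test_documented_bins(self, fraction, expected):
        assert quartile_bin(fraction) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            quartile_bin(1.2)
        with pytest.raises(ParameterError):
            quartile_bin(-0.1)


class TestSomaVolume:
    def test_marker_confined_to_nucleus(self):
        shape = (12, 12, 12)
        nucleus = cube(shape, (4, 4, 4), (8, 8, 8))
        assert soma_volume(nucleus, nucleus) == int(nucleus.sum())

    def test_marker_everywhere_equals_oracle_dilation(self):
        shape = (12, 12, 12)
        nucleus = cube(shape, (5, 5, 5), (8, 8, 8))
        full = np.ones(shape, bool)
        want = int(brute_force_dilate(nucleus, 3.0).sum())
        assert soma_volume(nucleus, full, dilation_radius=3.0) == want

    def test_zero_radius_reduces_to_nuclear_overlap(self):
        shape = (10, 10, 10)
        nucleus = cube(shape, (3, 3, 3), (7, 7, 7))
        ox42 = cube(shape, (0, 0, 0), (10, 10, 7))
        want = int((nucleus & ox42).sum())
        assert soma_volume(nucleus, ox42, dilation_radius=0.0) == want

    def test_monotone_in_radius(self, rng):
        shape = (12, 12, 12)
        nucleus = cube(shape, (5, 5, 5), (8, 8, 8))
        ox42 = rng.random(shape) > 0.4
        vols = [soma_volume(nucleus, ox42, r) for r in (0, 1, 2, 3, 4)]
        assert vols == sorted(vols)

    def test_exclude_nucleus_option(self):
        shape = (12, 12, 12)
        nucleus = cube(shape, (5, 5, 5), (8, 8, 8))
        full = np.ones(shape, bool)
        with_n = soma_volume(nucleus, full, 2.0, include_nucleus=True)
        without = soma_volume(nucleus, full, 2.0, include_nucleus=False)
        assert with_n - without == int(nucleus.sum())


class TestNonNuclearGR:
    def test_trivial_cases(self):
        shape = (6, 6, 6)
        gr = cube(shape, (0, 0, 0), (3, 6, 6))
        glia = cube(shape, (3, 0, 0), (6, 6, 6))
        assert nonnuclear_gr_volume(gr, glia, np.ones(shape, bool)) == 0  # disjoint
        assert nonnuclear_gr_volume(gr, gr, gr) == 0  # purely nuclear

    @settings(derandomize=True, max_examples=30)
    @given(
        gr=hnp.arrays(bool, (6, 6, 6)),
        glia=hnp.arrays(bool, (6, 6, 6)),
        dapi=hnp.arrays(bool, (6, 6, 6)),
    )
    def test_matches_set_arithmetic_and_partition_identity(self, gr, glia, dapi):
        got = nonnuclear_gr_volume(gr, glia, dapi)
        want = int((gr & glia & ~dapi).sum())
        assert got == want
        # |GR ∩ glia| = nuclear + non-nuclear, exactly
        assert int((gr & glia).sum()) == got + int((gr & glia & dapi).sum())


class TestHighGRCount:
    def _cell(self, frac, ctype="microglia"):
        return CellRecord(
            nucleus_label=1,
            cell_type=ctype,
            nucleus_volume=1200,
            nuclear_gr_fraction=frac,
            gr_quartile=quartile_bin(frac),
            soma_volume=0,
        )

    def test_empty_list(self):
        assert count_high_gr_nuclei([]) == 0

    def test_counts_only_q4(self):
        cells = [self._cell(f) for f in (0.1, 0.8, 0.9)]
        assert count_high_gr_nuclei(cells) == 2

    def test_boundary_three_quarters_not_high(self):
        cells = [self._cell(f) for f in (0.75, 0.5, 0.2)]
        assert count_high_gr_nuclei(cells) == 0

    def test_ignores_unclassified_cells(self):
        cells = [self._cell(0.9), self._cell(0.9, ctype="unclassified")]
        assert count_high_gr_nuclei(cells) == 1
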