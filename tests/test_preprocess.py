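"""SNP/individual quality filters, PAR exclusion and sex assignment."""

import numpy as np
import pytest

from blockclock import GenotypeTable, MarkerMap, ParameterError
from blockclock.preprocess import (
    HIGH_HET,
    LOW_CALLRATE,
    MISSING_10,
    MISSING_70,
    assign_sex,
    exclude_par,
    filter_loci,
    filter_missingness,
)


def _table(calls, breeds=None, names=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_m = calls.shape
    gt = GenotypeTable(
        individuals=np.array([f"i{k}" for k in range(n_ind)], dtype=object),
        breed=np.array(breeds or ["b0"] * n_ind, dtype=object),
        calls=calls,
    )
    mm = MarkerMap(
        chrom=np.array([chrom] * n_m, dtype=object),
        name=np.array(names or [f"m{j}" for j in range(n_m)], dtype=object),
        pos_bp=np.arange(1, n_m + 1) * 100,
    )
    return gt, mm


class TestFilterLoci:
    def _breed_grid(self, n_breeds, het_breeds, n_per=2):
        """One locus heterozygous in all members of het_breeds breeds."""
        breeds = [f"b{k}" for k in range(n_breeds) for _ in range(n_per)]
        calls = np.zeros((n_breeds * n_per, 2), dtype=np.int8)
        for k in range(het_breeds):
            calls[k * n_per : (k + 1) * n_per, 0] = 1  # het at locus 0
        return _table(calls, breeds=breeds)

    def test_high_het_in_ten_breeds_removed(self):
        gt, mm = self._breed_grid(12, het_breeds=10)
        out, out_map, report = filter_loci(gt, mm)
        assert report.removed_loci == {"m0": HIGH_HET}
        assert out.n_markers == 1 and out_map.name.tolist() == ["m1"]

    def test_nine_breeds_retained(self):
        gt, mm = self._breed_grid(12, het_breeds=9)
        out, _, report = filter_loci(gt, mm)
        assert report.removed_loci == {}
        assert out.n_markers == 2

    def test_clean_locus_untouched(self):
        gt, mm = _table(np.zeros((4, 3), dtype=int))
        out, _, report = filter_loci(gt, mm)
        assert out.n_markers == 3
        assert report.counts() == {}

    def test_low_callrate_rule(self):
        # locus 0 missing in half of each of 10 single-individual... use 10 breeds x 2
        breeds = [f"b{k}" for k in range(10) for _ in range(2)]
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[::2, 0] = -1  # call rate 0.5 < 0.8 in every breed
        gt, mm = _table(calls, breeds=breeds)
        _, _, report = filter_loci(gt, mm)
        assert report.removed_loci == {"m0": LOW_CALLRATE}

    def test_missing70_rule_is_at_least(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:7, 0] = -1  # exactly 70% missing -> removed (>=)
        gt, mm = _table(calls)
        _, _, report = filter_loci(gt, mm)
        assert report.removed_loci == {"m0": MISSING_70}

    def test_first_triggering_reason_wins(self):
        # heterozygous AND badly called in >= 10 breeds: reported as high_het
        breeds = [f"b{k}" for k in range(10) for _ in range(4)]
        calls = np.zeros((40, 1), dtype=np.int8)
        calls[0::4] = 1
        calls[1::4] = 1
        calls[2::4] = -1
        calls[3::4] = -1  # per breed: het 2/2 called, callrate 0.5
        gt, mm = _table(calls, breeds=breeds)
        _, _, report = filter_loci(gt, mm)
        assert report.removed_loci == {"m0": HIGH_HET}

    def test_empty_table_rejected(self):
        gt, mm = _table(np.zeros((2, 2), dtype=int))
        with pytest.raises(ParameterError):
            filter_loci(gt.subset_individuals(np.array([], dtype=int)), mm)

    def test_idempotent(self):
        gt, mm = self._breed_grid(12, het_breeds=10)
        g1, m1, _ = filter_loci(gt, mm)
        g2, m2, rep2 = filter_loci(g1, m1)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert rep2.removed_loci == {}


class TestFilterMissingness:
    def test_individual_over_ten_percent_dropped(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[0, :11] = -1  # 11% missing
        gt, mm = _table(calls)
        out, _, report = filter_missingness(gt, mm)
        assert report.removed_individuals == {"i0": MISSING_10}
        assert out.n_individuals == 1

    def test_exactly_ten_percent_retained(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[0, :10] = -1
        gt, mm = _table(calls)
        out, _, report = filter_missingness(gt, mm)
        assert report.removed_individuals == {}
        assert out.n_individuals == 2

    def test_order_dependence(self):
        # 10x10: i0 misses 2/10 loci -> dropped. Locus m0 is missing only
        # in survivor i1: 1/10 = 10% overall (would be retained), but 1/9
        # > 10% of the survivors -> dropped only because of the ordering.
        calls = np.zeros((10, 10), dtype=np.int8)
        calls[0, [1, 2]] = -1
        calls[1, 0] = -1
        gt, mm = _table(calls)
        out, out_map, report = filter_missingness(gt, mm)
        assert report.removed_individuals == {"i0": MISSING_10}
        assert report.removed_loci == {"m0": MISSING_10}
        assert out_map.name.tolist() == [f"m{j}" for j in range(1, 10)]

    def test_all_individuals_removed_is_an_error(self):
        calls = np.full((3, 4), -1, dtype=np.int8)
        gt, mm = _table(calls)
        with pytest.raises(ParameterError, match="threshold"):
            filter_missingness(gt, mm)


class TestExcludePar:
    def _x_map(self, positions):
        return MarkerMap(
            chrom=np.array(["X"] * len(positions), dtype=object),
            name=np.array([f"x{j}" for j in range(len(positions))], dtype=object),
            pos_bp=np.array(positions),
        )

    def test_boundary_marker_removed(self):
        # the PAR boundary is quoted 1-based; a marker AT the boundary
        # (0-based 137109767) is inside the PAR and removed
        mm = self._x_map([1000, 137_109_767])
        out = exclude_par(mm)
        assert out.name.tolist() == ["x0"]

    def test_marker_just_inside_retained(self):
        mm = self._x_map([137_109_766])
        out = exclude_par(mm)
        assert out.n_markers == 1

    def test_autosomes_untouched(self):
        mm = MarkerMap(
            chrom=np.array(["3"], dtype=object),
            name=np.array(["a"], dtype=object),
            pos_bp=np.array([140_000_000]),
        )
        assert exclude_par(mm).n_markers == 1


class TestAssignSex:
    def _xy_table(self, x_calls):
        x_calls = np.asarray(x_calls, dtype=np.int8)
        n_ind, n_x = x_calls.shape
        gt = GenotypeTable(
            individuals=np.array([f"i{k}" for k in range(n_ind)], dtype=object),
            breed=np.array(["b"] * n_ind, dtype=object),
            calls=x_calls,
        )
        mm = MarkerMap(
            chrom=np.array(["X"] * n_x, dtype=object),
            name=np.array([f"x{j}" for j in range(n_x)], dtype=object),
            pos_bp=np.arange(1, n_x + 1) * 1000,
        )
        return gt, mm

    def test_no_het_is_male(self):
        gt, mm = self._xy_table(np.zeros((1, 872), dtype=int))
        sex, _ = assign_sex(gt, mm)
        assert sex.sex["i0"] == "male"

    def test_high_het_is_female(self):
        calls = np.zeros((1, 872), dtype=np.int8)
        calls[0, :50] = 1  # 50/872 ~ 5.7%
        gt, mm = self._xy_table(calls)
        sex, _ = assign_sex(gt, mm)
        assert sex.sex["i0"] == "female"
        assert sex.x_het_fraction["i0"] == pytest.approx(50 / 872)

    def test_male_residual_hets_recoded_missing(self):
        calls = np.zeros((1, 300), dtype=np.int8)
        calls[0, [10, 20]] = 1  # 2/300 = 0.67% < 1%
        gt, mm = self._xy_table(calls)
        sex, out = assign_sex(gt, mm)
        assert sex.sex["i0"] == "male"
        assert out.calls[0, 10] == -1 and out.calls[0, 20] == -1
        assert (out.calls[0] == -1).sum() == 2

    def test_cohort_extremes(self):
        homo = np.zeros((5, 200), dtype=np.int8)
        sex, _ = assign_sex(*self._xy_table(homo))
        assert set(sex.sex.values()) == {"male"}
        het = np.zeros((5, 200), dtype=np.int8)
        het[:, :10] = 1  # 5% het everywhere
        sex, _ = assign_sex(*self._xy_table(het))
        assert set(sex.sex.values()) == {"female"}

    def test_all_missing_x_unassigned(self):
        calls = np.full((1, 10), -1, dtype=np.int8)
        gt, mm = self._xy_table(calls)
        sex, _ = assign_sex(gt, mm)
        assert sex.unassigned == ["i0"]
        assert sex.sex == {}
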