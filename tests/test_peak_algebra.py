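import subprocess

import numpy as np
import pytest

from episieve.peaks import (
    consensus_peaks,
    intersect_common,
    merge_union,
    subtract_specific,
)

from conftest import make_peakset, random_canonical
from oracles import (
    base_set,
    intersect_per_base,
    subtract_whole_peak,
    union_per_base,
)


def as_tuples(ps):
    return [(p.chrom, p.start, p.end) for p in ps]


class TestIntersectCommon:
    def test_empty_partner_gives_empty(self):
        a = make_peakset([(100, 200)])
        assert as_tuples(intersect_common(a, make_peakset([]))) == []

    def test_partial_overlap_segment(self):
        a = make_peakset([(100, 200)])
        b = make_peakset([(150, 250)])
        assert as_tuples(intersect_common(a, b)) == [("chr1", 150, 200)]

    def test_half_open_boundary_shares_no_base(self):
        a = make_peakset([(0, 50)])
        b = make_peakset([(50, 100)])
        assert as_tuples(intersect_common(a, b)) == []

    def test_one_peak_split_into_multiple_segments(self):
        """A peak spanning two disjoint partner peaks yields two segments,
        so common + specific counts need not add to the original count."""
        a = make_peakset([(100, 300)])
        b = make_peakset([(120, 150), (200, 260)])
        assert as_tuples(intersect_common(a, b)) == [
            ("chr1", 120, 150),
            ("chr1", 200, 260),
        ]

    def test_idempotence_on_identical_sets(self):
        a = make_peakset([(10, 20), (30, 45)])
        assert intersect_common(a, a) == a

    def test_disjoint_chromosomes_empty(self):
        a = make_peakset([("chr1", 0, 100)])
        b = make_peakset([("chr2", 0, 100)])
        assert as_tuples(intersect_common(a, b)) == []

    def test_non_canonical_input_rejected(self):
        bad = make_peakset([(0, 100), (50, 150)])
        with pytest.raises(ValueError, match="canonical"):
            intersect_common(bad, make_peakset([(0, 10)]))
        # auto-merge coalesces and proceeds
        ok = intersect_common(bad, make_peakset([(0, 10)]), auto_merge=True)
        assert as_tuples(ok) == [("chr1", 0, 10)]


class TestSubtractSpecific:
    def test_empty_partner_is_identity(self):
        a = make_peakset([(100, 200)])
        assert subtract_specific(a, make_peakset([])) == a

    def test_any_overlap_disqualifies_whole_peak(self):
        a = make_peakset([(100, 200)])
        b = make_peakset([(150, 250)])
        assert as_tuples(subtract_specific(a, b)) == []

    def test_surviving_peak_unmodified(self):
        a = make_peakset([(100, 200), (500, 600)])
        b = make_peakset([(150, 250)])
        assert as_tuples(subtract_specific(a, b)) == [("chr1", 500, 600)]

    def test_fractional_overlap_threshold(self):
        # 50 of 100 bases covered: removed at frac 0.4, kept at frac 0.6
        a = make_peakset([(0, 100)])
        b = make_peakset([(50, 150)])
        assert len(subtract_specific(a, b, min_overlap_frac=0.4)) == 0
        assert len(subtract_specific(a, b, min_overlap_frac=0.6)) == 1

    def test_partition_of_peak_counts(self):
        """|specific| + |overlapping| = |A| for any canonical A, B."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = make_peakset(random_canonical(rng))
            b = make_peakset(random_canonical(rng))
            specific = subtract_specific(a, b)
            overlapping = consensus_peaks(a, b, mode="a_overlapping")
            assert len(specific) + len(overlapping) == len(a)


class TestMergeUnion:
    def test_overlap_coalesced(self):
        out = merge_union(make_peakset([(100, 200)]), make_peakset([(150, 250)]))
        assert as_tuples(out) == [("chr1", 100, 250)]

    def test_disjoint_sets_sorted_concatenation(self):
        out = merge_union(
            make_peakset([("chr2", 5, 10)]), make_peakset([("chr1", 0, 3)])
        )
        assert as_tuples(out) == [("chr1", 0, 3), ("chr2", 5, 10)]

    def test_bookended_coalesce_configurable(self):
        a, b = make_peakset([(0, 10)]), make_peakset([(10, 20)])
        assert as_tuples(merge_union(a, b)) == [("chr1", 0, 20)]
        assert as_tuples(merge_union(a, b, coalesce_bookended=False)) == [
            ("chr1", 0, 10),
            ("chr1", 10, 20),
        ]


class TestConsensusModes:
    A = [(100, 200)]
    B = [(150, 250)]

    def test_empty_partner_empty_in_all_modes(self):
        a = make_peakset(self.A)
        for mode in ("intersect_segment", "a_overlapping", "union_component"):
            assert len(consensus_peaks(a, make_peakset([]), mode=mode)) == 0

    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("intersect_segment", [("chr1", 150, 200)]),
            ("a_overlapping", [("chr1", 100, 200)]),
            ("union_component", [("chr1", 100, 250)]),
        ],
    )
    def test_modes_on_overlapping_pair(self, mode, expected):
        out = consensus_peaks(make_peakset(self.A), make_peakset(self.B), mode=mode)
        assert as_tuples(out) == expected

    def test_union_component_requires_both_sets(self):
        # the [400, 500) component exists only in A: not consensus
        a = make_peakset([(100, 200), (400, 500)])
        b = make_peakset([(150, 250)])
        out = consensus_peaks(a, b, mode="union_component")
        assert as_tuples(out) == [("chr1", 100, 250)]

    def test_default_mode_is_intersect_segment(self):
        a, b = make_peakset(self.A), make_peakset(self.B)
        assert consensus_peaks(a, b) == consensus_peaks(a, b, mode="intersect_segment")


class TestOracleEquivalence:
    """Sweep implementations agree with per-base membership sets."""

    @pytest.mark.parametrize("seed", range(30))
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a_iv = random_canonical(rng)
        b_iv = random_canonical(rng)
        a, b = make_peakset(a_iv), make_peakset(b_iv)
        assert as_tuples(intersect_common(a, b)) == intersect_per_base(a_iv, b_iv)
        assert as_tuples(subtract_specific(a, b)) == subtract_whole_peak(a_iv, b_iv)
        # maximal per-base runs coalesce bookended intervals, matching
        # the default merge behaviour
        assert as_tuples(merge_union(a, b)) == union_per_base(a_iv, b_iv)

    def test_commutativity_as_base_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            a = make_peakset(random_canonical(rng))
            b = make_peakset(random_canonical(rng))
            ab = base_set(as_tuples(intersect_common(a, b)))
            ba = base_set(as_tuples(intersect_common(b, a)))
            assert ab == ba

    def test_partition_of_bases(self):
        """Every base of A is in exactly one of: common(A,B), A-minus-B bases."""
        rng = np.random.default_rng(123)
        a_iv, b_iv = random_canonical(rng), random_canonical(rng)
        a, b = make_peakset(a_iv), make_peakset(b_iv)
        common_bases = base_set(as_tuples(intersect_common(a, b)))
        a_bases = base_set(a_iv)
        complement = a_bases - base_set(b_iv)
        assert common_bases | complement == a_bases
        assert common_bases & complement == set()


class TestBedtoolsCrossCheck:
    """Independent external oracle for the bedtools-defined semantics."""

    def _write(self, tmp_path, name, intervals):
        path = tmp_path / name
        path.write_text(
            "".join(f"{c}\t{s}\t{e}\n" for c, s, e in sorted(intervals))
        )
        return path

    def _run(self, *args):
        out = subprocess.run(
            ["bedtools", "intersect", *args], capture_output=True, text=True, check=True
        )
        return [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.stdout.splitlines())
        ]

    def test_default_and_v_options_match(self, tmp_path):
        rng = np.random.default_rng(7)
        a_iv, b_iv = random_canonical(rng), random_canonical(rng)
        fa = self._write(tmp_path, "a.bed", a_iv)
        fb = self._write(tmp_path, "b.bed", b_iv)
        a, b = make_peakset(a_iv), make_peakset(b_iv)
        assert as_tuples(intersect_common(a, b)) == sorted(
            self._run("-a", str(fa), "-b", str(fb))
        )
        assert as_tuples(subtract_specific(a, b)) == sorted(
            self._run("-a", str(fa), "-b", str(fb), "-v")
        )
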