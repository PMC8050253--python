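import numpy as np
import pandas as pd
import pytest

from episieve.annotation import make_tss_windows
from episieve.core import GeneModel, GenomicInterval, SignalTrack
from episieve.profiles import (
    average_profile,
    expression_tertiles,
    gene_body_profile_matrix,
    peak_area_matrix,
    profile_matrix,
)


def gene(gene_id, start, end, strand, chrom="chr1"):
    return GeneModel(gene_id, gene_id, GenomicInterval(chrom, start, end, strand))


class TestProfileMatrix:
    def test_flat_field_gives_constant_bins(self):
        track = SignalTrack({"chr1": [(0, 100_000, 2.0)]})
        m = profile_matrix(track, [gene("g", 50_000, 52_000, "+")], flank=3000, bins=10)
        expected = 2.0 * 1e6 / track.library_size
        assert np.allclose(m.values, expected)

    def test_single_run_localized_to_its_bins(self):
        """Signal at [tss+100, tss+200) elevates exactly the overlapping bins."""
        tss = 50_000
        track = SignalTrack({"chr1": [(tss + 100, tss + 200, 5.0)]})
        m = profile_matrix(track, [gene("g", tss, tss + 2000, "+")],
                           flank=1000, bins=20)  # 100 bp bins
        hot = np.nonzero(m.values[0])[0]
        # window starts at tss-1000; [tss+100, tss+200) is bin 11
        assert list(hot) == [11]

    @pytest.mark.parametrize("seed", range(8))
    def test_bin_means_match_per_base_average(self, seed):
        rng = np.random.default_rng(seed)
        runs = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1, 300))
            width = int(rng.integers(1, 200))
            runs.append((pos, pos + width, float(rng.integers(0, 5))))
            pos += width
        track = SignalTrack({"chr1": runs})
        tss, flank, bins = 4000, 1500, 12
        m = profile_matrix(track, [gene("g", tss, tss + 500, "+")],
                           flank=flank, bins=bins)
        dense = np.zeros(20_000)
        for s, e, v in runs:
            dense[s:e] = v
        edges = np.round(np.linspace(tss - flank, tss + flank, bins + 1)).astype(int)
        expected = np.array([
            dense[a:b].mean() for a, b in zip(edges[:-1], edges[1:])
        ]) * 1e6 / track.library_size
        assert np.allclose(m.values[0], expected)

    def test_minus_strand_orientation_flip(self):
        """Genomic upstream signal of a minus-strand gene appears on the
        downstream (3') side of the oriented profile."""
        tss = 50_000
        track = SignalTrack({"chr1": [(tss + 500, tss + 900, 4.0)]})  # genomic right
        plus = profile_matrix(track, [gene("gp", tss, tss + 2000, "+")],
                              flank=1000, bins=10)
        minus = profile_matrix(track, [gene("gm", tss - 2000, tss + 1, "-")],
                               flank=1000, bins=10)
        # for the minus-strand gene, genomic-right is 5' -> early bins
        assert np.allclose(minus.values[0], plus.values[0][::-1])

    def test_clipped_window_averages_existing_bases(self):
        track = SignalTrack({"chr1": [(0, 10_000, 1.0)]})
        m = profile_matrix(track, [gene("g", 500, 2000, "+")], flank=3000, bins=6)
        expected = 1e6 / track.library_size
        # all in-bounds bins still average to the flat value
        assert np.allclose(m.values[0][m.values[0] > 0], expected)

    def test_invalid_bins_rejected(self):
        track = SignalTrack({"chr1": [(0, 100, 1.0)]})
        with pytest.raises(ValueError):
            profile_matrix(track, [gene("g", 50, 60, "+")], bins=1)


class TestAverageProfile:
    def test_single_gene_is_its_own_row(self):
        track = SignalTrack({"chr1": [(4000, 6000, 3.0)]})
        m = profile_matrix(track, [gene("g", 5000, 5500, "+")], flank=1000, bins=4)
        out = average_profile(m)
        assert np.allclose(out.loc["all"].to_numpy(), m.values[0])

    def test_groups_average_their_members(self):
        track = SignalTrack({"chr1": [(0, 100_000, 1.0)]})
        genes = [gene(f"g{i}", 20_000 + 10_000 * i, 22_000 + 10_000 * i, "+")
                 for i in range(4)]
        m = profile_matrix(track, genes, flank=1000, bins=4)
        out = average_profile(m, groups={"a": ["g0", "g1"], "b": ["g2", "g3"]})
        assert list(out.index) == ["a", "b"]
        assert np.allclose(out.loc["a"], out.loc["b"])

    def test_empty_group_raises(self):
        track = SignalTrack({"chr1": [(0, 10_000, 1.0)]})
        m = profile_matrix(track, [gene("g", 5000, 5100, "+")], flank=1000, bins=4)
        with pytest.raises(ValueError, match="no genes"):
            average_profile(m, groups={"empty": ["absent"]})


class TestExpressionTertiles:
    def test_nine_genes_split_evenly(self):
        expr = pd.Series({f"g{i}": float(9 - i) for i in range(9)})
        groups = expression_tertiles(expr)
        assert [len(groups[k]) for k in ("high", "medium", "low")] == [3, 3, 3]
        assert groups["high"] == ["g0", "g1", "g2"]

    def test_ten_genes_split_4_3_3(self):
        expr = pd.Series({f"g{i}": float(10 - i) for i in range(10)})
        groups = expression_tertiles(expr)
        assert [len(groups[k]) for k in ("high", "medium", "low")] == [4, 3, 3]

    def test_all_equal_deterministic_with_warning(self):
        expr = pd.Series({g: 1.0 for g in "abcdef"})
        with pytest.warns(UserWarning, match="equal"):
            groups = expression_tertiles(expr)
        assert groups["high"] == ["a", "b"]
        assert groups["low"] == ["e", "f"]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            expression_tertiles(pd.Series({"a": 1.0, "b": 2.0}))


class TestPeakAreaMatrix:
    def windows(self, tss=50_000, flank=3000):
        return make_tss_windows([gene("g", tss, tss + 1000, "+")], flank=flank)

    def test_zero_track_zero_area(self):
        track = SignalTrack({"chr1": [(0, 10, 0.0)]}, library_size=1.0)
        out = peak_area_matrix({"s": track}, self.windows())
        assert float(out.iloc[0, 0]) == 0.0

    def test_uniform_signal_closed_form(self):
        c, L = 2.5, 4.0e6
        track = SignalTrack({"chr1": [(0, 100_000, c)]}, library_size=L)
        out = peak_area_matrix({"s": track}, self.windows())
        w = self.windows()[0].width
        assert float(out.iloc[0, 0]) == pytest.approx(c * w * 1e6 / L)

    def test_library_rescaling_invariance(self):
        base = SignalTrack({"chr1": [(45_000, 55_000, 2.0)]}, library_size=1e6)
        doubled = SignalTrack({"chr1": [(45_000, 55_000, 4.0)]}, library_size=2e6)
        a = peak_area_matrix({"s": base}, self.windows())
        b = peak_area_matrix({"s": doubled}, self.windows())
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_additive_over_disjoint_subwindows(self):
        track = SignalTrack({"chr1": [(48_000, 52_000, 3.0)]})
        full = make_tss_windows([gene("g", 50_000, 51_000, "+")], flank=2000)
        left = make_tss_windows([gene("gl", 50_000, 51_000, "+")], flank=1000)
        area_full = peak_area_matrix({"s": track}, full).iloc[0, 0]
        area_left = peak_area_matrix({"s": track}, left).iloc[0, 0]
        right = track.integral_one("chr1", 48_000, 49_000) + track.integral_one(
            "chr1", 51_000, 52_000
        )
        right *= 1e6 / track.library_size
        assert area_full == pytest.approx(area_left + right)

    def test_missing_chromosome_warns_area_zero(self):
        track = SignalTrack({"chr2": [(0, 100, 1.0)]})
        with pytest.warns(UserWarning, match="no signal"):
            out = peak_area_matrix({"s": track}, self.windows())
        assert float(out.iloc[0, 0]) == 0.0


class TestGeneBodyProfile:
    def test_three_segments_and_orientation(self):
        g_plus = gene("gp", 50_000, 54_000, "+")
        track = SignalTrack({"chr1": [(50_000, 54_000, 2.0)]})
        m = gene_body_profile_matrix(track, [g_plus], flank=1000,
                                     flank_bins=5, body_bins=10)
        row = m.values[0]
        assert m.values.shape[1] == 20
        assert np.allclose(row[5:15], 2.0 * 1e6 / track.library_size)
        assert np.allclose(row[:5], 0) and np.allclose(row[15:], 0)

    def test_body_length_normalized(self):
        """Genes of different lengths map their bodies onto the same bins."""
        track = SignalTrack(
            {"chr1": [(50_000, 52_000, 1.0), (80_000, 88_000, 1.0)]}
        )
        m = gene_body_profile_matrix(
            track,
            [gene("a", 50_000, 52_000, "+"), gene("b", 80_000, 88_000, "+")],
            flank=500, flank_bins=2, body_bins=8,
        )
        body_a, body_b = m.values[0][2:10], m.values[1][2:10]
        assert np.allclose(body_a, body_b)
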