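"""Tests for windowed coverage, F/M ratio formation and sex calling."""

import numpy as np
import pytest

from karyoscope import (
    CoverageTrack,
    ScaffoldSpec,
    call_scaffolds,
    coverage_from_alignments,
    coverage_from_bedgraph,
    coverage_from_placements,
    make_windows,
    normalize_pair,
    ratio_track,
    simulate_genome,
    simulate_reads,
)
from karyoscope.io import write_bedgraph, write_sam
from karyoscope.sexscan import AUTOSOMAL, X_LINKED, ratio_table


def _track(grid, values, label="t", scale=1.0):
    values = np.asarray(values, dtype=float)
    return CoverageTrack(
        grid=grid, values=values, sample_label=label,
        library_size=float((values * grid.window_lengths()).sum()), scale=scale,
    )


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (250_000, [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]),
            (100_000, [(0, 100_000)]),
            (1, [(0, 1)]),
        ],
    )
    def test_tiling(self, length, expected):
        grid = make_windows({"s1": length}, 100_000)
        assert [(s, e) for _, s, e in grid.windows()] == expected
        # concatenation exactly tiles the scaffold
        assert int(grid.window_lengths().sum()) == length

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_windows({"s1": 0}, 100_000)
        with pytest.raises(ValueError):
            make_windows({"s1": 100}, 0)


class TestCoverageFromAlignments:
    def test_single_read_single_window(self, tmp_path):
        sam = tmp_path / "one.sam"
        write_sam({"s1": np.array([500])}, {"s1": 200_000}, 100, sam)
        grid = make_windows({"s1": 200_000}, 100_000)
        track = coverage_from_alignments(sam, grid)
        assert track.values[0] == pytest.approx(100 / 100_000)
        assert track.values[1] == 0.0
        assert track.library_size == 100

    def test_boundary_read_split_pro_rata(self, tmp_path):
        # read [99940, 100040): 60 bases in window 0, 40 in window 1
        sam = tmp_path / "straddle.sam"
        write_sam({"s1": np.array([99_940])}, {"s1": 200_000}, 100, sam)
        grid = make_windows({"s1": 200_000}, 100_000)
        track = coverage_from_alignments(sam, grid)
        bases = track.values * grid.window_lengths()
        assert bases[0] == pytest.approx(60)
        assert bases[1] == pytest.approx(40)

    def test_base_conservation_exact(self, toy_genome, toy_reads):
        female, _ = toy_reads
        grid = make_windows(toy_genome.scaffold_lengths, 100_000)
        track = coverage_from_placements(female, grid)
        attributed = float((track.values * grid.window_lengths()).sum())
        assert attributed == female.total_reads * female.read_length
        assert track.library_size == attributed

    def test_placements_and_sam_paths_agree(self, tmp_path):
        specs = [ScaffoldSpec("sA", 150_000), ScaffoldSpec("sB", 90_000)]
        g = simulate_genome(specs, seed=1, genes_per_mb=0, tandem_clusters=0,
                            with_sequence=False)
        reads = simulate_reads(g, "female", mean_depth=2, read_length=100, seed=2)
        sam = tmp_path / "r.sam"
        write_sam(reads.starts, g.scaffold_lengths, 100, sam)
        grid = make_windows(g.scaffold_lengths, 50_000)
        fast = coverage_from_placements(reads, grid)
        slow = coverage_from_alignments(sam, grid)
        np.testing.assert_allclose(fast.values, slow.values)

    def test_empty_input_warns_all_zero(self, tmp_path):
        sam = tmp_path / "empty.sam"
        write_sam({}, {"s1": 100_000}, 100, sam)
        grid = make_windows({"s1": 100_000}, 100_000)
        with pytest.warns(UserWarning, match="no usable alignments"):
            track = coverage_from_alignments(sam, grid)
        assert (track.values == 0).all()

    def test_unknown_scaffold_rejected(self, tmp_path):
        sam = tmp_path / "alien.sam"
        write_sam({"other": np.array([10])}, {"other": 100_000}, 100, sam)
        grid = make_windows({"s1": 100_000}, 100_000)
        with pytest.raises(ValueError, match="other"):
            coverage_from_alignments(sam, grid)


class TestCoverageFromBedgraph:
    def test_constant_field(self, tmp_path):
        bg = tmp_path / "c.bedgraph"
        write_bedgraph([("s1", 0, 250_000, 7.0)], bg)
        grid = make_windows({"s1": 250_000}, 100_000)
        track = coverage_from_bedgraph(bg, grid)
        np.testing.assert_allclose(track.values, 7.0)

    def test_half_window_weighted_mean(self, tmp_path):
        bg = tmp_path / "h.bedgraph"
        write_bedgraph([("s1", 0, 50_000, 10.0)], bg)
        grid = make_windows({"s1": 100_000}, 100_000)
        track = coverage_from_bedgraph(bg, grid)
        assert track.values[0] == pytest.approx(5.0)

    def test_round_trip_from_coverage_track(self, tmp_path, toy_genome, toy_reads):
        female, _ = toy_reads
        grid = make_windows(toy_genome.scaffold_lengths, 100_000)
        track = coverage_from_placements(female, grid)
        bg = tmp_path / "rt.bedgraph"
        names = grid.window_scaffold_names()
        starts, ends = grid.window_starts(), grid.window_ends()
        write_bedgraph(
            ((names[i], int(starts[i]), int(ends[i]), track.values[i])
             for i in range(grid.n_windows)),
            bg, precision=17,
        )
        back = coverage_from_bedgraph(bg, grid)
        np.testing.assert_allclose(back.values, track.values)

    def test_overlapping_intervals_rejected(self, tmp_path):
        bg = tmp_path / "o.bedgraph"
        write_bedgraph([("s1", 0, 60_000, 1.0), ("s1", 50_000, 90_000, 2.0)], bg)
        grid = make_windows({"s1": 100_000}, 100_000)
        with pytest.raises(ValueError, match="overlap"):
            coverage_from_bedgraph(bg, grid)


class TestNormalizeAndRatio:
    def test_median_becomes_one(self):
        grid = make_windows({"s": 500_000}, 100_000)
        f = _track(grid, [10, 20, 30, 20, 20])
        m = _track(grid, [5, 5, 5, 5, 5])
        nf, nm = normalize_pair(f, m)
        assert np.median(nf.values) == pytest.approx(1.0)
        assert np.median(nm.values) == pytest.approx(1.0)
        np.testing.assert_allclose(nf.values, np.array([10, 20, 30, 20, 20]) / 20)

    def test_scale_invariance(self):
        grid = make_windows({"s": 500_000}, 100_000)
        m1 = _track(grid, [4, 6, 8, 6, 5])
        m2 = _track(grid, np.array([4, 6, 8, 6, 5]) * 10.0)
        f = _track(grid, [5, 5, 5, 5, 5])
        _, n1 = normalize_pair(f, m1)
        _, n2 = normalize_pair(f, m2)
        np.testing.assert_allclose(n1.values, n2.values)

    def test_all_zero_track_rejected(self):
        grid = make_windows({"s": 200_000}, 100_000)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_pair(_track(grid, [0, 0]), _track(grid, [1, 1]))

    def test_different_depths_agree_after_normalization(self):
        # female 20x vs male 35x: autosomal normalized values agree
        spec = ScaffoldSpec("a", 2_000_000)
        g = simulate_genome([spec], seed=0, genes_per_mb=0, tandem_clusters=0,
                            with_sequence=False)
        grid = make_windows(g.scaffold_lengths, 100_000)
        f = coverage_from_placements(
            simulate_reads(g, "female", mean_depth=20, read_length=100, seed=1), grid
        )
        m = coverage_from_placements(
            simulate_reads(g, "male", mean_depth=35, read_length=100, seed=2), grid
        )
        nf, nm = normalize_pair(f, m)
        np.testing.assert_allclose(nf.values, nm.values, rtol=0.05)

    @pytest.mark.parametrize(
        "f,m,expected", [(2.0, 1.0, 1.0), (3.0, 3.0, 0.0)]
    )
    def test_ratio_arithmetic(self, f, m, expected):
        grid = make_windows({"s": 100_000}, 100_000)
        r = ratio_track(_track(grid, [f], scale=10), _track(grid, [m], scale=10))
        assert r.log2_ratio[0] == pytest.approx(expected)
        assert not r.masked[0]

    def test_zero_and_low_depth_masked(self):
        grid = make_windows({"s": 300_000}, 100_000)
        f = _track(grid, [1.0, 1.0, 0.05], scale=10)   # raw: 10, 10, 0.5
        m = _track(grid, [0.0, 1.0, 1.0], scale=10)
        r = ratio_track(f, m, min_depth=1.0)
        assert r.masked[0]          # male zero
        assert not r.masked[1]
        assert r.masked[2]          # female raw 0.5 < 1
        assert np.isnan(r.log2_ratio[0])

    def test_swap_negates_unmasked_ratios_exactly(self, toy_genome, toy_reads):
        female, male = toy_reads
        grid = make_windows(toy_genome.scaffold_lengths, 100_000)
        f = coverage_from_placements(female, grid)
        m = coverage_from_placements(male, grid)
        nf, nm = normalize_pair(f, m)
        fwd = ratio_track(nf, nm)
        rev = ratio_track(nm, nf)
        np.testing.assert_array_equal(fwd.masked, rev.masked)
        ok = ~fwd.masked
        np.testing.assert_array_equal(fwd.log2_ratio[ok], -rev.log2_ratio[ok])


@pytest.fixture(scope="module")
def toy_ratio(toy_genome, toy_reads):
    female, male = toy_reads
    grid = make_windows(toy_genome.scaffold_lengths, 100_000)
    nf, nm = normalize_pair(
        coverage_from_placements(female, grid),
        coverage_from_placements(male, grid),
    )
    return ratio_track(nf, nm)


class TestCallScaffolds:
    def test_planted_x_recovered(self, toy_genome, toy_ratio):
        calls = call_scaffolds(toy_ratio)
        by = calls.set_index("scaffold")["call"]
        for name in toy_genome.scaffold_lengths:
            expected = X_LINKED if name in toy_genome.truth_x else AUTOSOMAL
            assert by[name] == expected

    def test_identical_tracks_all_autosomal(self):
        grid = make_windows({"a": 300_000, "b": 200_000}, 100_000)
        t = _track(grid, [5.0] * 5, scale=4)
        nf, nm = normalize_pair(t, t)
        calls = call_scaffolds(ratio_track(nf, nm))
        assert (calls["call"] == AUTOSOMAL).all()
        assert (calls["median_log2_ratio"] == 0).all()

    def test_scale_invariance_of_calls(self, toy_genome, toy_reads):
        female, male = toy_reads
        grid = make_windows(toy_genome.scaffold_lengths, 100_000)
        f = coverage_from_placements(female, grid)
        m = coverage_from_placements(male, grid)
        base = call_scaffolds(ratio_track(*normalize_pair(f, m)))
        import dataclasses
        f10 = dataclasses.replace(f, values=f.values * 10, library_size=f.library_size * 10)
        scaled = call_scaffolds(ratio_track(*normalize_pair(f10, m)))
        assert list(base["call"]) == list(scaled["call"])

    def test_even_window_median_midpoint_convention(self):
        # two windows straddling the X band: numpy median = midpoint
        grid = make_windows({"s": 200_000}, 100_000)
        f = _track(grid, [2.0, 1.2], scale=10)
        m = _track(grid, [1.0, 1.0], scale=10)
        r = ratio_track(f, m)
        med = float(np.median(r.log2_ratio))
        calls = call_scaffolds(r, x_band=(0.6, 1.4))
        expected = X_LINKED if 0.6 <= med <= 1.4 else AUTOSOMAL
        assert calls["call"][0] == expected

    def test_fully_masked_scaffold_ambiguous(self):
        grid = make_windows({"s": 200_000}, 100_000)
        r = ratio_track(_track(grid, [0.0, 0.0]), _track(grid, [1.0, 1.0]))
        calls = call_scaffolds(r)
        assert calls["call"][0] == "ambiguous"
        assert calls["n_unmasked"][0] == 0

    def test_band_validation(self, toy_ratio):
        with pytest.raises(ValueError, match="x_band"):
            call_scaffolds(toy_ratio, x_band=(1.4, 0.6))

    def test_recovery_across_seeds_at_10x(self):
        # the planted X is recovered and no autosome ever called X-linked
        specs = [
            ScaffoldSpec("x", 1_200_000, is_x=True),
            ScaffoldSpec("a1", 1_000_000),
            ScaffoldSpec("a2", 800_000),
        ]
        g = simulate_genome(specs, seed=0, genes_per_mb=0, tandem_clusters=0,
                            with_sequence=False)
        grid = make_windows(g.scaffold_lengths, 100_000)
        for seed in range(20):
            f = coverage_from_placements(
                simulate_reads(g, "female", 10, 100, seed=2 * seed), grid)
            m = coverage_from_placements(
                simulate_reads(g, "male", 10, 100, seed=2 * seed + 1), grid)
            calls = call_scaffolds(ratio_track(*normalize_pair(f, m)))
            by = calls.set_index("scaffold")["call"]
            assert by["x"] == X_LINKED
            assert by["a1"] == AUTOSOMAL and by["a2"] == AUTOSOMAL


def test_ratio_table_shape(toy_genome, toy_reads):
    female, male = toy_reads
    grid = make_windows(toy_genome.scaffold_lengths, 100_000)
    f = coverage_from_placements(female, grid)
    m = coverage_from_placements(male, grid)
    nf, nm = normalize_pair(f, m)
    r = ratio_track(nf, nm)
    df = ratio_table(nf, nm, r)
    assert list(df.columns) == [
        "scaffold", "start", "end", "depth_f", "depth_m", "log2_ratio", "masked"
    ]
    assert len(df) == grid.n_windows
    np.testing.assert_allclose(df["depth_f"], f.values)
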