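"""Contextual signal features: geometry, bin means, z-scoring."""

import numpy as np
import pytest

import tadbound as tb
from tadbound.signal import (
    bin_signal,
    make_bins,
    region_length,
    signal_matrix,
    signal_vector,
    zscore_by_factor,
)


@pytest.mark.parametrize(
    "bin_size,bin_number,expected",
    [(40000, 10, 840000), (1, 0, 1), (40000, 8, 680000), (40000, 6, 520000)],
)
def test_region_length(bin_size, bin_number, expected):
    assert region_length(tb.BinConfig(bin_size, bin_number)) == expected


class TestMakeBins:
    def test_tiling_around_center(self):
        center = tb.GenomicLocus("chr1", 400000, 440000, tb.BOUNDARY)
        bins = make_bins(center, tb.BinConfig(40000, 10))
        assert len(bins) == 21
        assert bins[0].start == 0 and bins[-1].end == 840000
        assert bins[10] == center
        for a, b in zip(bins, bins[1:]):
            assert a.end == b.start  # contiguous, ordered upstream->downstream

    def test_bin_number_zero_returns_center_only(self):
        center = tb.GenomicLocus("chr1", 100, 200)
        assert make_bins(center, tb.BinConfig(100, 0)) == [center]

    def test_out_of_bounds_upstream(self):
        center = tb.GenomicLocus("chr1", 0, 40000)
        with pytest.raises(tb.EdgeError):
            make_bins(center, tb.BinConfig(40000, 10))

    def test_out_of_bounds_downstream_with_chrom_length(self):
        center = tb.GenomicLocus("chr1", 40000, 80000)
        with pytest.raises(tb.EdgeError):
            make_bins(center, tb.BinConfig(40000, 1), chrom_length=100000)


class TestBinSignal:
    def test_constant_track(self):
        track = tb.SignalTrack.from_intervals("X", [("chr1", 0, 1000, 2.0)])
        assert bin_signal(track, tb.GenomicLocus("chr1", 0, 1000)) == 2.0

    def test_fully_uncovered(self):
        track = tb.SignalTrack.from_intervals("X", [("chr1", 0, 100, 2.0)])
        assert bin_signal(track, tb.GenomicLocus("chr1", 1000, 1100)) == 0.0

    def test_half_covered_weighted_mean(self):
        track = tb.SignalTrack.from_intervals("X", [("chr1", 0, 50, 4.0)])
        assert bin_signal(track, tb.GenomicLocus("chr1", 0, 100)) == pytest.approx(2.0)


@pytest.mark.parametrize(
    "n_tracks,bin_number,expected",
    [(9, 10, 189), (9, 8, 153), (9, 6, 117), (1, 1, 3)],
)
def test_signal_vector_dimensionality(n_tracks, bin_number, expected):
    tracks = [
        tb.SignalTrack.from_intervals(f"m{i}", [("chr1", 0, 10_000_000, 1.0)])
        for i in range(n_tracks)
    ]
    config = tb.BinConfig(40000, bin_number)
    locus = tb.GenomicLocus("chr1", 40000 * (bin_number + 1), 40000 * (bin_number + 2))
    vec = signal_vector(tracks, locus, config)
    assert vec.shape == (expected,)
    np.testing.assert_allclose(vec, 1.0)


def test_signal_vector_matches_per_base_oracle(rng):
    """Bin means agree with a brute-force per-base average."""
    bin_size, bin_number = 10, 2
    config = tb.BinConfig(bin_size, bin_number)
    # random piecewise track over [0, 200) with gaps
    base = np.zeros(200)
    intervals = []
    pos = 0
    while pos < 190:
        width = int(rng.integers(3, 15))
        if rng.random() < 0.7:
            v = float(rng.normal())
            intervals.append(("chr1", pos, min(pos + width, 200), v))
            base[pos : pos + width] = v
        pos += width
    track = tb.SignalTrack.from_intervals("X", intervals)
    locus = tb.GenomicLocus("chr1", 100, 110)
    vec = signal_vector([track], locus, config)
    oracle = [
        base[s : s + bin_size].mean()
        for s in range(100 - bin_number * bin_size, 100 + (bin_number + 1) * bin_size, bin_size)
    ]
    np.testing.assert_allclose(vec, oracle, atol=1e-9)


def test_shift_by_one_bin_shifts_block():
    """Moving the locus one bin downstream shifts the per-mark block by one."""
    bin_size = 10
    values = [("chr1", i * bin_size, (i + 1) * bin_size, float(i)) for i in range(20)]
    track = tb.SignalTrack.from_intervals("X", values)
    config = tb.BinConfig(bin_size, 3)
    v1 = signal_vector([track], tb.GenomicLocus("chr1", 50, 60), config)
    v2 = signal_vector([track], tb.GenomicLocus("chr1", 60, 70), config)
    np.testing.assert_allclose(v1[1:], v2[:-1])


def test_signal_matrix_drops_edge_loci(caplog):
    track = tb.SignalTrack.from_intervals("X", [("chr1", 0, 1000, 1.0)])
    config = tb.BinConfig(100, 2)
    loci = [
        tb.GenomicLocus("chr1", 0, 100, tb.BOUNDARY),  # upstream edge
        tb.GenomicLocus("chr1", 500, 600, tb.BOUNDARY),
    ]
    m = signal_matrix([track], loci, config)
    assert len(m.data) == 1
    assert m.loci[0].start == 500


class TestZscoreByFactor:
    def _matrix(self, rows):
        import pandas as pd

        df = pd.DataFrame(
            rows, columns=["A@-1", "A@0", "A@1"], index=[f"r{i}" for i in range(len(rows))]
        )
        return tb.FeatureMatrix(df, np.zeros(len(rows)), ("A",), 1)

    def test_hand_zscore(self):
        z = zscore_by_factor(self._matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.data.to_numpy()[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_block_maps_to_zeros(self):
        z = zscore_by_factor(self._matrix([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(z.data.to_numpy()[0], 0.0)

    def test_idempotent_on_standardized_rows(self, rng):
        rows = rng.normal(size=(4, 3))
        z1 = zscore_by_factor(self._matrix(rows))
        z2 = zscore_by_factor(z1)
        np.testing.assert_allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-12)

    def test_blocks_scored_independently(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            rng.normal(size=(3, 6)),
            columns=["A@-1", "A@0", "A@1", "B@-1", "B@0", "B@1"],
        )
        m = tb.FeatureMatrix(df, np.zeros(3), ("A", "B"), 1)
        z = zscore_by_factor(m).data.to_numpy()
        for row in z:
            for block in (row[:3], row[3:]):
                assert block.mean() == pytest.approx(0.0, abs=1e-12)
                assert block.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_feature_matrix_tsv_roundtrip(tmp_path, strong_matrix):
    p = tmp_path / "m.tsv"
    strong_matrix.to_tsv(p)
    back = tb.FeatureMatrix.from_tsv(p)
    assert list(back.data.columns) == list(strong_matrix.data.columns)
    assert back.marks == strong_matrix.marks
    assert back.bin_number == strong_matrix.bin_number
    assert back.kmer_k == strong_matrix.kmer_k
    np.testing.assert_allclose(
        back.data.to_numpy(), strong_matrix.data.to_numpy(), rtol=1e-6
    )
    np.testing.assert_array_equal(back.labels, strong_matrix.labels)
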