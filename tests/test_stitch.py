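"""Mosaic assembly: flat-field inversion, offset recovery, global layout,
feathered fusion."""

import numpy as np
import pytest

from widefield3d import (
    OffsetEstimate,
    TileSet,
    Volume,
    combine_channel_offsets,
    estimate_offset,
    flatfield_correct,
    fuse,
    global_layout,
    stitch_tileset,
)
from widefield3d.phantom import make_tile_fixture, nuclei_spec
from widefield3d.stitch import _feather_weights


def _vol(data, voxel=(1.0, 0.5, 0.5)):
    return Volume(data=np.asarray(data, dtype=float), voxel_size=voxel)


class TestFlatField:
    def test_self_correction_gives_uniform_mean(self, rng):
        ref = 0.5 + rng.random((16, 16))
        tile = _vol(np.broadcast_to(ref, (4, 16, 16)).copy())
        out = flatfield_correct(tile, ref)
        assert np.allclose(out.data, ref.mean())

    def test_vignette_inverted_exactly(self, rng):
        scene = 100.0 * np.ones((4, 16, 16))
        y, x = np.mgrid[-8:8, -8:8] / 8.0
        vignette = 1.0 - 0.4 * (y**2 + x**2) / 2
        tile = _vol(scene * vignette[None])
        out = flatfield_correct(tile, vignette)
        expected = 100.0 * vignette.mean()
        assert np.allclose(out.data, expected, rtol=1e-6)

    def test_nonpositive_reference_rejected(self, rng):
        ref = rng.random((8, 8))
        ref[3, 3] = 0.0
        with pytest.raises(ValueError, match="positive"):
            flatfield_correct(_vol(np.ones((2, 8, 8))), ref)


class TestEstimateOffset:
    def test_tile_against_itself(self, rng):
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.random((12, 32, 32)), 1)
        v = _vol(data)
        est = estimate_offset(v, v, nominal_overlap=1.0, direction="right")
        assert est.shift == (0, 0, 0)
        assert est.score > 0.99

    def test_planted_shift_recovered_exactly(self, rng):
        spec = nuclei_spec(shape=(16, 48, 96), n_objects=30,
                           radius_range_um=(0.8, 1.5),
                           background="smooth_random", background_fraction=0.4,
                           noise="poisson", seed=3, margin_um=3.0)
        _, _, src = make_tile_fixture(spec, (1, 1), 0.2, 0, seed=0)
        a = _vol(src.data[2:14, 4:44, :48], voxel=(0.8, 0.34, 0.34))
        b = _vol(src.data[0:12, 7:47, 27:75], voxel=(0.8, 0.34, 0.34))
        # b's origin sits at (-2, +3, +27) relative to a's origin
        est = estimate_offset(a, b, nominal_overlap=0.4, direction="right")
        assert est.shift == (-2, 3, 27)

    def test_flat_tiles_flagged_low_confidence(self):
        a = _vol(np.full((10, 16, 32), 5.0))
        b = _vol(np.full((10, 16, 32), 5.0))
        est = estimate_offset(a, b, nominal_overlap=0.3, direction="right")
        assert est.low_confidence
        assert est.score == 0.0
        assert est.shift == (0, 0, 32 - round(0.3 * 32))

    def test_tiny_strip_rejected(self, rng):
        a = _vol(rng.random((4, 16, 16)))
        with pytest.raises(ValueError, match="8"):
            estimate_offset(a, a, nominal_overlap=0.1, direction="right")

    def test_shift_recovery_under_noise(self, rng):
        # planted integer shifts with additive Gaussian noise at SNR >= 5:
        # recovered exactly in >= 99% of randomized trials
        from scipy.ndimage import gaussian_filter

        n_trials = 100
        hits = 0
        for t in range(n_trials):
            trial_rng = np.random.default_rng(1000 + t)
            base = gaussian_filter(trial_rng.random((12, 40, 100)), (1, 2, 2))
            base = (base - base.min()) / np.ptp(base) * 100
            jitter = (int(trial_rng.integers(-2, 3)),
                      int(trial_rng.integers(-3, 4)),
                      int(trial_rng.integers(-3, 4)))
            nominal_x = 40  # tile width 48, overlap 8
            ox = nominal_x + jitter[2]
            a = base[2:10, 4:36, :48].copy()
            b = base[2 + jitter[0]:10 + jitter[0],
                     4 + jitter[1]:36 + jitter[1], ox:ox + 48].copy()
            sigma = base.std() / 5.0
            a += trial_rng.normal(0, sigma, a.shape)
            b += trial_rng.normal(0, sigma, b.shape)
            est = estimate_offset(_vol(a.clip(0)), _vol(b.clip(0)),
                                  nominal_overlap=8 / 48, direction="right")
            expected = (jitter[0], jitter[1], ox)
            hits += (est.shift == expected)
        assert hits / n_trials >= 0.99


class TestChannelConsensus:
    def test_unanimous_channels(self):
        ests = [OffsetEstimate((0, 1, 40), 0.9, c) for c in range(3)]
        assert combine_channel_offsets(ests).shift == (0, 1, 40)

    def test_score_weighting_dominates(self):
        ests = [OffsetEstimate((0, 0, 4), 0.9, 0), OffsetEstimate((0, 0, 0), 0.1, 1)]
        assert combine_channel_offsets(ests).shift == (0, 0, 4)

    def test_single_channel_passthrough(self):
        est = OffsetEstimate((1, 2, 3), 0.5, 0)
        assert combine_channel_offsets([est]) is est

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_channel_offsets([])


class TestGlobalLayout:
    def _tileset(self, rng, rows, cols, shape=(4, 16, 16)):
        tiles = [_vol(rng.random(shape)) for _ in range(rows * cols)]
        return TileSet(tiles=tiles, grid_shape=(rows, cols), overlap_fraction=0.25)

    def test_consistent_offsets_reproduce_grid(self, rng):
        ts = self._tileset(rng, 2, 2)
        offsets = {
            ((0, 0), (0, 1)): OffsetEstimate((0, 0, 12), 1.0),
            ((1, 0), (1, 1)): OffsetEstimate((0, 0, 12), 1.0),
            ((0, 0), (1, 0)): OffsetEstimate((0, 12, 0), 1.0),
            ((0, 1), (1, 1)): OffsetEstimate((0, 12, 0), 1.0),
        }
        layout = global_layout(ts, offsets)
        assert layout.positions[(1, 1)] == (0, 12, 12)
        assert layout.canvas_shape == (4, 28, 28)

    def test_cycle_inconsistency_distributed_as_least_squares(self, rng):
        # one perturbed edge in a 2x2 cycle: compare against the dense
        # normal-equation solve done independently here
        ts = self._tileset(rng, 2, 2)
        shifts = {
            ((0, 0), (0, 1)): (0, 0, 12),
            ((1, 0), (1, 1)): (0, 0, 16),  # perturbed
            ((0, 0), (1, 0)): (0, 12, 0),
            ((0, 1), (1, 1)): (0, 12, 0),
        }
        offsets = {k: OffsetEstimate(v, 1.0) for k, v in shifts.items()}
        layout = global_layout(ts, offsets)

        # oracle: positions p minimizing sum ||p_b - p_a - s||^2, p_0 = 0
        idx = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}
        a_rows, b_rows = [[1, 0, 0, 0]], [[0, 0, 0]]
        for (na, nb), s in shifts.items():
            row = [0, 0, 0, 0]
            row[idx[nb]] = 1
            row[idx[na]] = -1
            a_rows.append(row)
            b_rows.append(list(s))
        sol, *_ = np.linalg.lstsq(np.array(a_rows, float),
                                  np.array(b_rows, float), rcond=None)
        sol -= sol.min(axis=0)
        for node, i in idx.items():
            assert layout.positions[node] == tuple(np.round(sol[i]).astype(int))

    def test_strip_positions_are_cumulative_sums(self, rng):
        ts = self._tileset(rng, 1, 4)
        offsets = {
            ((0, c), (0, c + 1)): OffsetEstimate((0, 0, 10 + c), 1.0)
            for c in range(3)
        }
        layout = global_layout(ts, offsets)
        assert layout.positions[(0, 3)] == (0, 0, 10 + 11 + 12)

    def test_disconnected_graph_rejected(self, rng):
        ts = self._tileset(rng, 2, 2)
        offsets = {((0, 0), (0, 1)): OffsetEstimate((0, 0, 12), 1.0)}
        with pytest.raises(ValueError, match="connect"):
            global_layout(ts, offsets)


class TestFuse:
    def test_feather_weights_partition_of_unity(self, rng):
        ts = TileSet(tiles=[_vol(np.ones((4, 12, 12))) for _ in range(2)],
                     grid_shape=(1, 2), overlap_fraction=0.25)
        offsets = {((0, 0), (0, 1)): OffsetEstimate((0, 0, 8), 1.0)}
        layout = global_layout(ts, offsets)
        out = fuse(ts, layout)
        assert np.allclose(out.data, 1.0)  # constant tiles, no seam anywhere

    def test_single_tile_identity(self, rng):
        data = rng.random((4, 12, 12))
        ts = TileSet(tiles=[_vol(data)], grid_shape=(1, 1), overlap_fraction=0.1)
        from widefield3d.stitch import MosaicLayout

        layout = MosaicLayout(positions={(0, 0): (0, 0, 0)}, canvas_shape=(4, 12, 12))
        out = fuse(ts, layout)
        assert np.allclose(out.data, data)

    def test_weights_positive_interior(self):
        w = _feather_weights((3, 5, 5))
        assert w.min() > 0
        assert w[1, 2, 2] == w.max()


class TestEndToEnd:
    def test_three_by_three_reassembly(self):
        # phantom cut into 3x3 jittered overlapping tiles, stitched back:
        # voxelwise agreement inside the jitter margin (noiseless)
        spec = nuclei_spec(shape=(12, 120, 120), n_objects=40,
                           radius_range_um=(0.8, 1.5),
                           background="smooth_random", background_fraction=0.3,
                           noise="none", seed=6, margin_um=3.0)
        tiles, truth, source = make_tile_fixture(spec, (3, 3), 0.2, 2, seed=7)
        fused, layout, offsets = stitch_tileset(tiles)
        assert all(layout.positions[k] == truth[k] for k in truth)
        m = 3  # jitter margin: tiles pushed inward leave uncovered border
        a = fused.data[:, m:-m, m:-m]
        b = source.data[:, m:-m, m:-m]
        rms = np.sqrt(((a - b) ** 2).mean()) / np.sqrt((b ** 2).mean())
        assert rms < 0.02
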