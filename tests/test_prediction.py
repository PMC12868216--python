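import numpy as np
import pytest

from osteoseg.fitting import Checkpoint, softmax
from osteoseg.prediction import (
    ConfidenceSummary,
    ProbabilityMap,
    assign_labels,
    estimate_batch_size,
    extract_chunks,
    merge_chunks,
    plan_chunks,
    predict_volume,
)
from osteoseg.volume_io import ScanVolume


class ConstantStub:
    """Emits the same logit vector at every pixel."""

    def __init__(self, logits=(0.0, 2.0, 1.0)):
        self.logits = np.asarray(logits, dtype=np.float32)

    def forward(self, x, train=False):
        n, _, h, w = x.shape
        out = np.zeros((n, 3, h, w), dtype=np.float32)
        out += self.logits[None, :, None, None]
        return out


class PixelwiseStub:
    """Translation-invariant: logits are a fixed function of the input pixel."""

    def forward(self, x, train=False):
        v = x[:, 0]
        return np.stack([-v, v, 0.5 * v], axis=1).astype(np.float32)


def _meta(**kw):
    meta = {"architecture": "tiny_unet", "backbone": "none", "fit_mode": "2D",
            "normalization": "zscore", "patch_px": 64, "version": "t",
            "base_channels": 16}
    meta.update(kw)
    return meta


class TestPlanChunks:
    def test_single_exact_chunk(self):
        grid = plan_chunks((512, 512), 512, 0.25)
        assert grid.origins == ((0, 0),)

    def test_768_chunk_512_overlap_half(self):
        grid = plan_chunks((768, 768), 512, 0.5)
        ys = sorted({y for y, _ in grid.origins})
        assert ys == [0, 256]
        # brute-force pixel coverage
        covered = np.zeros((768, 768), dtype=int)
        for y, x in grid.origins:
            covered[y:y + 512, x:x + 512] += 1
        assert (covered >= 1).all()

    def test_small_tile_padded(self):
        grid = plan_chunks((500, 500), 512, 0.25)
        assert grid.origins == ((0, 0),)
        assert grid.padded_shape == (512, 512)

    @pytest.mark.parametrize("shape,chunk,overlap", [
        ((100, 130), 32, 0.0), ((97, 65), 32, 0.25), ((64, 64), 48, 0.5)])
    def test_full_coverage_property(self, shape, chunk, overlap):
        grid = plan_chunks(shape, chunk, overlap)
        covered = np.zeros(grid.padded_shape, dtype=int)
        for y, x in grid.origins:
            assert y + chunk <= grid.padded_shape[0]
            assert x + chunk <= grid.padded_shape[1]
            covered[y:y + chunk, x:x + chunk] += 1
        assert (covered >= 1).all()

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            plan_chunks((64, 64), 0)
        with pytest.raises(ValueError):
            plan_chunks((64, 64), 32, 1.0)


class TestMergeChunks:
    def test_constant_chunks_identity(self):
        grid = plan_chunks((48, 48), 32, 0.5)
        v = np.array([0.2, 0.5, 0.3])
        chunks = [np.broadcast_to(v[:, None, None], (3, 32, 32))] * len(grid.origins)
        out = merge_chunks(chunks, grid).finalized()
        np.testing.assert_allclose(out, v[:, None, None] * np.ones((3, 48, 48)))

    def test_hand_average_on_overlap_strip(self):
        grid = plan_chunks((4, 6), 4, 0.5)  # origins x = 0 and 2
        assert grid.origins == ((0, 0), (0, 2))
        a = np.zeros((3, 4, 4)); a[1] = 0.2; a[0] = 0.8
        b = np.zeros((3, 4, 4)); b[1] = 0.6; b[0] = 0.4
        out = merge_chunks([a, b], grid).finalized()
        np.testing.assert_allclose(out[1, :, 2:4], 0.4)  # (0.2 + 0.6) / 2
        np.testing.assert_allclose(out[1, :, :2], 0.2)
        np.testing.assert_allclose(out[1, :, 4:], 0.6)

    def test_normalization_preserved(self):
        rng = np.random.default_rng(4)
        grid = plan_chunks((40, 40), 32, 0.25)
        chunks = []
        for _ in grid.origins:
            z = rng.normal(size=(3, 32, 32))
            chunks.append(softmax(z[None], axis=1)[0])
        out = merge_chunks(chunks, grid).finalized()
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-5)

    def test_count_mismatch(self):
        grid = plan_chunks((64, 64), 32, 0.0)
        with pytest.raises(ValueError, match="chunks"):
            merge_chunks([np.zeros((3, 32, 32))], grid)


class TestAssignLabels:
    def test_low_confidence_goes_background(self):
        probs = np.array([0.2, 0.45, 0.35])[:, None, None] * np.ones((3, 2, 2))
        assert (assign_labels(probs, 0.5) == 0).all()

    def test_certain_background_stays(self):
        probs = np.array([1.0, 0.0, 0.0])[:, None, None] * np.ones((3, 2, 2))
        assert (assign_labels(probs, 0.5) == 0).all()

    def test_confident_bone(self):
        probs = np.array([0.1, 0.6, 0.3])[:, None, None] * np.ones((3, 2, 2))
        assert (assign_labels(probs, 0.5) == 1).all()

    def test_tie_breaks_to_lowest_class(self):
        probs = np.array([0.5, 0.5, 0.0])[:, None, None] * np.ones((3, 1, 1))
        assert assign_labels(probs, 0.0)[0, 0] == 0

    def test_threshold_range_checked(self):
        with pytest.raises(ValueError):
            assign_labels(np.ones((3, 1, 1)) / 3, 1.5)


class TestPredictVolume:
    def _volume(self, shape=(2, 48, 48), seed=0):
        rng = np.random.default_rng(seed)
        vox = rng.integers(0, 60000, shape).astype(np.uint16)
        return ScanVolume(scan_id="v", voxels=vox, bit_depth="u16")

    def test_constant_stub_composition(self):
        vol = self._volume()
        ckpt = Checkpoint(weights={}, metadata=_meta())
        stub = ConstantStub((0.0, 2.0, 1.0))
        mask, conf = predict_volume(ckpt, vol, chunk_px=32, threshold=0.5, model=stub)
        expected = softmax(np.array([0.0, 2.0, 1.0])[None, :, None, None], axis=1)[0]
        want = 1 if expected[1, 0, 0] >= 0.5 else 0
        assert (mask.labels == want).all()
        assert isinstance(conf, ConfidenceSummary)
        assert conf.mean_confidence == pytest.approx(float(expected.max()), abs=1e-6)

    @pytest.mark.parametrize("overlap", [0.0, 0.25, 0.5])
    def test_chunked_equals_unchunked(self, overlap):
        vol = self._volume(shape=(2, 64, 64), seed=3)
        ckpt = Checkpoint(weights={}, metadata=_meta())
        stub = PixelwiseStub()
        chunked, _ = predict_volume(ckpt, vol, chunk_px=32, threshold=0.5,
                                    overlap_fraction=overlap, model=stub)
        whole, _ = predict_volume(ckpt, vol, chunk_px=64, threshold=0.5,
                                  overlap_fraction=0.0, model=stub)
        np.testing.assert_array_equal(chunked.labels, whole.labels)

    def test_chunked_probabilities_close(self):
        # probability-level identity for a translation-invariant stub
        from osteoseg.prediction import plan_chunks as _pc
        from osteoseg.volume_io import compute_norm_stats, normalize

        vol = self._volume(shape=(1, 48, 48), seed=5)
        stats = compute_norm_stats(vol, "zscore")
        tile = normalize(vol.voxels[0], stats)
        stub = PixelwiseStub()
        direct = softmax(stub.forward(tile[None, None])[0:1], axis=1)[0]
        grid = _pc((48, 48), 32, 0.5)
        chunks = extract_chunks(tile, grid)[:, None]
        probs = softmax(stub.forward(chunks), axis=1)
        merged = merge_chunks(probs, grid).finalized()
        np.testing.assert_allclose(merged, direct, atol=1e-5)

    def test_threshold_one_all_background(self):
        vol = self._volume()
        ckpt = Checkpoint(weights={}, metadata=_meta())
        mask, _ = predict_volume(ckpt, vol, chunk_px=32, threshold=1.0,
                                 model=ConstantStub((0.0, 2.0, 1.0)))
        assert (mask.labels == 0).all()

    def test_output_shape_and_classes(self):
        vol = self._volume(shape=(3, 50, 70))
        ckpt = Checkpoint(weights={}, metadata=_meta())
        mask, _ = predict_volume(ckpt, vol, chunk_px=32, model=PixelwiseStub())
        assert mask.shape == vol.shape
        assert set(np.unique(mask.labels)) <= {0, 1, 2}

    def test_missing_metadata_refused(self):
        vol = self._volume()
        ckpt = Checkpoint(weights={}, metadata={"architecture": "tiny_unet"})
        with pytest.raises(ValueError, match="normalization"):
            predict_volume(ckpt, vol, chunk_px=32, model=ConstantStub())

    def test_estimate_batch_size_floor(self):
        assert estimate_batch_size(512, 2**22) == 16
        assert estimate_batch_size(10_000, 2**22) == 1


class TestProbabilityMap:
    def test_uncovered_pixel_rejected(self):
        pmap = ProbabilityMap(accumulator=np.zeros((3, 2, 2)),
                              count=np.array([[1.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="uncovered"):
            pmap.finalized()
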