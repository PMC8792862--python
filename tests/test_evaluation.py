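"""Overlap metrics against a set-based oracle, and the inference rule."""

import numpy as np
import pytest

from ushapegan.evaluation import (dice, evaluate_images, jaccard, predict_mask,
                                  summarize)
from ushapegan.types import Radiograph


def set_oracle(pred, truth):
    """Independent implementation on explicit pixel-coordinate sets."""
    A = {(r, c) for r, c in zip(*np.nonzero(pred))}
    B = {(r, c) for r, c in zip(*np.nonzero(truth))}
    if not A and not B:
        return 1.0, 1.0
    inter = len(A & B)
    j = inter / len(A | B) if A | B else 1.0
    d = 2 * inter / (len(A) + len(B)) if A or B else 1.0
    return j, d


class TestMetrics:
    def test_identity_and_disjoint(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[2:4, 2:4] = 1
        b = np.zeros((8, 8), dtype=np.uint8)
        b[5:7, 5:7] = 1
        assert jaccard(a, a) == 1.0 and dice(a, a) == 1.0
        assert jaccard(a, b) == 0.0 and dice(a, b) == 0.0

    def test_half_overlap_counts(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1  # 4 px
        b = np.zeros((4, 4), dtype=np.uint8)
        b[0, 2:4] = 1
        b[1, 0:2] = 1  # 4 px, overlap 2
        assert jaccard(a, b) == pytest.approx(2 / 6)
        assert dice(a, b) == pytest.approx(4 / 8)

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert jaccard(z, z) == 1.0 and dice(z, z) == 1.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            b = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            assert jaccard(a, b) == jaccard(b, a)
            assert dice(a, b) == dice(b, a)
            assert 0.0 <= jaccard(a, b) <= 1.0 <= 1.0
            assert 0.0 <= dice(a, b) <= 1.0

    def test_matches_set_oracle_and_algebraic_identity(self, rng):
        for _ in range(1000):
            a = (rng.random((16, 16)) < rng.random()).astype(np.uint8)
            b = (rng.random((16, 16)) < rng.random()).astype(np.uint8)
            j, d = jaccard(a, b), dice(a, b)
            oj, od = set_oracle(a, b)
            assert j == pytest.approx(oj, abs=1e-12)
            assert d == pytest.approx(od, abs=1e-12)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), dtype=np.uint8), np.zeros((5, 5), dtype=np.uint8))


class _StubDiscriminator:
    """Fixed probability map, for exercising the inference rule."""

    def __init__(self, probs):
        self.probs = probs

    def __call__(self, x, train=True):
        return self.probs[None]


class TestPredictMask:
    def test_lung_probability_one_gives_all_ones(self):
        probs = np.zeros((3, 4, 4))
        probs[0] = 1.0
        mask = predict_mask(_StubDiscriminator(probs), np.zeros((4, 4)))
        np.testing.assert_array_equal(mask, 1)

    def test_fake_channel_is_ignored(self):
        # (lung 0.4, background 0.1, fake 0.5) -> lung
        probs = np.zeros((3, 1, 1))
        probs[:, 0, 0] = [0.4, 0.1, 0.5]
        mask = predict_mask(_StubDiscriminator(probs), np.zeros((1, 1)))
        assert mask[0, 0] == 1

    def test_tie_goes_to_background(self):
        probs = np.zeros((3, 1, 1))
        probs[:, 0, 0] = [0.3, 0.3, 0.4]
        mask = predict_mask(_StubDiscriminator(probs), np.zeros((1, 1)))
        assert mask[0, 0] == 0


class TestReports:
    def _stub(self, truth):
        probs = np.zeros((3,) + truth.shape)
        probs[0][truth == 1] = 1.0
        probs[1][truth == 0] = 1.0
        return _StubDiscriminator(probs)

    def test_perfect_predictions(self, tiny_phantoms):
        p = tiny_phantoms[0]
        df = evaluate_images(self._stub(p.mask), [p])
        s = summarize(df)
        assert s["dice_mean"] == 1.0 and s["jaccard_mean"] == 1.0
        assert s["dice_sd"] == 0.0  # singleton: sd reported as 0

    def test_rowwise_dice_jaccard_identity(self, tiny_phantoms):
        p = tiny_phantoms[0]
        q = tiny_phantoms[1]
        df = evaluate_images(self._stub(p.mask), [p, q])
        for _, row in df.iterrows():
            assert row["dice"] == pytest.approx(
                2 * row["jaccard"] / (1 + row["jaccard"]), abs=1e-9)

    def test_missing_mask_listed_not_silent(self, tiny_phantoms):
        p = tiny_phantoms[0]
        bare = Radiograph("nomask", p.pixels)
        df = evaluate_images(self._stub(p.mask), [p, bare])
        assert len(df) == 2
        assert df.loc[df.image_id == "nomask", "note"].item() != ""
        assert np.isnan(df.loc[df.image_id == "nomask", "dice"].item())
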