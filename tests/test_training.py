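"""Training loop invariants: learning, schedule, determinism, resume,
and the algebra between modes.  All runs are tiny (32px, a few epochs)."""

import numpy as np
import pandas as pd
import pytest

from ushapegan import UShapedGAN
from ushapegan import io as uio
from ushapegan.training import TrainConfig, train
from ushapegan.types import DatasetManifest, ManifestEntry

FAST = dict(resolution=32, batch_size=8, lr_discriminator=1e-3,
            lr_generator=1e-3, encoder_channels=(8, 16, 24, 32),
            decoder_channels=(32, 24, 16, 8))


def semi_labels(Y, n_labeled):
    out = -np.ones_like(Y)
    out[:n_labeled] = Y[:n_labeled]
    return out


class TestFit:
    def test_supervised_loss_decreases(self, tiny_arrays):
        X, Y = tiny_arrays
        est = UShapedGAN(mode="supervised", epochs=3, random_state=0, **FAST)
        est.fit(X[:10], Y[:10])
        hist = est.loss_history_
        assert hist.L_l.iloc[-1] < hist.L_l.iloc[0]
        assert (hist.L_u == 0).all() and (hist.L_g == 0).all()

    def test_learning_rate_decays_by_factor(self, tiny_arrays):
        X, Y = tiny_arrays
        est = UShapedGAN(mode="supervised", epochs=4, lr_decay_epoch=2,
                         random_state=0, **FAST)
        est.fit(X[:8], Y[:8])
        lrs = est.loss_history_.lr_discriminator.to_numpy()
        assert lrs[1] == pytest.approx(FAST["lr_discriminator"])
        assert lrs[2] == pytest.approx(0.1 * FAST["lr_discriminator"])

    def test_semisup_trajectory_is_deterministic(self, tiny_arrays):
        X, Y = tiny_arrays
        runs = []
        for _ in range(2):
            est = UShapedGAN(mode="semi_supervised", epochs=2, random_state=5,
                             **FAST)
            est.fit(X, semi_labels(Y, 6))
            runs.append(est.loss_history_)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_semisup_without_unlabeled_or_generator_equals_supervised(self, tiny_arrays):
        """Mode algebra: semi-supervised with zero unannotated data and the
        generator off reduces exactly to supervised training."""
        X, Y = tiny_arrays
        a = UShapedGAN(mode="supervised", epochs=2, random_state=3, **FAST)
        a.fit(X[:10], Y[:10])
        b = UShapedGAN(mode="semi_supervised", generator_enabled=False,
                       epochs=2, random_state=3, **FAST)
        b.fit(X[:10], Y[:10])
        pd.testing.assert_frame_equal(
            a.loss_history_.drop(columns="lr_generator"),
            b.loss_history_.drop(columns="lr_generator"))

    def test_losses_are_finite_and_bundle_consistent(self, tiny_arrays):
        X, Y = tiny_arrays
        est = UShapedGAN(mode="semi_supervised", epochs=2, random_state=1, **FAST)
        est.fit(X, semi_labels(Y, 6))
        h = est.loss_history_
        assert np.isfinite(h[["L_l", "L_u", "L_g", "L_D", "L_G"]].to_numpy()).all()
        np.testing.assert_allclose(h.L_D, h.L_l + h.L_u + h.L_g, rtol=1e-9)

    def test_original_gan_mode_trains(self, tiny_arrays):
        X, Y = tiny_arrays
        est = UShapedGAN(mode="original_gan", epochs=2, random_state=0, **FAST)
        est.fit(X, semi_labels(Y, 6))
        assert est.discriminator_.spec.n_classes == 2
        assert est.predict(X[:2]).shape == (2, 32, 32)
        assert np.isfinite(est.loss_history_.L_D.to_numpy()).all()

    def test_requires_annotated_images(self, tiny_arrays):
        X, Y = tiny_arrays
        est = UShapedGAN(mode="semi_supervised", epochs=1, random_state=0, **FAST)
        with pytest.raises(ValueError, match="annotated"):
            est.fit(X, semi_labels(Y, 0))

    def test_partial_annotation_rejected(self, tiny_arrays):
        X, Y = tiny_arrays
        bad = semi_labels(Y, 4)
        bad[6, 0, 0] = 1  # one labeled pixel inside an unannotated plane
        est = UShapedGAN(epochs=1, random_state=0, **FAST)
        with pytest.raises(ValueError, match="fully"):
            est.fit(X, bad)

    def test_sklearn_param_interface(self):
        est = UShapedGAN(epochs=7)
        assert est.get_params()["epochs"] == 7
        est.set_params(epochs=3, mode="uda")
        assert est.epochs == 3 and est.mode == "uda"


class TestCheckpointResume:
    def test_resume_reproduces_uninterrupted_trajectory(self, tiny_arrays, tmp_path):
        X, Y = tiny_arrays
        y = semi_labels(Y, 6)
        full = UShapedGAN(mode="semi_supervised", epochs=4, random_state=2, **FAST)
        full.fit(X, y)

        part = UShapedGAN(mode="semi_supervised", epochs=4, random_state=2,
                          checkpoint_every=2, checkpoint_dir=str(tmp_path), **FAST)
        part.fit(X, y)
        ckpt = tmp_path / "checkpoint_epoch0002.npz"
        assert ckpt.exists()
        resumed = UShapedGAN.load_checkpoint(ckpt)
        resumed.fit(X, y)
        pd.testing.assert_frame_equal(resumed.loss_history_, full.loss_history_)
        np.testing.assert_array_equal(resumed.predict(X[:4]), full.predict(X[:4]))


class TestManifestTraining:
    @pytest.fixture()
    def phantom_dir(self, tmp_path, tiny_phantoms):
        from ushapegan import io as _io
        entries = []
        for p in tiny_phantoms:
            img = tmp_path / f"{p.image_id}.png"
            msk = tmp_path / f"{p.image_id}_mask.png"
            _io.save_image(img, p.pixels)
            _io.save_mask(msk, p.mask)
            entries.append(ManifestEntry(image=str(img), mask=str(msk),
                                         pool="annotated"))
        return DatasetManifest(entries, resolution=32, seed=0)

    def test_train_writes_losses_and_checkpoint(self, phantom_dir, tmp_path):
        man = uio.make_semisup_splits(phantom_dir, 0.5, 2, seed=0)
        cfg = TrainConfig(mode="semi_supervised", epochs=2, seed=0,
                          resolution=32, batch_size=8)
        out = tmp_path / "run"
        state = train(cfg, man, out_dir=out)
        assert (out / "losses.csv").exists() and (out / "final.npz").exists()
        df = pd.read_csv(out / "losses.csv")
        assert list(df.epoch) == [1, 2]
        assert state.epoch == 2

    def test_uda_pools_respect_splits(self, phantom_dir):
        man = uio.make_uda_splits(phantom_dir, phantom_dir, seed=0)
        from ushapegan.training import load_pools
        X, y = load_pools(man, "uda")
        n_src_train = sum(1 for e in man.entries
                          if e.pool == "source" and e.split == "train")
        n_tgt_train = sum(1 for e in man.entries
                          if e.pool == "target" and e.split == "train")
        assert len(X) == n_src_train + n_tgt_train
        assert (y[n_src_train:] == -1).all()
        assert (y[:n_src_train] >= 0).all()

    def test_supervised_mode_requires_annotated_pool(self, phantom_dir):
        man = DatasetManifest(
            [ManifestEntry(image=e.image, mask=None, pool="unannotated")
             for e in phantom_dir.entries], resolution=32)
        from ushapegan.training import load_pools
        with pytest.raises(ValueError):
            load_pools(man, "supervised")
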