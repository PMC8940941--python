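"""cGAN engine: builders, objective closed forms, gradients, training."""

import numpy as np
import pytest
from scipy import ndimage

from fiberdl.gan import (
    GanConfig,
    TrainingPair,
    build_discriminator,
    build_generator,
    gan_objective,
    infer,
    load_bundle,
    save_bundle,
    to_unit,
    train,
)


def _param_checksum(net) -> bytes:
    import hashlib

    h = hashlib.sha256()
    for p in net.params():
        h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
    return h.digest()


def _smooth_images(rng, n, size):
    out = []
    for _ in range(n):
        img = ndimage.gaussian_filter(rng.uniform(0, 255, (size, size)), 3)
        img = (img - img.min()) / (np.ptp(img) + 1e-9) * 255
        out.append(img)
    return out


TINY = GanConfig(
    image_size=32, gen_depth=3, base_channels=8, patch_scale=16,
    epochs=3, batch_size=4, seed=0, dtype="float32",
)


class TestBuilders:
    def test_generator_preserves_shape(self):
        cfg = GanConfig(image_size=128, gen_depth=3, base_channels=8, patch_scale=70)
        G = build_generator(cfg)
        out = G.forward(np.zeros((1, 1, 128, 128), dtype=np.float32), train=False)
        assert out.shape == (1, 1, 128, 128)

    def test_same_seed_identical_parameters(self):
        assert _param_checksum(build_generator(TINY)) == _param_checksum(
            build_generator(TINY)
        )
        assert _param_checksum(build_discriminator(TINY)) == _param_checksum(
            build_discriminator(TINY)
        )

    def test_untrained_output_bounded_to_unit_range(self, rng):
        G = build_generator(TINY)
        for _ in range(100):
            x = rng.uniform(-1, 1, (1, 1, 32, 32)).astype(np.float32)
            out = G.forward(x, train=False)
            assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_discriminator_outputs_probabilities(self, rng):
        D = build_discriminator(TINY)
        cand = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        cond = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        p = D(cand, cond, train=False)
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_patch_field_shrinks_with_patch_scale(self, rng):
        # larger receptive field per output unit -> coarser probability field
        sizes = []
        for ps in (16, 34, 70):
            cfg = GanConfig(image_size=128, gen_depth=3, base_channels=4, patch_scale=ps)
            D = build_discriminator(cfg)
            x = rng.uniform(-1, 1, (1, 1, 128, 128)).astype(np.float32)
            sizes.append(D(x, x, train=False).shape[-1])
        assert sizes[0] > sizes[1] > sizes[2]

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            GanConfig(image_size=100, gen_depth=3)

    def test_patch_scale_exceeding_image_rejected(self):
        with pytest.raises(ValueError, match="patch_scale"):
            GanConfig(image_size=32, gen_depth=2, patch_scale=64)


class _ConstantD:
    """Stub discriminator emitting a constant probability field."""

    def __init__(self, p):
        self.p = p

    def __call__(self, candidate, condition=None, train=True):
        return np.full((candidate.shape[0], 1, 4, 4), self.p)


class TestObjective:
    def test_coin_flip_discriminator_closed_form(self, rng):
        x = rng.uniform(-1, 1, (2, 1, 16, 16))
        losses = gan_objective(x.copy(), x, x, _ConstantD(0.5), l1_weight=100.0)
        assert losses["d_loss"] == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_perfect_generator_zero_l1(self, rng):
        x = rng.uniform(-1, 1, (2, 1, 16, 16))
        losses = gan_objective(x.copy(), x, x, _ConstantD(0.3), l1_weight=100.0)
        assert losses["l1"] == 0.0
        assert losses["g_loss"] == pytest.approx(losses["g_adv"])

    def test_initial_discriminator_near_equilibrium(self, rng):
        # untrained D on balanced real/fake batches sits near log 4
        cfg = GanConfig(image_size=32, gen_depth=2, base_channels=8, patch_scale=16,
                        seed=3, dtype="float64")
        G, D = build_generator(cfg), build_discriminator(cfg)
        y = rng.uniform(-1, 1, (4, 1, 32, 32))
        x = rng.uniform(-1, 1, (4, 1, 32, 32))
        fake = G.forward(y, train=False)
        losses = gan_objective(fake, x, y, D, l1_weight=100.0)
        assert 1.0 <= losses["d_loss"] <= 1.8

    def test_combined_loss_gradient_matches_finite_differences(self, rng):
        # numerical-gradient oracle on a 16x16 toy, float64
        cfg = GanConfig(image_size=16, gen_depth=2, base_channels=4, patch_scale=16,
                        seed=0, dtype="float64", dropout_p=0.0)
        G, D = build_generator(cfg), build_discriminator(cfg)
        y = rng.uniform(-1, 1, (2, 1, 16, 16))
        x = rng.uniform(-1, 1, (2, 1, 16, 16))
        lam = 100.0
        eps = 1e-7

        def loss():
            fake = G.forward(y, train=True)
            p = D(fake, y, train=True)
            adv = -np.log(np.clip(p, eps, 1 - eps)).mean()
            return adv + lam * np.abs(fake - x).mean()

        for p in G.params() + D.params():
            p.zero_grad()
        fake = G.forward(y, train=True)
        prob = D(fake, y, train=True)
        grad_fake = D.backward(-1.0 / (np.clip(prob, eps, 1 - eps) * prob.size))
        G.backward(grad_fake + lam * np.sign(fake - x) / fake.size)

        checked = 0
        for prm in (G.params()[0], G.params()[4]):
            idx = np.unravel_index(np.argmax(np.abs(prm.grad)), prm.grad.shape)
            analytic = prm.grad[idx]
            h = 1e-6
            orig = prm.data[idx]
            prm.data[idx] = orig + h
            lp = loss()
            prm.data[idx] = orig - h
            lm = loss()
            prm.data[idx] = orig
            numeric = (lp - lm) / (2 * h)
            assert analytic == pytest.approx(numeric, rel=1e-4)
            checked += 1
        assert checked == 2


class TestTraining:
    def test_history_one_record_per_epoch(self, rng):
        imgs = _smooth_images(rng, 6, 32)
        pairs = [TrainingPair(x=i, y=i) for i in imgs]
        _, hist = train(pairs, TINY)
        assert len(hist) == 3
        assert [r["epoch"] for r in hist.records] == [0, 1, 2]

    def test_same_seed_identical_history_and_model(self, rng):
        imgs = _smooth_images(rng, 6, 32)
        pairs = [TrainingPair(x=i, y=i) for i in imgs]
        b1, h1 = train(pairs, TINY)
        b2, h2 = train(pairs, TINY)
        assert h1.records == h2.records
        assert b1.param_checksum() == b2.param_checksum()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train([], TINY)

    def test_geometry_mismatch_rejected(self, rng):
        pairs = [TrainingPair(x=np.zeros((16, 16)), y=np.zeros((16, 16)))]
        with pytest.raises(ValueError, match="image_size"):
            train(pairs, TINY)

    def test_converges_on_identity_task(self, rng):
        # noise-free y = x at 32x32: 30 epochs must cut validation L1 to
        # under 20% of its epoch-1 value
        imgs = _smooth_images(rng, 16, 32)
        pairs = [TrainingPair(x=i, y=i) for i in imgs]
        cfg = GanConfig(image_size=32, gen_depth=3, base_channels=16, patch_scale=16,
                        epochs=30, batch_size=4, seed=0, dtype="float32")
        _, hist = train(pairs, cfg)
        df = hist.to_frame()
        assert df["val_l1"].iloc[-1] < 0.2 * df["val_l1"].iloc[0]

    def test_l1_dominant_regime_at_least_as_accurate(self, rng):
        # lambda -> large approaches plain L1 regression, which on the
        # identity task cannot be worse than the default mixed objective
        imgs = _smooth_images(rng, 12, 32)
        pairs = [TrainingPair(x=i, y=i) for i in imgs]
        base = dict(image_size=32, gen_depth=3, base_channels=8, patch_scale=16,
                    epochs=15, batch_size=4, seed=0, dtype="float32")
        _, h_default = train(pairs, GanConfig(l1_weight=100.0, **base))
        _, h_l1 = train(pairs, GanConfig(l1_weight=1e5, **base))
        assert (
            h_l1.to_frame()["val_l1"].iloc[-1]
            <= h_default.to_frame()["val_l1"].iloc[-1]
        )


@pytest.fixture(scope="module")
def bundle():
    rng = np.random.default_rng(7)
    imgs = _smooth_images(rng, 6, 32)
    pairs = [TrainingPair(x=i, y=i) for i in imgs]
    bundle, _ = train(pairs, TINY)
    return bundle


class TestInference:
    def test_shape_and_dtype_follow_input(self, bundle, rng):
        frame8 = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        out = infer(bundle, frame8)
        assert out.shape == frame8.shape and out.dtype == np.uint8
        framef = frame8.astype(np.float64)
        outf = infer(bundle, framef)
        assert outf.dtype == np.float64
        assert outf.min() >= 0 and outf.max() <= 255

    def test_deterministic_inference(self, bundle, rng):
        frame = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        a, b = infer(bundle, frame), infer(bundle, frame)
        assert np.array_equal(a, b)

    def test_geometry_mismatch_rejected(self, bundle):
        with pytest.raises(ValueError, match="image_size"):
            infer(bundle, np.zeros((64, 64)))

    def test_checkpoint_round_trip(self, bundle, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        assert loaded.param_checksum() == bundle.param_checksum()
        frame = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        assert np.array_equal(infer(loaded, frame), infer(bundle, frame))

    def test_missing_checkpoint_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="checkpoint"):
            load_bundle(tmp_path / "absent.npz")


def test_unit_range_round_trip(rng):
    img = rng.integers(0, 256, (16, 16)).astype(np.float64)
    from fiberdl.gan import from_unit

    assert np.allclose(from_unit(to_unit(img)), img)
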