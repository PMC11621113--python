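"""Unit tests for the FAL-CNN architecture: construction, gating, encoder,
decoder, multi-pass forward and the feature embedding store."""

import math

import numpy as np
import pytest
from scipy import signal

import falcnn as f
from falcnn import autodiff as ad


def _rand_images(rng, spec, batch=2):
    return rng.standard_normal(
        (batch, 3, spec.input_size, spec.input_size)).astype(np.float32)


# ----------------------------------------------------------- construction

def test_build_is_deterministic_and_finite(mini_spec):
    m1 = f.build_model(mini_spec, seed=42)
    m2 = f.build_model(mini_spec, seed=42)
    assert m1.n_parameters() == m2.n_parameters() > 0
    for (n1, p1), (n2, p2) in zip(sorted(m1.named_params().items()),
                                  sorted(m2.named_params().items())):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)
        assert np.all(np.isfinite(p1.data))


def test_vgg19_fam_sites_at_canonical_indices():
    assert f.fam_site_indices(f.ModelSpec.vgg19()) == [0, 5, 10, 19, 28]


@pytest.mark.parametrize("kwargs,field", [
    (dict(input_size=63), "input_size"),
    (dict(n_iterations=-1), "n_iterations"),
    (dict(fc_width=0), "fc_width"),
    (dict(n_classes=1), "n_classes"),
])
def test_invalid_spec_names_offending_field(kwargs, field):
    base = dict(scale_groups=(f.ScaleGroup(1, 8), f.ScaleGroup(1, 16),
                              f.ScaleGroup(1, 32)),
                fc_width=32, n_classes=3, n_iterations=1, input_size=64)
    base.update(kwargs)
    with pytest.raises(f.ConfigurationError, match=field):
        f.ModelSpec(**base)


def test_single_scale_group_rejected():
    with pytest.raises(f.ConfigurationError, match="scale_groups"):
        f.ModelSpec(scale_groups=(f.ScaleGroup(1, 8),), fc_width=8,
                    n_classes=2, n_iterations=0, input_size=32)


# ------------------------------------------------------------------- gate

def test_gate_is_elementwise_sigmoid(rng):
    assert f.gate(np.array(0.0)) == pytest.approx(0.5)
    assert f.gate(np.array(20.0)) == pytest.approx(1.0, abs=1e-8)
    assert f.gate(np.array(-20.0)) == pytest.approx(0.0, abs=1e-8)
    x = rng.standard_normal((4, 3)) * 3
    got = f.gate(x)
    for i in range(4):
        for j in range(3):
            assert got[i, j] == pytest.approx(1.0 / (1.0 + math.exp(-x[i, j])),
                                              rel=1e-5)
    assert np.all(got > 0) and np.all(got < 1)


# -------------------------------------------------------------------- FAM

def test_fam_apply_multiplies_elementwise(rng):
    feats = f.LevelActivation(0, np.full((1, 2, 2, 2), 3.0, np.float32))
    out = f.fam_apply(feats, np.full((1, 2, 2, 2), 0.5, np.float32))
    np.testing.assert_allclose(out.features, 1.5)

    ident = f.fam_apply(feats, np.ones((1, 2, 2, 2), np.float32))
    np.testing.assert_array_equal(ident.features, feats.features)
    none_case = f.fam_apply(feats, None)
    np.testing.assert_array_equal(none_case.features, feats.features)

    x = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    g = rng.uniform(0, 1, (1, 3, 4, 4)).astype(np.float32)
    got = f.fam_apply(f.LevelActivation(1, x), g).features
    for idx in np.ndindex(x.shape):
        assert got[idx] == pytest.approx(x[idx] * g[idx], rel=1e-6)

    with pytest.raises(ValueError, match="shape"):
        f.fam_apply(feats, np.ones((1, 2, 3, 2), np.float32))


# ---------------------------------------------------------------- encoder

def test_encoder_pass_shapes_and_determinism(mini_model, mini_spec, rng):
    x = _rand_images(rng, mini_spec)
    emb1, levels = f.encoder_pass(mini_model, x)
    emb2, _ = f.encoder_pass(mini_model, x)
    np.testing.assert_array_equal(emb1, emb2)
    assert emb1.shape == (2, mini_spec.fc_width)
    assert len(levels) == 3
    for lvl, la in enumerate(levels):
        s = mini_spec.input_size >> lvl
        assert la.features.shape == (2, mini_spec.scale_groups[lvl].channels, s, s)
    with pytest.raises(ValueError, match="expected images"):
        f.encoder_pass(mini_model, x[:, :, :16, :16])


def test_saturated_feedback_equals_no_feedback(mini_model, mini_spec, rng):
    x = _rand_images(rng, mini_spec)
    emb0, _ = f.encoder_pass(mini_model, x)
    sat = f.FeedbackStack(iteration=1, logits=[
        np.full((2, mini_spec.fam_in_channels(l),
                 mini_spec.input_size >> l, mini_spec.input_size >> l),
                20.0, np.float32)
        for l in range(3)])
    emb_sat, _ = f.encoder_pass(mini_model, x, sat)
    np.testing.assert_allclose(emb_sat, emb0, atol=1e-4)


# ---------------------------------------------------------------- decoder

def test_decoder_pass_shapes_match_fam_sites(mini_model, mini_spec, rng):
    x = _rand_images(rng, mini_spec)
    _, levels = f.encoder_pass(mini_model, x)
    stack = f.decoder_pass(mini_model, levels)
    assert len(stack.logits) == 3
    for lvl, logits in enumerate(stack.logits):
        s = mini_spec.input_size >> lvl
        assert logits.shape == (2, mini_spec.fam_in_channels(lvl), s, s)
    stack2 = f.decoder_pass(mini_model, levels)
    for a, b in zip(stack.logits, stack2.logits):
        np.testing.assert_array_equal(a, b)


def test_decoder_handles_degenerate_and_missing_levels(mini_model, mini_spec):
    zero_levels = [f.LevelActivation(l, np.zeros(
        (1, mini_spec.scale_groups[l].channels,
         mini_spec.input_size >> l, mini_spec.input_size >> l), np.float32))
        for l in range(3)]
    stack = f.decoder_pass(mini_model, zero_levels)
    for logits in stack.logits:
        assert np.all(np.isfinite(logits))
    with pytest.raises(ValueError, match="level"):
        f.decoder_pass(mini_model, zero_levels[:2])


# ---------------------------------------------------------------- forward

@pytest.mark.parametrize("n_iter", [0, 1, 2, 3, 4])
def test_fes_shape_per_iteration_count(n_iter, rng):
    spec = f.ModelSpec.mini(n_classes=3, n_iterations=n_iter, input_size=32)
    model = f.build_model(spec, seed=0)
    x = _rand_images(rng, spec, batch=2)
    out = f.forward(model, x)
    assert out.embeddings.embeddings.shape == (2, spec.fc_width, n_iter + 1)
    assert len(out.attention) == n_iter
    np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(out.predicted_class, out.probs.argmax(axis=1))


def test_zero_iterations_never_runs_decoder(rng):
    spec = f.ModelSpec.mini(n_classes=3, n_iterations=0, input_size=32)
    model = f.build_model(spec, seed=0)
    out = f.forward(model, _rand_images(rng, spec))
    assert model.decoder_calls == 0
    assert out.attention == []


def test_forward_rejects_excess_iterations(mini_model, mini_spec, rng):
    with pytest.raises(ValueError, match="n_iterations"):
        f.forward(mini_model, _rand_images(rng, mini_spec), n_iterations=5)


@pytest.mark.parametrize("image_fill", [0.0, 1.0, 1e4, -1e4])
def test_forward_stable_on_degenerate_images(mini_model, mini_spec, image_fill):
    x = np.full((1, 3, 32, 32), image_fill, np.float32)
    out = f.forward(mini_model, x)
    assert np.all(np.isfinite(out.probs))
    np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)


def test_forward_bitwise_reproducible(mini_model, mini_spec, rng):
    x = _rand_images(rng, mini_spec)
    out1 = f.forward(mini_model, x)
    out2 = f.forward(mini_model, x)
    np.testing.assert_array_equal(out1.probs, out2.probs)
    np.testing.assert_array_equal(out1.embeddings.embeddings,
                                  out2.embeddings.embeddings)


def test_saturated_gates_make_iterations_agree(rng):
    """Forcing the decoder logit heads to large outputs makes every gate ~1,
    so all FES slots must hold (numerically) the same embedding."""
    spec = f.ModelSpec.mini(n_classes=3, n_iterations=2, input_size=32)
    model = f.build_model(spec, seed=0)
    for head in model.dec_head:
        head.w.data[:] = 0.0
        head.b.data[:] = 25.0
    out = f.forward(model, _rand_images(rng, spec))
    fes = out.embeddings.embeddings
    for k in range(1, fes.shape[2]):
        np.testing.assert_allclose(fes[:, :, k], fes[:, :, 0], atol=1e-4)


def test_doubling_input_size_doubles_level_dims(rng):
    for size in (32, 64):
        spec = f.ModelSpec.mini(n_classes=3, n_iterations=0, input_size=size)
        model = f.build_model(spec, seed=0)
        _, levels = f.encoder_pass(model, _rand_images(rng, spec, batch=1))
        for lvl, la in enumerate(levels):
            assert la.features.shape[2] == size >> lvl


# ---------------------------------------------------------- gradient flow

def _training_step_grads(n_iterations, rng):
    spec = f.ModelSpec.mini(n_classes=3, n_iterations=n_iterations,
                            input_size=32)
    model = f.build_model(spec, seed=0)
    x = ad.Tensor(_rand_images(rng, spec, batch=4))
    out = model._forward_graph(x, n_iterations)
    loss = ad.cross_entropy(out["logits"], np.array([0, 1, 2, 0]))
    loss.backward()
    return model


def test_gradient_reaches_decoder_only_with_feedback(rng):
    with_fb = _training_step_grads(1, rng)
    norms = [np.linalg.norm(p.grad) for p in with_fb.decoder_params()
             if p.grad is not None]
    assert norms and all(n > 0 for n in norms)
    assert all(p.grad is not None for p in with_fb.decoder_params())

    without = _training_step_grads(0, rng)
    assert all(p.grad is None for p in without.decoder_params())
    assert without.fc1.w.grad is not None  # encoder still learns


# ------------------------------------------------- numerical cross-checks

def test_conv2d_matches_scipy_correlate(rng):
    """The im2col convolution agrees with scipy's 2-D correlation."""
    x = rng.standard_normal((1, 2, 6, 6)).astype(np.float32)
    w = rng.standard_normal((3, 2, 3, 3)).astype(np.float32)
    b = rng.standard_normal(3).astype(np.float32)
    out = ad.conv2d(ad.Tensor(x), ad.Tensor(w), ad.Tensor(b)).data
    for co in range(3):
        expect = b[co] + sum(
            signal.correlate2d(x[0, ci], w[co, ci], mode="same")
            for ci in range(2))
        np.testing.assert_allclose(out[0, co], expect, atol=1e-4)


def test_upsample_backward_is_exact_adjoint(rng):
    """<A x, y> == <x, A^T y> for the bilinear upsampling operator."""
    x = ad.Tensor(rng.standard_normal((1, 1, 5, 5)).astype(np.float32),
                  requires_grad=True)
    y = rng.standard_normal((1, 1, 10, 10)).astype(np.float32)
    up = ad.upsample2x(x)
    lhs = float((up.data * y).sum())
    # backward of sum(up * y) w.r.t. x gives A^T y
    loss = ad.mul(up, ad.Tensor(y))
    loss.backward()
    rhs = float((x.data * x.grad).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)


# ------------------------------------------------------------ persistence

def test_checkpoint_roundtrip(tmp_path, mini_spec, rng):
    model = f.build_model(mini_spec, seed=3)
    x = _rand_images(rng, mini_spec)
    path = str(tmp_path / "model.npz")
    model.norm_mean = np.array([1.0, 2.0, 3.0], np.float32)
    model.norm_std = np.array([4.0, 5.0, 6.0], np.float32)
    f.save_checkpoint(model, path)
    loaded = f.load_checkpoint(path)
    assert loaded.spec == mini_spec
    np.testing.assert_array_equal(loaded.norm_mean, model.norm_mean)
    np.testing.assert_array_equal(f.forward(loaded, x).probs,
                                  f.forward(model, x).probs)


def test_encoder_weight_loading_hook(mini_spec):
    model = f.build_model(mini_spec, seed=4)
    w = np.ones_like(model.enc_groups[0][0].w.data)
    f.load_encoder_weights(model, {"enc.g0.c0.w": w})
    np.testing.assert_array_equal(model.enc_groups[0][0].w.data, w)
    with pytest.raises(KeyError):
        f.load_encoder_weights(model, {"fc1.w": w})
    with pytest.raises(ValueError, match="shape"):
        f.load_encoder_weights(model, {"enc.g0.c0.w": np.ones((2, 2))})
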