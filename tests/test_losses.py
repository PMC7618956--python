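"""Loss terms against closed forms and independent looped oracles."""

import numpy as np
import pytest

from voxelrep.autodiff import Tensor
from voxelrep.losses import (LossConfig, batch_loss, kl_loss,
                             multi_similarity_loss, reconstruction_loss,
                             similarity_tensor)

from oracles import (kl_loss_loops, multi_similarity_loops,
                     recon_loss_loops, similarity_tensor_loops)


def random_batch(rng, b=3, r=2, d_ms=3):
    emb = rng.standard_normal((b, r, d_ms))
    x = rng.random((b, r, 16, 16, 16))
    mu_x = rng.random((b, r, 16, 16, 16))
    sizes = rng.uniform(4, 12, size=(b, r))
    mu = rng.standard_normal((b, r, 5))
    sigma = rng.uniform(0.2, 2.0, size=(b, r, 5))
    return emb, x, mu_x, sizes, mu, sigma


def test_reconstruction_loss_matches_looped_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        b = int(rng.integers(1, 5))
        r = int(rng.integers(1, 4))
        _, x, mu_x, sizes, _, _ = random_batch(rng, b, r)
        got = reconstruction_loss(x, mu_x, sizes).item()
        want = recon_loss_loops(x, mu_x, sizes)
        assert got == pytest.approx(want, rel=1e-9)


def test_reconstruction_closed_form_single_patch():
    # b=1, a=2, constant residual c: loss = 16^3 c^2 / 8
    c = 0.25
    x = np.zeros((1, 1, 16, 16, 16))
    mu_x = np.full_like(x, c)
    got = reconstruction_loss(x, mu_x, size=2.0).item()
    assert got == pytest.approx(16**3 * c**2 / 8, rel=1e-12)


def test_reconstruction_perfect_and_duplication_invariance():
    rng = np.random.default_rng(1)
    _, x, mu_x, sizes, _, _ = random_batch(rng, 2, 2)
    assert reconstruction_loss(x, x, sizes).item() == 0.0
    single = reconstruction_loss(x, mu_x, sizes).item()
    doubled = reconstruction_loss(np.concatenate([x, x]),
                                  np.concatenate([mu_x, mu_x]),
                                  np.concatenate([sizes, sizes])).item()
    assert doubled == pytest.approx(single, rel=1e-9)


def test_reconstruction_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        reconstruction_loss(np.zeros((1, 1, 16, 16, 16)),
                            np.zeros((2, 1, 16, 16, 16)), size=8.0)


def test_kl_matches_looped_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        b = int(rng.integers(1, 5))
        r = int(rng.integers(1, 4))
        _, _, _, _, mu, sigma = random_batch(rng, b, r)
        got = kl_loss(mu, sigma).item()
        assert got == pytest.approx(kl_loss_loops(mu, sigma, b), rel=1e-9)


def test_kl_closed_forms():
    assert kl_loss(np.zeros((1, 1, 4)), np.ones((1, 1, 4))).item() == 0.0
    # b = d = 1, single replicate, mu=1, sigma=1 -> 1/2
    assert kl_loss(np.array([[[1.0]]]), np.array([[[1.0]]])).item() == \
        pytest.approx(0.5, abs=1e-12)


def test_kl_nonnegative_and_duplication_invariant():
    rng = np.random.default_rng(3)
    _, _, _, _, mu, sigma = random_batch(rng, 3, 2)
    single = kl_loss(mu, sigma).item()
    assert single >= 0.0
    doubled = kl_loss(np.concatenate([mu, mu]),
                      np.concatenate([sigma, sigma])).item()
    assert doubled == pytest.approx(single, rel=1e-12)


def test_kl_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        kl_loss(np.zeros((1, 1, 2)), np.array([[[1.0, 0.0]]]))


def test_similarity_tensor_matches_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(20):
        emb = rng.standard_normal((int(rng.integers(2, 5)),
                                   int(rng.integers(1, 4)),
                                   int(rng.integers(1, 5))))
        got = similarity_tensor(emb).data
        assert np.allclose(got, similarity_tensor_loops(emb), atol=1e-6)


def test_similarity_extremes_and_zero_vector():
    emb = np.array([[[1.0, 0.0]], [[0.0, 2.0]], [[-3.0, 0.0]], [[0.0, 0.0]]])
    S = similarity_tensor(emb).data          # (1, 4, 1, 4)
    assert S[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-5)
    assert S[0, 0, 0, 1] == pytest.approx(0.0, abs=1e-5)   # orthogonal
    assert S[0, 0, 0, 2] == pytest.approx(-1.0, abs=1e-5)  # antiparallel
    assert S[0, 0, 0, 3] == pytest.approx(0.0, abs=1e-6)   # zero vector
    identical = similarity_tensor(np.ones((3, 2, 4)))
    assert np.allclose(identical.data, 1.0, atol=1e-6)


def test_multi_similarity_matches_looped_oracle():
    rng = np.random.default_rng(5)
    cfg = LossConfig(alpha=1.7, beta=3.1, margin=0.4)
    for _ in range(20):
        b = int(rng.integers(2, 5))
        r = int(rng.integers(1, 4))
        emb = rng.standard_normal((b, r, int(rng.integers(1, 5))))
        S = similarity_tensor(emb)
        got = multi_similarity_loss(S, cfg).item()
        want = multi_similarity_loops(S.data, cfg.alpha, cfg.beta, cfg.margin)
        assert got == pytest.approx(want, rel=1e-9)


def test_multi_similarity_hand_value_at_margin():
    # b=2, n_pos=1, every similarity equal to the margin:
    # pos = (1/a) log 2, neg = (1/b) log 3 for each of the 4 anchors
    cfg = LossConfig(alpha=2.0, beta=2.0, margin=0.5)
    S = Tensor(np.full((2, 2, 2, 2), 0.5))
    want = np.log(2) / 2 + np.log(3) / 2
    assert multi_similarity_loss(S, cfg).item() == pytest.approx(want, rel=1e-12)


def test_multi_similarity_prefers_separated_embeddings():
    cfg = LossConfig(alpha=2.0, beta=2.0, margin=0.5)
    at_margin = multi_similarity_loss(Tensor(np.full((2, 2, 2, 2), 0.5)), cfg)
    S = np.full((2, 2, 2, 2), -1.0)
    for i in range(2):
        S[:, i, :, i] = 1.0
    separated = multi_similarity_loss(Tensor(S), cfg)
    assert separated.item() < at_margin.item()


def test_multi_similarity_monotonic_in_similarities():
    rng = np.random.default_rng(6)
    cfg = LossConfig(alpha=2.0, beta=2.0, margin=0.5)
    emb = rng.standard_normal((3, 2, 4))
    S = similarity_tensor(emb).data.copy()
    base = multi_similarity_loss(Tensor(S), cfg).item()
    eps = 1e-4
    up = S.copy()
    up[0, 1, 1, 1] += eps          # a within-sample similarity
    up[1, 1, 0, 1] += eps          # its symmetric partner
    assert multi_similarity_loss(Tensor(up), cfg).item() < base
    down = S.copy()
    down[0, 1, 1, 2] += eps        # a cross-sample similarity
    down[1, 2, 0, 1] += eps
    assert multi_similarity_loss(Tensor(down), cfg).item() > base


def test_multi_similarity_requires_two_samples():
    with pytest.raises(ValueError):
        multi_similarity_loss(Tensor(np.zeros((2, 1, 2, 1))), LossConfig())


def test_batch_loss_weighted_sum_and_theta_gradient():
    cfg = LossConfig(theta_kl=0.5, theta_ms=2.0)
    assert batch_loss(1.0, 1.0, 1.0, cfg).item() == pytest.approx(3.5)
    zero_cfg = LossConfig(theta_kl=0.0, theta_ms=0.0)
    assert batch_loss(1.25, 7.0, 9.0, zero_cfg).item() == pytest.approx(1.25)
    # d(total)/d(theta) equals the corresponding term value
    kl_term, ms_term = 0.7, 1.9
    theta = Tensor(np.array(0.5), requires_grad=True)
    total = Tensor(np.array(1.0)) + theta * kl_term + Tensor(np.array(2.0)) * ms_term
    total.backward()
    assert theta.grad == pytest.approx(kl_term)


def test_batch_loss_rejects_non_finite_terms():
    with pytest.raises(FloatingPointError):
        batch_loss(np.nan, 0.0, 0.0, LossConfig())
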