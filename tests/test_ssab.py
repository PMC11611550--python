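"""Attention-unit contracts and the brute-force self-similarity oracle."""

import numpy as np
import pytest

from smartpet.grad import Tensor
from smartpet.ssab import (CBAMAttention, SSABBlock, SSABConfig, SelfAttention,
                           SimilarityAttention, build_attention,
                           self_similarity_map)


def sssim_oracle(f: np.ndarray, win: int, k2: float, big_l: float) -> np.ndarray:
    """Nested-loop sliding-window (zero-padded box mean) similarity score."""
    d, h, w = f.shape
    r = win // 2
    out = np.zeros_like(f, dtype=np.float64)
    c2 = (k2 * big_l) ** 2
    for i in range(d):
        for j in range(h):
            for k in range(w):
                acc = 0.0
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        for dk in range(-r, r + 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if 0 <= ii < d and 0 <= jj < h and 0 <= kk < w:
                                acc += f[ii, jj, kk]
                m = acc / win**3
                out[i, j, k] = (2 * m + c2) / (2 * m * m + c2)
    return out


class TestSelfSimilarityMap:
    def test_matches_brute_force_oracle(self, rng):
        f = rng.normal(size=(7, 7, 7)).astype(np.float64)
        cfg = SSABConfig(window_size=3, dynamic_range_policy="fixed", fixed_range=2.0)
        got = self_similarity_map(Tensor(f[None, None]), cfg).data[0, 0]
        want = sssim_oracle(f, 3, 0.03, 2.0)
        assert np.abs(got - want).max() < 1e-6

    def test_constant_zero_input_scores_one(self):
        cfg = SSABConfig(window_size=3, dynamic_range_policy="fixed", fixed_range=2.0)
        f = Tensor(np.zeros((1, 2, 6, 6, 6)))
        out = self_similarity_map(f, cfg)
        assert np.allclose(out.data, 1.0)  # (0 + c2)/(0 + c2)

    def test_constant_input_closed_form(self):
        v = 0.5
        cfg = SSABConfig(window_size=3, dynamic_range_policy="fixed", fixed_range=2.0)
        c2 = (0.03 * 2.0) ** 2
        assert c2 == pytest.approx(0.0036)  # k2=0.03, L=2 for [-1,1] data
        # interior voxels see a full window of the constant
        f = Tensor(np.full((1, 1, 9, 9, 9), v))
        out = self_similarity_map(f, cfg).data[0, 0, 4, 4, 4]
        assert out == pytest.approx((2 * v + c2) / (2 * v**2 + c2), rel=1e-9)

    def test_window_larger_than_grid_rejected(self, rng):
        f = Tensor(rng.normal(size=(1, 1, 4, 4, 4)))
        with pytest.raises(ValueError, match="window"):
            self_similarity_map(f, SSABConfig(window_size=5))

    def test_canonical_variant_is_finite_and_bounded(self, rng):
        f = Tensor(rng.normal(size=(1, 2, 8, 8, 8)))
        out = self_similarity_map(f, SSABConfig(window_size=3, canonical_sssim=True))
        assert np.isfinite(out.data).all()
        assert (np.abs(out.data) <= 1.0 + 1e-9).all()


class TestSimilarityAttention:
    def test_shape_preserved_and_multiplier_in_unit_interval(self, rng):
        cfg = SSABConfig(window_size=3)
        unit = SimilarityAttention(4, cfg, np.random.default_rng(0))
        f = Tensor(rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        out = unit(f)
        assert out.shape == f.shape
        a = unit.attention_map(f)
        assert (a > 0).all() and (a < 1).all()

    def test_saturated_negative_logits_zero_the_output(self, rng):
        cfg = SSABConfig(window_size=3)
        unit = SimilarityAttention(2, cfg, np.random.default_rng(0))
        for conv in (unit.conv_score, unit.conv_feat):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = -25.0
        f = Tensor(rng.normal(size=(1, 2, 8, 8, 8)))
        out = unit(f)
        assert np.abs(out.data).max() < 1e-8


class TestSelfAttention:
    def test_gamma_zero_init_is_identity(self, rng):
        unit = SelfAttention(8, SSABConfig(), np.random.default_rng(1))
        f = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        assert np.array_equal(unit(f).data, f.data)

    def test_softmax_rows_sum_to_one(self, rng):
        from smartpet.grad import softmax
        unit = SelfAttention(8, SSABConfig(), np.random.default_rng(1))
        f = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        npos = 64
        q = unit.query(f).reshape(1, -1, npos)
        k = unit.key(f).reshape(1, -1, npos)
        attn = softmax(q.transpose(0, 2, 1) @ k, axis=-1)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_spatial_permutation_equivariance(self, rng):
        """1x1 projections + softmax attention commute with any permutation
        of the flattened spatial positions."""
        unit = SelfAttention(8, SSABConfig(), np.random.default_rng(2))
        unit.gamma.data[:] = 0.7  # make the attended term visible
        f = rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32)
        perm = np.random.default_rng(3).permutation(64)
        out = unit(Tensor(f)).data.reshape(8, 64)
        f_perm = f.reshape(1, 8, 64)[:, :, perm].reshape(1, 8, 4, 4, 4)
        out_perm = unit(Tensor(f_perm)).data.reshape(8, 64)
        assert np.allclose(out[:, perm], out_perm, atol=1e-5)

    def test_position_budget_enforced(self, rng):
        cfg = SSABConfig(attention_budget=10)
        unit = SelfAttention(8, cfg, np.random.default_rng(0))
        f = Tensor(rng.normal(size=(1, 8, 4, 4, 4)))
        with pytest.raises(ValueError, match="budget"):
            unit(f)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            SelfAttention(4, SSABConfig(sa_reduction=8), np.random.default_rng(0))


class TestCBAM:
    def test_multipliers_in_unit_interval_and_shape_preserved(self, rng):
        cfg = SSABConfig(ca_reduction=4)
        unit = CBAMAttention(8, cfg, np.random.default_rng(0))
        f = Tensor(rng.normal(size=(2, 8, 6, 6, 6)).astype(np.float32))
        out = unit(f)
        assert out.shape == f.shape
        ca, sa = unit.attention_maps(f)
        assert (ca > 0).all() and (ca < 1).all()
        assert (sa > 0).all() and (sa < 1).all()

    def test_constant_channels_equalize_pooling_branches(self):
        cfg = SSABConfig(ca_reduction=4)
        unit = CBAMAttention(8, cfg, np.random.default_rng(0))
        vals = np.arange(8, dtype=np.float32).reshape(1, 8, 1, 1, 1)
        f = Tensor(np.broadcast_to(vals, (1, 8, 5, 5, 5)).copy())
        avg = f.data.mean(axis=(2, 3, 4))
        mx = f.data.max(axis=(2, 3, 4))
        assert np.allclose(avg, mx)


class TestSSABBlock:
    def test_shape_preserved_for_arbitrary_grids(self, rng):
        cfg = SSABConfig(window_size=3, sa_reduction=8, ca_reduction=8)
        block = SSABBlock(16, cfg, np.random.default_rng(0))
        for sp in [(4, 4, 4), (4, 6, 8)]:
            f = Tensor(rng.normal(size=(1, 16, *sp)).astype(np.float32))
            assert block(f).shape == f.shape

    def test_gradients_reach_every_unit(self, rng):
        cfg = SSABConfig(window_size=3, sa_reduction=8, ca_reduction=8)
        block = SSABBlock(8, cfg, np.random.default_rng(0))
        f = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        (block(f) ** 2).sum().backward()
        for unit in (block.self_attn, block.sim_attn, block.cbam, block.fusion):
            grads = [p.grad for p in unit.parameters()]
            assert any(g is not None and np.isfinite(g).all() and np.abs(g).sum() > 0
                       for g in grads), type(unit).__name__

    def test_deterministic_forward(self, rng):
        cfg = SSABConfig(window_size=3, sa_reduction=4, ca_reduction=4)
        block = SSABBlock(8, cfg, np.random.default_rng(5))
        f = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        assert np.array_equal(block(f).data, block(f).data)

    def test_attention_factory_covers_all_types(self):
        cfg = SSABConfig(sa_reduction=4, ca_reduction=4)
        rng = np.random.default_rng(0)
        assert build_attention("none", 8, cfg, rng) is None
        for kind, cls in [("ssab", SSABBlock), ("self", SelfAttention),
                          ("similarity", SimilarityAttention), ("cbam", CBAMAttention)]:
            assert isinstance(build_attention(kind, 8, cfg, rng), cls)
        with pytest.raises(ValueError):
            build_attention("frequency", 8, cfg, rng)
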