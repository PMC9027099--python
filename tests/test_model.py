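"""Scale-attention weights, generator and discriminator contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thinsr._exceptions import ConstructionError
from thinsr.model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    compute_alignment_weights,
    load_generator,
    save_generator,
)


class TestAlignmentWeights:
    @pytest.mark.parametrize(
        "s,expected",
        [
            (1.5, [1, 0, 0, 0, 0]),
            (6.5, [0, 0, 0, 0, 1]),
            (3.4, [0, 0.6, 0.4, 0, 0]),
            (4.0, [0, 0, 1, 0, 0]),
            (2.0, [1, 0, 0, 0, 0]),
            (5.999, [0, 0, 0, 0.001, 0.999]),
        ],
    )
    def test_known_values(self, s, expected):
        w = compute_alignment_weights(s)
        assert np.allclose(w.alpha, expected, atol=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            compute_alignment_weights(0.0)
        with pytest.raises(ValueError):
            compute_alignment_weights(-1.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=300, deadline=None)
    def test_simplex_and_adjacency_invariants(self, s):
        a = compute_alignment_weights(s).alpha
        assert np.all(a >= 0)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)
        nz = np.flatnonzero(a > 1e-12)
        assert len(nz) <= 2
        if len(nz) == 2:
            assert nz[1] == nz[0] + 1

    def test_piecewise_linear_continuity(self):
        # |alpha(s + d) - alpha(s)| <= d componentwise on [2, 6]
        s_grid = np.linspace(2.0, 6.0, 1001)
        alphas = np.stack([compute_alignment_weights(s).alpha for s in s_grid])
        deltas = np.abs(np.diff(alphas, axis=0))
        step = s_grid[1] - s_grid[0]
        assert deltas.max() <= step + 1e-9


class TestGenerator:
    def test_untrained_is_identity_for_any_alpha(self, rng, tiny_generator):
        patch = rng.uniform(0, 10000, size=(2, 1, 16, 16, 16)).astype(np.float32)
        for s in (1.5, 3.7, 6.0):
            out = tiny_generator.forward(patch, compute_alignment_weights(s).alpha)
            assert np.array_equal(out, patch)

    def test_shape_preserving(self, rng, tiny_generator):
        patch = rng.uniform(0, 10000, size=(1, 1, 32, 32, 32)).astype(np.float32)
        out = tiny_generator.forward(patch, compute_alignment_weights(4).alpha)
        assert out.shape == patch.shape

    def test_one_hot_alpha_uses_only_that_branch(self, rng):
        gen = build_generator(GeneratorConfig(n_residual_layers=2, channels=4), seed=1)
        # give the exits nonzero weights so branch usage is observable
        for e in gen.exit:
            e.w[...] = rng.normal(0, 0.01, size=e.w.shape).astype(np.float32)
        patch = rng.uniform(0, 10000, size=(1, 1, 12, 12, 12)).astype(np.float32)
        alpha = compute_alignment_weights(3).alpha  # one-hot on branch index 1
        ref = gen.forward(patch, alpha)
        for i in (0, 2, 3, 4):
            gen.entry[i].w[...] = 0.0
            gen.exit[i].w[...] = 0.0
        assert np.array_equal(gen.forward(patch, alpha), ref)

    def test_entry_mixture_linear_in_alpha(self, rng):
        gen = build_generator(GeneratorConfig(n_residual_layers=2, channels=4), seed=2)
        patch = rng.uniform(0, 10000, size=(1, 1, 8, 8, 8)).astype(np.float32)

        def entry_mix(alpha):
            xs = (patch * gen.IN_SCALE).astype(np.float32)
            return sum(
                alpha[i] * gen.entry[i].forward(xs)
                for i in range(len(alpha))
                if alpha[i]
            )

        a1 = np.array([1.0, 0, 0, 0, 0])
        a2 = np.array([0, 1.0, 0, 0, 0])
        mixed = entry_mix(0.5 * (a1 + a2))
        mean = 0.5 * (entry_mix(a1) + entry_mix(a2))
        assert np.allclose(mixed, mean, atol=1e-4)

    def test_forward_deterministic(self, rng, tiny_generator):
        patch = rng.uniform(0, 10000, size=(1, 1, 8, 8, 8)).astype(np.float32)
        alpha = compute_alignment_weights(2.5).alpha
        assert np.array_equal(
            tiny_generator.forward(patch, alpha),
            tiny_generator.forward(patch, alpha),
        )

    def test_alpha_not_summing_to_one_rejected(self, rng, tiny_generator):
        patch = rng.uniform(0, 1, size=(1, 1, 8, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError):
            tiny_generator.forward(patch, np.array([0.5, 0.2, 0, 0, 0]))

    def test_backbone_sharing_param_growth(self):
        base = build_generator(GeneratorConfig(n_residual_layers=4, channels=8), seed=0)
        grown = build_generator(
            GeneratorConfig(n_residual_layers=4, channels=8, scale_set=(2, 3, 4, 5, 6, 7)),
            seed=0,
        )
        per_branch = (
            base.entry[0].w.size
            + base.entry[0].b.size
            + base.exit[0].w.size
            + base.exit[0].b.size
        )
        assert grown.n_params() - base.n_params() == per_branch

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConstructionError):
            GeneratorConfig(n_residual_layers=0)
        with pytest.raises(ConstructionError):
            GeneratorConfig(scale_set=(3, 2))
        with pytest.raises(ConstructionError):
            GeneratorConfig(kernel_size=4)

    def test_checkpoint_round_trip(self, rng, tmp_path, tiny_generator):
        gen = tiny_generator
        for p in gen.params():
            p += rng.normal(0, 0.01, size=p.shape).astype(np.float32)
        path = tmp_path / "g.npz"
        save_generator(path, gen, stage_tag="mse")
        back, tag = load_generator(path)
        assert tag == "mse"
        patch = rng.uniform(0, 10000, size=(1, 1, 8, 8, 8)).astype(np.float32)
        alpha = compute_alignment_weights(4).alpha
        assert np.array_equal(gen.forward(patch, alpha), back.forward(patch, alpha))


class TestDiscriminator:
    def test_scores_in_unit_interval(self, rng):
        disc = build_discriminator(DiscriminatorConfig(channels=8), seed=0)
        batch = rng.uniform(0, 10000, size=(3, 1, 32, 32, 32)).astype(np.float32)
        scores = disc.forward(batch)
        assert scores.shape == (3,)
        assert np.all((scores > 0) & (scores < 1))

    def test_wrong_patch_size_raises(self, rng):
        disc = build_discriminator(DiscriminatorConfig(channels=8), seed=0)
        with pytest.raises(ValueError):
            disc.forward(rng.uniform(size=(1, 1, 31, 31, 31)).astype(np.float32))

    def test_input_size_must_match_stride_pyramid(self):
        with pytest.raises(ConstructionError):
            DiscriminatorConfig(channels=8, n_strided_blocks=4, input_size=24)
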