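"""Learning-rate schedule, stage-1/stage-2 training mechanics."""

import numpy as np
import pytest

from thinsr._exceptions import TrainingError
from thinsr.losses import RandomConvFeatureExtractor
from thinsr.model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    compute_alignment_weights,
    load_generator,
    save_generator,
)
from thinsr.phantom import PhantomSpec, generate_training_fixture
from thinsr.training import (
    TrainConfig,
    TrainState,
    lr_schedule_step,
    train_stage1_mse,
    train_stage2_gan,
)


def plateau(state, config, n=1):
    """Feed enough stagnant cycles to trigger ``n`` plateau events."""
    for _ in range(n * config.plateau_patience):
        state = lr_schedule_step(state, state.best_val_loss * 2.0, config)
    return state


@pytest.fixture(scope="module")
def small_corpus():
    pairs, split = generate_training_fixture(
        4, PhantomSpec(shape=(32, 32, 32)), factors=(4,), mode="thick", seed=0
    )
    train = [p for p in pairs if p.patient_id in split.train_ids]
    val = [p for p in pairs if p.patient_id in split.val_ids]
    return train, val


def desk_config(**kw):
    return GeneratorConfig(n_residual_layers=2, channels=4, **kw)


class TestLrSchedule:
    def test_one_plateau_event_divides_by_three(self):
        config = TrainConfig()
        state = TrainState(current_lr=3e-4, best_val_loss=1.0)
        state = plateau(state, config, n=1)
        assert state.current_lr == pytest.approx(1e-4, rel=1e-12)
        assert not state.stage_complete

    def test_three_plateau_events_complete_the_stage(self):
        config = TrainConfig()
        state = TrainState(current_lr=3e-4, best_val_loss=1.0)
        state = plateau(state, config, n=3)
        assert state.current_lr == pytest.approx(3e-4 / 27, rel=1e-12)
        assert state.current_lr == pytest.approx(1.111e-5, rel=1e-3)
        assert state.stage_complete

    def test_improving_validation_keeps_rate(self):
        config = TrainConfig()
        state = TrainState(current_lr=3e-4, best_val_loss=float("inf"))
        loss = 100.0
        for _ in range(50):
            state = lr_schedule_step(state, loss, config)
            loss *= 0.9
        assert state.current_lr == 3e-4
        assert state.decays_used == 0

    def test_single_stagnant_cycle_does_not_decay(self):
        config = TrainConfig(plateau_patience=3)
        state = TrainState(current_lr=3e-4, best_val_loss=1.0)
        state = lr_schedule_step(state, 2.0, config)
        assert state.current_lr == 3e-4 and state.stagnant_cycles == 1
        # an improvement resets the stagnation counter
        state = lr_schedule_step(state, 0.5, config)
        assert state.stagnant_cycles == 0

    def test_lr_invariant_follows_decay_count(self):
        config = TrainConfig()
        state = TrainState(current_lr=3e-4, best_val_loss=1.0)
        for n in (1, 2, 3):
            state = plateau(state, config, n=1)
            assert state.current_lr == pytest.approx(
                config.lr_init / config.lr_decay_factor**state.decays_used
            )
            assert state.decays_used == n


class TestStage1:
    def test_loss_decreases_and_is_deterministic(self, small_corpus):
        train, val = small_corpus
        config = TrainConfig(stage="mse", max_epochs=3, batch_size=2, seed=0)
        results = []
        for _ in range(2):
            gen = build_generator(desk_config(), seed=0)
            gen, state = train_stage1_mse(train, gen, config, val_pairs=val)
            results.append((gen, state))
        g1, s1 = results[0]
        g2, s2 = results[1]
        assert s1.history[-1]["train_mse"] < s1.history[0]["train_mse"]
        for p, q in zip(g1.params(), g2.params()):
            assert np.array_equal(p, q)
        assert s1.history == s2.history

    def test_empty_corpus_rejected(self):
        gen = build_generator(desk_config(), seed=0)
        with pytest.raises(TrainingError):
            train_stage1_mse([], gen, TrainConfig(stage="mse"))

    def test_checkpoint_round_trip_preserves_forward(self, small_corpus, tmp_path):
        train, val = small_corpus
        gen = build_generator(desk_config(), seed=0)
        gen, _ = train_stage1_mse(
            train, gen, TrainConfig(stage="mse", max_epochs=1, batch_size=2, seed=0)
        )
        save_generator(tmp_path / "g.npz", gen, stage_tag="mse")
        back, _ = load_generator(tmp_path / "g.npz")
        patch = train[0].lr_patch[None, None]
        alpha = compute_alignment_weights(4).alpha
        assert np.array_equal(gen.forward(patch, alpha), back.forward(patch, alpha))


class TestStage2:
    @pytest.fixture()
    def setup(self, small_corpus):
        train, val = small_corpus
        gen = build_generator(desk_config(), seed=0)
        gen, _ = train_stage1_mse(
            train, gen, TrainConfig(stage="mse", max_epochs=1, batch_size=2, seed=0)
        )
        disc = build_discriminator(DiscriminatorConfig(channels=4), seed=0)
        extractor = RandomConvFeatureExtractor(seed=0, channels=4)
        return train, gen, disc, extractor

    def test_all_loss_terms_finite_and_logged(self, setup):
        train, gen, disc, extractor = setup
        config = TrainConfig(stage="gan", max_epochs=4, batch_size=2, seed=0)
        gen, disc, state = train_stage2_gan(
            train, gen, disc, extractor, config, max_batches=4
        )
        assert len(state.history) == 4
        for rec in state.history:
            for key in ("l_mse", "l_per", "l_gan", "l_total", "d_loss"):
                assert np.isfinite(rec[key])

    def test_wiring_with_zero_weights_gives_pure_perceptual(self, setup):
        train, gen, disc, extractor = setup
        config = TrainConfig(
            stage="gan", max_epochs=1, batch_size=2, seed=0, lambda_w=0.0, mu_w=0.0
        )
        _, _, state = train_stage2_gan(
            train, gen, disc, extractor, config, max_batches=1
        )
        rec = state.history[0]
        assert rec["l_total"] == pytest.approx(rec["l_per"], rel=1e-12)

    def test_discriminator_step_isolated_from_generator(self, setup):
        train, gen, disc, extractor = setup
        before = [p.copy() for p in gen.params()]
        d_before = [p.copy() for p in disc.params()]
        config = TrainConfig(stage="gan", max_epochs=1, batch_size=2, seed=0)
        gen, disc, _ = train_stage2_gan(
            train, gen, disc, extractor, config, max_batches=1
        )
        # one batch = one D step + one G step; both nets moved, and the
        # gradient bookkeeping kept them separate (no shared arrays)
        assert any(not np.array_equal(a, b) for a, b in zip(before, gen.params()))
        assert any(not np.array_equal(a, b) for a, b in zip(d_before, disc.params()))
        assert not any(p1 is p2 for p1 in gen.params() for p2 in disc.params())

    def test_untrained_generator_warns(self, small_corpus):
        train, _ = small_corpus
        gen = build_generator(desk_config(), seed=0)
        disc = build_discriminator(DiscriminatorConfig(channels=4), seed=0)
        extractor = RandomConvFeatureExtractor(seed=0, channels=4)
        config = TrainConfig(stage="gan", max_epochs=1, batch_size=2, seed=0)
        with pytest.warns(UserWarning):
            train_stage2_gan(train, gen, disc, extractor, config, max_batches=1)
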