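"""Two-stage optimization: MSE pre-training, then perceptual + GAN tuning.

Stage 1 minimizes voxelwise MSE with Adam, which converges to a sharp but
somewhat smooth solution; it is the initialization for stage 2, where the
generator is fine-tuned with the combined loss (perceptual + weighted
adversarial + weighted MSE) while a discriminator is trained alternately
against it, one discriminator step then one generator step per batch.

The learning-rate schedule is plateau-driven: start at 3e-4 and divide by 3
whenever the validation loss stops improving for a full cycle (one epoch);
after three decays the stage is complete.  Stage 2 runs at a smaller fixed
rate for a fixed epoch budget, since "stop when it looks good" is not
automatable; the loss history is persisted for inspection instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._exceptions import TrainingError
from .dataset import PatchPair
from .losses import (
    DEFAULT_LAMBDA,
    DEFAULT_MU,
    FeatureExtractor,
    LossBundle,
    adversarial_losses,
    perceptual_batch_with_grad,
    total_generator_loss,
)
from .model import Discriminator, Generator, compute_alignment_weights
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainState",
    "lr_schedule_step",
    "train_stage1_mse",
    "train_stage2_gan",
]

_REL_TOL = 1e-6  # relative improvement below this counts as a plateau


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training stage."""

    stage: str = "mse"
    lr_init: float = 3e-4
    lr_decay_factor: float = 3.0
    max_decay_cycles: int = 3
    batch_size: int = 16
    max_epochs: int = 30
    seed: int = 0
    lambda_w: float = DEFAULT_LAMBDA
    mu_w: float = DEFAULT_MU
    stage2_lr: float = 1e-4
    #: discriminator rate; faster than the generator's (two-time-scale
    #: updates) so D tracks the slowly fine-tuning G
    disc_lr: float = 3e-4
    #: consecutive stagnant validation cycles that make one plateau event
    plateau_patience: int = 3

    def __post_init__(self) -> None:
        if self.stage not in ("mse", "gan"):
            raise ValueError(f"stage must be 'mse' or 'gan', got {self.stage!r}")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must exceed 1")
        if self.max_decay_cycles < 1:
            raise ValueError("max_decay_cycles must be >= 1")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


@dataclass
class TrainState:
    """Mutable record of training progress."""

    epoch: int = 0
    current_lr: float = 3e-4
    decays_used: int = 0
    best_val_loss: float = float("inf")
    stagnant_cycles: int = 0
    stage_complete: bool = False
    history: List[Dict[str, float]] = field(default_factory=list)
    rng_seed: int = 0


def lr_schedule_step(
    state: TrainState, val_loss: float, config: TrainConfig
) -> TrainState:
    """Plateau schedule: divide the rate by the decay factor on stagnation.

    A cycle whose validation loss improves (strictly, beyond 1e-6 relative)
    keeps the rate and resets the stagnation counter; once
    ``plateau_patience`` consecutive cycles stagnate (one *plateau event*)
    the rate is divided by ``lr_decay_factor``.  After ``max_decay_cycles``
    plateau events the stage is flagged complete.
    """
    improved = val_loss < state.best_val_loss * (1.0 - _REL_TOL) or not np.isfinite(
        state.best_val_loss
    )
    new = replace_state(state)
    if improved and np.isfinite(val_loss):
        new.best_val_loss = float(val_loss)
        new.stagnant_cycles = 0
        return new
    new.stagnant_cycles += 1
    if new.stagnant_cycles < config.plateau_patience:
        return new
    new.stagnant_cycles = 0
    new.decays_used += 1
    new.current_lr = config.lr_init / config.lr_decay_factor**new.decays_used
    if new.decays_used >= config.max_decay_cycles:
        new.stage_complete = True
    return new


def replace_state(state: TrainState) -> TrainState:
    return TrainState(
        epoch=state.epoch,
        current_lr=state.current_lr,
        decays_used=state.decays_used,
        best_val_loss=state.best_val_loss,
        stagnant_cycles=state.stagnant_cycles,
        stage_complete=state.stage_complete,
        history=list(state.history),
        rng_seed=state.rng_seed,
    )


def _batches_by_scale(
    pairs: Sequence[PatchPair], batch_size: int, rng: np.random.Generator
) -> List[Tuple[int, np.ndarray, np.ndarray]]:
    """Shuffle pairs and group them into scale-homogeneous batches.

    The generator mixes branches with one alpha per forward pass, so every
    batch holds patches produced by a single degradation factor.
    """
    by_scale: Dict[int, List[PatchPair]] = {}
    for pp in pairs:
        by_scale.setdefault(pp.scale_s, []).append(pp)
    batches = []
    for s in sorted(by_scale):
        group = by_scale[s]
        order = rng.permutation(len(group))
        for i0 in range(0, len(group), batch_size):
            sel = [group[i] for i in order[i0 : i0 + batch_size]]
            lr = np.stack([pp.lr_patch for pp in sel])[:, None]
            hr = np.stack([pp.hr_patch for pp in sel])[:, None]
            batches.append((s, lr, hr))
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _mse_and_grad(sr: np.ndarray, hr: np.ndarray) -> Tuple[float, np.ndarray]:
    diff = sr.astype(np.float64) - hr.astype(np.float64)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff


def _val_mse(pairs: Sequence[PatchPair], gen: Generator) -> float:
    if not pairs:
        return float("nan")
    total = 0.0
    count = 0
    for pp in pairs:
        alpha = compute_alignment_weights(pp.scale_s, gen.config.scale_set).alpha
        sr = gen.forward(pp.lr_patch[None, None], alpha)
        total += float(np.sum((sr[0, 0].astype(np.float64) - pp.hr_patch) ** 2))
        count += pp.hr_patch.size
    return total / count


def train_stage1_mse(
    corpus: Sequence[PatchPair],
    gen: Generator,
    config: TrainConfig,
    val_pairs: Optional[Sequence[PatchPair]] = None,
) -> Tuple[Generator, TrainState]:
    """Pixel-wise pre-training of the generator.

    ``corpus`` is the training patch list; ``val_pairs`` (if given) drives
    the plateau learning-rate schedule, otherwise the epoch training loss
    does.  The parameters returned are the best-validation snapshot, not
    the last epoch's - on small corpora the final epochs routinely overfit
    past the best generalizing model.  Deterministic for a fixed config
    seed.
    """
    if not corpus:
        raise TrainingError("empty training corpus")
    rng = np.random.default_rng(config.seed)
    opt = Adam(gen.params(), lr=config.lr_init)
    state = TrainState(current_lr=config.lr_init, rng_seed=config.seed)
    best_params = [p.copy() for p in gen.params()]
    best_loss = float("inf")
    for epoch in range(config.max_epochs):
        opt.lr = state.current_lr
        epoch_loss = 0.0
        n_batches = 0
        for s, lr_b, hr_b in _batches_by_scale(corpus, config.batch_size, rng):
            alpha = compute_alignment_weights(s, gen.config.scale_set).alpha
            sr = gen.forward(lr_b, alpha)
            loss, gsr = _mse_and_grad(sr, hr_b)
            if not np.isfinite(loss):
                raise TrainingError(f"MSE diverged at epoch {epoch}: {state}")
            gen.zero_grad()
            gen.backward(gsr.astype(np.float32))
            opt.step(gen.grads())
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        val_loss = _val_mse(val_pairs, gen) if val_pairs else train_loss
        state.epoch = epoch + 1
        state.history.append(
            {"epoch": epoch + 1, "train_mse": train_loss, "val_mse": val_loss,
             "lr": state.current_lr}
        )
        if np.isfinite(val_loss) and val_loss < best_loss:
            best_loss = val_loss
            best_params = [p.copy() for p in gen.params()]
        state = lr_schedule_step(state, val_loss, config)
        if state.stage_complete:
            break
    gen.load_state_arrays(best_params)
    return gen, state


def train_stage2_gan(
    corpus: Sequence[PatchPair],
    gen: Generator,
    disc: Discriminator,
    extractor: FeatureExtractor,
    config: TrainConfig,
    max_batches: Optional[int] = None,
) -> Tuple[Generator, Discriminator, TrainState]:
    """Adversarial fine-tuning with the combined generator loss.

    Per batch: one discriminator update (real vs. generated patches), then
    one generator update driven by perceptual + lambda*adversarial +
    mu*MSE.  Gradients are isolated: the discriminator step touches no
    generator parameter and vice versa.  ``max_batches`` caps the total
    number of alternating updates (smoke runs); otherwise ``max_epochs``
    epochs are run.
    """
    if not corpus:
        raise TrainingError("empty training corpus")
    import warnings

    is_pretrained = any(np.any(w.w != 0) for w in gen.exit)
    if not is_pretrained:
        warnings.warn(
            "stage-2 training from an untrained generator; the pixel-wise "
            "pre-trained model is the intended initialization",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed + 1)
    opt_g = Adam(gen.params(), lr=config.stage2_lr)
    opt_d = Adam(disc.params(), lr=config.disc_lr)
    state = TrainState(current_lr=config.stage2_lr, rng_seed=config.seed)
    done = 0
    for epoch in range(config.max_epochs):
        for s, lr_b, hr_b in _batches_by_scale(corpus, config.batch_size, rng):
            alpha = compute_alignment_weights(s, gen.config.scale_set).alpha
            # --- discriminator step (generator frozen) ---
            sr = gen.forward(lr_b, alpha)
            d_real = disc.forward(hr_b)
            # d(-log sigmoid(z))/dz = sigmoid(z) - 1 ; target real=1
            g_logit_real = (d_real - 1.0) / len(d_real)
            disc.zero_grad()
            disc.backward_from_dlogit(g_logit_real)
            d_fake = disc.forward(sr)
            g_logit_fake = d_fake / len(d_fake)
            disc.backward_from_dlogit(g_logit_fake)
            _, d_loss = adversarial_losses(d_real, d_fake)
            opt_d.step(disc.grads())
            # --- generator step (discriminator frozen) ---
            sr = gen.forward(lr_b, alpha)
            l_mse, g_mse = _mse_and_grad(sr, hr_b)
            l_per, g_per_b = perceptual_batch_with_grad(
                sr[:, 0], hr_b[:, 0], extractor
            )
            g_per = g_per_b[:, None]
            d_fake2 = disc.forward(sr)
            l_gan = float(-np.mean(np.log(np.clip(d_fake2, 1e-7, 1 - 1e-7))))
            disc.zero_grad()  # discard: this pass only routes gradient to G
            g_sr_gan = disc.backward_from_dlogit((d_fake2 - 1.0) / len(d_fake2))
            disc.zero_grad()
            bundle = total_generator_loss(
                l_per, l_gan, l_mse, config.lambda_w, config.mu_w
            )
            if not np.isfinite(bundle.l_total):
                raise TrainingError(f"GAN stage diverged: {bundle}")
            g_total = (
                g_per
                + config.lambda_w * g_sr_gan
                + config.mu_w * g_mse
            ).astype(np.float32)
            gen.zero_grad()
            gen.backward(g_total)
            opt_g.step(gen.grads())
            state.history.append(
                {
                    "batch": done + 1,
                    "l_mse": l_mse,
                    "l_per": l_per,
                    "l_gan": l_gan,
                    "l_total": bundle.l_total,
                    "d_loss": d_loss,
                    "d_real_mean": float(np.mean(d_real)),
                    "d_fake_mean": float(np.mean(d_fake)),
                }
            )
            done += 1
            if max_batches is not None and done >= max_batches:
                state.epoch = epoch + 1
                return gen, disc, state
        state.epoch = epoch + 1
    return gen, disc, state
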