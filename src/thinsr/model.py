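"""Scale-attention residual 3D generator and patch discriminator.

One network serves a continuum of through-plane upsampling factors.  The
trick is a small set of integer *scale branches* (one per trained factor,
default {2, 3, 4, 5, 6}) at the entrance and exit of a shared residual
backbone, mixed by alignment weights alpha(s): a requested factor s between
trained integers m and m+1 activates exactly the two neighbouring branches
with weights (1 - t, t), t = s - m, clamped to one-hot outside [2, 6].
Nearly all parameters live in the backbone and are shared across scales.

The generator is *pre-upsampling residual*: its input patch is already
cubically interpolated to the target grid and the network predicts only a
residual correction.  The final exit convolutions are zero-initialized, so
an untrained generator is exactly the identity - i.e. plain tricubic
interpolation, the baseline the trained model must beat.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._exceptions import ConstructionError
from .nn import Adam, Conv, Linear, leaky_relu, leaky_relu_grad, relu, relu_grad, sigmoid

__all__ = [
    "ScaleWeights",
    "GeneratorConfig",
    "DiscriminatorConfig",
    "compute_alignment_weights",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "save_generator",
    "load_generator",
]

DEFAULT_SCALES: Tuple[int, ...] = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ScaleWeights:
    """Alignment weights over the trained scale set for a requested factor.

    ``alpha`` is non-negative, sums to one, and has at most two nonzero
    entries which are adjacent.  ``m`` and ``t`` are the integer part and
    fraction used to build it (``m`` is clamped into the trained range).
    """

    alpha: np.ndarray
    s: float
    m: int
    t: float

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=np.float64)
        object.__setattr__(self, "alpha", a)
        if np.any(a < -1e-12) or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must be non-negative and sum to 1")
        nz = np.flatnonzero(a > 1e-12)
        if len(nz) > 2 or (len(nz) == 2 and nz[1] != nz[0] + 1):
            raise ValueError("alpha must have at most two adjacent nonzeros")


def compute_alignment_weights(
    s: float, scale_set: Sequence[int] = DEFAULT_SCALES
) -> ScaleWeights:
    """Map a requested real factor s onto branch mixing weights.

    Below the smallest trained scale the first branch takes all the weight;
    above the largest, the last branch does.  In between, weight is split
    linearly between the two bracketing branches, so alpha is a continuous,
    piecewise-linear function of s and integer s is one-hot on its own
    branch.
    """
    s = float(s)
    if not np.isfinite(s) or s <= 0:
        raise ValueError(f"sampling factor must be positive, got {s}")
    scales = [int(v) for v in scale_set]
    if len(scales) < 1 or any(
        b <= a for a, b in zip(scales, scales[1:])
    ):
        raise ValueError("scale_set must be strictly increasing")
    alpha = np.zeros(len(scales), dtype=np.float64)
    if s < scales[0]:
        alpha[0] = 1.0
        return ScaleWeights(alpha, s, scales[0], 0.0)
    if s >= scales[-1]:
        alpha[-1] = 1.0
        return ScaleWeights(alpha, s, scales[-1], 0.0)
    for i in range(len(scales) - 1):
        lo, hi = scales[i], scales[i + 1]
        if lo <= s < hi:
            t = (s - lo) / (hi - lo)
            alpha[i] = 1.0 - t
            alpha[i + 1] = t
            return ScaleWeights(alpha, s, lo, t)
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of the scale-attention generator.

    ``n_residual_layers`` counts the 3D convolutions in the shared backbone
    (entry/exit branch convolutions are extra); they are arranged as
    two-convolution residual blocks.  Defaults follow the full-size model
    (14 layers, 64 channels); desk-scale work uses a reduced config.
    """

    n_residual_layers: int = 14
    channels: int = 64
    scale_set: Tuple[int, ...] = DEFAULT_SCALES
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.n_residual_layers < 1:
            raise ConstructionError("n_residual_layers must be >= 1")
        if self.channels < 1:
            raise ConstructionError("channels must be >= 1")
        ss = tuple(int(v) for v in self.scale_set)
        if any(b <= a for a, b in zip(ss, ss[1:])) or not ss:
            raise ConstructionError("scale_set must be strictly increasing")
        object.__setattr__(self, "scale_set", ss)
        if self.kernel_size % 2 != 1:
            raise ConstructionError("kernel_size must be odd")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Architecture of the patch discriminator (SRGAN-style)."""

    channels: int = 32
    n_strided_blocks: int = 4
    input_size: int = 32

    def __post_init__(self) -> None:
        if self.input_size % (2**self.n_strided_blocks) != 0:
            raise ConstructionError(
                "input_size must be divisible by 2**n_strided_blocks"
            )


def _check_alpha(alpha: np.ndarray, n: int) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=np.float64).ravel()
    if alpha.shape[0] != n:
        raise ValueError(f"alpha must have length {n}")
    if np.any(alpha < -1e-12) or abs(alpha.sum() - 1.0) > 1e-6:
        raise ValueError("alpha must be non-negative and sum to 1")
    return alpha


#: internal intensity normalization: features live near unit scale while
#: the interface stays in standardized units (0, 10000)
_INTENSITY_CEILING = 10000.0


class Generator:
    """Scale-attention residual 3D CNN (pre-upsampling, residual output).

    Inputs are divided by the standardization ceiling before the entry
    branches and the predicted residual is multiplied back, so network
    features are near unit scale (well-conditioned for Adam) while the
    interface speaks standardized intensity units end to end.
    """

    IN_SCALE = 1.0 / _INTENSITY_CEILING
    #: residual-branch scaling: the residual is emitted at one tenth of the
    #: intensity ceiling, the usual residual-scaling stabilization for SR
    #: networks - keeps early optimizer steps from kicking the output far
    #: from the interpolation baseline.
    OUT_SCALE = 0.1 * _INTENSITY_CEILING

    def __init__(self, config: GeneratorConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        k = config.kernel_size
        pad = k // 2
        n_scales = len(config.scale_set)
        self.entry = [
            Conv(1, c, k, ndim=3, padding=pad, rng=rng) for _ in range(n_scales)
        ]
        n_blocks, extra = divmod(config.n_residual_layers, 2)
        self.blocks: List[Tuple[Conv, Conv]] = []
        for _ in range(n_blocks):
            self.blocks.append(
                (
                    Conv(c, c, k, ndim=3, padding=pad, rng=rng),
                    Conv(c, c, k, ndim=3, padding=pad, rng=rng),
                )
            )
        self.tail: Optional[Conv] = (
            Conv(c, c, k, ndim=3, padding=pad, rng=rng) if extra else None
        )
        # zero-initialized exits make the untrained network the identity
        self.exit = [
            Conv(c, 1, k, ndim=3, padding=pad, zero_init=True)
            for _ in range(n_scales)
        ]
        self._cache: Dict[str, object] = {}

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> List[Conv]:
        layers: List[Conv] = list(self.entry)
        for c1, c2 in self.blocks:
            layers += [c1, c2]
        if self.tail is not None:
            layers.append(self.tail)
        layers += list(self.exit)
        return layers

    def params(self) -> List[np.ndarray]:
        return [p for l in self._layers() for p in l.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for l in self._layers() for g in l.grads()]

    def zero_grad(self) -> None:
        for l in self._layers():
            l.zero_grad()

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        """Predict the super-resolved patch: input + mixed residual.

        ``x``: (N, 1, d, h, w) standardized intensities; ``alpha``: mixing
        weights over the scale branches (must sum to 1).  Only branches with
        nonzero weight are evaluated.
        """
        alpha = _check_alpha(alpha, len(self.config.scale_set))
        if x.ndim == 3:
            x = x[None, None]
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, d, h, w), got {x.shape}")
        active = [i for i, a in enumerate(alpha) if a != 0.0]
        xs = (x * self.IN_SCALE).astype(np.float32)
        h = None
        for i in active:
            out = self.entry[i].forward(xs)
            h = alpha[i] * out if h is None else h + alpha[i] * out
        feats = [h]
        for c1, c2 in self.blocks:
            a1 = c1.forward(h)
            r1 = relu(a1)
            a2 = c2.forward(r1)
            h = h + a2
            feats.append((a1, h))
        if self.tail is not None:
            at = self.tail.forward(h)
            h = relu(at)
            feats.append(at)
        res = None
        for i in active:
            out = self.exit[i].forward(h)
            res = alpha[i] * out if res is None else res + alpha[i] * out
        self._cache = {"alpha": alpha, "active": active, "feats": feats}
        return x + self.OUT_SCALE * res

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients for d(loss)/d(output) = ``gy``."""
        cache = self._cache
        alpha: np.ndarray = cache["alpha"]  # type: ignore[assignment]
        active: List[int] = cache["active"]  # type: ignore[assignment]
        feats = cache["feats"]  # type: ignore[assignment]
        gy = (gy * self.OUT_SCALE).astype(np.float32)
        gh = None
        for i in active:
            g = self.exit[i].backward(alpha[i] * gy)
            gh = g if gh is None else gh + g
        if self.tail is not None:
            at = feats[-1]
            gh = self.tail.backward(relu_grad(at, gh))
        n_blocks = len(self.blocks)
        for bi in range(n_blocks - 1, -1, -1):
            c1, c2 = self.blocks[bi]
            a1, _h_out = feats[bi + 1]
            g2 = c2.backward(gh)
            g1 = c1.backward(relu_grad(a1, g2))
            gh = gh + g1
        for i in active:
            self.entry[i].backward(alpha[i] * gh, need_input_grad=False)

    # -- state --------------------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        return self.params()

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state does not match architecture")
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError("state does not match architecture")
            p[...] = a


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Construct a generator; untrained it is the identity on its input."""
    return Generator(config, seed=seed)


class Discriminator:
    """3D strided-convolution classifier scoring 32^3 patches as real/fake."""

    def __init__(self, config: DiscriminatorConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        self.convs: List[Conv] = []
        in_ch = 1
        size = config.input_size
        for b in range(config.n_strided_blocks):
            out_ch = min(c * 2**b, 8 * c)
            self.convs.append(
                Conv(in_ch, out_ch, 3, ndim=3, stride=2, padding=1, rng=rng)
            )
            in_ch = out_ch
            size //= 2
        self.flat_features = in_ch * size**3
        self.fc = Linear(self.flat_features, 1, rng=rng)
        self._cache: Dict[str, object] = {}

    def _layers(self):
        return [*self.convs, self.fc]

    def params(self) -> List[np.ndarray]:
        return [p for l in self._layers() for p in l.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for l in self._layers() for g in l.grads()]

    def zero_grad(self) -> None:
        for l in self._layers():
            l.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Score a batch of patches; returns sigmoid scores in (0, 1)."""
        if x.ndim == 3:
            x = x[None, None]
        if x.ndim == 4:
            x = x[:, None]
        n = self.config.input_size
        if x.shape[2:] != (n, n, n):
            raise ValueError(
                f"discriminator expects {n}^3 patches, got {x.shape[2:]}"
            )
        pre = []
        h = (x * (1.0 / _INTENSITY_CEILING)).astype(np.float32)
        for conv in self.convs:
            a = conv.forward(h)
            pre.append(a)
            h = leaky_relu(a)
        flat = h.reshape(h.shape[0], -1)
        logit = self.fc.forward(flat)[:, 0]
        score = sigmoid(logit)
        self._cache = {"pre": pre, "shape": h.shape, "logit": logit}
        return score

    def backward_from_dlogit(self, dlogit: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(logit); returns d(loss)/d(input patch)."""
        cache = self._cache
        g = self.fc.backward(np.asarray(dlogit, dtype=np.float32)[:, None])
        g = g.reshape(cache["shape"])  # type: ignore[arg-type]
        for conv, a in zip(reversed(self.convs), reversed(cache["pre"])):  # type: ignore[arg-type]
            g = conv.backward(leaky_relu_grad(a, g))
        return g * (1.0 / _INTENSITY_CEILING)

    @property
    def last_logits(self) -> np.ndarray:
        return self._cache["logit"]  # type: ignore[return-value]


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, seed=seed)


# -- checkpointing ----------------------------------------------------------

def save_generator(path, gen: Generator, stage_tag: str = "untrained") -> None:
    """Single-file checkpoint: parameters + config + training-stage tag."""
    meta = json.dumps(
        {"config": asdict(gen.config), "stage": stage_tag, "format": 1}
    )
    arrays = {f"p{i:04d}": a for i, a in enumerate(gen.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_generator(path) -> Tuple[Generator, str]:
    """Load a generator checkpoint; returns (generator, stage_tag)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["scale_set"] = tuple(cfg["scale_set"])
        gen = Generator(GeneratorConfig(**cfg), seed=0)
        arrays = [data[f"p{i:04d}"] for i in range(len(gen.params()))]
    gen.load_state_arrays(arrays)
    return gen, meta["stage"]
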