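"""Generator and U-shaped discriminator architectures.

The generator maps a standard-normal noise vector to a single-channel image
in [0, 1].  Each *generator block* is a pointwise (1x1) convolution for
channel reduction followed by two 4x4 fractionally strided convolutions,
each upsampling by 2, so a block multiplies the spatial resolution by 4.
Instance normalization and LeakyReLU sit between layers; convolutions that
feed a normalization carry no bias.  With the pointwise reduction switched
off, nothing reduces the channel dimension, so every feature map stays at
full width — the expensive baseline the reduced design is measured against.

The discriminator is an encoder–decoder ("U-shaped") network that assigns
every pixel a probability distribution over three labels: lung, background,
and fake.  A soft maximum (channel softmax) over the three output maps makes
them a distribution; there is no explicit "real" output — real-ness is
1 - P(fake).  Skip connections concatenate encoder features into the
matching decoder stage.  Grayscale input is replicated to 3 channels before
the encoder, matching an RGB-native encoder such as ResNet-50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import count_parameters, count_flops  # re-exported

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "count_parameters",
    "count_flops",
    "FULL_SCALE_CHANNELS",
]

#: Default generator channel schedule at 1,024x1,024 output: first entry is
#: the channel width of the 4x4 base feature map, the rest are the widths
#: after each of the four generator blocks.
FULL_SCALE_CHANNELS = (1024, 512, 256, 128, 64)


def _n_blocks(base: int, out: int) -> int:
    n = 0
    r = base
    while r < out:
        r *= 4
        n += 1
    if r != out:
        raise ValueError(
            f"output_resolution {out} is not base_resolution {base} x 4^k"
        )
    return n


@dataclass
class GeneratorSpec:
    noise_dim: int = 100
    base_resolution: int = 4
    output_resolution: int = 1024
    channel_schedule: tuple = FULL_SCALE_CHANNELS
    pointwise_reduction: bool = True

    def __post_init__(self):
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        n_blocks = _n_blocks(self.base_resolution, self.output_resolution)
        if len(self.channel_schedule) != n_blocks + 1:
            raise ValueError(
                f"channel_schedule must have {n_blocks + 1} entries (base width"
                f" plus one per block) for output {self.output_resolution} from"
                f" base {self.base_resolution}; got {len(self.channel_schedule)}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.channel_schedule) - 1

    @classmethod
    def full_scale(cls, pointwise_reduction: bool = True) -> "GeneratorSpec":
        return cls(pointwise_reduction=pointwise_reduction)

    @classmethod
    def desk(cls, output_resolution: int = 32) -> "GeneratorSpec":
        """Small schedule for CPU-scale work (output 32 or 64)."""
        if output_resolution == 32:
            return cls(base_resolution=2, output_resolution=32,
                       channel_schedule=(64, 32, 16))
        if output_resolution == 64:
            return cls(base_resolution=4, output_resolution=64,
                       channel_schedule=(64, 32, 16))
        raise ValueError("desk presets cover output_resolution 32 and 64")


@dataclass
class DiscriminatorSpec:
    encoder: str = "small-cnn"  # small-cnn | resnet50-random | resnet50-pretrained
    encoder_channels: tuple = (16, 32, 64, 128)  # small-cnn stage widths
    decoder_channel_schedule: tuple = (64, 48, 32, 16)
    n_classes: int = 3
    skip_connections: bool = True
    pretrained_weights: str | None = None  # .npz path for resnet50-pretrained
    image_head: bool = False  # whole-image real/fake head (classic-GAN ablation)

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        self.decoder_channel_schedule = tuple(int(c) for c in self.decoder_channel_schedule)
        if self.encoder not in ("small-cnn", "resnet50-random", "resnet50-pretrained"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        n_stages = 4 if self.encoder == "small-cnn" else 5
        if len(self.decoder_channel_schedule) != n_stages:
            raise ValueError(
                f"decoder_channel_schedule needs {n_stages} entries for"
                f" encoder {self.encoder!r} (one x2 upsampling per encoder"
                f" downsampling), got {len(self.decoder_channel_schedule)}"
            )

    @property
    def total_stride(self) -> int:
        return 16 if self.encoder == "small-cnn" else 32

    @classmethod
    def desk(cls) -> "DiscriminatorSpec":
        return cls(encoder_channels=(8, 16, 24, 32),
                   decoder_channel_schedule=(32, 24, 16, 8))


# ---------------------------------------------------------------------------
# generator


def _gen_block(c_in: int, c_out: int, reduce: bool, rng) -> list[nn.Layer]:
    """One generator block: optional 1x1 reduction, then two x2 upsamplings."""
    layers: list[nn.Layer] = []
    if reduce:
        layers += [nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng),
                   nn.InstanceNorm2d(c_out), nn.LeakyReLU(0.2)]
        width = c_out
    else:
        width = c_in
    layers += [nn.ConvTranspose2d(width, width, 4, stride=2, pad=1, bias=False, rng=rng),
               nn.InstanceNorm2d(width), nn.LeakyReLU(0.2),
               nn.ConvTranspose2d(width, width, 4, stride=2, pad=1, bias=False, rng=rng),
               nn.InstanceNorm2d(width), nn.LeakyReLU(0.2)]
    return layers


class Generator:
    """Callable noise → image network; ``g(z)`` with z of shape (n, noise_dim)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        cs = spec.channel_schedule
        base, c0 = spec.base_resolution, cs[0]
        layers: list[nn.Layer] = [
            nn.Dense(spec.noise_dim, base * base * c0, bias=False, rng=rng),
            nn.Reshape((c0, base, base)),
            nn.InstanceNorm2d(c0), nn.LeakyReLU(0.2),
        ]
        width = c0
        for i in range(spec.n_blocks):
            layers += _gen_block(width, cs[i + 1], spec.pointwise_reduction, rng)
            width = cs[i + 1] if spec.pointwise_reduction else width
        layers += [nn.Conv2d(width, 1, 1, bias=True, rng=rng),
                   nn.Tanh(), nn.AffineScale(0.5, 0.5)]
        self.net = nn.Sequential(layers)

    def __call__(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.spec.noise_dim:
            raise ValueError(f"noise must be (n, {self.spec.noise_dim})")
        return self.net.forward(z, train=train)

    forward = __call__

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def flops(self, batch: int = 1):
        return self.net.flops((batch, self.spec.noise_dim))


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


# ---------------------------------------------------------------------------
# discriminator encoders


def _small_cnn_stages(channels, rng) -> list[nn.Sequential]:
    """Four stride-2 stages mirroring the stage layout of a ResNet encoder,
    at a width that trains in minutes on one CPU."""
    stages = []
    c_prev = 3
    for c in channels:
        stages.append(nn.Sequential([
            nn.Conv2d(c_prev, c, 3, stride=2, pad=1, bias=False, rng=rng),
            nn.InstanceNorm2d(c), nn.LeakyReLU(0.2),
        ]))
        c_prev = c
    return stages


class _Bottleneck(nn.Layer):
    """ResNet bottleneck: 1x1 reduce → 3x3 → 1x1 expand, plus identity or
    projection shortcut.  Instance norm stands in for batch norm so the
    randomly initialized encoder is batch-size independent."""

    def __init__(self, c_in, c_mid, c_out, stride, rng):
        self.conv1 = nn.Conv2d(c_in, c_mid, 1, bias=False, rng=rng)
        self.n1 = nn.InstanceNorm2d(c_mid)
        self.conv2 = nn.Conv2d(c_mid, c_mid, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.n2 = nn.InstanceNorm2d(c_mid)
        self.conv3 = nn.Conv2d(c_mid, c_out, 1, bias=False, rng=rng)
        self.n3 = nn.InstanceNorm2d(c_out)
        self.act = nn.LeakyReLU(0.0)  # plain ReLU
        self.a1, self.a2 = nn.LeakyReLU(0.0), nn.LeakyReLU(0.0)
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.nproj = nn.InstanceNorm2d(c_out)
        else:
            self.proj = None

    def params(self):
        out = self.conv1.params() + self.conv2.params() + self.conv3.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train=True):
        h = self.a1.forward(self.n1.forward(self.conv1.forward(x, train), train), train)
        h = self.a2.forward(self.n2.forward(self.conv2.forward(h, train), train), train)
        h = self.n3.forward(self.conv3.forward(h, train), train)
        if self.proj is not None:
            sc = self.nproj.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.act.forward(h + sc, train)

    def backward(self, dout):
        d = self.act.backward(dout)
        dh = self.conv1.backward(self.n1.backward(self.a1.backward(
            self.conv2.backward(self.n2.backward(self.a2.backward(
                self.conv3.backward(self.n3.backward(d))))))))
        if self.proj is not None:
            dsc = self.proj.backward(self.nproj.backward(d))
        else:
            dsc = d
        return dh + dsc

    def flops(self, in_shape):
        total, shape = self.conv1.flops(in_shape)
        for lay in (self.conv2, self.conv3):
            ops, shape = lay.flops(shape)
            total += ops
        if self.proj is not None:
            ops, _ = self.proj.flops(in_shape)
            total += ops
        return total, shape


def _resnet50_stages(rng) -> list[nn.Sequential]:
    """ResNet-50 stage layout: stem (stride 2), maxpool + 3 bottlenecks,
    then 4, 6, and 3 bottlenecks, total stride 32."""

    def layer(c_in, c_mid, c_out, blocks, stride):
        mods = [_Bottleneck(c_in, c_mid, c_out, stride, rng)]
        mods += [_Bottleneck(c_out, c_mid, c_out, 1, rng) for _ in range(blocks - 1)]
        return mods

    stem = nn.Sequential([
        nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        nn.InstanceNorm2d(64), nn.LeakyReLU(0.0),
    ])
    return [
        stem,
        nn.Sequential([nn.MaxPool2d(3, 2, 1)] + layer(64, 64, 256, 3, 1)),
        nn.Sequential(layer(256, 128, 512, 4, 2)),
        nn.Sequential(layer(512, 256, 1024, 6, 2)),
        nn.Sequential(layer(1024, 512, 2048, 3, 2)),
    ]


def _decoder_block(c_in, c_out, rng) -> nn.Sequential:
    """Decoder block: 3x3 convolution, pointwise connector, then a 4x4
    fractionally strided convolution upsampling by 2."""
    return nn.Sequential([
        nn.Conv2d(c_in, c_in, 3, pad=1, bias=False, rng=rng),
        nn.InstanceNorm2d(c_in), nn.LeakyReLU(0.2),
        nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng),
        nn.InstanceNorm2d(c_out), nn.LeakyReLU(0.2),
        nn.ConvTranspose2d(c_out, c_out, 4, stride=2, pad=1, bias=False, rng=rng),
        nn.InstanceNorm2d(c_out), nn.LeakyReLU(0.2),
    ])


class Discriminator:
    """Image → per-pixel class probability map over (lung, background, fake).

    Input may be (n, H, W), (n, 1, H, W) or (n, 3, H, W); single-channel
    input is replicated to 3 channels.  Output is (n, n_classes, H, W) with
    every pixel's probabilities summing to 1.
    """

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.encoder == "small-cnn":
            self.stages = _small_cnn_stages(spec.encoder_channels, rng)
            enc_out = list(spec.encoder_channels)
        else:
            self.stages = _resnet50_stages(rng)
            enc_out = [64, 256, 512, 1024, 2048]
            if spec.encoder == "resnet50-pretrained":
                if spec.pretrained_weights is None:
                    raise ValueError(
                        "encoder='resnet50-pretrained' needs a pretrained_weights"
                        " .npz path (no weight source is bundled); use"
                        " 'resnet50-random' for a randomly initialized encoder"
                    )
                self._load_encoder_npz(spec.pretrained_weights)
        dec = spec.decoder_channel_schedule
        skips = enc_out[:-1][::-1]  # deepest-but-one ... shallowest
        self.blocks = []
        c_prev = enc_out[-1]
        for i, c in enumerate(dec):
            self.blocks.append(_decoder_block(c_prev, c, rng))
            c_prev = c + (skips[i] if spec.skip_connections and i < len(skips) else 0)
        self._skip_widths = skips
        self.head = nn.Conv2d(c_prev, spec.n_classes, 1, bias=True, rng=rng)
        self.softmax = nn.ChannelSoftmax()
        if spec.image_head:
            # ResNet-style classification tail: global average pool + dense
            self.img_dense = nn.Dense(enc_out[-1], 1, bias=True, rng=rng)
            self.img_sigmoid = nn.Sigmoid()
        self.last_image_prob_: np.ndarray | None = None
        self._cache = None
        self._img_hw = None

    # -- weights ----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for st in self.stages:
            out.extend(st.params())
        for bl in self.blocks:
            out.extend(bl.params())
        out.extend(self.head.params())
        if self.spec.image_head:
            out.extend(self.img_dense.params())
        return out

    def _load_encoder_npz(self, path: str) -> None:
        data = np.load(path)
        enc_params = []
        for st in self.stages:
            enc_params.extend(st.params())
        for i, p in enumerate(enc_params):
            arr = np.asarray(data[f"enc_{i}"], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"enc_{i}: shape {arr.shape} != {p.value.shape}")
            p.value[...] = arr

    # -- forward/backward --------------------------------------------------
    @staticmethod
    def _to_rgb(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] == 1:
            x = np.repeat(x, 3, axis=1)
        if x.shape[1] != 3:
            raise ValueError("input must have 1 or 3 channels")
        return x

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._to_rgb(x)
        h, w = x.shape[2], x.shape[3]
        if h != w or h % self.spec.total_stride:
            raise ValueError(
                f"input resolution {h}x{w} must be square and divisible by"
                f" the encoder's total stride {self.spec.total_stride}"
            )
        feats = []
        out = x
        for st in self.stages:
            out = st.forward(out, train=train)
            feats.append(out)
        skips = feats[:-1][::-1]
        h_dec = feats[-1]
        if self.spec.image_head:
            hw = feats[-1].shape[2] * feats[-1].shape[3]
            pooled = feats[-1].mean(axis=(2, 3))
            self.last_image_prob_ = self.img_sigmoid.forward(
                self.img_dense.forward(pooled, train=train), train=train)[:, 0]
            self._img_hw = (feats[-1].shape[2], feats[-1].shape[3], hw)
        used_skip = []
        for i, bl in enumerate(self.blocks):
            h_dec = bl.forward(h_dec, train=train)
            if self.spec.skip_connections and i < len(skips):
                used_skip.append(h_dec.shape[1])
                h_dec = np.concatenate([h_dec, skips[i]], axis=1)
        logits = self.head.forward(h_dec, train=train)
        probs = self.softmax.forward(logits, train=train)
        if train:
            self._cache = used_skip
        return probs

    forward = __call__

    def backward(self, dprobs: np.ndarray,
                 dimage_prob: np.ndarray | None = None) -> np.ndarray:
        """Backpropagate dL/dprobs (and optionally dL/d(image-level real
        probability)); accumulates parameter grads and returns dL/d(input
        image), summed back to a single channel."""
        used_skip = self._cache
        self._cache = None
        d = self.head.backward(self.softmax.backward(dprobs))
        n_st = len(self.stages)
        stage_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.blocks) - 1, -1, -1):
            if self.spec.skip_connections and i < n_st - 1:
                c_own = used_skip[i]
                d_skip = d[:, c_own:]
                # skips[i] is the output of encoder stage n_st - 2 - i
                j = n_st - 2 - i
                stage_grads[j] = stage_grads.get(j, 0) + d_skip
                d = d[:, :c_own]
            d = self.blocks[i].backward(d)
        g = d
        if dimage_prob is not None:
            if not self.spec.image_head:
                raise ValueError("no image head on this discriminator")
            dp = self.img_sigmoid.backward(np.asarray(dimage_prob)[:, None])
            dpool = self.img_dense.backward(dp)
            hb, wb, hw = self._img_hw
            g = g + dpool[:, :, None, None] / hw
        for j in range(n_st - 1, -1, -1):
            if j in stage_grads:
                g = g + stage_grads[j]
            g = self.stages[j].backward(g)
        return g.sum(axis=1, keepdims=True)

    def flops(self, in_shape):
        n = in_shape[0]
        shape = (n, 3, in_shape[-2], in_shape[-1])
        total = 0
        feats_shapes = []
        for st in self.stages:
            ops, shape = st.flops(shape)
            total += ops
            feats_shapes.append(shape)
        skips = feats_shapes[:-1][::-1]
        for i, bl in enumerate(self.blocks):
            ops, shape = bl.flops(shape)
            total += ops
            if self.spec.skip_connections and i < len(skips):
                shape = (shape[0], shape[1] + skips[i][1], shape[2], shape[3])
        ops, shape = self.head.flops(shape)
        return total + ops, shape


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)


# ---------------------------------------------------------------------------
# checkpoint helpers: weights + the full spec as embedded JSON


def save_model(path, generator: Generator | None, discriminator: Discriminator,
               extra: dict | None = None) -> None:
    arrays = {}
    meta = {"discriminator_spec": asdict(discriminator.spec), "extra": extra or {}}
    for i, p in enumerate(discriminator.params()):
        arrays[f"d_{i}"] = p.value
    if generator is not None:
        meta["generator_spec"] = asdict(generator.spec)
        for i, p in enumerate(generator.params()):
            arrays[f"g_{i}"] = p.value
    arrays["spec_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[Generator | None, Discriminator, dict]:
    data = np.load(path)
    meta = json.loads(bytes(data["spec_json"].tobytes()).decode())
    dspec = DiscriminatorSpec(**meta["discriminator_spec"])
    disc = Discriminator(dspec)
    for i, p in enumerate(disc.params()):
        p.value[...] = data[f"d_{i}"]
    gen = None
    if "generator_spec" in meta:
        gspec = GeneratorSpec(**meta["generator_spec"])
        gen = Generator(gspec)
        for i, p in enumerate(gen.params()):
            p.value[...] = data[f"g_{i}"]
    return gen, disc, meta.get("extra", {})
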