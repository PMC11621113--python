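"""Feedback-attention ladder CNN (FAL-CNN).

A VGG-style feedforward encoder is folded against a U-Net-style decoder:
after a forward pass, the decoder walks back up the encoder's per-level
activations (with forward skip connections) and emits multi-channel spatial
attention logits for every scale-group.  On the next pass those logits,
squashed through a sigmoid, multiplicatively gate the features entering each
scale-group (Feedback Attention Module, FAM).  The C-dimensional embedding of
every pass — the initial one plus one per feedback iteration — is kept in a
Feature Embedding Store (FES) of shape B x C x (N+1), reduced by a fully
connected layer to B x C and classified by a final FC + softmax.

Everything runs on the in-package numpy autodiff engine; with a fixed seed,
builds and forward passes are bitwise reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor


class ConfigurationError(ValueError):
    """Raised when a ModelSpec violates its invariants; names the field."""


# --------------------------------------------------------------------- spec

@dataclass(frozen=True)
class ScaleGroup:
    n_convs: int
    channels: int


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a FAL-CNN architecture.

    ``fc_width`` is C, the width of the fully connected layers and therefore
    of each stored embedding; ``n_iterations`` is N, the number of feedback
    iterations the FES is dimensioned for (0..4 in the reference setup).
    """

    scale_groups: tuple[ScaleGroup, ...]
    fc_width: int
    n_classes: int
    n_iterations: int
    input_size: int
    gate: str = "sigmoid_mul"
    preset: str | None = None

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ConfigurationError(
                f"n_iterations must be >= 0, got {self.n_iterations}")
        if len(self.scale_groups) < 2:
            raise ConfigurationError(
                f"scale_groups needs at least 2 groups, got {len(self.scale_groups)}")
        if self.input_size % (2 ** len(self.scale_groups)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by "
                f"2^{len(self.scale_groups)} (scale_groups)")
        if self.fc_width < 1:
            raise ConfigurationError(f"fc_width must be positive, got {self.fc_width}")
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.gate != "sigmoid_mul":
            raise ConfigurationError(f"unknown gate {self.gate!r}")
        for g in self.scale_groups:
            if g.n_convs < 1 or g.channels < 1:
                raise ConfigurationError(f"invalid scale_group {g}")

    @property
    def n_levels(self) -> int:
        return len(self.scale_groups)

    def level_size(self, level: int) -> int:
        """Spatial side length H_l = W_l = input_size / 2^l."""
        return self.input_size >> level

    def fam_in_channels(self, level: int) -> int:
        """Channel count of the features entering the FAM at ``level``."""
        return 3 if level == 0 else self.scale_groups[level - 1].channels

    @staticmethod
    def vgg19(n_classes: int = 9, n_iterations: int = 1) -> "ModelSpec":
        return ModelSpec(
            scale_groups=tuple(ScaleGroup(n, c) for n, c in
                               zip((2, 2, 4, 4, 4), (64, 128, 256, 512, 512))),
            fc_width=4096, n_classes=n_classes, n_iterations=n_iterations,
            input_size=224, preset="vgg19")

    @staticmethod
    def mini(n_classes: int = 3, n_iterations: int = 1,
             input_size: int = 64) -> "ModelSpec":
        """Small configuration for CPU-scale experiments and tests."""
        return ModelSpec(
            scale_groups=(ScaleGroup(1, 8), ScaleGroup(1, 16), ScaleGroup(1, 32)),
            fc_width=64, n_classes=n_classes, n_iterations=n_iterations,
            input_size=input_size, preset="mini")

    def to_yaml(self) -> str:
        d = {"scale_groups": [[g.n_convs, g.channels] for g in self.scale_groups],
             "fc_width": self.fc_width, "n_classes": self.n_classes,
             "n_iterations": self.n_iterations, "input_size": self.input_size,
             "gate": self.gate, "preset": self.preset}
        return yaml.safe_dump(d)

    @staticmethod
    def from_yaml(text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        return ModelSpec(
            scale_groups=tuple(ScaleGroup(n, c) for n, c in d["scale_groups"]),
            fc_width=d["fc_width"], n_classes=d["n_classes"],
            n_iterations=d["n_iterations"], input_size=d["input_size"],
            gate=d.get("gate", "sigmoid_mul"), preset=d.get("preset"))


def fam_site_indices(spec: ModelSpec) -> list[int]:
    """Layer indices of the FAM insertion sites in the plain encoder.

    Counted over the un-augmented sequential encoder (conv and ReLU modules
    plus one pooling module per group), each FAM sits immediately before the
    first convolution of its scale-group; for the vgg19 preset this yields
    the canonical indices [0, 5, 10, 19, 28].
    """
    idx, pos = [], 0
    for g in spec.scale_groups:
        idx.append(pos)
        pos += 2 * g.n_convs + 1  # conv+relu pairs, then the pool
    return idx


# ------------------------------------------------------------- domain types

@dataclass
class LevelActivation:
    """Batched feature map of one encoder level (B x C_l x H_l x W_l)."""
    level: int
    features: np.ndarray


@dataclass
class FeedbackStack:
    """Per-level attention logits emitted by one decoder run."""
    iteration: int
    logits: list[np.ndarray]  # one array per FAM site, shallowest first


@dataclass
class FeatureEmbeddingStore:
    """Embeddings of every feedforward pass, shape B x C x (N+1)."""
    embeddings: np.ndarray


@dataclass
class ModelOutput:
    probs: np.ndarray
    predicted_class: np.ndarray
    attention: list[FeedbackStack]
    embeddings: FeatureEmbeddingStore


# -------------------------------------------------------------------- model

class _Conv:
    def __init__(self, rng, c_in, c_out):
        fan_in = c_in * 9
        self.w = Tensor(ad.kaiming_init(rng, (c_out, c_in, 3, 3), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)


class _Linear:
    def __init__(self, rng, n_in, n_out):
        self.w = Tensor(ad.kaiming_init(rng, (n_out, n_in), n_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.linear(x, self.w, self.b)


class Model:
    """A built FAL-CNN: encoder groups, decoder ladder, FES head."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        L = spec.n_levels
        chans = [g.channels for g in spec.scale_groups]

        # encoder: per group, n_convs 3x3 convolutions (ReLU), then 2x2 pool
        self.enc_groups: list[list[_Conv]] = []
        c_in = 3
        for g in spec.scale_groups:
            convs = []
            for _ in range(g.n_convs):
                convs.append(_Conv(rng, c_in, g.channels))
                c_in = g.channels
            self.enc_groups.append(convs)

        bottom = spec.level_size(L - 1) // 2  # spatial side after final pool
        self.fc1 = _Linear(rng, chans[-1] * bottom * bottom, spec.fc_width)
        self.fc2 = _Linear(rng, spec.fc_width, spec.fc_width)

        # decoder ladder: deepest-to-shallowest merge + per-level logit head
        self.dec_merge: list[_Conv] = [None] * L
        self.dec_head: list[_Conv] = [None] * L
        for lvl in range(L - 1, -1, -1):
            carry = chans[lvl + 1] if lvl < L - 1 else chans[L - 1]
            self.dec_merge[lvl] = _Conv(rng, carry + chans[lvl], chans[lvl])
            self.dec_head[lvl] = _Conv(rng, chans[lvl], spec.fam_in_channels(lvl))

        self.fes_fc = _Linear(rng, spec.fc_width * (spec.n_iterations + 1),
                              spec.fc_width)
        self.cls_fc = _Linear(rng, spec.fc_width, spec.n_classes)
        # down-scaled classification init: training starts from a near-uniform
        # softmax (loss ~ log K) instead of arbitrarily confident logits,
        # while keeping gradient flow into the layers below nonzero
        self.cls_fc.w.data *= 0.01

        self.decoder_calls = 0  # instrumentation: counts decoder executions
        self.norm_mean: np.ndarray | None = None  # per-channel, set by training
        self.norm_std: np.ndarray | None = None

    # -- parameter access -------------------------------------------------
    def named_params(self) -> dict[str, Tensor]:
        out = {}
        for gi, convs in enumerate(self.enc_groups):
            for ci, c in enumerate(convs):
                out[f"enc.g{gi}.c{ci}.w"] = c.w
                out[f"enc.g{gi}.c{ci}.b"] = c.b
        for name, lin in (("fc1", self.fc1), ("fc2", self.fc2),
                          ("fes_fc", self.fes_fc), ("cls_fc", self.cls_fc)):
            out[f"{name}.w"] = lin.w
            out[f"{name}.b"] = lin.b
        for lvl in range(self.spec.n_levels):
            out[f"dec.m{lvl}.w"] = self.dec_merge[lvl].w
            out[f"dec.m{lvl}.b"] = self.dec_merge[lvl].b
            out[f"dec.h{lvl}.w"] = self.dec_head[lvl].w
            out[f"dec.h{lvl}.b"] = self.dec_head[lvl].b
        return out

    def params(self) -> list[Tensor]:
        return list(self.named_params().values())

    def decoder_params(self) -> list[Tensor]:
        return [t for n, t in self.named_params().items() if n.startswith("dec.")]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- graph builders ----------------------------------------------------
    def _encode(self, x: Tensor, gates: list[Tensor] | None):
        """One feedforward pass; returns (embedding, per-level activations)."""
        if x.data.ndim != 4 or x.data.shape[1] != 3 or \
                x.data.shape[2] != self.spec.input_size or \
                x.data.shape[3] != self.spec.input_size:
            raise ValueError(
                f"expected images (B, 3, {self.spec.input_size}, "
                f"{self.spec.input_size}), got {x.data.shape}")
        levels: list[Tensor] = []
        h = x
        for lvl, convs in enumerate(self.enc_groups):
            if gates is not None:
                g = gates[lvl]
                if g.data.shape != h.data.shape:
                    raise ValueError(
                        f"gate shape {g.data.shape} != features {h.data.shape} "
                        f"at level {lvl}")
                h = ad.mul(h, g)
            for c in convs:
                h = ad.relu(c(h))
            levels.append(h)          # pre-pool: H_l = input_size / 2^l
            h = ad.maxpool2(h)
        B = h.data.shape[0]
        flat = ad.reshape(h, (B, -1))
        emb = ad.relu(self.fc2(ad.relu(self.fc1(flat))))
        return emb, levels

    def _decode(self, levels: list[Tensor]) -> list[Tensor]:
        """U-Net style ascent producing attention logits per FAM site."""
        L = self.spec.n_levels
        if len(levels) != L:
            raise ValueError(f"expected {L} level activations, got {len(levels)}")
        self.decoder_calls += 1
        d = ad.maxpool2(levels[-1])
        logits: list[Tensor] = [None] * L
        for lvl in range(L - 1, -1, -1):
            d = ad.upsample2x(d)
            d = ad.relu(self.dec_merge[lvl](ad.concat([d, levels[lvl]], axis=1)))
            logits[lvl] = self.dec_head[lvl](d)
        return logits

    def _forward_graph(self, x: Tensor, n_iterations: int):
        """Unrolled multi-pass graph; returns dict of Tensors."""
        spec = self.spec
        if n_iterations < 0 or n_iterations > spec.n_iterations:
            raise ValueError(
                f"n_iterations {n_iterations} outside 0..{spec.n_iterations}")
        embs: list[Tensor] = []
        attn: list[list[Tensor]] = []
        emb, levels = self._encode(x, None)
        embs.append(emb)
        for _k in range(n_iterations):
            fb_logits = self._decode(levels)
            attn.append(fb_logits)
            gates = [ad.sigmoid(l) for l in fb_logits]
            emb, levels = self._encode(x, gates)
            embs.append(emb)
        # FES is dimensioned for the configured N; unused slots stay zero
        missing = spec.n_iterations + 1 - len(embs)
        stack = list(embs)
        if missing:
            B = x.data.shape[0]
            stack += [Tensor(np.zeros((B, spec.fc_width), dtype=np.float32))] * missing
        fes_flat = ad.concat(stack, axis=1)        # B x C(N+1)
        reduced = ad.relu(self.fes_fc(fes_flat))   # B x C
        logits = self.cls_fc(reduced)
        return {"logits": logits, "embs": embs, "attn": attn}


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct a FAL-CNN with seeded (He-normal) weight initialisation."""
    return Model(spec, seed)


# --------------------------------------------------------- public operations

def gate(logits: np.ndarray) -> np.ndarray:
    """Map decoder logits to multiplicative attention gates in (0, 1)."""
    return ad.sigmoid_np(logits)


def fam_apply(features: LevelActivation,
              gate_values: np.ndarray | None) -> LevelActivation:
    """Multiplicative feedback attention: features ⊙ gates (identity if None)."""
    if gate_values is None:
        return LevelActivation(features.level, features.features.copy())
    gate_values = np.asarray(gate_values, dtype=np.float32)
    if gate_values.shape != features.features.shape:
        raise ValueError(
            f"gate shape {gate_values.shape} != feature shape "
            f"{features.features.shape}")
    return LevelActivation(features.level, features.features * gate_values)


def encoder_pass(model: Model, images: np.ndarray,
                 feedback: FeedbackStack | None = None):
    """Run the encoder once; returns (embedding B x C, level activations).

    ``feedback`` carries raw decoder logits; they are squashed through the
    sigmoid gate here before the multiplicative modules apply them.
    """
    with ad.no_grad():
        x = Tensor(np.asarray(images, dtype=np.float32))
        gates = None
        if feedback is not None:
            gates = [Tensor(gate(l)) for l in feedback.logits]
        emb, levels = model._encode(x, gates)
    return emb.data, [LevelActivation(l, t.data) for l, t in enumerate(levels)]


def decoder_pass(model: Model, levels: list[LevelActivation]) -> FeedbackStack:
    """Run the decoder on encoder level activations; returns attention logits."""
    with ad.no_grad():
        lts = [Tensor(lv.features) for lv in
               sorted(levels, key=lambda lv: lv.level)]
        logits = model._decode(lts)
    return FeedbackStack(iteration=0, logits=[t.data for t in logits])


def forward(model: Model, images: np.ndarray,
            n_iterations: int | None = None) -> ModelOutput:
    """Full multi-pass inference; images must already be standardized."""
    if n_iterations is None:
        n_iterations = model.spec.n_iterations
    with ad.no_grad():
        out = model._forward_graph(Tensor(np.asarray(images, dtype=np.float32)),
                                   n_iterations)
    probs = ad.softmax_np(out["logits"].data, axis=1)
    fes = np.stack([e.data for e in out["embs"]]
                   + [np.zeros_like(out["embs"][0].data)]
                   * (model.spec.n_iterations + 1 - len(out["embs"])), axis=2)
    return ModelOutput(
        probs=probs,
        predicted_class=probs.argmax(axis=1),
        attention=[FeedbackStack(k + 1, [t.data for t in stack])
                   for k, stack in enumerate(out["attn"])],
        embeddings=FeatureEmbeddingStore(fes))


# -------------------------------------------------------- input preparation

def standardize(images: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """(B, H, W, 3) or (H, W, 3) uint8/float -> (B, 3, H, W) standardized."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    x = x.transpose(0, 3, 1, 2)
    mean = np.asarray(mean, dtype=np.float32).reshape(1, 3, 1, 1)
    std = np.asarray(std, dtype=np.float32).reshape(1, 3, 1, 1)
    return (x - mean) / np.maximum(std, 1e-6)


def classify(model: Model, images: np.ndarray,
             n_iterations: int | None = None) -> ModelOutput:
    """Standardize raw (B, H, W, 3) images with the model's stored training
    statistics and run ``forward``."""
    if model.norm_mean is None:
        raise ValueError("model has no stored normalization statistics; "
                         "train it or set norm_mean/norm_std")
    x = standardize(images, model.norm_mean, model.norm_std)
    return forward(model, x, n_iterations)


# ------------------------------------------------------------ serialization

def save_checkpoint(model: Model, path: str) -> None:
    """Native format: npz archive of weights with the YAML spec embedded."""
    arrays = {name: t.data for name, t in model.named_params().items()}
    arrays["_spec_yaml"] = np.frombuffer(model.spec.to_yaml().encode(), dtype=np.uint8)
    arrays["_seed"] = np.array([model.seed])
    if model.norm_mean is not None:
        arrays["_norm_mean"] = model.norm_mean
        arrays["_norm_std"] = model.norm_std
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str) -> Model:
    with np.load(path) as z:
        spec = ModelSpec.from_yaml(bytes(z["_spec_yaml"]).decode())
        model = Model(spec, seed=int(z["_seed"][0]))
        for name, t in model.named_params().items():
            t.data = z[name].astype(np.float32)
        if "_norm_mean" in z:
            model.norm_mean = z["_norm_mean"].astype(np.float32)
            model.norm_std = z["_norm_std"].astype(np.float32)
    return model


def load_encoder_weights(model: Model, weights: dict[str, np.ndarray]) -> None:
    """Hook for initialising encoder convolutions from pretrained weights.

    ``weights`` maps parameter names (``enc.g{group}.c{conv}.w`` / ``.b``) to
    arrays of matching shape; unknown names raise, decoder/head weights are
    untouched.
    """
    named = model.named_params()
    for name, arr in weights.items():
        if not name.startswith("enc."):
            raise KeyError(f"{name!r} is not an encoder parameter")
        if name not in named:
            raise KeyError(f"unknown encoder parameter {name!r}")
        arr = np.asarray(arr, dtype=np.float32)
        if arr.shape != named[name].data.shape:
            raise ValueError(f"shape mismatch for {name}: "
                             f"{arr.shape} vs {named[name].data.shape}")
        named[name].data = arr


def save_attention_archive(output: ModelOutput, path: str) -> None:
    """Dump per-iteration, per-level attention logits keyed iter{k}/level{l}."""
    arrays = {}
    for stack in output.attention:
        for lvl, arr in enumerate(stack.logits):
            arrays[f"iter{stack.iteration}/level{lvl}"] = arr
    np.savez_compressed(path, **arrays)
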