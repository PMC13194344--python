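"""Multi-task vision-language model: encoders, cross-attention fusion,
classification head and text decoder, plus the ablation variants.

Architecture
------------
Two encoders produce token-level features and a mean-pooled embedding per
modality.  A cross-attention layer attends the pooled embedding of each
modality over the token features of the other, yielding one context vector
per stream.  Each head consumes ``[embedding ‖ context]`` (embedding first,
context second):

* landmark classifier — 3-layer MLP over ``[image_pooled ‖ image_context]``
  with a per-class sigmoid;
* text decoder — 2-layer LSTM whose initial hidden/cell states are projected
  from ``[text_pooled ‖ text_context]``, emitting tokens greedily (argmax).

The decoder is specified as bidirectional in its lineage; since causal
generation cannot condition on future outputs, the two stacked layers here
run forward-only and the bidirectional summarisation of the conditioning
input is carried by the (bidirectionally self-attending) text encoder.

Encoders are pluggable: any object mapping the raw input to
``(token_features, pooled)`` of width ``embed_dim`` with ``frozen``/
``freeze()`` satisfies the contract.  The built-in desk-scale defaults are a
4-block conv net (images) and a 2-layer transformer encoder (text); both act
as stand-ins for domain pre-trained encoders and are frozen by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .textproc import TokenSequence, Vocabulary

VARIANTS = ("A_full", "B_image_only", "C_text_only", "D_no_cross_attention")


@dataclass
class ModelConfig:
    embed_dim: int = 128
    n_classes: int = 16
    vocab_size: int = 256
    image_size: int = 64
    conv_channels: tuple[int, ...] = (16, 32, 64, 128)
    text_layers: int = 2
    text_heads: int = 4
    max_text_len: int = 300
    attention_heads: int = 4
    classifier_hidden: tuple[int, int] = (256, 128)
    decoder_hidden: int = 128
    decoder_layers: int = 2
    max_gen_len: int = 32
    train_attention: bool = False

    def __post_init__(self) -> None:
        if self.conv_channels[-1] != self.embed_dim:
            raise ValueError("last conv channel count must equal embed_dim")
        if self.embed_dim % self.attention_heads:
            raise ValueError("embed_dim must be divisible by attention_heads")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        d["classifier_hidden"] = tuple(d["classifier_hidden"])
        return cls(**d)


@dataclass
class EmbeddingSet:
    image_tokens: Tensor | None   # (B, P, d)
    image_pooled: Tensor | None   # (B, d)
    text_tokens: Tensor | None    # (B, T, d)
    text_pooled: Tensor | None    # (B, d)
    text_mask: np.ndarray | None  # (B, T) bool, True = real token


@dataclass
class FusedFeatures:
    image_context: Tensor | None      # text-informed, (B, d)
    text_context: Tensor | None       # image-informed, (B, d)
    classifier_input: Tensor | None   # [image_pooled ‖ image_context], (B, 2d)
    decoder_init: Tensor | None       # [text_pooled ‖ text_context], (B, 2d)
    attention_maps: dict[str, np.ndarray] = field(default_factory=dict)


def _token_norm(t: Tensor) -> Tensor:
    """Per-token feature normalisation (parameter-free layer norm)."""
    mu = t.mean(axis=-1, keepdims=True)
    c = t - mu
    var = (c * c).mean(axis=-1, keepdims=True)
    return c * ((var + 1e-5) ** -0.5)


class ConvImageEncoder(nn.Module):
    """Frozen-by-default featuriser: conv stack + positional code + patch bypass.

    Stands in for a domain pre-trained vision encoder.  Three ingredients keep
    the mean-pooled embedding informative about *where* content appears (the
    property contrastive pre-training buys a real encoder):

    * a 4-block strided conv stack (He-scaled init) for colour/texture mixing,
    * per-token feature normalisation followed by a fixed random sign code per
      grid position, so different positions occupy distinguishable subspaces,
    * an unshared linear projection of each raw patch added to its token
      (a local bypass that survives pooling).
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        chans = config.conv_channels
        self.blocks = []
        c_in = 3
        for c_out in chans:
            conv = nn.Conv2d(c_in, c_out, kernel=3, stride=2, rng=rng, pad=1)
            conv.weight.data *= np.sqrt(6.0)   # He-uniform gain for ReLU
            self.blocks.append(conv)
            c_in = c_out
        self.grid = config.image_size // (2 ** len(chans))
        self.d = config.embed_dim
        P = self.grid * self.grid
        self.pos_code = Tensor(
            rng.choice([-1.0, 1.0], size=(1, P, self.d)).astype(nn.DTYPE),
            requires_grad=True)
        patch = config.image_size // self.grid
        self._patch = patch
        self.patch_proj = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(patch * patch * 3),
                       size=(P, patch * patch * 3, self.d)).astype(nn.DTYPE),
            requires_grad=True)

    def _patches(self, x: Tensor) -> Tensor:
        """(B, H, W, 3) -> (P, B, patch*patch*3)."""
        B = x.shape[0]
        g, p = self.grid, self._patch
        t = x.reshape(B, g, p, g, p, 3).transpose(1, 3, 0, 2, 4, 5)
        return t.reshape(g * g, B, p * p * 3)

    def __call__(self, images: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        x = images if isinstance(images, Tensor) else Tensor(
            np.asarray(images, dtype=nn.DTYPE))
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected (B, H, W, 3) images, got {x.shape}")
        h = x
        for block in self.blocks:
            h = block(h).relu()
        conv_tokens = _token_norm(
            h.reshape(h.shape[0], self.grid * self.grid, self.d))
        bypass = (self._patches(x) @ self.patch_proj)      # (P, B, d)
        bypass = _token_norm(bypass).transpose(1, 0, 2)    # (B, P, d)
        tokens = conv_tokens * self.pos_code + bypass
        return tokens, tokens.mean(axis=1)


class TransformerTextEncoder(nn.Module):
    """2-layer transformer encoder; pooled output is the pad-masked mean.

    Frozen by default as a stand-in for a text encoder pre-trained with a
    bag-of-words objective.  The blocks use a near-identity residual init
    (scaled-down output projections), so the pooled embedding approximates a
    bag of token embeddings plus a positional mean — the smooth,
    content-based geometry such pre-training produces, which the focal
    cosine-similarity objective needs to yield informative gradients.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d = config.embed_dim
        self.token_embed = nn.Embedding(config.vocab_size, d, rng)
        self.pos_embed = nn.Embedding(config.max_text_len, d, rng)
        self.blocks = [nn.TransformerBlock(d, config.text_heads, rng,
                                           residual_scale=0.1)
                       for _ in range(config.text_layers)]
        self.norm = nn.LayerNorm(d)
        self.vocab_size = config.vocab_size
        self.max_len = config.max_text_len

    @property
    def embedding_table(self) -> np.ndarray:
        return self.token_embed.weight.data

    def __call__(self, ids: np.ndarray, mask: np.ndarray | None = None
                 ) -> tuple[Tensor, Tensor]:
        ids = np.asarray(ids)
        if ids.max(initial=0) >= self.vocab_size:
            raise ValueError("token id out of vocabulary range")
        if ids.shape[1] > self.max_len:
            raise ValueError(f"sequence longer than max_text_len={self.max_len}")
        if mask is None:
            mask = np.ones(ids.shape, dtype=bool)
        return self.encode_embedded(self.token_embed(ids), mask)

    def encode_embedded(self, embedded: Tensor, mask: np.ndarray
                        ) -> tuple[Tensor, Tensor]:
        """Forward from (possibly soft / probability-weighted) token
        embeddings instead of hard ids — the differentiable entry point used
        by the focal cosine-similarity objective."""
        x = embedded + self.pos_embed(np.arange(embedded.shape[1]))
        for block in self.blocks:
            x = block(x, mask=mask)
        tokens = self.norm(x)
        # pad positions excluded from the pooled mean
        m = mask.astype(nn.DTYPE)[..., None]
        denom = np.maximum(m.sum(axis=1), 1.0).astype(nn.DTYPE)
        pooled = (tokens * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)
        return tokens, pooled


class LandmarkClassifier(nn.Module):
    """3-layer fully-connected head -> per-class sigmoid probabilities."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        h1, h2 = config.classifier_hidden
        self.fc1 = nn.Linear(2 * config.embed_dim, h1, rng)
        self.fc2 = nn.Linear(h1, h2, rng)
        self.fc3 = nn.Linear(h2, config.n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid()


class TextDecoder(nn.Module):
    """2-layer LSTM generator conditioned through its initial state."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, h = config.embed_dim, config.decoder_hidden
        self.layers = config.decoder_layers
        self.hidden = h
        self.token_embed = nn.Embedding(config.vocab_size, d, rng)
        self.init_proj = nn.Linear(2 * d, 2 * self.layers * h, rng)
        self.lstm = nn.LSTM(d, h, self.layers, rng)
        self.out = nn.Linear(h, config.vocab_size, rng)

    def initial_state(self, decoder_init: Tensor) -> list[tuple[Tensor, Tensor]]:
        z = self.init_proj(decoder_init).tanh()
        h = self.hidden
        state = []
        for layer in range(self.layers):
            state.append((z[:, 2 * layer * h:(2 * layer + 1) * h],
                          z[:, (2 * layer + 1) * h:(2 * layer + 2) * h]))
        return state

    def teacher_forced(self, decoder_init: Tensor, input_ids: np.ndarray) -> Tensor:
        """Logits (B, T, V) for each position given ground-truth prefixes."""
        state = self.initial_state(decoder_init)
        emb = self.token_embed(np.asarray(input_ids))
        xproj = self.lstm.project_inputs(emb)   # one batched matmul
        hiddens = []
        for t in range(input_ids.shape[1]):
            o, state = self.lstm.step(xproj[:, t, :], state, x_projected=True)
            hiddens.append(o)
        return self.out(ad.stack(hiddens, axis=1))

    def generate(self, decoder_init: Tensor, start_ids: list[list[int]],
                 end_id: int, max_gen_len: int) -> list[list[int]]:
        """Batched greedy (argmax) decoding; stops at END or max_gen_len."""
        B = decoder_init.shape[0]
        state = self.initial_state(decoder_init)
        with ad.no_grad():
            # feed the start tokens (outputs before the last are discarded)
            max_s = max(len(s) for s in start_ids)
            last_logits = None
            for t in range(max_s):
                ids = np.array([s[min(t, len(s) - 1)] for s in start_ids])
                o, state = self.lstm.step(self.token_embed(ids), state)
                last_logits = self.out(o)
            done = np.zeros(B, dtype=bool)
            result: list[list[int]] = [[] for _ in range(B)]
            for _ in range(max_gen_len):
                nxt = last_logits.data.argmax(axis=-1)
                for b in range(B):
                    if not done[b]:
                        if int(nxt[b]) == end_id:
                            done[b] = True
                        else:
                            result[b].append(int(nxt[b]))
                if done.all():
                    break
                o, state = self.lstm.step(self.token_embed(nxt), state)
                last_logits = self.out(o)
        return result


class MultiTaskVLM(nn.Module):
    """The fused multi-task model (one ablation variant per instance)."""

    def __init__(self, config: ModelConfig, variant: str = "A_full",
                 seed: int = 0, image_encoder=None, text_encoder=None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.config = config
        self.variant = variant
        ss = np.random.SeedSequence([seed, 0x30DE1])
        r_img, r_txt, r_attn, r_cls, r_dec = (
            np.random.default_rng(s) for s in ss.spawn(5))

        has_image = variant != "C_text_only"
        has_text = variant != "B_image_only"
        has_attention = variant in ("A_full",)

        self.image_encoder = (image_encoder or ConvImageEncoder(config, r_img)) \
            if has_image else None
        self.text_encoder = (text_encoder or TransformerTextEncoder(config, r_txt)) \
            if has_text else None
        self.attn_image_to_text = nn.MultiHeadAttention(
            config.embed_dim, config.attention_heads, r_attn) if has_attention else None
        self.attn_text_to_image = nn.MultiHeadAttention(
            config.embed_dim, config.attention_heads, r_attn) if has_attention else None
        # the cross-attention projections are frozen by default at desk
        # scale: the fusion layer is a stable feature channel carrying each
        # modality's content to the other head, rather than a trainable,
        # drifting input that the small heads would have to chase
        if has_attention and not config.train_attention:
            for attn in (self.attn_image_to_text, self.attn_text_to_image):
                attn.freeze()
        self.classifier = LandmarkClassifier(config, r_cls) if has_image else None
        self.decoder = TextDecoder(config, r_dec) if has_text else None

    # -- encoding -------------------------------------------------------------

    def encode_image(self, images) -> tuple[Tensor, Tensor]:
        if self.image_encoder is None:
            raise ValueError(f"variant {self.variant} has no image pathway")
        return self.image_encoder(images)

    def encode_text(self, ids: np.ndarray, mask: np.ndarray | None = None
                    ) -> tuple[Tensor, Tensor]:
        if self.text_encoder is None:
            raise ValueError(f"variant {self.variant} has no text pathway")
        return self.text_encoder(ids, mask)

    def embed(self, images=None, text_ids=None, text_mask=None) -> EmbeddingSet:
        it = ip = tt = tp = None
        if images is not None and self.image_encoder is not None:
            it, ip = self.encode_image(images)
        if text_ids is not None and self.text_encoder is not None:
            tt, tp = self.encode_text(text_ids, text_mask)
        return EmbeddingSet(it, ip, tt, tp, text_mask)

    # -- fusion ---------------------------------------------------------------

    def cross_attend(self, emb: EmbeddingSet) -> FusedFeatures:
        """Pooled-query cross-attention in both directions, then concatenation
        [embedding ‖ context].  Variants without attention substitute zero
        contexts of matching width so head shapes stay identical."""
        d = self.config.embed_dim
        maps: dict[str, np.ndarray] = {}

        def zeros_like_pooled(p: Tensor) -> Tensor:
            return Tensor(np.zeros((p.shape[0], d), dtype=nn.DTYPE))

        image_context = text_context = None
        classifier_input = decoder_init = None

        if self.variant == "A_full" and emb.image_pooled is not None \
                and emb.text_pooled is not None:
            q_img = emb.image_pooled.reshape(emb.image_pooled.shape[0], 1, d)
            ctx, w = self.attn_image_to_text(q_img, emb.text_tokens,
                                             key_mask=emb.text_mask)
            image_context = ctx.reshape(ctx.shape[0], d)
            maps["image_to_text"] = w.mean(axis=1)[:, 0, :]   # (B, T)
            q_txt = emb.text_pooled.reshape(emb.text_pooled.shape[0], 1, d)
            ctx, w = self.attn_text_to_image(q_txt, emb.image_tokens)
            text_context = ctx.reshape(ctx.shape[0], d)
            maps["text_to_image"] = w.mean(axis=1)[:, 0, :]   # (B, P)
        if emb.image_pooled is not None and self.classifier is not None:
            ic = image_context if image_context is not None \
                else zeros_like_pooled(emb.image_pooled)
            classifier_input = ad.concat([emb.image_pooled, ic], axis=-1)
        if emb.text_pooled is not None and self.decoder is not None:
            tc = text_context if text_context is not None \
                else zeros_like_pooled(emb.text_pooled)
            decoder_init = ad.concat([emb.text_pooled, tc], axis=-1)
        return FusedFeatures(image_context, text_context, classifier_input,
                             decoder_init, maps)

    # -- heads ----------------------------------------------------------------

    def classify_landmarks(self, fused: FusedFeatures) -> Tensor:
        if self.classifier is None or fused.classifier_input is None:
            raise ValueError(f"variant {self.variant} produces no classifications")
        return self.classifier(fused.classifier_input)

    def generate_text(self, fused: FusedFeatures, start_tokens: list[list[int]],
                      vocab: Vocabulary, mode: str = "greedy",
                      max_gen_len: int | None = None) -> list[TokenSequence]:
        if self.decoder is None or fused.decoder_init is None:
            raise ValueError(f"variant {self.variant} produces no text outputs")
        if mode != "greedy":
            raise ValueError("only greedy (argmax) decoding is supported")
        if not start_tokens or any(len(s) == 0 for s in start_tokens):
            raise ValueError("start_tokens must be non-empty")
        n = self.config.max_gen_len if max_gen_len is None else max_gen_len
        ids = self.decoder.generate(fused.decoder_init, start_tokens,
                                    vocab.end_id, n)
        return [TokenSequence(np.array(s, dtype=np.int64)) for s in ids]

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        state = self.state_dict()
        meta = {"config": self.config.to_dict(), "variant": self.variant}
        np.savez(path, __meta__=json.dumps(meta),
                 **{k: v for k, v in state.items()})

    @classmethod
    def load(cls, path) -> "MultiTaskVLM":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        model = cls(ModelConfig.from_dict(meta["config"]), meta["variant"])
        model.load_state_dict({k: archive[k] for k in archive.files
                               if k != "__meta__"})
        return model


def make_variant(config: ModelConfig, variant: str, seed: int = 0,
                 **encoders) -> MultiTaskVLM:
    """Construct one of the ablation variants.

    A_full — both streams fused by cross-attention;
    B_image_only — text encoder and decoder removed, classifier sees
        [image_pooled ‖ 0];
    C_text_only — image pathway removed, decoder sees [text_pooled ‖ 0];
    D_no_cross_attention — both heads kept, contexts replaced by zeros
        (streams independent, no attention parameters).
    """
    return MultiTaskVLM(config, variant=variant, seed=seed, **encoders)
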