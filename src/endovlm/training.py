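"""Multi-task batch construction and the single-pass joint training loop.

Every optimizer step consumes one :class:`TaskBatch` — the concatenation of
three equal-sized sub-batches, one per task — runs a joint forward pass
through the shared (frozen) encoders and all three heads, combines the three
losses under the configured strategy, and performs exactly one backward pass
and parameter update.  Teacher forcing conditions both text heads during
training; the learning rate warms up linearly over the first epochs; early
stopping monitors the combined loss on a 90/10 internal validation split at
activity granularity.

When encoders are frozen (the default, mirroring the downstream-training
setting the architecture is designed for), their outputs are precomputed and
cached, which is what makes desk-scale CPU training practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from . import objectives as obj
from .autodiff import Tensor
from .model import EmbeddingSet, MultiTaskVLM
from .objectives import LossStrategy
from .synth.dataset import DatasetManifest, FrameRecord, load_image
from .textproc import (Vocabulary, encode_time, keyword_start_token,
                       make_context_window, tokenize)


@dataclass
class TrainConfig:
    batch_size: int = 48          # desk default; reference-scale setting is 128
    lr: float = 1e-3              # desk default; reference-scale setting is 1e-4
    optimizer: str = "radam"
    warmup_epochs: int = 10
    epochs: int = 20
    seed: int = 0
    freeze_encoders: bool = True
    strategy: LossStrategy = field(default_factory=LossStrategy)
    val_fraction: float = 0.10
    patience: int = 10
    adam_betas: tuple[float, float] = (0.9, 0.99)
    fcs_temperature: float = 0.5
    context_limit: int = 250
    val_batches: int = 4

    def __post_init__(self) -> None:
        if self.batch_size % 3:
            raise ValueError("batch_size must be divisible by 3")
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must not exceed epochs")


@dataclass
class TaskBatch:
    sub1: list[FrameRecord]   # task 1: image + paired text -> landmark bits
    sub2: list[FrameRecord]   # task 2: current description (+time) -> next
    sub3: list[FrameRecord]   # task 3: keyword + context -> report sentence

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.sub1), len(self.sub2), len(self.sub3))


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    steps: int = 0
    metadata: dict = field(default_factory=dict)

    def row(self, **kwargs) -> None:
        self.epochs.append(kwargs)

    def to_csv(self, path) -> None:
        import csv
        if not self.epochs:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.epochs[0]))
            writer.writeheader()
            writer.writerows(self.epochs)


def set_seed(seed: int) -> np.random.Generator:
    """One reproducibility context: every stochastic element of a run
    (sampling, init) derives from generators spawned off this seed."""
    return np.random.default_rng(np.random.SeedSequence([seed]))


def task2_eligible(records: list[FrameRecord]) -> list[FrameRecord]:
    """Frames with a successor activity (last activity has no target)."""
    return [r for r in records if r.description_next is not None]


def build_task_batch(records: list[FrameRecord], batch_size: int,
                     rng: np.random.Generator) -> TaskBatch:
    """Three independent uniform sub-samples of size batch_size/3."""
    if batch_size % 3:
        raise ValueError("batch_size must be divisible by 3")
    n = batch_size // 3
    eligible2 = task2_eligible(records)
    if not records or not eligible2:
        raise ValueError("manifest does not supply all three channel types")
    pick = lambda pool: [pool[i] for i in rng.integers(len(pool), size=n)]
    return TaskBatch(sub1=pick(records), sub2=pick(eligible2), sub3=pick(records))


# --- tensorisation helpers ---------------------------------------------------

def _pad_ids(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = True
    return ids, mask


def task_text_inputs(records: list[FrameRecord], task: int, vocab: Vocabulary,
                     context_limit: int = 250) -> list[list[int]]:
    """Encoder-side token ids for a sub-batch of the given task."""
    out = []
    for r in records:
        if task == 1:
            ids = tokenize(r.description_prev, vocab).ids.tolist()
        elif task == 2:
            ids = tokenize(r.description_current, vocab).ids.tolist()
            ids += encode_time(min(r.t_procedure, 1.0),
                               min(r.t_observation, 1.0), vocab).ids.tolist()
        else:
            ids = make_context_window(r.report_history, r.keyword, vocab,
                                      token_limit=context_limit).ids.tolist()
        out.append(ids)
    return out


def task_targets(records: list[FrameRecord], task: int, vocab: Vocabulary
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(decoder_input_ids, target_ids, mask) for task 2 or 3."""
    inputs, targets = [], []
    for r in records:
        if task == 2:
            toks = tokenize(r.description_next, vocab).ids.tolist()
            start = [vocab.start_id]
        else:
            toks = tokenize(r.report_target, vocab).ids.tolist()
            start = [vocab.id(keyword_start_token(r.keyword))]
        inputs.append(start + toks)
        targets.append(toks + [vocab.end_id])
    in_ids, mask = _pad_ids(inputs, vocab.pad_id)
    tgt_ids, _ = _pad_ids(targets, vocab.pad_id)
    return in_ids, tgt_ids, mask


class FrozenEncoderCache:
    """Caches frozen-encoder outputs keyed by frame path / token tuple."""

    def __init__(self, model: MultiTaskVLM, manifest: DatasetManifest):
        self.model = model
        self.manifest = manifest
        self.images: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.texts: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def image_features(self, records: list[FrameRecord]) -> tuple[Tensor, Tensor]:
        missing = [r for r in records if r.image_path not in self.images]
        if missing:
            with ad.no_grad():
                for i in range(0, len(missing), 256):
                    chunk = missing[i:i + 256]
                    imgs = np.stack([load_image(self.manifest, r) for r in chunk])
                    tok, pool = self.model.encode_image(imgs)
                    for j, r in enumerate(chunk):
                        self.images[r.image_path] = (tok.data[j], pool.data[j])
            feats = [self.images[r.image_path] for r in records]
        else:
            feats = [self.images[r.image_path] for r in records]
        tokens = Tensor(np.stack([f[0] for f in feats]))
        pooled = Tensor(np.stack([f[1] for f in feats]))
        return tokens, pooled

    def text_features(self, id_lists: list[list[int]], pad_id: int
                      ) -> tuple[Tensor, Tensor, np.ndarray]:
        keys = [tuple(ids) for ids in id_lists]
        missing = sorted({k for k in keys if k not in self.texts}, key=len)
        for i in range(0, len(missing), 64):
            chunk = [list(k) for k in missing[i:i + 64]]
            ids, mask = _pad_ids(chunk, pad_id)
            with ad.no_grad():
                tok, pool = self.model.encode_text(ids, mask)
            for j, k in enumerate(missing[i:i + 64]):
                self.texts[k] = (tok.data[j, :len(k)], pool.data[j])
        T = max(len(k) for k in keys)
        d = next(iter(self.texts.values()))[0].shape[-1]
        tokens = np.zeros((len(keys), T, d), dtype=nn.DTYPE)
        pooled = np.zeros((len(keys), d), dtype=nn.DTYPE)
        mask = np.zeros((len(keys), T), dtype=bool)
        for i, k in enumerate(keys):
            tok, pool = self.texts[k]
            tokens[i, :len(k)] = tok
            pooled[i] = pool
            mask[i, :len(k)] = True
        return Tensor(tokens), Tensor(pooled), mask


def split_train_val(records: list[FrameRecord], val_fraction: float,
                    rng: np.random.Generator
                    ) -> tuple[list[FrameRecord], list[FrameRecord]]:
    """90/10 split at activity granularity, stratified by landmark
    configuration (activities grouped by state id, split within groups)."""
    by_state: dict[int, list[tuple[int, int]]] = {}
    for r in records:
        by_state.setdefault(r.state_id, [])
        key = (r.procedure_id, r.activity_index)
        if key not in by_state[r.state_id]:
            by_state[r.state_id].append(key)
    val_keys: set[tuple[int, int]] = set()
    for state in sorted(by_state):
        acts = sorted(by_state[state])
        rng.shuffle(acts)
        n_val = max(1, int(round(val_fraction * len(acts)))) \
            if len(acts) > 1 else 0
        val_keys.update(acts[:n_val])
    train = [r for r in records if (r.procedure_id, r.activity_index) not in val_keys]
    val = [r for r in records if (r.procedure_id, r.activity_index) in val_keys]
    return train, val


# --- losses for one TaskBatch ------------------------------------------------

def _batch_losses(model: MultiTaskVLM, batch: TaskBatch, vocab: Vocabulary,
                  cache: FrozenEncoderCache | None, config: TrainConfig,
                  manifest: DatasetManifest) -> dict[str, Tensor]:
    losses: dict[str, Tensor] = {}
    gamma = config.strategy.gamma

    def encode(records, task):
        images = texts = None
        text_tokens = text_pooled = text_mask = None
        img_tokens = img_pooled = None
        if model.image_encoder is not None:
            if cache is not None:
                img_tokens, img_pooled = cache.image_features(records)
            else:
                imgs = np.stack([load_image(manifest, r) for r in records])
                img_tokens, img_pooled = model.encode_image(imgs)
        if model.text_encoder is not None:
            id_lists = task_text_inputs(records, task, vocab,
                                        config.context_limit)
            if cache is not None:
                text_tokens, text_pooled, text_mask = cache.text_features(
                    id_lists, vocab.pad_id)
            else:
                ids, text_mask = _pad_ids(id_lists, vocab.pad_id)
                text_tokens, text_pooled = model.encode_text(ids, text_mask)
        return EmbeddingSet(img_tokens, img_pooled, text_tokens, text_pooled,
                            text_mask)

    if model.classifier is not None:
        fused = model.cross_attend(encode(batch.sub1, task=1))
        probs = model.classify_landmarks(fused)
        targets = np.stack([r.landmark_vector.bits for r in batch.sub1]).astype(float)
        losses["l_bce"] = obj.bce_loss_t(targets, probs)

    if model.decoder is not None:
        # task 2: next structured description, KLD (one-hot -> summed NLL)
        fused = model.cross_attend(encode(batch.sub2, task=2))
        in_ids, tgt_ids, mask = task_targets(batch.sub2, 2, vocab)
        logits = model.decoder.teacher_forced(fused.decoder_init, in_ids)
        losses["l_kld"] = obj.nll_loss_t(ad.log_softmax(logits, axis=-1),
                                         tgt_ids, mask)
        # task 3: report sentence, focal cosine similarity between frozen
        # text-encoder embeddings of target and candidate; the candidate is a
        # soft-input relaxation (probability-weighted token embeddings pushed
        # through the frozen encoder) so the loss stays differentiable
        fused = model.cross_attend(encode(batch.sub3, task=3))
        in_ids, tgt_ids, mask = task_targets(batch.sub3, 3, vocab)
        logits = model.decoder.teacher_forced(fused.decoder_init, in_ids)
        # sharpened relaxation: temperature < 1 penalises diffuse mixtures
        # that could match the target embedding without committing to tokens
        probs = ad.softmax(logits * (1.0 / config.fcs_temperature), axis=-1)
        table = model.text_encoder.embedding_table          # (V, d), frozen
        soft_emb = probs @ Tensor(table)
        _, cand = model.text_encoder.encode_embedded(soft_emb, mask)
        if cache is not None:
            _, tgt_pooled, _ = cache.text_features(
                [row[msk].tolist() for row, msk in zip(tgt_ids, mask)],
                vocab.pad_id)
            tgt_emb = tgt_pooled.data
        else:
            with ad.no_grad():
                _, tgt_t = model.encode_text(tgt_ids, mask)
            tgt_emb = tgt_t.data
        losses["l_fcs"] = obj.fcs_loss_t(tgt_emb, cand, gamma=gamma)
    return losses


def combined_from_components(losses: dict[str, Tensor],
                             strategy: LossStrategy):
    """Combine whichever components the variant produces; with fewer than
    three, product strategies fall back to the geometric/arithmetic mean of
    the available components."""
    comps = [losses[k] for k in ("l_bce", "l_kld", "l_fcs") if k in losses]
    if len(comps) == 3:
        return obj.combine_losses(comps[0], comps[1], comps[2], strategy)
    if len(comps) == 1:
        return comps[0]
    if strategy.name == "AL":
        return (comps[0] + comps[1]) * 0.5
    prod = comps[0].clip_min(strategy.epsilon) * comps[1].clip_min(strategy.epsilon)
    return prod ** 0.5


def fit(model: MultiTaskVLM, manifest: DatasetManifest, vocab: Vocabulary,
        config: TrainConfig, records: list[FrameRecord] | None = None
        ) -> tuple[MultiTaskVLM, TrainHistory]:
    """Joint single-pass training with frozen encoders and early stopping.

    `records` restricts training to a subset (e.g. the non-held-out
    procedures of a cross-validation fold); defaults to the whole manifest.
    """
    rng = set_seed(config.seed)
    records = list(manifest.records if records is None else records)
    train_recs, val_recs = split_train_val(records, config.val_fraction, rng)
    if not val_recs:
        val_recs = train_recs[: config.batch_size]

    if config.freeze_encoders:
        for enc in (model.image_encoder, model.text_encoder):
            if enc is not None and hasattr(enc, "freeze"):
                enc.freeze()
        cache = FrozenEncoderCache(model, manifest)
    else:
        cache = None

    # prior-logit initialisation of the classifier output bias: rare classes
    # start at their empirical log-odds instead of 0.5, the standard remedy
    # for slow rare-class take-off under long-tail label frequencies
    if model.classifier is not None and \
            not np.any(model.classifier.fc3.bias.data):
        freq = np.stack([r.landmark_vector.bits for r in train_recs]).mean(0)
        freq = np.clip(freq, 1e-3, 1 - 1e-3)
        model.classifier.fc3.bias.data = np.log(freq / (1 - freq)).astype(
            model.classifier.fc3.bias.data.dtype)

    params = [p for p in model.parameters() if p.requires_grad]
    optim = nn.RAdam(params, lr=config.lr, betas=config.adam_betas)
    if config.optimizer.lower() not in ("radam",):
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    history = TrainHistory(metadata={
        "seed": config.seed, "optimizer": config.optimizer,
        "strategy": config.strategy.name, "lr": config.lr,
        "n_train": len(train_recs), "n_val": len(val_recs),
        "frozen_encoders": config.freeze_encoders,
    })
    steps_per_epoch = max(1, len(train_recs) // config.batch_size)
    best_val = np.inf
    best_epoch = -1
    bad_epochs = 0

    val_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))

    for epoch in range(config.epochs):
        warm = min(1.0, (epoch + 1) / max(config.warmup_epochs, 1))
        optim.lr = config.lr * warm
        sums = {"l_bce": 0.0, "l_kld": 0.0, "l_fcs": 0.0, "combined": 0.0}
        counts = {k: 0 for k in sums}
        for _ in range(steps_per_epoch):
            batch = build_task_batch(train_recs, config.batch_size, rng)
            losses = _batch_losses(model, batch, vocab, cache, config, manifest)
            combined = combined_from_components(losses, config.strategy)
            if not np.isfinite(float(combined.data)) or \
                    not all(np.isfinite(float(v.data)) for v in losses.values()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"{ {k: float(v.data) for k, v in losses.items()} }")
            optim.zero_grad()
            combined.backward()
            optim.step()
            history.steps += 1
            for k, v in losses.items():
                sums[k] += float(v.data)
                counts[k] += 1
            sums["combined"] += float(combined.data)
            counts["combined"] += 1
        row = {"epoch": epoch, "lr": optim.lr}
        for k in sums:
            row[f"train_{k}"] = sums[k] / counts[k] if counts[k] else np.nan

        # validation (no grad, fixed seeded batches)
        vrng = np.random.default_rng(val_rng.integers(2 ** 31))
        vsums = {k: 0.0 for k in sums}
        vcounts = {k: 0 for k in sums}
        n_vb = min(config.val_batches,
                   max(1, len(val_recs) // config.batch_size))
        with ad.no_grad():
            for _ in range(n_vb):
                batch = build_task_batch(val_recs, config.batch_size, vrng)
                losses = _batch_losses(model, batch, vocab, cache, config,
                                       manifest)
                combined = combined_from_components(losses, config.strategy)
                for k, v in losses.items():
                    vsums[k] += float(v.data)
                    vcounts[k] += 1
                vsums["combined"] += float(combined.data)
                vcounts["combined"] += 1
        for k in vsums:
            row[f"val_{k}"] = vsums[k] / vcounts[k] if vcounts[k] else np.nan
        history.row(**row)

        if row["val_combined"] < best_val - 1e-12:
            best_val = row["val_combined"]
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break

    # early stopping decides when to stop; the final weights are kept (the
    # per-epoch validation minimum is too noisy at desk scale to select on)
    history.best_epoch = best_epoch
    return model, history
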