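"""Evaluation: metric suite, LOPO cross-validation, ablation/loss sweeps,
class-wise reporting and attention export.

Task-1 classification is scored with per-class and macro precision/recall/F1
at a 0.5 threshold.  Task-2 description prediction is scored at token level
(bag-of-tokens matching against the reference).  Task-3 report generation is
scored with corpus BLEU-2, ROUGE-1/ROUGE-L F-measures, mean embedding cosine
similarity, and the composite f1* — the harmonic mean of BLEU-2
(precision-like) and ROUGE-1 (recall-like).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from . import autodiff as ad
from .model import ModelConfig, MultiTaskVLM, make_variant
from .synth.dataset import DatasetManifest, FrameRecord, load_image
from .textproc import Vocabulary, detokenize, keyword_start_token, word_tokens
from .training import (FrozenEncoderCache, TrainConfig, _pad_ids, fit,
                       task_text_inputs)


# --- fold construction -------------------------------------------------------

@dataclass
class FoldSpec:
    held_out_procedure_id: int
    train_ids: set      # (procedure_id, activity_index) keys
    val_ids: set

    def __post_init__(self) -> None:
        if self.train_ids & self.val_ids:
            raise ValueError("train/val overlap")
        if any(pid == self.held_out_procedure_id for pid, _ in
               self.train_ids | self.val_ids):
            raise ValueError("held-out procedure leaked into train/val")


def lopo_folds(manifest: DatasetManifest, val_fraction: float = 0.10,
               seed: int = 0) -> list[FoldSpec]:
    """Leave-one-patient-out folds: one per procedure; the remaining
    procedures are split 90/10 at activity granularity, stratified by
    landmark configuration (state id)."""
    pids = manifest.procedure_ids
    if len(pids) < 2:
        raise ValueError("LOPO needs at least 2 procedures")
    folds = []
    for held_out in pids:
        rng = np.random.default_rng(np.random.SeedSequence([seed, held_out]))
        rest = [r for r in manifest.records if r.procedure_id != held_out]
        by_state: dict[int, list] = {}
        for r in rest:
            key = (r.procedure_id, r.activity_index)
            group = by_state.setdefault(r.state_id, [])
            if key not in group:
                group.append(key)
        train_ids, val_ids = set(), set()
        for state in sorted(by_state):
            acts = sorted(by_state[state])
            rng.shuffle(acts)
            n_val = max(1, int(round(val_fraction * len(acts)))) \
                if len(acts) > 1 else 0
            val_ids.update(acts[:n_val])
            train_ids.update(acts[n_val:])
        folds.append(FoldSpec(held_out, train_ids, val_ids))
    return folds


# --- task 1 metrics ----------------------------------------------------------

def multilabel_metrics(predictions, targets, threshold: float = 0.5) -> dict:
    """Per-class and macro precision/recall/F1 with 0/0 := 0."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets)
    if predictions.shape != targets.shape:
        raise ValueError(f"shape mismatch {predictions.shape} vs {targets.shape}")
    binary = (predictions >= threshold).astype(int)
    cols = []
    for j in range(binary.shape[1]):
        cols.append(precision_recall_fscore_support(
            targets[:, j], binary[:, j], average="binary", pos_label=1,
            zero_division=0)[:3])
    p, r, f1 = (np.array([c[i] for c in cols]) for i in range(3))
    return {
        "per_class": {"precision": p, "recall": r, "f1": f1},
        "macro": {"precision": float(p.mean()), "recall": float(r.mean()),
                  "f1": float(f1.mean())},
    }


def token_prf(reference: str, hypothesis: str) -> tuple[float, float, float]:
    """Bag-of-tokens precision/recall/F1 of a generated sentence."""
    ref = Counter(word_tokens(reference))
    hyp = Counter(word_tokens(hypothesis))
    overlap = sum((ref & hyp).values())
    p = overlap / max(sum(hyp.values()), 1)
    r = overlap / max(sum(ref.values()), 1)
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


# --- task 3 metrics ----------------------------------------------------------

def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def corpus_bleu2(references: list[str], hypotheses: list[str],
                 smooth_eps: float | None = None) -> float:
    """Corpus BLEU with uniform 1/2,1/2 n-gram weights and the standard
    brevity penalty.  `smooth_eps` adds epsilon to zero clipped counts
    (useful for tiny corpora); None disables smoothing."""
    num = [0.0, 0.0]
    den = [0.0, 0.0]
    ref_len = hyp_len = 0
    for ref, hyp in zip(references, hypotheses):
        rt, ht = word_tokens(ref), word_tokens(hyp)
        ref_len += len(rt)
        hyp_len += len(ht)
        for n in (1, 2):
            rc, hc = _ngrams(rt, n), _ngrams(ht, n)
            num[n - 1] += sum(min(c, rc[g]) for g, c in hc.items())
            den[n - 1] += max(sum(hc.values()), 0)
    precisions = []
    for n in (0, 1):
        if den[n] == 0:
            return 0.0
        p = num[n] / den[n]
        if p == 0.0:
            if smooth_eps is None:
                return 0.0
            p = smooth_eps
        precisions.append(p)
    bp = 1.0 if hyp_len > ref_len else float(np.exp(1.0 - ref_len / max(hyp_len, 1)))
    return bp * float(np.exp(0.5 * np.log(precisions[0]) + 0.5 * np.log(precisions[1])))


def _rouge_n_f(ref: list[str], hyp: list[str], n: int) -> float:
    rc, hc = _ngrams(ref, n), _ngrams(hyp, n)
    overlap = sum((rc & hc).values())
    total_r, total_h = sum(rc.values()), sum(hc.values())
    if overlap == 0 or not total_r or not total_h:
        return 0.0
    p, r = overlap / total_h, overlap / total_r
    return 2 * p * r / (p + r)


def _lcs_len(a: list[str], b: list[str]) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def _rouge_l_f(ref: list[str], hyp: list[str]) -> float:
    if not ref or not hyp:
        return 0.0
    lcs = _lcs_len(ref, hyp)
    if lcs == 0:
        return 0.0
    p, r = lcs / len(hyp), lcs / len(ref)
    return 2 * p * r / (p + r)


def text_metrics(references: list[str], hypotheses: list[str],
                 embed_fn=None, smooth_eps: float | None = None) -> dict:
    """Corpus BLEU-2, mean sentence ROUGE-1/ROUGE-L F, mean embedding cosine,
    and f1* (harmonic mean of BLEU-2 and ROUGE-1)."""
    if not references or len(references) != len(hypotheses):
        raise ValueError("need equal-length, non-empty reference/hypothesis lists")
    bleu2 = corpus_bleu2(references, hypotheses, smooth_eps)
    r1 = float(np.mean([_rouge_n_f(word_tokens(r), word_tokens(h), 1)
                        for r, h in zip(references, hypotheses)]))
    rl = float(np.mean([_rouge_l_f(word_tokens(r), word_tokens(h))
                        for r, h in zip(references, hypotheses)]))
    cos = np.nan
    if embed_fn is not None:
        er = np.asarray(embed_fn(references), dtype=float)
        eh = np.asarray(embed_fn(hypotheses), dtype=float)
        norms = np.linalg.norm(er, axis=-1) * np.linalg.norm(eh, axis=-1)
        cos = float(np.mean((er * eh).sum(-1) / np.maximum(norms, 1e-12)))
    f1_star = 2 * bleu2 * r1 / (bleu2 + r1) if bleu2 + r1 > 0 else 0.0
    return {"bleu2": bleu2, "rouge1": r1, "rougeL": rl,
            "cosine": cos, "f1_star": f1_star}


def classwise_frequency_correlation(per_class_f1, frequencies) -> float:
    """Spearman rank correlation between class frequency and per-class F1.
    Returns 0.0 when either input is constant (tie convention)."""
    f1 = np.asarray(per_class_f1, dtype=float)
    fr = np.asarray(frequencies, dtype=float)
    if f1.size != fr.size or f1.size < 3:
        raise ValueError("need >= 3 paired classes")
    if np.ptp(f1) == 0 or np.ptp(fr) == 0:
        return 0.0
    rho, _ = stats.spearmanr(fr, f1)
    return float(rho)


# --- attention export --------------------------------------------------------

@dataclass
class AttentionRecord:
    sample_id: str
    image_attention: np.ndarray | None
    text_attention: np.ndarray | None
    task_outputs: dict
    category: str


def categorize_result(mean_f1: float, classification_correct: bool) -> str:
    """Positive: mean F1 > 0.65 and correct landmark classification.
    Negative: mean F1 < 0.3 and incorrect classification.  Else neither."""
    if mean_f1 > 0.65 and classification_correct:
        return "positive"
    if mean_f1 < 0.3 and not classification_correct:
        return "negative"
    return "neither"


def export_attention(model: MultiTaskVLM, manifest: DatasetManifest,
                     record: FrameRecord, vocab: Vocabulary,
                     embed_fn=None) -> AttentionRecord:
    """Extract cross-attention weights for one sample and categorize the
    multi-task result (positive / negative / neither)."""
    if model.variant != "A_full":
        raise ValueError("attention export requires the full model (variant A)")
    with ad.no_grad():
        img = load_image(manifest, record)[None]
        ids, mask = _pad_ids(task_text_inputs([record], 1, vocab), vocab.pad_id)
        emb = model.embed(images=img, text_ids=ids, text_mask=mask)
        fused = model.cross_attend(emb)
        probs = model.classify_landmarks(fused).data[0]
        pred_bits = (probs >= 0.5).astype(int)
        target_bits = np.asarray(record.landmark_vector.bits)
        correct = bool(np.array_equal(pred_bits, target_bits))
        f1s = [multilabel_metrics(probs[None], target_bits[None])["macro"]["f1"]]
        # task 2/3 sentence-level scores where applicable
        cw_ids, cw_mask = _pad_ids(task_text_inputs([record], 3, vocab),
                                   vocab.pad_id)
        emb3 = model.embed(images=img, text_ids=cw_ids, text_mask=cw_mask)
        fused3 = model.cross_attend(emb3)
        gen = model.generate_text(
            fused3, [[vocab.id(keyword_start_token(record.keyword))]], vocab)
        hyp = detokenize(gen[0], vocab)
        tm = text_metrics([record.report_target], [hyp], embed_fn,
                          smooth_eps=1e-9)
        f1s.append(tm["f1_star"])
    mean_f1 = float(np.mean(f1s))
    return AttentionRecord(
        sample_id=record.image_path,
        image_attention=fused.attention_maps.get("text_to_image"),
        text_attention=fused.attention_maps.get("image_to_text"),
        task_outputs={"probs": probs, "report_hypothesis": hyp,
                      "mean_f1": mean_f1, **tm},
        category=categorize_result(mean_f1, correct))


# --- model evaluation on held-out data --------------------------------------

def evaluate_model(model: MultiTaskVLM, manifest: DatasetManifest,
                   records: list[FrameRecord], vocab: Vocabulary,
                   config: TrainConfig | None = None,
                   max_frames: int = 400, seed: int = 0) -> dict:
    """Score all applicable tasks on a held-out record set.

    Task 1 uses up to `max_frames` frames; tasks 2/3 are scored once per
    activity (records within an activity share text channels)."""
    config = config or TrainConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7A]))
    cache = FrozenEncoderCache(model, manifest)
    out: dict = {}

    if model.classifier is not None:
        recs = list(records)
        if len(recs) > max_frames:
            recs = [recs[i] for i in rng.choice(len(recs), max_frames,
                                                replace=False)]
        probs_all, targets = [], []
        with ad.no_grad():
            for i in range(0, len(recs), 64):
                chunk = recs[i:i + 64]
                emb = _encode_chunk(model, cache, chunk, 1, vocab, config)
                fused = model.cross_attend(emb)
                probs_all.append(model.classify_landmarks(fused).data)
                targets.extend(r.landmark_vector.bits for r in chunk)
        mm = multilabel_metrics(np.concatenate(probs_all), np.stack(targets))
        out["task1"] = mm

    if model.decoder is not None:
        # one representative frame per activity
        by_act: dict[tuple, FrameRecord] = {}
        for r in records:
            by_act.setdefault((r.procedure_id, r.activity_index), r)
        acts = list(by_act.values())
        # task 2
        eligible = [r for r in acts if r.description_next is not None]
        if eligible:
            hyps = _generate(model, cache, eligible, 2, vocab, config)
            prf = [token_prf(r.description_next, h)
                   for r, h in zip(eligible, hyps)]
            out["task2"] = {
                "precision": float(np.mean([x[0] for x in prf])),
                "recall": float(np.mean([x[1] for x in prf])),
                "f1": float(np.mean([x[2] for x in prf])),
            }
        # task 3
        hyps = _generate(model, cache, acts, 3, vocab, config)
        refs = [r.report_target for r in acts]
        embed_fn = make_embed_fn(model, vocab) if model.text_encoder else None
        out["task3"] = text_metrics(refs, hyps, embed_fn, smooth_eps=1e-9)
    return out


def _encode_chunk(model, cache, records, task, vocab, config):
    img_tokens = img_pooled = text_tokens = text_pooled = text_mask = None
    if model.image_encoder is not None:
        img_tokens, img_pooled = cache.image_features(records)
    if model.text_encoder is not None:
        id_lists = task_text_inputs(records, task, vocab, config.context_limit)
        text_tokens, text_pooled, text_mask = cache.text_features(
            id_lists, vocab.pad_id)
    from .model import EmbeddingSet
    return EmbeddingSet(img_tokens, img_pooled, text_tokens, text_pooled,
                        text_mask)


def _generate(model, cache, records, task, vocab, config) -> list[str]:
    hyps = []
    with ad.no_grad():
        for i in range(0, len(records), 64):
            chunk = records[i:i + 64]
            emb = _encode_chunk(model, cache, chunk, task, vocab, config)
            fused = model.cross_attend(emb)
            if task == 2:
                starts = [[vocab.start_id]] * len(chunk)
            else:
                starts = [[vocab.id(keyword_start_token(r.keyword))]
                          for r in chunk]
            gen = model.generate_text(fused, starts, vocab)
            hyps.extend(detokenize(g, vocab) for g in gen)
    return hyps


def make_embed_fn(model: MultiTaskVLM, vocab: Vocabulary):
    """Sentence embedding via the frozen text encoder's pooled output."""
    from .textproc import tokenize

    def embed(texts: list[str]) -> np.ndarray:
        id_lists = [tokenize(t, vocab).ids.tolist() or [vocab.unk_id]
                    for t in texts]
        ids, mask = _pad_ids(id_lists, vocab.pad_id)
        with ad.no_grad():
            _, pooled = model.encode_text(ids, mask)
        return pooled.data

    return embed


# --- experiment harness ------------------------------------------------------

def run_experiment(manifest: DatasetManifest, vocab: Vocabulary,
                   variants: list[str], strategies: list[str],
                   train_config: TrainConfig,
                   model_config: ModelConfig | None = None,
                   folds: list[FoldSpec] | None = None,
                   max_folds: int | None = None) -> pd.DataFrame:
    """Train and evaluate every requested (fold x variant x strategy) cell.

    Returns a tidy DataFrame with per-cell rows plus 'aggregate' rows holding
    the unweighted mean over folds.  Failures are recorded and the sweep
    continues.
    """
    from .objectives import LossStrategy
    if model_config is None:
        model_config = ModelConfig(n_classes=manifest.generator_config.n_classes,
                                   vocab_size=len(vocab))
    folds = folds or lopo_folds(manifest, train_config.val_fraction,
                                train_config.seed)
    if max_folds is not None:
        folds = folds[:max_folds]
    rows = []
    for fold in folds:
        held = [r for r in manifest.records
                if r.procedure_id == fold.held_out_procedure_id]
        train_recs = [r for r in manifest.records
                      if (r.procedure_id, r.activity_index) in
                      (fold.train_ids | fold.val_ids)]
        for variant in variants:
            for strat in strategies:
                cell = {"fold": fold.held_out_procedure_id,
                        "variant": variant, "strategy": strat}
                try:
                    cfg = TrainConfig(**{**asdict_train(train_config),
                                         "strategy": LossStrategy(
                                             strat, train_config.strategy.gamma)})
                    model = make_variant(model_config, variant,
                                         seed=train_config.seed)
                    model, _ = fit(model, manifest, vocab, cfg,
                                   records=train_recs)
                    metrics = evaluate_model(model, manifest, held, vocab, cfg,
                                             seed=train_config.seed)
                    rows.append({**cell, **_flatten(metrics)})
                except Exception as exc:   # cell failure: record, continue
                    rows.append({**cell, "error": str(exc)})
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns
                   if c not in ("fold", "variant", "strategy", "error")]
    if metric_cols:
        agg = (df.groupby(["variant", "strategy"])[metric_cols]
               .mean(numeric_only=True).reset_index())
        agg.insert(0, "fold", "aggregate")
        df = pd.concat([df, agg], ignore_index=True)
    return df


def asdict_train(cfg: TrainConfig) -> dict:
    from dataclasses import asdict
    d = asdict(cfg)
    d.pop("strategy")
    return d


def _flatten(metrics: dict) -> dict:
    flat = {}
    for task, vals in metrics.items():
        for k, v in vals.items():
            if k == "per_class":
                for m, arr in v.items():
                    for j, x in enumerate(arr):
                        flat[f"{task}_class{j}_{m}"] = float(x)
            elif isinstance(v, dict):
                for m, x in v.items():
                    flat[f"{task}_{k}_{m}"] = float(x)
            else:
                flat[f"{task}_{k}"] = float(v)
    return flat
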