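"""Metric correctness (against independent oracles), folds and exports."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from endovlm.evaluation import (categorize_result, classwise_frequency_correlation,
                                corpus_bleu2, export_attention, lopo_folds,
                                multilabel_metrics, run_experiment,
                                text_metrics, token_prf)
from endovlm.model import ModelConfig, make_variant
from endovlm.training import TrainConfig


# --- independent reference implementations (kept deliberately naive) ---------

def ref_bleu2(references, hypotheses):
    """Reference corpus BLEU-2 with exact rational arithmetic."""
    def grams(tokens, n):
        return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))
    clipped = {1: 0, 2: 0}
    total = {1: 0, 2: 0}
    rlen = hlen = 0
    for ref, hyp in zip(references, hypotheses):
        r, h = ref.split(), hyp.split()
        rlen += len(r)
        hlen += len(h)
        for n in (1, 2):
            hg, rg = grams(h, n), grams(r, n)
            for g, c in hg.items():
                clipped[n] += min(c, rg.get(g, 0))
                total[n] += c
    if total[1] == 0 or total[2] == 0:
        return 0.0
    p1 = Fraction(clipped[1], total[1])
    p2 = Fraction(clipped[2], total[2])
    if p1 == 0 or p2 == 0:
        return 0.0
    bp = 1.0 if hlen > rlen else float(np.exp(1 - rlen / hlen))
    return bp * float(np.sqrt(float(p1) * float(p2)))


def ref_rouge1_f(reference, hypothesis):
    r, h = reference.split(), hypothesis.split()
    overlap = sum((Counter(r) & Counter(h)).values())
    if overlap == 0:
        return 0.0
    prec = overlap / len(h)
    rec = overlap / len(r)
    return 2 * prec * rec / (prec + rec)


def ref_rougeL_f(reference, hypothesis):
    r, h = reference.split(), hypothesis.split()
    # quadratic LCS by memoised recursion
    import functools

    @functools.lru_cache(maxsize=None)
    def lcs(i, j):
        if i == len(r) or j == len(h):
            return 0
        if r[i] == h[j]:
            return 1 + lcs(i + 1, j + 1)
        return max(lcs(i + 1, j), lcs(i, j + 1))

    ell = lcs(0, 0)
    if ell == 0:
        return 0.0
    prec, rec = ell / len(h), ell / len(r)
    return 2 * prec * rec / (prec + rec)


def toy_corpus(n_pairs=20):
    """20 sentence pairs with varied overlap, built from domain phrases."""
    rng = np.random.default_rng(12)
    parts = ["now inspect the", "now resect the", "then irrigate the"]
    names = ["middle nasal concha", "middle nasal meatus", "bulla ethmoidalis",
             "cranial base", "processus uncinatus", "sphenoethmoidal recess"]
    refs, hyps = [], []
    for i in range(n_pairs):
        a, b = rng.choice(names, 2, replace=False)
        refs.append(f"{parts[i % 3]} {a} region")
        hyps.append(f"{parts[(i + i // 3) % 3]} {b if i % 2 else a} region")
    return refs, hyps


class TestMultilabelMetrics:
    def test_perfect_predictions(self):
        y = np.array([[1, 0, 1], [0, 1, 1]])
        m = multilabel_metrics(y.astype(float), y)
        assert m["macro"] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_hand_computed_class(self):
        # class 0: TP=1, FP=0, FN=1 -> P=1, R=0.5, F1=2/3
        targets = np.array([[1], [1], [0]])
        preds = np.array([[0.9], [0.1], [0.2]])
        m = multilabel_metrics(preds, targets)
        assert m["per_class"]["precision"][0] == pytest.approx(1.0)
        assert m["per_class"]["recall"][0] == pytest.approx(0.5)
        assert m["per_class"]["f1"][0] == pytest.approx(2 / 3)

    def test_macro_is_unweighted_mean(self):
        targets = np.array([[1, 1], [1, 1], [0, 0]])
        preds = np.array([[0.9, 0.9], [0.1, 0.1], [0.2, 0.2]])
        m = multilabel_metrics(preds, targets)
        assert m["macro"]["f1"] == pytest.approx(2 / 3)

    def test_zero_over_zero_is_zero(self):
        m = multilabel_metrics(np.array([[0.1]]), np.array([[0]]))
        assert m["macro"]["f1"] == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            multilabel_metrics(np.zeros((2, 3)), np.zeros((2, 4)))


class TestTextMetrics:
    def test_identity_scores_one(self):
        refs = ["now inspect the cranial base region"] * 3
        m = text_metrics(refs, list(refs))
        for k in ("bleu2", "rouge1", "rougeL", "f1_star"):
            assert m[k] == pytest.approx(1.0)

    def test_worked_bleu2_example(self):
        got = corpus_bleu2(["the middle nasal concha"],
                           ["the middle nasal meatus"])
        assert got == pytest.approx(np.sqrt(0.75 * (2 / 3)), abs=1e-9)
        assert got == pytest.approx(0.7071, abs=1e-4)

    def test_f1_star_harmonic_mean(self):
        # oracle: harmonic mean of bleu2=0.5 and rouge1=1.0 is 2/3
        b, r = 0.5, 1.0
        assert 2 * b * r / (b + r) == pytest.approx(2 / 3)
        refs, hyps = toy_corpus()
        m = text_metrics(refs, hyps)
        expect = 2 * m["bleu2"] * m["rouge1"] / (m["bleu2"] + m["rouge1"])
        assert m["f1_star"] == pytest.approx(expect, rel=1e-12)

    def test_matches_independent_reference_on_toy_corpus(self):
        refs, hyps = toy_corpus()
        m = text_metrics(refs, hyps)
        assert m["bleu2"] == pytest.approx(ref_bleu2(refs, hyps), abs=1e-6)
        assert m["rouge1"] == pytest.approx(
            np.mean([ref_rouge1_f(r, h) for r, h in zip(refs, hyps)]), abs=1e-6)
        assert m["rougeL"] == pytest.approx(
            np.mean([ref_rougeL_f(r, h) for r, h in zip(refs, hyps)]), abs=1e-6)

    def test_empty_lists_raise(self):
        with pytest.raises(ValueError):
            text_metrics([], [])

    def test_token_prf_bag_matching(self):
        p, r, f = token_prf("the middle nasal concha",
                            "the the middle concha")
        # overlap: the(1) + middle(1) + concha(1) = 3; hyp 4 tokens, ref 4
        assert p == pytest.approx(3 / 4)
        assert r == pytest.approx(3 / 4)
        assert f == pytest.approx(3 / 4)


class TestFolds:
    def test_one_fold_per_procedure(self, tiny_manifest):
        folds = lopo_folds(tiny_manifest, seed=0)
        assert len(folds) == len(tiny_manifest.procedure_ids)
        assert sorted(f.held_out_procedure_id for f in folds) == \
            tiny_manifest.procedure_ids

    def test_held_out_never_in_train_or_val(self, tiny_manifest):
        for fold in lopo_folds(tiny_manifest, seed=0):
            pids = {pid for pid, _ in fold.train_ids | fold.val_ids}
            assert fold.held_out_procedure_id not in pids
            assert not (fold.train_ids & fold.val_ids)

    def test_train_val_cover_all_other_activities(self, tiny_manifest):
        all_acts = {(r.procedure_id, r.activity_index)
                    for r in tiny_manifest.records}
        for fold in lopo_folds(tiny_manifest, seed=0):
            rest = {(p, a) for p, a in all_acts
                    if p != fold.held_out_procedure_id}
            assert fold.train_ids | fold.val_ids == rest

    def test_single_procedure_rejected(self, tiny_manifest):
        from endovlm.synth.dataset import DatasetManifest
        single = DatasetManifest(
            records=[r for r in tiny_manifest.records if r.procedure_id == 0],
            generator_config=tiny_manifest.generator_config,
            n_kept=1, n_discarded=0)
        with pytest.raises(ValueError):
            lopo_folds(single)


class TestCorrelation:
    def test_monotone_increasing_gives_one(self):
        freqs = [0.05, 0.1, 0.2, 0.25]
        f1 = [0.3, 0.5, 0.7, 0.9]
        assert classwise_frequency_correlation(f1, freqs) == pytest.approx(1.0)

    def test_constant_f1_gives_zero(self):
        assert classwise_frequency_correlation([0.5] * 5,
                                               [0.1, 0.2, 0.3, 0.4, 0.5]) == 0.0

    def test_matches_brute_force_rank_formula(self):
        # oracle: Spearman = Pearson correlation of the rank vectors
        freqs = np.array([0.05, 0.25, 0.10, 0.20])
        f1 = np.array([0.40, 0.75, 0.55, 0.50])
        def ranks(x):
            order = np.argsort(x)
            r = np.empty_like(order, dtype=float)
            r[order] = np.arange(1, len(x) + 1)
            return r
        rf, rg = ranks(freqs), ranks(f1)
        expect = np.corrcoef(rf, rg)[0, 1]
        assert classwise_frequency_correlation(f1, freqs) == \
            pytest.approx(expect, abs=1e-12)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            classwise_frequency_correlation([0.1, 0.2], [0.1, 0.2])


class TestAttentionExport:
    @pytest.mark.parametrize("mean_f1,correct,expected", [
        (0.8, True, "positive"),
        (0.8, False, "neither"),
        (0.2, False, "negative"),
        (0.2, True, "neither"),
        (0.5, True, "neither"),
    ])
    def test_categorisation_rule(self, mean_f1, correct, expected):
        assert categorize_result(mean_f1, correct) == expected

    def test_export_shapes_and_normalisation(self, tiny_manifest, tiny_vocab,
                                             small_model_config):
        model = make_variant(small_model_config, "A_full", seed=0)
        rec = tiny_manifest.records[10]
        out = export_attention(model, tiny_manifest, rec, tiny_vocab)
        grid = model.image_encoder.grid
        assert out.image_attention.shape == (1, grid * grid)
        assert np.allclose(out.image_attention.sum(), 1.0, atol=1e-5)
        assert np.allclose(out.text_attention.sum(), 1.0, atol=1e-5)
        assert out.category in ("positive", "negative", "neither")

    def test_variant_without_attention_rejected(self, tiny_manifest, tiny_vocab,
                                                small_model_config):
        model = make_variant(small_model_config, "D_no_cross_attention", seed=0)
        with pytest.raises(ValueError):
            export_attention(model, tiny_manifest, tiny_manifest.records[0],
                             tiny_vocab)


class TestRunExperiment:
    def test_sweep_produces_cells_and_aggregate(self, tiny_manifest,
                                                tiny_vocab, small_model_config):
        cfg = TrainConfig(epochs=1, warmup_epochs=1, batch_size=24, seed=0,
                          val_batches=1)
        df = run_experiment(tiny_manifest, tiny_vocab,
                            variants=["B_image_only", "C_text_only"],
                            strategies=["GL"], train_config=cfg,
                            model_config=small_model_config, max_folds=1)
        assert set(df["variant"]) == {"B_image_only", "C_text_only"}
        assert "aggregate" in set(df["fold"].astype(str))
        b = df[(df.variant == "B_image_only") & (df.fold != "aggregate")].iloc[0]
        c = df[(df.variant == "C_text_only") & (df.fold != "aggregate")].iloc[0]
        # image-only rows carry no text metrics; text-only rows no landmark ones
        assert b.filter(like="task3").isna().all()
        assert not np.isnan(b["task1_macro_f1"])
        assert c.filter(like="task1").isna().all()
        assert not np.isnan(c["task3_f1_star"])
        agg = df[(df.fold == "aggregate") & (df.variant == "B_image_only")]
        assert agg["task1_macro_f1"].iloc[0] == pytest.approx(b["task1_macro_f1"])
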