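"""Train the full cross-attention model jointly on all three tasks.

Generates a compact dataset, holds one procedure out, trains variant A with
the geometric-mean objective and frozen encoders, and reports held-out
landmark F1, description-prediction token F1 and report-generation metrics.
Takes a couple of minutes on one CPU.
"""

import tempfile

import numpy as np

from endovlm import (GeneratorConfig, ModelConfig, TrainConfig, build_dataset,
                     build_vocab, fit, lopo_folds, make_variant)
from endovlm.evaluation import evaluate_model

out = tempfile.mkdtemp(prefix="endovlm_train_")
config = GeneratorConfig(seed=3, n_procedures=3,
                         activities_per_procedure=(22, 28),
                         activity_duration=(2.0, 4.0))
manifest = build_dataset(config, out)
vocab = build_vocab(sorted({t for r in manifest.records
                            for t in (r.description_prev,
                                      r.description_current,
                                      r.report_target)}))
print(f"{manifest.n_kept} frames, vocabulary of {len(vocab)} tokens")

fold = lopo_folds(manifest, seed=0)[0]
train_recs = [r for r in manifest.records
              if (r.procedure_id, r.activity_index)
              in (fold.train_ids | fold.val_ids)]
held = [r for r in manifest.records
        if r.procedure_id == fold.held_out_procedure_id]

model = make_variant(ModelConfig(vocab_size=len(vocab)), "A_full", seed=0)
train_config = TrainConfig(epochs=20, warmup_epochs=2, lr=2e-3,
                           batch_size=24, seed=0)
model, history = fit(model, manifest, vocab, train_config, records=train_recs)

first, last = history.epochs[0], history.epochs[-1]
print(f"combined loss: {first['train_combined']:.3f} -> "
      f"{last['train_combined']:.3f} over {len(history.epochs)} epochs "
      f"({history.steps} joint updates)")

res = evaluate_model(model, manifest, held, vocab, train_config)
print(f"held-out procedure {fold.held_out_procedure_id}:")
print(f"  landmark classification macro F1 : {res['task1']['macro']['f1']:.3f}")
print(f"  description prediction token F1  : {res['task2']['f1']:.3f}")
print(f"  report generation f1*            : {res['task3']['f1_star']:.3f} "
      f"(BLEU-2 {res['task3']['bleu2']:.3f}, ROUGE-1 {res['task3']['rouge1']:.3f})")
print("High landmark F1 on an unseen procedure means the head reads the")
print("anatomical configuration from pixels, not from memorised frames.")
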