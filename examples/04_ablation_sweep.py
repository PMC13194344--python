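"""Compare ablation variants: what does cross-modal fusion contribute?

Trains the full model (A), the text-only model (C) and the no-cross-attention
model (D) on the same fold and compares report-generation f1*.  The report
sentence names the landmarks visible in the frame, which the text context
only predicts probabilistically; the gap (or lack of one) between A and the
image-blind variants measures how much of that image-borne content the
focal cosine-similarity objective manages to exploit at this training scale.
"""

import tempfile

from endovlm import GeneratorConfig, TrainConfig, build_dataset, build_vocab
from endovlm.evaluation import run_experiment

out = tempfile.mkdtemp(prefix="endovlm_ablate_")
config = GeneratorConfig(seed=4, n_procedures=3,
                         activities_per_procedure=(12, 16),
                         activity_duration=(2.0, 4.0))
manifest = build_dataset(config, out)
vocab = build_vocab(sorted({t for r in manifest.records
                            for t in (r.description_prev,
                                      r.description_current,
                                      r.report_target)}))

df = run_experiment(manifest, vocab,
                    variants=["A_full", "C_text_only",
                              "D_no_cross_attention"],
                    strategies=["GL"],
                    train_config=TrainConfig(epochs=30, warmup_epochs=3, lr=2e-3,
                                             batch_size=24, seed=0),
                    max_folds=1)
cell = df[df.fold != "aggregate"]
print(cell[["variant", "task3_f1_star", "task3_bleu2",
            "task3_rouge1"]].to_string(index=False))
print("\nf1* is the harmonic mean of BLEU-2 and ROUGE-1.  At reference scale")
print("the full model leads; at this desk scale the weakly-supervised")
print("generation head often cannot yet cash in its image pathway — see the")
print("methods note for the analysis.")
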