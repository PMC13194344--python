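"""Export cross-attention maps with positive/negative result categories.

After a short training run, extracts for a handful of frames the weights the
pooled text query places on image patches (and vice versa), plus the
multi-task result category: positive (mean F1 > 0.65 and correct landmark
classification), negative (mean F1 < 0.3 and incorrect), or neither.
"""

import tempfile

import numpy as np

from endovlm import (GeneratorConfig, ModelConfig, TrainConfig, build_dataset,
                     build_vocab, fit, make_variant)
from endovlm.evaluation import export_attention, make_embed_fn

out = tempfile.mkdtemp(prefix="endovlm_attn_")
config = GeneratorConfig(seed=6, n_procedures=2,
                         activities_per_procedure=(10, 12),
                         activity_duration=(2.0, 4.0))
manifest = build_dataset(config, out)
vocab = build_vocab(sorted({t for r in manifest.records
                            for t in (r.description_prev,
                                      r.description_current,
                                      r.report_target)}))
model = make_variant(ModelConfig(vocab_size=len(vocab)), "A_full", seed=0)
model, _ = fit(model, manifest, vocab,
               TrainConfig(epochs=20, warmup_epochs=2, lr=2e-3,
                           batch_size=24, seed=0))

embed_fn = make_embed_fn(model, vocab)
rng = np.random.default_rng(0)
for i in rng.choice(len(manifest.records), 5, replace=False):
    rec = export_attention(model, manifest, manifest.records[int(i)], vocab,
                           embed_fn)
    top_patch = int(np.argmax(rec.image_attention))
    print(f"{rec.sample_id}: category={rec.category:8s} "
          f"mean_f1={rec.task_outputs['mean_f1']:.2f} "
          f"strongest image patch={top_patch} "
          f"(weight {rec.image_attention.max():.2f})")
print("\nEach map row is a softmax distribution (weights sum to 1); the")
print("strongest patch shows where the text query looks in the frame.")
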