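# Methods

## The model

`endovlm` implements a compact multi-task vision-language model (VLM) for
endoscopic sinus-surgery assistance. One network serves three tasks at the
same temporal resolution:

1. **Landmark classification** — each frame carries a binary vector
   c(i,t) ∈ {0,1}^K over K anatomical landmark classes (default K = 16);
   the model predicts per-class probabilities ĉ(i,t).
2. **Structured-description prediction** — each activity (a contiguous video
   segment with one stable anatomical configuration) has a templated 5-slot
   sentence S_D = (step count, main cavity, landmark group, landmarks,
   movement direction); the model predicts the *next* activity's S_D from the
   current one, sequence-to-sequence.
3. **Report generation** — given the spoken keyword k_t and the serialized
   history h_t of previous (keyword, sentence) pairs (truncated to the most
   recent 250 tokens), the model generates the current report sentence
   s_R(t), starting from a keyword-specific start token.

A vision encoder E_I and a text encoder E_S produce token-level features and
a mean-pooled embedding per modality. A cross-attention layer uses each
modality's pooled embedding as the query over the other modality's token
features, producing one context vector per stream; each head consumes the
concatenation [embedding ‖ context] (embedding first). The classification
head is a 3-layer MLP with a per-class sigmoid; the text head is a 2-layer
LSTM whose initial hidden/cell states are projected from the fused text
vector, decoding greedily (argmax) to END. The nominal decoder in this model
family is described as bidirectional; since causal generation cannot
condition on future outputs, the two stacked layers here run forward-only
and the bidirectional summarisation of the conditioning input is carried by
the (bidirectionally self-attending) text encoder. This resolution is a
documented simplification, not a claim about the original design.

### Losses

* L_BCE — mean binary cross-entropy over the K classes (natural log).
* L_KLD — KL divergence between target and predicted per-position token
  distributions, summed over unmasked positions. Targets are one-hot, so
  this equals the summed negative log-likelihood of the correct tokens; the
  training loop divides by the batch size so magnitudes are batch-invariant.
* L_FCS — focal cosine-similarity loss (1 − cos(e(ŝ), e(s)))^γ between
  sentence embeddings from the **frozen** text encoder, γ ∈ [1,2]
  (default 2, the sharp end of the range). Because argmax decoding is not
  differentiable, the candidate embedding is a soft-input relaxation: the
  decoder's per-position token probabilities — sharpened with a temperature
  of 0.5, since a diffuse mixture can match the target embedding in cosine
  without committing to any token — are mixed into probability-weighted
  token embeddings and pushed through the frozen encoder.

Combination strategies, with l1, l2, l3 = L_BCE, L_KLD, L_FCS:

| strategy | formula | log-log elasticities |
|---|---|---|
| GL (geometric) | (l1·l2·l3)^{1/3} | (⅓, ⅓, ⅓) |
| FL_img (image-focused) | l1·√(l2·l3) | (1, ½, ½) |
| FL_txt (text-focused) | l2·l3·√l1 | (½, 1, 1) |
| AL (arithmetic) | (l1+l2+l3)/3 | ∝ l_i |

GL is scale-invariant: every task receives the same relative gradient budget
regardless of absolute loss magnitudes. Components are floored at 1e-8
before roots so gradients stay finite as any component approaches zero.
Note the FL_txt formula is not dimension-matched to FL_img (it is quadratic
rather than ^{3/2} in the losses); it is implemented exactly as defined.

### Fusion at desk scale

The cross-attention projections are **frozen by default**
(`ModelConfig.train_attention` re-enables training). At reference scale the
fusion layer is trained jointly; at ~10³ updates a trainable context is a
moving input distribution that the small heads must chase, and in repeated
experiments it degraded every task relative to the zero-context variants.
Frozen, the fusion layer is a stable random feature channel that carries
each modality's content to the other head — the heads then decide what to
use. Attention maps are still content-dependent (softmax over token
similarities) and exported as usual.

### Training

Each mini-batch is the concatenation of three equal sub-batches, one per
task; one joint forward pass, one combined loss, one backward pass, one
RAdam update ("single-pass" training). Encoders are frozen by default and
their outputs cached, which is what makes desk-scale CPU training practical.
Teacher forcing conditions both text heads during training; evaluation uses
greedy decoding. The learning rate warms up linearly; training monitors the
combined loss on a 90/10 internal split at activity granularity (stratified
by anatomical configuration) for early stopping (patience 10); the final
weights are kept — at desk scale the per-epoch validation minimum is too
noisy to select weights on. The classifier's output bias is initialised to
the empirical class log-odds — the standard remedy for slow rare-class
take-off under long-tail frequencies. RAdam runs with β₂ = 0.99: the
geometric-mean objective multiplies each task gradient by a factor that
varies strongly across batches, and a faster second moment keeps that
multiplicative noise from suppressing rare-class updates.

Reference-scale defaults kept in `TrainConfig`: batch 128→48 (desk), RAdam,
lr 1e-4 (reference scale), warm-up 10 epochs. The desk-scale runs in the
examples, tests and acceptance script use 20 epochs with a warm-up of 2
epochs (the same 10%-of-schedule proportion as 10-of-100 at reference
scale) and lr 2e-3; at ~10^3 updates with heads trained from scratch the
reference-scale lr is too conservative — with it, rare-class probabilities
are still rising through the 0.5 threshold when the budget ends.

## Ablation variants

* **A_full** — both streams, cross-attention fusion.
* **B_image_only** — text encoder and decoder removed; the classifier sees
  [image_pooled ‖ 0]; no text outputs.
* **C_text_only** — image pathway removed; the decoder sees
  [text_pooled ‖ 0]; no classifications.
* **D_no_cross_attention** — both heads kept, both context vectors replaced
  by zeros (independent streams); no attention parameters. Heads are
  weight-compatible with A.

With fewer than three loss components (B, C), product strategies fall back
to the geometric mean of the available components and AL to their mean.

## The synthetic procedure generator

No deposited data exists for this problem (the source videos are private),
so the generator is a first-class, tested component that emulates the
*structure* of an aligned multimodal FESS corpus:

* **Activities and the Markov chain.** A procedure is a sequence of
  activities; each activity's anatomical configuration is one state from a
  recurring catalogue (default 20 states over 16 classes), constant within
  the activity. States evolve by a row-stochastic transition matrix; the
  default is ring-biased (0.7 to the successor state, rest uniform), making
  the next configuration predictable above chance — the property Task 2
  needs — while keeping the stationary distribution uniform.
* **Long-tail frequencies.** Class j is a member of round(f_j·20) catalogue
  states, with balanced state sizes; under the uniform stationary
  distribution the expected activity-level frequency equals the configured
  f_j. Defaults span 0.25 down to 0.05 (head classes above 20%, tail
  classes at 5%), mirroring a strongly skewed clinical label distribution.
  Because labels are constant within an activity, the *activity* — not the
  frame — is the independent unit of label randomness: fidelity checks use
  binomial bands at the effective number of independent draws
  (n_eff = (Σw)²/Σw² over activity frame-counts w), not at the frame count.
* **Images.** Frames are 64×64 RGB; each present landmark is drawn as a
  class-coloured square glyph at a fixed home cell of a 4×4 grid with seeded
  jitter, over a dark textured background with additive Gaussian pixel noise
  (σ = 0.05 of full scale). A rule-based oracle (`oracle_decode_frame`)
  recovers the landmark vector by colour/position matching at ≥99% exact
  accuracy — a non-learned proof that the images carry the label
  information, hence that Task 1 is learnable from pixels.
* **Text channels.** Descriptions are rendered from the invertible 5-slot
  template; report sentences follow a short keyword-conditioned template
  naming the visible landmarks; keywords are drawn at random per activity
  from a closed verb set so they do not leak the anatomical state.
* **Channel discards.** A configurable fraction of candidate frames loses
  one channel at random and is discarded, reproducing the kept/discarded
  bookkeeping of aligned multimodal corpora.
* **Determinism.** Identical (config, seed) reproduce byte-identical
  manifests and images.

What the generator does **not** emulate: real endoscopic appearance
(specularities, blur, occlusion, tissue deformation), annotation noise,
free-form sentence variability, or inter-patient anatomy differences.
Passing tests therefore demonstrate that the architecture, objectives and
evaluation machinery behave as specified under controlled conditions — they
say nothing about clinical performance on real video.

### Task-1 text pairing

At classification time the model is given the *previous* activity's
description alongside the frame (a generic "procedure start" sentence for
the first activity). Pairing with the *current* description would hand the
classifier a textual copy of its own target — the current description is
derived from the same annotation as the label vector, and at runtime it is
itself a model output. With the previous description the text contributes a
genuine Markov prior while the image remains the only reliable source.

## Evaluation

* Task 1: per-class and macro precision/recall/F1 at threshold 0.5
  (0/0 := 0; macro is the unweighted class mean).
* Task 2: token-level (bag-of-tokens) precision/recall/F1 against the
  reference description.
* Task 3: corpus BLEU-2 (uniform ½/½ weights, standard brevity penalty;
  optional add-epsilon smoothing for tiny corpora), sentence-averaged
  ROUGE-1 and ROUGE-L F-measures, mean cosine similarity of frozen-encoder
  sentence embeddings, and f1* — the harmonic mean of BLEU-2
  (precision-like) and ROUGE-1 (recall-like).
* Cross-validation: leave-one-patient-out; each fold holds out one
  procedure entirely and splits the rest 90/10 at activity granularity,
  stratified by anatomical configuration.
* Attention export: per-patch and per-token cross-attention weights with a
  result category — positive (mean F1 > 0.65 and exactly correct landmark
  classification), negative (mean F1 < 0.3 and incorrect), else neither.
* Long-tail analysis: Spearman rank correlation between class frequency and
  per-class F1 (0 by convention if either input is constant).

## Numerical choices

* float32 weights; natural logarithm everywhere; probability and loss
  floors at 1e-8 (1e-12 inside cosine norms).
* Softmax rows are computed with max-subtraction; attention masks use a
  −1e9 additive bias on padded keys.
* Greedy decoding only; ties in argmax resolve to the lowest token id
  (numpy convention).
* Round-half-even quantisation of time fractions to a 101-token vocabulary.
* The whole stack (autodiff, layers, RAdam) is implemented on numpy; all
  randomness flows through explicitly seeded `numpy.random.Generator`
  objects, so every run is reproducible from its seed.

## Problem sizes

Default desk-scale study: 5 procedures × 30–50 activities × 5 frames/s with
2–8 s activities ≈ 5k frames; model width d = 128 (~1M trainable head
parameters next to the frozen encoders and fusion layer); training 20
epochs ≈ 1.5k joint updates. The generator-fidelity checks use a
~20k-frame dataset. The modality-ablation study uses a 3-procedure
(~600-frame) corpus with a *flat* transition matrix — the next anatomical
configuration is then unpredictable from history, so report content is
image-borne by construction — trained for 45 epochs per variant and seed.
These sizes
are the package's desk-scale stand-in for the reference setting of 30
procedures / 130k frames / 176M parameters; they were chosen so that every
experiment, including the leave-one-out ablations, runs on one CPU core in
minutes.

## Known limitations

* Glyph images make Task 1 nearly noiseless at convergence; absolute metric
  values are not comparable to real-video numbers — only directional and
  structural claims (variant orderings, frequency–F1 correlation) transfer.
* **The FCS objective alone does not train report generation to exploit the
  image at desk scale.** Its gradient through a bag-like frozen sentence
  embedding is the same at every sequence position, so it rewards emitting
  the right content words but carries almost no per-token ordering signal.
  Consequence: in the desk-scale ablation the fused model edges out the
  no-cross-attention variant but does not reliably beat the text-only
  variant on f1* — text-only spends its whole training budget on the
  language tasks, and the fused model's extra context input costs more than
  the weakly-supervised head can recover. The pathway itself is sound: swapping
  the task-3 loss for token-level negative log-likelihood in a diagnostic
  makes the fused model clearly outscore the text-only variant
  (f1* 0.46 vs 0.32) on the same cross-modal corpus. Reproducing the
  reference ordering therefore appears to require either the reference
  training scale (~10⁵ updates with richly pre-trained encoders) or a
  stronger generation objective, and the desk-scale ablation result should
  be read with that in mind.
* The 20-state catalogue couples rare classes to few configurations, so
  rare-class F1 is sensitive to which states a held-out procedure happens
  to visit.
* `fit` holds the frozen-encoder feature cache in memory; very large
  synthetic datasets would need a disk-backed cache.
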