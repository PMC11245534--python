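# pkword2vec

Prior-knowledge-regularized skip-gram word embeddings for small corpora,
with Wasserstein-distance hyperparameter selection and a blinded pairwise
evaluation harness.

## Why

Word embedding models such as word2vec normally need millions of training
tokens. Clinical message corpora — for example the secure messages patients
exchange with their care team through a hospital portal — are often far
smaller, and models trained on them learn word semantics poorly,
especially for rare terms. `pkword2vec` trains skip-gram-with-negative-
sampling (SGNS) embeddings on such corpora while *regularizing* each word
toward its most similar words in larger pre-trained embedding sources
(one source per word category, e.g. a general news-corpus word2vec for
everyday words and a SNOMED-graph embedding for medical terms). The prior
sources may have any vector dimension; only their similarity structure is
used.

## The model

Every word has a center vector `v` and a context vector `u`. The training
objective is

```
Loss = Loss_SGNS + alpha * Loss_PK
```

* `Loss_SGNS` is the classic skip-gram negative-sampling loss over
  (center, context) pairs within a window of size `m`, with `K` negatives
  drawn from the smoothed unigram distribution `P(w) ∝ count(w)^0.75`:
  `-log σ(uᵀv) - Σ_k log σ(-u_kᵀv)`.

* `Loss_PK`: whenever a center word `t` covered by a prior source is
  processed, one word `j` is sampled with probability
  `p_tj = softmax(cos(t, j))` over the covered same-category words whose
  pre-trained cosine clears a threshold `θ` (the mean of the pooled top-10
  similarity scores). The penalty

  ```
  γ(t) · Ψ,   Ψ = [1 − cos(u_t, u_j)] + [1 − cos(v_t, v_j)],
  γ(t) = τ / rel_freq(t)
  ```

  pulls `t` toward `j` in both vector spaces, discounted for frequent
  words so corpus evidence dominates where it is plentiful. Words outside
  every prior source contribute nothing. `alpha = 0` recovers plain SGNS
  bit-for-bit.

Hyperparameters are selected by matching *similarity distributions* (the
pooled top-10 cosine scores across the vocabulary): the embedding size `d`
minimizes the 1-D Wasserstein distance to a large reference model, and the
prior weight `alpha` minimizes the pairwise Wasserstein distances among
the low/mid/high word-frequency tertiles. Model comparison uses blinded
A/B tasks (a probe word and both models' five most similar words, in
randomized order) scored by majority-vote support rate and by the sample
skewness of per-task preference proportions.

See `docs/methods.md` for assumptions, parameter units and defaults, and
numerical choices.

## Worked example

No clinical corpus ships with the package (such data is access-restricted),
so the example runs on the built-in synthetic world: a 300-word Zipf
corpus with 20 planted 5-word synonym clusters across 500 short documents,
an 80/20 non-medical/medical split, and a toy pre-trained prior covering
70% of each category:

```python
from pkword2vec import *
from pkword2vec.corpus import MEDICAL, NON_MEDICAL
from pkword2vec.tuning import select_alpha

spec = SyntheticSpec(seed=1)
corpus = generate_corpus(spec)
vocab = build_vocabulary(corpus.docs, corpus.lexicon)
prior_map = generate_prior(spec, corpus)
sources = [build_prior_source(prior_map, vocab, NON_MEDICAL, name="toy-general"),
           build_prior_source(prior_map, vocab, MEDICAL, name="toy-medical")]

config = TrainConfig(dim=25, seed=1)
alpha, table = select_alpha(corpus.docs, vocab, sources,
                            grid=(0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
                            config=config)
sgns, _ = train(corpus.docs, vocab, (), config.with_(alpha=0.0))
pk, _   = train(corpus.docs, vocab, sources, config.with_(alpha=alpha))
```

On this world the tertile-balance criterion selects `alpha = 300` (the
operative scale depends on the corpus size through `τ·T`; see the methods
note), and recall@5 of planted cluster-mates rises from **0.033** for the
SGNS baseline to **0.290** for the regularized model — the low-frequency
words gain the most. Simulated reviewers with a 0.9 per-vote preference
give an overall support rate of **1.000** over 200 blinded tasks and a
left sample skew of **+0.65** for low-frequency probes against **+0.28**
for high-frequency ones.

The same pipeline is available from the shell:

```sh
pkword2vec synth --out-dir work --seed 1
pkword2vec train --corpus work/corpus.txt --lexicon work/lexicon.tsv \
    --no-mask --alpha 0 --dim 25 --seed 1 --out work/sgns.vec
pkword2vec train --corpus work/corpus.txt --lexicon work/lexicon.tsv \
    --no-mask --alpha 300 --dim 25 --seed 1 \
    --prior toy:non-medical:work/prior.vec \
    --prior toy-med:medical:work/prior.vec --out work/pk.vec
pkword2vec similar --model work/pk.vec --word w000 --k 5
```

Raw text corpora go through `pkword2vec preprocess`, which masks URLs,
email addresses, phone numbers, timestamps and numerals before
tokenization.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — synthetic
world, prior-weight selection, baseline and regularized training, blinded
task generation and vote scoring — logging summary figures to stderr and
writing the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
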