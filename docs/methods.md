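# Methods

This note documents the model implemented by `pkword2vec`, the choices
made where the design was genuinely open, and what the synthetic test
world does and does not establish.

## Model

### Skip-gram with negative sampling (SGNS)

Each vocabulary word has a center vector `v` (used when the word anchors a
prediction) and a context vector `u` (used when it neighbors another
center word). For a token stream `w_1 … w_T` and window `m`, every
(center, context) pair within the window contributes

```
-log σ(u_ctxᵀ v_ctr) − Σ_{k=1..K} log σ(−u_kᵀ v_ctr)
```

with `K` negatives drawn from the unigram distribution
`P(w) ∝ count(w)^ρ`. Negatives that collide with the pair's own center or
context word are resampled.

### Prior-knowledge regularizer

A *prior source* is a pre-trained embedding restricted to the corpus
vocabulary words of one category (each category has exactly one source;
unknown words default to the non-medical category). For a covered word
`t`, the candidate set is every covered same-category word `j ≠ t` whose
pre-trained cosine is at least `θ`, and the sampling distribution is the
softmax (temperature 1, normalized after thresholding) of the surviving
cosines. `θ` is calibrated as the mean of the pooled top-10 cosine scores;
by default calibration runs on the corpus-restricted vectors (the small-
corpus focus), with whole-model calibration available via a flag.
Candidate tables are precomputed once — they depend only on the fixed
pre-trained space — so each training step costs one inverse-CDF draw.

Each time a covered center word `t` is processed, one `j ~ p_tj` is drawn
and the penalty `γ(t)·Ψ` is added, where
`Ψ = [1 − cos(u_t,u_j)] + [1 − cos(v_t,v_j)]` and `γ(t) = τ/rel_freq(t)`
(`rel_freq = count/T`, so `γ` is dimensionless). Exactly one prior word is
sampled per center-word *occurrence*, not per window pair, and the sum
over occurrences means each word type's total prior weight per epoch is
`τ·T` regardless of its frequency — rare words get the same total pull
from far fewer, individually stronger nudges. Disabling
`context_regularization` drops the `u`-space term; the context term exists
because context vectors of co-occurring words estimate each other's center
vectors, so regularizing them propagates the prior signal to words with no
prior knowledge of their own.

Total objective: `Loss = Loss_SGNS + α · Loss_PK`. At `α = 0` the trainer
is bit-identical to plain SGNS (prior sampling uses its own RNG stream, so
its mere presence cannot perturb the baseline path).

## Optimization

Plain single-threaded SGD with a linearly decaying learning rate
(default initial 0.025, floor 1e-4 of the initial). Center rows are
initialized uniformly in `[−0.5/d, 0.5/d]`, context rows at zero (the
word2vec convention). Four independent RNG streams (initialization,
document shuffling, negative sampling, prior sampling) are spawned from
the seed, making runs exactly reproducible and the `α = 0` path exactly
the SGNS path.

`batch_size` (default 10,000 occurrences) is the data-grouping and
loss-accounting unit. Parameter updates, however, are applied every
`update_every = 8` occurrences with summed gradients: applying a single
summed update per 10,000-occurrence batch accumulates thousands of stale
gradients per frequent row and diverges, while averaging over the batch
leaves only a handful of effective steps per epoch on a small corpus and
cannot converge. The micro-batch update keeps the learning rate at its
classic per-example scale; one micro-step is numerically identical to
`params -= lr * grad` for the analytic batch gradient (tested).

## The α scale

The per-type prior weight per epoch is `τ·T`. With the default
`τ = 1e-5`, a multi-million-token corpus gives `τ·T` in the tens, whereas
the desk-scale synthetic corpus (25,000 tokens) gives `τ·T = 0.25` —
roughly 280× smaller. Under plain SGD the regime where the prior
meaningfully competes with the SGNS gradient is where the per-occurrence
weight `α·γ` for a median-frequency word reaches ~0.1–1; at desk scale
(`γ_median ≈ 6e-3`) that is `α ≈ 10–300`. The tuning grid for the
synthetic world is therefore `{0, 1, 3, 10, 30, 100, 300}`. Published α
values for large corpora are not transferable across corpus sizes or
optimizer normalizations; the tuning procedure below, not a fixed
constant, is the portable object.

## Hyperparameter selection

The *similarity distribution* of a model pools, for every word, its
cosine similarities to its 10 most similar words; it is a fingerprint of
embedding geometry that needs no external word-pair benchmark.

* **Embedding size `d`** — for each grid value, train pure SGNS with a
  fixed seed and compute the 1-D Wasserstein distance between its
  similarity distribution and a large reference model's, both restricted
  to their shared vocabulary (like-for-like); pick the argmin.
* **Prior weight `α`** — for each grid value, train the regularized model
  and compute the three pairwise Wasserstein distances among the low-,
  mid- and high-frequency tertile similarity distributions. The score is
  their mean; the variance of the three breaks ties. This favors weights
  at which embedding quality is balanced across frequency, since frequent
  words are otherwise represented better. Distances to the reference model
  per tertile are reported as diagnostics only.

Tertiles order words by ascending count with word-id tie-break and split
into three groups whose sizes differ by at most one (remainder to the
lower tertiles first). One training run per grid point with a fixed seed;
a repeats option exists for variance estimates.

## Evaluation harness

`generate_tasks` samples probe words without replacement, preserving the
vocabulary's category proportions (largest-remainder rounding), and emits
blinded A/B tasks pairing both models' top-5 lists with a per-task
randomized assignment; the same seed reproduces the task set, assignments
included. Overlapping top-5 lists are allowed (an option can require
disjoint lists). Scoring reports:

* **Support rate** — the fraction of tasks the regularized model wins by
  majority vote, overall and stratified by category, prior coverage and
  frequency tertile. Exact ties and unvoted tasks are reported separately
  and excluded from the denominator (with an odd number of voters per
  task, ties cannot occur).
* **Preference skewness** — the adjusted Fisher–Pearson sample skewness of
  the per-task proportion of reviewers choosing the regularized model, per
  tertile. Proportions piled near 1.0 stretch a tail to the *left*, so the
  raw standardized third moment is negative there; the report carries both
  `skewness` (raw) and `left_skew` (its negation, the convention under
  which such results are usually quoted as large positive values). A
  stratum of identical proportions reports 0; fewer than 3 voted tasks in
  a stratum is an error.

The mixed-effects regression sometimes fitted to such vote tables is out
of scope, but the task schema retains the covariates (category, prior
coverage, stratum) needed to fit one externally.

## Synthetic world

The generator emulates the statistical shape of a small clinical-message
corpus with no access-restricted data: Zipf marginals (exponent 1.05 —
flat enough that a 300-word vocabulary is fully observed in 25,000
tokens), 500 documents of 50 tokens, 20 planted 5-word synonym clusters
assigned at random ranks so clusters span the frequency range, an 80/20
non-medical/medical partition, and a toy prior embedding built from
cluster centroids plus Gaussian noise (scale 0.1), covering 70% of each
category. Cluster co-occurrence comes from a mixture process — each
document activates 2 clusters and reweights their members' Zipf mass by
`boost` (default 5) — so `boost = 1` is exactly the null Zipf model and
within-cluster lift is directly countable. The prior lives in 32
dimensions, deliberately unrelated to the trained dimension.

What a green test establishes: the regularizer recovers planted synonym
structure that the corpus alone cannot (cluster-mate recall@5 rises from
~0.03 to ~0.25–0.30), the gain concentrates on rare words, and the
context term propagates signal to uncovered words. What it does not: any
claim about real clinical language — the world has no morphology, no
polysemy, no document topicality beyond the planted clusters, and its
SGNS baseline is deliberately data-starved.

Because the underfit baseline has globally inflated cosines, the
propagation of prior signal to uncovered words is measured
discriminatively — own-cluster-centroid cosine minus mean
other-centroid cosine — rather than by raw centroid cosine, which any
differentiation of a degenerate space would lower.

## Numerical choices

* Sigmoid values are clamped to `[1e-12, 1 − 1e-12]` inside logs; the
  sigmoid itself underflows to exactly 0/1 harmlessly.
* Cosine terms skip (zero loss, zero gradient) any pair involving a
  vector of norm < 1e-9 — this occurs only for still-zero context rows in
  the first micro-batches. The standalone `psi` function rejects zero
  vectors outright.
* Top-k neighbor queries break cosine ties by word id; candidate tables
  order by descending cosine with id tie-break; tertile ties break by id.
  All selection procedures are deterministic given the seed.
* Degenerate inputs error early: empty corpora and vocabularies, fewer
  than 11 covered words for θ calibration, fewer than `k + 1` words for a
  similarity distribution, malformed vector files (header, dimension,
  duplicates, truncation).
* Word-frequency discounting uses relative frequency, so `γ` and hence
  `α` are invariant to duplicating every document.

## Known limitations

* The trainer is desk-scale: dense numpy batches, full-matrix scatter
  adds, no hierarchical softmax, no multi-threading. Vocabularies beyond
  ~10⁴ words or corpora beyond ~10⁷ tokens need a different engine.
* `θ` calibration and candidate construction are O(|V|²) in the covered
  vocabulary (chunked, but quadratic).
* The operative `α` range depends on corpus size through `τ·T`; values
  tuned on one corpus do not transfer (see "The α scale").
* Masking rules are pragmatic regexes, not a de-identification guarantee.
* With very few voters per task, majority ties are excluded from the
  support rate, which can bias it when tie rates differ across strata.
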