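# themeclust

EM-based thematic clustering of text documents with cluster-dependent
subject-term selection.

## What it does

Most document-clustering pipelines partition a corpus and only afterwards
ask what each cluster is about. `themeclust` couples the two: a *theme* is a
pair (U, V) of a subject-term set U and a document set V such that the terms
of U occur with elevated probability exactly in the documents of V. Under a
Bernoulli term-occurrence model, a term t ∈ U occurs in a document of V with
probability p_t and outside V with probability q_t, while every other term
occurs everywhere at its background rate r_t = n_t / N (n_t the term's
document frequency, N the corpus size). Fitting both the term set and the
partition in one EM loop yields clusters that come with their own
human-readable description — useful for organizing large biomedical
literature collections (e.g. grouping a disease-query result set into
sub-topics such as particular proteins, treatments or pathologies).

The score driving subject-term selection is the gain in expected
complete-data log-likelihood from modelling term t theme-specifically
instead of with its background rate:

    α_t = n_st ln(p_t/r_t) + (n_s − n_st) ln((1−p_t)/(1−r_t))
        + (n_t − n_st) ln(q_t/r_t) + (N − n_t − n_s + n_st) ln((1−q_t)/(1−r_t))

with n_s = Σ_d pz_d the (soft) cluster size and n_st = Σ_d δ_td pz_d the
term/cluster co-occurrence. Each cluster keeps the n_U largest-α terms as
its subject terms; documents are re-assigned to the cluster with the highest
posterior membership pz_d; clusters that win no document vanish, so the
final cluster count is data-driven. Restarts are ranked by the theme score
Q = Σ_i Σ_{t∈U_i} (α_t^{V_i})², which tracks clustering quality against
ground truth closely (measured rank correlation ≈ 0.99 on planted corpora).

The package also implements the matching evaluation toolkit — normalized
mutual information (NMI), paired F-score between two runs' subject-term
sets, title selection by T(P) = Σ_{t⊆P} α_t·DF(t), hypergeometric label
enrichment — and a planted-theme synthetic corpus generator so the whole
pipeline is testable without any external corpus.

## Worked example

Generate a planted corpus of 3 themes × 100 documents (30 theme terms per
theme at p_in = 0.3 / p_out = 0.01, 500 background terms at 0.05), cluster
it, and score against the planted labels:

```sh
themeclust simulate --themes 3 --docs-per-theme 100 --theme-vocab 30 \
    --bg-vocab 500 --seed 0 --output corpus
themeclust cluster --input corpus/corpus.jsonl --format jsonl \
    --k 3 --n-u 100 --restarts 20 --seed 0 --no-bigrams --output run
themeclust evaluate --assignments run.assignments.tsv --truth corpus/labels.tsv
```

prints

```
wrote 300 documents to corpus
best Q=106022.0578 (seed 4), final k=3
NMI	1.000000
```

i.e. the best theme-score run among 20 restarts recovers the planted
partition exactly (NMI = 1). The per-cluster subject terms in
`run.themes.json` are the planted vocabularies — each cluster's top terms
are drawn from a single theme:

```
cluster 0 (100 docs): theme1_term15 theme1_term1 theme1_term18 ...
cluster 1 (100 docs): theme0_term23 theme0_term17 theme0_term2 ...
cluster 2 (100 docs): theme2_term25 theme2_term9 theme2_term1 ...
```

and `themeclust enrich --assignments run.assignments.tsv --labels
corpus/labels.tsv --top 1` shows each cluster perfectly enriched for its own
planted label (hypergeometric p = 2.4e-82 for 100/100 labelled documents in
a cluster of 100 from a corpus of 300).

Real corpora are read from a directory of text files, JSON Lines
(`{"id": ..., "text": ...}`), or tab-separated `id title abstract` records;
see `themeclust cluster --help` for the preprocessing knobs (stopword list,
unigram/bigram terms, document-frequency floor).

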