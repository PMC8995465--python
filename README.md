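# litscape

Offline bibliometric topic-modeling of PubMed-style corpora.

Large literature fields — the motivating case is pancreatic cancer research,
tens of thousands of abstracts over 25 years — are too big to survey by
reading. `litscape` reimplements the machine-learning bibliometric workflow
used for such surveys as a tested, fully offline pipeline for anyone who has
a MEDLINE/PubMed XML download (or wants to rehearse the analysis on a
synthetic stand-in):

1. **Screening** — parse PubMed article-set XML; exclude records by
   publication type (meeting abstracts, proceedings papers, corrections, book
   reviews, news items) or missing metadata, then by non-English language or
   incomplete abstract, with flowchart-style accounting of every removal.
2. **Topic modeling** — latent Dirichlet allocation fitted by collapsed
   Gibbs sampling. Each document d mixes K topics, θ_d ~ Dir(α); each topic k
   is a word distribution φ_k ~ Dir(β). Token topics are resampled from
   p(z_i = k | z₋ᵢ, w) ∝ (n_kw + β)/(n_k + Vβ) · (n_dk + α), and the number
   of topics is chosen by held-out perplexity
   exp(−Σ_d Σ_w c_dw log Σ_k θ_dk φ_kw / N).
3. **Topic network** — each document is labelled with its two
   highest-probability topics; nodes are topics (size = primary-topic
   publications), edges count documents sharing that top-2 pair; communities
   come from Louvain modularity maximisation,
   Q = Σ_c [W_c/m − γ(d_c/2m)²].
4. **Trends** — publications per year, mean annual output, average
   year-over-year growth, OLS slopes per category, MeSH-descriptor frequency
   and proportion series, emerging-term detection (first appearance after a
   baseline year), country shares resolved from affiliations, and
   topic-by-year heatmap matrices.
5. **Synthetic corpora** — a seed-deterministic generator plants known topic
   structure, per-year prevalence drift, country/language/publication-type
   distributions and exclusion flags, so every stage can be validated against
   ground truth without a live download.

## Worked example

```python
from litscape import (GeneratorConfig, generate, apply_type_filter,
                      apply_language_abstract_filter, build_corpus, fit, LdaConfig,
                      assign_topics, build_network, louvain, modularity, top_terms)
from litscape.trends import annual_counts, mean_annual, avg_growth_rate, country_shares

records, truth = generate(GeneratorConfig(D=1000, V=150, doc_length_mean=80, seed=4))
kept, n_type = apply_type_filter(records)
kept, n_lang = apply_language_abstract_filter(kept, min_abstract_tokens=40)
print(f"screened {len(records)} -> {len(kept)} (type: {n_type}, language/abstract: {n_lang})")

corpus = build_corpus(kept, min_df=5)
model = fit(corpus, LdaConfig(K=5, alpha=0.1, beta=0.01, n_iterations=500, burn_in=250, seed=4))
print("top terms, topic 0:", [t for t, _ in top_terms(model, 0, 5)])

assignments = assign_topics(model.theta, model.doc_ids)
network = build_network(assignments, n_topics=model.K)
partition = louvain(network, seed=4)
print(f"network: {network.number_of_nodes()} topics, {network.number_of_edges()} edges, "
      f"{len(set(partition.values()))} communities (Q={modularity(network, partition):.3f})")

counts = annual_counts(kept, (1996, 2021))
print(f"mean annual output: {mean_annual(int(counts.sum()), len(counts))}, "
      f"avg growth rate: {avg_growth_rate(counts.values):.2f}%")
print(country_shares(kept).head(3).to_string(index=False))
```

prints

```
screened 1000 -> 837 (type: 3, language/abstract: 160)
top terms, topic 0: ['qn', 'qde', 'qed', 'qag', 'qdn']
network: 5 topics, 10 edges, 1 communities (Q=0.000)
mean annual output: 32, avg growth rate: 5.50%
      country  count  percentage
United States    236        28.2
        China    142        17.0
        Japan     65         7.8
```

The screening line is the two-stage exclusion accounting (3 records carried
excluded publication types or missing metadata; 160 were non-English or had
abstracts under 40 tokens). Topic-0 terms are the generator's synthetic
vocabulary — on real abstracts they would be the words an analyst uses to
label the topic. With only five broad topics every top-2 pair occurs, so the
network is a single dense community (Q = 0); at realistic K (the workflow
default is 50) the network decomposes into thematic clusters. The trend lines
recover what the generator planted: ~5.4% annual growth and the configured
country shares.

The same pipeline runs from the shell:

```sh
litscape all --config config.yaml          # simulate/parse -> ... -> report
litscape filter --config config.yaml       # or any single stage
```

where `config.yaml` sets paths, screening thresholds, LDA settings and the
trend window (see `litscape.pipeline.PipelineConfig`). To analyse a real
download, point `input_xml` at a PubMed article-set XML file.

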