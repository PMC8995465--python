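# Methods

## Corpus screening

A corpus is a list of `PublicationRecord`s parsed from PubMed article-set
XML (`lxml`). Screening happens in two auditable stages, mirroring the
flowchart conventions of bibliometric studies:

1. **Type / missing-data stage.** A record is removed iff any of its
   publication types is in the excluded set — default {Meeting Abstract,
   Proceedings Paper, Correction, Book Review, News Item} — or mandatory
   metadata (PMID, title, publication year) is missing. The excluded-type
   list and the missing-data rule are deliberately combined into one stage
   because published flowcharts report them as a single count.
2. **Language / abstract stage.** A record is removed iff its XML `Language`
   element is not English or its tokenized abstract has fewer than
   `min_abstract_tokens` tokens. "Incomplete abstract" has no standard
   definition; we operationalise it as a token floor, default 50, which
   removes stubs and truncated imports without discarding genuinely short
   abstracts. Language comes from metadata, not text detection, matching
   MEDLINE practice.

Both filters preserve input order and are idempotent; a `FilterReport`
enforces the accounting identity initial − stage1 − stage2 = final. Records
outside the configured year window are dropped before stage 1.

**Country resolution** scans comma-separated affiliation segments right to
left (affiliations conventionally end with the country) against a bundled
gazetteer of country names, common variants and US state names/postal codes.
Two-letter gazetteer entries match only upper-case tokens so prose words
("in", "or") cannot fire postal codes. Unresolvable records count under an
"Unknown" sentinel — kept in denominators, excluded from rankings — rather
than being dropped.

## Text preprocessing

Lower-case alphabetic tokenization (punctuation and standalone numbers
dropped, hyphenated compounds split), a packaged English stopword list, a
document-frequency floor (`min_df`, default 5), no stemming or n-grams.
Vocabulary terms are sorted lexicographically, so construction is invariant
to document order. Abstract-only text is modeled by default; titles can be
concatenated in via `use_title`.

## Latent Dirichlet allocation

Inference is collapsed Gibbs sampling: θ and φ are integrated out and each
token's topic is resampled from

p(z_i = k | z₋ᵢ, w) ∝ (n_kw + β)/(n_k + Vβ) · (n_dk + α).

Defaults: α = 50/K, β = 0.01 (the usual heuristics for abstract-length
documents), 1,000 sweeps with 500 burn-in. φ and θ are posterior means
computed from counts averaged over every 10th post-burn-in sweep — variance
reduction at no cost to determinism. `log_joint` evaluates the exact
collapsed joint p(w, z) via log-gamma identities; it doubles as the
enumeration oracle in the tests and as the model-selection criterion across
restarts.

**Determinism.** The per-token sweep is JIT-compiled (numba) and uses an
explicit 64-bit LCG whose state is seeded through a splitmix64 finalizer, so
identical seed and input give bit-identical assignments on any platform, and
nearby integer seeds give unrelated streams.

**Restarts.** Gibbs chains on near-single-topic corpora occasionally stall
in a topic merge/split mode. With `n_restarts > 1`, independent chains run
from seeds seed, seed+1, … and the chain whose final state has the highest
collapsed log-joint is kept — standard practice for mode-seeking MCMC and
fully deterministic.

**Topic-number selection.** `select_k` splits documents 90/10 by seed, fits
each candidate K on the training part, folds held-out documents in (Gibbs on
z with φ fixed, 50 sweeps) and reports held-out perplexity. Perplexity of a
uniform topic-word model is exactly V, a useful sanity anchor. Only the
perplexity criterion is automated; redundancy/legibility judgments about K
are left to the analyst.

## Topic network and communities

Each document's top-2 topics come from a stable argsort of its θ row, ties
broken toward the lowest topic index. Node size counts **primary**-topic
documents, so sizes partition the corpus; edge weights count documents per
unordered top-2 pair; hence Σ sizes = Σ weights = D, checked as an invariant.
Zero-document topics are retained as size-0 nodes. Graphs serialise to
GraphML/GEXF (networkx) for downstream visualisation tools.

Louvain maximises weighted modularity Q = Σ_c [W_c/m − γ(d_c/2m)²]
(resolution γ, default 1) in the canonical two phases: shuffled-order local
moves, each node to its **best**-gain neighbouring community, repeated until
stable, then community aggregation. Best-gain (rather than first-positive)
moves follow the original algorithm and reach better optima; visit order is
shuffled by the seed, so results are deterministic per seed. Modularity is
asserted non-decreasing across levels. Isolated nodes keep their own
communities; edgeless graphs return singletons. An exhaustive set-partition
search (restricted growth strings, ≤ 10 nodes) provides the global optimum
as a test oracle. Like every greedy modularity maximiser, Louvain can stop
in a local optimum on dense weighted graphs; the reference networkx
implementation stalls on the identical instances, and multiple seeds recover
the optimum.

## Trends

All per-year tallies are zero-filled over a contiguous window and
permutation-invariant. Conventions worth stating:

- `mean_annual` truncates (floor) rather than rounds, matching how such
  means are conventionally reported (60,296/25 → 2,411).
- `avg_growth_rate` is the arithmetic mean of year-over-year percentage
  changes — the most literal reading of "average growth rate"; `cagr` is
  available as the geometric alternative.
- `proportion` uses exact decimal arithmetic with half-away-from-zero
  rounding (37/118 → 31.4%).
- MeSH trend machinery also serves publication-type categories
  (`attribute="pub_types"`) and arbitrary term lists such as gene symbols.
- An "emerging term" is a descriptor whose first corpus appearance is after
  the baseline year; ordering is by total count, ties lexicographic.

## Synthetic corpus generator

The generator emulates the statistical shape of a MEDLINE download:
per-record metadata, abstracts drawn from a planted LDA process
(θ_d ~ Dir(α_true·K·prevalence[year]), tokens topic-then-word), per-year
prevalence drift, country/language/publication-type label distributions, and
exact exclusion-stage flag counts. Defaults describe the emulated study
conditions: a 1996–2021 window with ~5.42% annual output growth, five
planted topics drifting linearly (early topics fade, late topics rise),
~100-token abstracts, Dirichlet(0.1)/Dirichlet(0.01) document and topic
priors, country shares concentrated in the usual top publishing countries
with a 20% unresolvable mass, and flag fractions matching the real screening
(~0.26% type exclusions, ~16% language/abstract exclusions). Per-year sizes
come from a largest-remainder allocation of geometric growth weights, so
they sum exactly to D.

MeSH descriptors attach to documents whose dominant planted topic matches
the term's topic, never before the term's configured emergence year, and each
term is guaranteed one occurrence in its emergence year (when that year has
documents), making first-appearance statistics exactly recoverable. The
screening-accounting fixture (`make_paper_fixture`) instantiates the
generator at 60,453 records with exactly 157 and 9,642 flags and minimal
6-token abstracts; because flagged "incomplete" abstracts are empty, any
completeness threshold in [1, 6] reproduces the accounting, and the fixture
is screened with a threshold of 5.

**What the generator does not emulate:** natural-language prose (abstracts
are token streams — adequate because every consumer sees only bag-of-words
counts), citation structure, journal metadata, MeSH hierarchy, or correlated
noise between metadata fields. Passing recovery tests therefore demonstrate
correctness of the algorithms under the generative assumptions, not
robustness to real-text phenomena like synonymy or OCR noise.

## Problem sizes and numerical choices

Recovery tests use planted corpora of 300–2,000 documents with vocabularies
of 120–200 words and 60–100-token abstracts — large enough for the
law-of-large-numbers properties they assert (token-topic frequencies within
2% at D = 2,000; matched total-variation recovery error ~0.01 at D = 500),
small enough that the full suite runs in well under a minute. The
micro-scale sampler check (2 documents × 2 tokens, V = 3, K = 2) compares
10,000 chain endpoints against the exactly enumerated collapsed posterior by
chi-square. Degenerate inputs are errors, not silent defaults: empty corpora,
zero-weight graphs, zero denominators, mismatched lengths and out-of-range
topics all raise. Ties anywhere (argmax topics, top terms, rankings) break
deterministically toward the lowest index or lexicographic order.
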