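# Methods

## The discovery problem

Clinicians describing serious mental illness (SMI) in free-text notes use a
far richer vocabulary than curated terminologies record: "combatative",
"truculent" or "stared menacingly" all express aggression, but none is a
terminology entry. Given a large patient-attributed corpus and a *small*
amount of prior knowledge — a lexicon of literal stems for internationally
recognised symptom concepts — the pipeline finds the regions of the
vocabulary where clinician-preferred symptom language lives, so that human
curation can focus on a few thousand candidate terms instead of a million.

The chain is: phrase-aware vocabulary construction → CBOW word embedding →
k-means clustering of the term vectors → prior-concept relevance scoring →
robust outlier selection → curation analytics. The bespoke element is the
scoring step; everything around it is standard machinery.

## Pre-processing and phrase induction

Documents are segmented into sentences at terminal punctuation and
lowercased; tokens are runs of letters/digits/apostrophes or single
punctuation symbols. The segmenter sits behind a small interface so an
unsupervised boundary model can be substituted where one is available; the
packaged implementation is rule-based, which is exact on the synthetic
corpora (whose sentences end in `.`) and hermetic for tests.

No stemming, lemmatisation or spell correction is applied anywhere: the
point of the exercise is to observe language as written, and misspellings
are themselves discoverable synonyms.

Fixed collocations are joined into single underscore tokens in two passes
(bigrams, then trigrams as bigram+unigram joins). A pair (a, b) is joined
iff

    count(ab) >= min_count   and   (count(ab) − min_count) · N
                                   ───────────────────────────  >= threshold
                                      count(a) · count(b)

with N the corpus token count. Both `min_count` (default 10, which doubles
as the discount δ) and `threshold` (default 10) are configurable; the
discounted pointwise form is the standard sampling-based collocation score
for this task. Joins are restricted to word-like tokens and capped at
trigram order. Application is greedy left-to-right and idempotent; joining
conserves tokens (the underscore orders of the output always sum to the
input length).

The vocabulary records exact corpus frequency, n-gram order and a word flag
(≥ 1 alphabetic character) per term; unigram/bigram/trigram/non-word
subtotals partition the vocabulary, so their sum is the total size — the
reporting path checks this identity rather than assuming it.

## The CBOW embedding

The embedding is a compact continuous-bag-of-words trainer with negative
sampling, written against numpy. A term is predicted from the average of
its context vectors within a sentence window (windows never cross sentence
boundaries, matching the sentence-level tokenisation); the input matrix W
(o × n for o vocabulary terms) is the embedding. Parameters that matter:

| parameter | default | notes |
|---|---|---|
| n (dimension) | 100 (library), 50 (pipeline) | 50 is ample for vocabularies of ~10³ terms |
| window | 5 | context half-width in tokens |
| min_count | 5 | terms below it are not embedded |
| negative | 5 | noise samples per prediction, unigram^0.75 distribution |
| epochs | 1 (library), 10 (pipeline) | see below |
| alpha → min_alpha | 0.025 → 1e-4 | linear decay over all updates |

Hierarchical softmax is not implemented; negative sampling is the simpler
contract to reproduce, and its seeded single-threaded update order makes
vectors bit-reproducible for a fixed seed.

On a production-scale corpus (tens of millions of records) one epoch
suffices because the update volume is enormous. A desk-scale synthetic
corpus of ~10⁵ tokens delivers roughly 10⁻³ of that volume per pass, so the
pipeline default is 10 epochs — chosen once, as a scaling compensation, so
that the total number of gradient updates is large enough for family
structure to emerge; single-epoch behaviour remains available through
`EmbeddingParams`.

## Clustering and choosing k

Terms are partitioned with Euclidean k-means++ on the raw (unnormalised)
vectors, 8 independent seeded restarts, best inertia wins, ties to the
lowest restart index. Pairwise-distance methods (silhouette, classic elbow
on sample distances) need O(n²) memory and are deliberately avoided; k is
instead chosen from the **minimum pairwise centroid distance** curve over a
k grid: while genuine structure remains, new centroids stay far apart; once
k exceeds the real cluster count, some cluster is split and the minimum
distance collapses to within-cluster scale.

`suggest_k` returns the smallest scanned k after which every later step's
relative decrease stays below a flatten tolerance; if the decline never
flattens the largest scanned k is returned with a `no_elbow` flag. An
explicit k always overrides the suggestion — on real corpora this choice is
usually made by eye.

Two numerical choices deserve note:

- **Grid** (pipeline default 2–28, denser at small k): the embedding
  vocabulary is ~1.4k terms, so scanning into the hundreds would only chart
  the splitting of individual planted families.
- **Flatten tolerance** (pipeline default 0.25): on corpora with many tight
  sub-clusters inside one symptom super-cluster, the curve descends in
  plateau steps of ~0.2 relative as successive families are split off,
  while the genuine macro-drops are 0.6–0.8 relative. The tolerance sits
  between the two scales. The `suggest_k` function default is stricter
  (0.05), appropriate for smooth curves.

## Relevance scoring and selection

Each prior concept (PC) i is a literal lowercase stem (underscores span
induced n-gram boundaries, e.g. `eye_contact`); the packaged lexicon holds
38 SMI symptom stems. Matching is case-insensitive substring containment
compiled as literal regular expressions — every packaged pattern is a
literal stem, so containment and regex search coincide. The count matrix
x has x[i, j] = number of cluster-j terms containing stem i (a term
containing two stems increments both rows).

Each row is min–max rescaled: with u_i = min_j x_ij and v_i = max_j x_ij,

    x′_ij = (x_ij − u_i) / (v_i − u_i),

so no single over-represented stem can dominate — adding a constant to a
whole PC row provably changes nothing downstream (asserted as a property
test). A constant row (v = u) carries no between-cluster information and is
defined as all zeros, which neutralises that PC consistently with the
equal-weighting intent. The cluster score is the size-normalised rescaled
mass

    z_j = Σ_i x′_ij / s_j ,

with s_j the cluster's term count; the division removes the advantage large
clusters would gain just by holding more terms.

Selection is robust because score distributions are heavily skewed: select
every cluster with z_j ≥ median(z) + 6·MAD(z), where the MAD is the
*unscaled* median absolute deviation (no normal-consistency constant). The
≥ is deliberate ("at least" six MADs). When MAD(z) = 0 — more than half the
clusters score identically, typically zero — the threshold collapses onto
the median and the rule degenerates: clusters strictly above the median are
selected, or every cluster when all scores tie, and a `degenerate_mad` flag
is raised so the selection is treated with suspicion.

## Curation analytics

First-stage filtering removes, with reason codes: terms containing any
single-character token part (tokenisation debris such as `y`), terms
composed entirely of stop words (`of_the`), and terms with no alphabetic
character. The stopword list is packaged and swappable.

Agreement between two annotators over a closed category scheme — eight
substantive psychiatric-assessment categories (Appearance/Behaviour,
Speech, Affect/Mood, Thought, Perception, Cognition, Insight, Personality)
plus a residual Other — is summarised with Cohen's κ = (p_o − p_e)/(1 − p_e),
p_e from the marginal category frequencies, with the degenerate
both-annotators-constant-and-identical case defined as κ = 1. The
per-category agreement table is label-agnostic (any labelling flows
through; everything except Other counts as substantive), so published
tables with historical category labels can be fed through the same
reporting path.

Concept frequencies are counted over **raw document text**, not phrased
tokens: a concept's stem (underscores → spaces) is matched case-insensitively
as a substring, and distinct patient ids and document ids are counted. A
document belongs to exactly one patient, so document count ≥ patient count
always. The anonymity rule then discards any concept appearing in
`min_patients` (default 10) **or fewer** unique patient records — the
boundary is strict. Terminology mapping (direct / synonym-or-partial /
novel) is a manual protocol; the module only stores and tallies its
outcomes.

## The synthetic corpus generator

The generator emulates the statistical structure the pipeline exploits,
not clinical language:

- **Documents**: 250 patients × 4–12 documents × 3–8 sentences
  (~2,000 documents, ~10⁵ tokens) under the default configuration.
- **Symptom sentences** (35% of sentences): one of ~20 carrier templates
  with 1–3 slots, all slots filled from a single randomly chosen synonym
  family. Most templates have one slot, so family identity is a
  second-order signal (within-sentence co-occurrence) on top of the shared
  carrier contexts — the symptom vocabulary forms one broad context regime
  with family sub-structure, which is what makes mixed symptom clusters,
  and hence discovery of non-seeded families, possible at moderate k.
- **Families**: 30 synonym families of 3–6 surface terms. Unigram families
  mix shared-stem morphological variants (stem + suffix) with unrelated
  synonym words — mirroring how "agitated/agitation" co-exist with
  "combatative" as expressions of one concept. One family in five is a
  two-token collocation with a shared head, exercising the phrase-induction
  path.
- **PC lexicon**: 12 of the 30 families seed the lexicon, the pattern being
  the 4-character stem prefix (or the canonical joined bigram). Family
  terms that do not contain any lexicon pattern — unrelated synonyms of
  seeded families plus all terms of the 18 unseeded families — are the
  *discoverable* ground truth.
- **Background**: 1,500 words sampled Zipf(1.05) in filler sentences. Each
  unigram PC pattern is additionally embedded inside 3 unrelated background
  words ("homographs", the way "elat" sits inside "related"). This
  word-sense collision is essential to a non-degenerate study: without it
  every background cluster scores exactly zero and the median/MAD rule
  degenerates, which real corpora — where stems hit ambiguous words spread
  over many clusters — do not exhibit.
- **Misspellings** (3% of symptom emissions): one character substitution,
  deletion or adjacent transposition at position ≥ 4, so the first four
  characters — and therefore stem matching — survive, mirroring observed
  variants like "combatative". Injected variants are recorded in the
  ground truth as family members.
- All randomness flows from one generator seeded by the config; corpora
  are byte-identical across runs with the same seed.

What the generator does **not** emulate: real clinical syntax, section
structure, de-identification artefacts, acronym ambiguity, and the heavy
tail of a million-term vocabulary. A passing recovery test therefore shows
that the pipeline's machinery — phrasing, embedding, clustering, scoring,
selection — correctly exploits shared-context structure at realistic
signal-to-noise; it does not certify performance on any specific EHR
corpus.

## Recovery evaluation

`evaluate_recovery` reports the fraction of discoverable planted terms that
end up inside the selected clusters. Terms below the embedding frequency
floor are excluded from the denominator (nothing downstream ever sees
them); background terms inside the selection are counted as the cost of the
trawl. On the reference corpus (default configuration and seed) the
pipeline suggests k = 8, selects a single symptom cluster non-degenerately,
and recovers ≥ 99% of eligible discoverable terms with no background terms
selected; the regression suite asserts the pre-registered ≥ 70% bound
rather than the observed value.

## Known limitations

- The CBOW trainer is plain numpy and single-threaded: ample for ~10⁵-token
  corpora, not for production-scale ones.
- The flatten-tolerance elbow rule inherits the elbow method's fragility;
  the `no_elbow` flag and the explicit-k override exist precisely because
  the choice is judgement-laden on real data.
- Substring stem matching over-counts stems that occur inside unrelated
  words; the min–max rescaling bounds, but does not eliminate, the effect.
- The SNOMED-style mapping step is represented as a data model and summary
  only; actual terminology release parsing is out of scope.
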