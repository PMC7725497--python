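# Methods

This note documents the models and procedures implemented in `hatescan`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Corpus hygiene

A record is treated as a retweet when its text starts with `RT @` (a
boolean metadata flag is unavailable once tweets are reduced to the five
retained attributes: id, text, creation time, user id, location).
Duplicate detection keys on the *orthographically normalized* text:
"identical content" is ambiguous about spelling variants, and
normalizing first prevents near-identical bot copies from surviving as
distinct. Within a duplicate group the earliest `created_at` survives,
ties broken by lexicographic id; output order is input order.

## Text preprocessing

Normalization folds the three hamzated/madda alef forms (U+0623, U+0625,
U+0622) to bare alef, alef maksura (U+0649) to yeh, teh marbuta (U+0629)
to heh, strips the harakat range U+064B–U+065F, removes punctuation and
symbol characters, case-folds Latin script and collapses whitespace.
This is the conventional Arabic normalization triple; it is idempotent.

Cleaning replaces URLs and @-mentions with the literal tokens `URL` and
`mention` *before* removing non-Arabic letters (private-use sentinels
carry the placeholders through that step, which also makes re-cleaning
cleaned text a no-op). Emoji handling differs by consumer: classifier
inputs get lower-cased, underscore-joined short-name description tokens
(e.g. `enraged_face`), because affect-bearing emoji are signal for hate
classification; topic-model inputs drop emoji entirely. The short-name
table covers the emoji the generator emits; any other pictograph maps to
the generic token `emoji`. "Consecutive word" removal is interpreted as
collapsing immediately repeated identical tokens — the narrowest reading
that is well defined. Arabic punctuation and digits are removed together
with other punctuation. Lemmatization is a pluggable token→lemma table
(any morphological analyzer's output can be injected; none is bundled),
and stop-word removal is an order-preserving filter against a normalized
stop list (a 40-word Arabic function-word list ships as the default).

## Geolocation

The lexicon is built from a (country, name, name_type) gazetteer with
name_type ∈ {country, city, alias}. Every name is normalized and
expanded with morphological variants: the bare form, the definite
article `ال` + name, and the proclitics `و`, `ب`, `ل`, `في` attached to
both (Arabic-script names only; the clitic set is a declared choice —
the variant inventory of informal place-name writing is open-ended).
Resolution normalizes the query, collects candidate matches over all
contiguous token n-grams (longest first, so multiword aliases like
`دار زايد` match) plus the full string, then applies: a single candidate
country wins; with several, a match on a country-type name outranks
city/alias matches; any remaining tie is UNRESOLVED. UNRESOLVED is a
value, not an error — those records are dropped, as in the study design.
The precedence-then-drop rule is deliberately conservative: silently
assigning an ambiguous "Tripoli" to either country would corrupt every
per-country statistic downstream.

The packaged default gazetteer covers the 22 Arab League states with
Arabic country/city names and common informal aliases (`Q8`, `KSA`,
`Dar Zayed`, …). Its names are chosen to be unambiguous across
countries so that noise-free synthetic corpora resolve exactly;
ambiguous fixtures for testing the tie rule are built explicitly.

## Hate scorer

Architecture: embedding (dim 100, index 0 = padding, frozen at zero;
one dedicated unknown index) → three parallel 1-D convolution branches
with kernel sizes 2, 3, 4 (100 filters each, rectified) → global max
pooling per branch, concatenated → dense 64 rectified → single sigmoid
unit. Loss is binary cross-entropy, optimized with Adam (lr 1e-3,
β = 0.9/0.999), batch size 32, 5 epochs, max sequence length 50. The
kernel-size triple is the defining choice; the remaining sizes are
conventional short-text defaults and all are configurable. The network
is implemented directly on NumPy with explicit backpropagation, making
training a pure function of (config, data, seed): a fixed seed
reproduces vocabularies and scores bit for bit.

Vocabulary takes the most frequent `vocab_size` tokens, frequency ties
broken lexicographically (stability across runs). Scores at or above
0.5 are hate. Levels bin the hate range as low [0.50, 0.675), average
[0.675, 0.855), high [0.855, 1.0]: the published two-decimal bin labels
(0.50–0.67, 0.68–0.85, 0.86–1.00) leave the intervals 0.67–0.68 and
0.85–0.86 unassigned, so the bins here meet at the gap midpoints —
every score must receive a level. Checkpoints are a directory of
config (JSON), vocabulary (TSV) and weights (JSON), all plain text.

Tests verify that training on a vocabulary-separable synthetic set
reaches held-out F1 ≥ 0.95 while shuffled-label training stays near the
chance floor (single-shuffle F1 is noisy — roughly 0.3–0.6 across
shuffles — so the reproduction script reports a 3-shuffle mean). These
sizes (n = 2,000, embedding/filters 50/50, max_len 30, 3 epochs) train
in a few seconds and are the package's standard test conditions.

## Stratified statistics

The three study periods are 2020-01-27..02-29, 03-01..03-31 and
04-01..04-30. The published period boundaries ("March 1-30" vs "April
1-30") leave March 31 unassigned; it is folded into the second window
so every timestamp belongs to exactly one period, and the report
metadata notes this. Timestamps outside all windows raise an error
rather than being silently dropped or reassigned.

Per stratum (country or period) the table reports n_total, n_hate,
n_nonhate, the three level counts, pct_hate = n_hate/n_total·100, level
percentages relative to the stratum's n_hate, and the mean hate score
over hate tweets (NaN when a stratum has no hate tweets). Reported
percentages are rounded **half-up** to one decimal (two where the
source tables print two); raw values are retained in machine-readable
output, and all percentages are recomputable from the reported counts.
Percent change is (after − before)/before · 100 and is undefined for
before ≤ 0. Pearson r/p uses the standard product-moment statistic with
the two-sided t-transform p on n−2 df (scipy's implementation; tests
check it against a hand-expanded formula to 1e-12), requiring n ≥ 3 and
nonzero variance.

## Topic model

Features are TF-IDF over unigrams plus adjacent bigrams: raw term
counts, smoothed idf ln((1+n)/(1+df)) + 1, L2-normalized rows, minimum
document frequency 2 (prevents singleton-bigram vocabulary blowup; the
exact weighting variant is a recorded, configurable default). The
factorization X ≈ WH (W, H ≥ 0) minimizes the Frobenius reconstruction
error by multiplicative updates, whose objective is provably
non-increasing; the recorded objective trace is asserted monotone in
tests and an independent cross-check compares the final error against
scikit-learn's coordinate-descent NMF on the same matrix.
Initialization is the deterministic nonnegative double-SVD scheme with
zero entries filled by the matrix mean, so fits are reproducible
without seed sweeps (the `seed` parameter exists for interface
stability only). Default k = 7 topics, matching the study configuration
this pipeline reimplements.

Topic summaries: top-n terms per topic by H weight (ties lexicographic)
and the share of documents whose W row peaks on each topic (ties to the
lowest index; all-zero rows land in a separate `unassigned` bucket).
Whether a published "distribution" column is an argmax share or a
normalized weight mass is generally ambiguous; argmax share is the
declared choice here. A UMass coherence diagnostic is provided as a
clearly-labelled optional extension.

## Synthetic data: what it emulates, and what it does not

The corpus generator is a pure function of (config, seed). Texts are
8–18 synthetic tokens over the Arabic alphabet mixed with genuine Arabic
function words; 20 % of tweets get a URL, 20 % a mention, 15 % an emoji.
Hate tweets (Bernoulli per record at `hate_prevalence`, default 0.03)
additionally carry 3–5 anchor tokens of exactly one planted topic
(7 topics × 4 anchors by default, mixture configurable); non-hate tweets
never contain anchors. Countries follow a Gulf/Egypt-heavy mixture and
periods a 0.217/0.464/0.319 split shaped like the study's per-period
volumes. Locations are drawn from the record's true country's gazetteer
rows; at `alias_noise_rate` (default 0.15) an informal alias or
clitic-prefixed variant is used instead. Beyond the core knobs the
generator adds `retweet_rate`, `unlocated_rate` (default 0.05 each) and
`topic_weights`, because the dedup and resolver stages need retweets and
unresolvable locations to act on. Duplicates are verbatim copies of
earlier non-retweet records (text, location and derived labels copied;
own id and timestamp). Timestamps are uniform within each period
window — the analysis has period-level resolution only, so no intra-day
structure is modelled.

The labelled training set draws each hate text either entirely from a
hate-indicative pool (probability = `separability`) or entirely from
the benign pool; non-hate texts use the benign pool only. This makes
the number of indicative hate texts exactly Binomial(n_hate,
separability) and the two classes vocabulary-disjoint at separability
1. Note the training-set pools are independent of any corpus's
vocabulary: to score a generated corpus coherently, train on a balanced
corpus from the same generator seed (which shares its background and
anchor pools) — `examples/04` and `hatescan simulate training
--corpus-seed` do exactly this.

The epidemic series standardizes the hate-count vector, adds an
orthogonalized noise vector scaled by √(1−ρ²), and maps the result to
nonnegative integer case counts, so the sample correlation equals the
target ρ exactly before rounding (and exactly, by an integer affine
construction, at ρ = ±1 with zero noise); `noise_scale` adds further
independent noise. Deaths are `deaths_per_case` × cases plus noise,
floored at zero. Fewer than 3 strata or constant hate counts are
rejected as degenerate.

**Limitations.** Passing tests on this generator demonstrate the
pipeline's mechanics — conservation of counts, exact geolocation under
clean input, separable-class learnability, planted-topic and
planted-correlation recovery — not performance on real Arabic social
media. Real tweets have dialectal morphology, code-switching, sarcasm
and topic drift that the token-stream model does not imitate (by
design: the anchors are neutral placeholder tokens, and no actual hate
speech is generated or shipped). Real location strings are noisier than
the alias model, and real hate/case correlations are confounded in ways
a planted-ρ construction is not. Published real-data figures that
depend on the unavailable hydrated corpus (overall corpus totals, the
observed r = 0.1982, the concrete topic term lists) are therefore out
of reach at desk scale; the reproduction script instead recomputes the
published tables' arithmetic from their printed counts and demonstrates
the statistical machinery on the generator.
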