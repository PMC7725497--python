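# hatescan

A tested, reusable pipeline for surveilling hate speech in Arabic
COVID-19-era tweets, aimed at infodemiology and computational social
science researchers. It covers the full analysis chain:

1. **Corpus hygiene** — retweet removal and deduplication of identical
   content (keyed on orthographically normalized text).
2. **Text preprocessing** — Arabic orthographic normalization
   (أ/إ/آ → ا, ى → ي, ة → ه, diacritics stripped), URL/mention
   placeholder tokens, and two cleaning modes: emoji become description
   tokens for the classifier and are deleted for the topic model.
3. **Geolocation** — free-form profile location strings ("Riyadh", "Q8",
   "دار زايد") resolved to countries through a gazetteer-derived lexicon
   expanded with definite-article and proclitic variants; ambiguous
   matches resolve by country-name precedence or are dropped.
4. **Hate scoring** — a convolutional text classifier (embedding → three
   parallel convolution branches with kernel sizes 2, 3, 4 → global max
   pooling → dense → sigmoid), implemented directly on NumPy with
   explicit backpropagation. Each tweet gets a score *s* ∈ [0, 1];
   *s* ≥ 0.5 is labelled hate and binned into levels
   **low** [0.50, 0.675), **average** [0.675, 0.855), **high** [0.855, 1].
5. **Stratified statistics** — per-country and per-period tables
   (counts, hate shares, level shares, mean hate score), signed percent
   changes (after − before)/before × 100, and the Pearson correlation
   *r* (with two-sided *p* from the *t* transform on *n*−2 df) between
   per-(country, period) hate counts and epidemic case counts.
6. **Topic extraction** — TF-IDF (unigrams + adjacent bigrams, smoothed
   idf, L2 rows) and nonnegative matrix factorization X ≈ WH fitted by
   multiplicative updates from a deterministic SVD-based initialization;
   topics are summarized by top terms and by document share (argmax of
   each W row).

Because hydrated tweet collections cannot be redistributed, the package
ships a **synthetic corpus generator** that reproduces the statistical
structure every stage relies on: Arabic-script token streams with
URLs/mentions/emojis, a few percent hate prevalence with planted topic
anchor vocabularies, gazetteer-drawn location strings with informal-alias
noise, verbatim duplicates and retweets, timestamps spanning
2020-01-27..2020-04-30, and epidemic series with an exactly controlled
correlation to hate counts. All generated ground truth is returned
alongside, so every pipeline stage is testable end to end.

## Worked example

```bash
python examples/04_aggregate_and_correlate.py
```

prints (abridged):

```
by-period table:
         n_total  n_hate  pct_hate  mean_hate_score
stratum
0            583      21     3.602            0.981
1           1245      43     3.454            0.994
2            782      23     2.941            0.997

hate-tweet change period 1 -> 2: +104.8%
hate-tweet change period 2 -> 3: -46.5%

Pearson hate vs cases over 66 strata: r=0.2000 (p=0.11) — near the planted 0.2
```

Reading: of 2,610 deduplicated, geolocated synthetic tweets, about 3 %
per period are scored as hate; hate volume roughly doubles into the
March period and falls by half after it (tracking the planted period
mixture); and the hate-count/case-count correlation recovers the
generator's planted ρ = 0.2 — a weak association. The other examples
(`examples/01…05`) each demonstrate one capability: corpus generation,
cleaning + geolocation, classifier training and level binning, and NMF
topic recovery of the planted anchors.

The same stages are available as a thin CLI:

```bash
hatescan simulate corpus --n 5000 --seed 7 --out corpus.jsonl
hatescan simulate gazetteer --out gaz.tsv
hatescan resolve --gazetteer gaz.tsv --in corpus.jsonl --out resolved.jsonl
hatescan simulate training --n 2000 --corpus-seed 7 --out train.tsv
hatescan train --data train.tsv --out model
hatescan score --model model --in resolved.jsonl --out scored.jsonl
hatescan aggregate --in scored.jsonl --out report/
hatescan topics --in scored.jsonl --k 7 --out topics/
```

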