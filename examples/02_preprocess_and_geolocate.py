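"""Clean a corpus and resolve profile locations to countries.

Shows the two text-cleaning modes (emoji become description tokens for the
classifier, disappear for the topic model), retweet/duplicate removal, and
gazetteer-based location resolution including informal aliases like "Q8".
"""
import hatescan as hs

text = "تجربة جديدة 😡 http://t.co/abc @friend"
print("classifier tokens:", hs.clean_text(text, "classifier").tokens)
print("topic tokens     :", hs.clean_text(text, "topic").tokens)

corpus = hs.generate_corpus(hs.CorpusConfig(n_tweets=800, seed=3))
deduped = hs.remove_retweets_and_duplicates(corpus.records)
print(f"\n{len(corpus.records)} records -> {len(deduped)} after removing "
      f"retweets and identical texts")

lexicon = hs.build_lexicon(hs.default_gazetteer())
for raw in ("Riyadh", "Q8", "دار زايد", "بالكويت", "somewhere"):
    print(f"location {raw!r:12} -> {hs.resolve_location(raw, lexicon)}")

resolved = hs.attach_countries(deduped, lexicon)
print(f"\n{len(resolved)}/{len(deduped)} records resolved to a country; "
      "the rest (empty or unrecognizable locations) are dropped, as in the "
      "study design")
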