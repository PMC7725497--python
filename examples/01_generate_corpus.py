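"""Generate a synthetic tweet corpus and inspect its ground truth.

The generator emulates the statistical shape of an Arabic COVID-19 tweet
collection: a few percent of tweets are hate-labelled and built around one
planted topic's anchor vocabulary, locations come from a gazetteer of Arab
countries (sometimes as informal aliases), and a few records are verbatim
duplicates or retweets.
"""
import hatescan as hs

config = hs.CorpusConfig(n_tweets=1000, hate_prevalence=0.03, seed=7)
corpus = hs.generate_corpus(config)

labels = corpus.labels
print(f"records generated      : {len(corpus.records)}")
print(f"hate-labelled          : {int(labels.is_hate.sum())} "
      f"(prevalence {labels.is_hate.mean():.1%})")
print(f"verbatim duplicates    : {int((labels.duplicate_of != '').sum())}")
print(f"retweet-marked         : {int(labels.is_retweet.sum())}")
print(f"distinct countries     : {labels.country.nunique()}")
print(f"planted topics         : {len(corpus.anchors)} "
      f"(anchors per topic: {len(corpus.anchors[0])})")
print("\nfirst record:")
print(corpus.records[0].to_json())
# The hate prevalence is binomial around 3%; every hate tweet's text
# contains anchors of exactly one planted topic, which the topic model
# should later recover.
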