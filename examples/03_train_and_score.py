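"""Train the parallel-kernel CNN hate scorer and bin scores into levels.

Training data is a synthetic labelled set whose hate class carries
indicative vocabulary.  After training, every score >= 0.5 is a hate label,
further binned into low/average/high hate levels.
"""
import numpy as np
from sklearn.metrics import f1_score

import hatescan as hs

df = hs.generate_labeled_training_set(n=2000, separability=1.0, seed=11)
texts = [hs.preprocess_text(t, "classifier").tokens for t in df.text]
labels = df.label.to_numpy()
mask = np.arange(len(df)) % 5 != 0   # 80/20 split

config = hs.CNNConfig(epochs=3, seed=1, embed_dim=50,
                      filters_per_kernel=50, max_len=30)
model = hs.train(config, [t for t, m in zip(texts, mask) if m],
                 labels[mask].tolist())
print("epoch losses:", [round(l, 4) for l in model.loss_trace])

test_texts = [t for t, m in zip(texts, mask) if not m]
pred = (model.scores(test_texts) >= 0.5).astype(int)
print(f"held-out F1: {f1_score(labels[~mask], pred):.3f} "
      "(the classes are vocabulary-disjoint, so near-perfect is expected)")

for score in (0.12, 0.55, 0.72, 0.93):
    hs_score = hs.classify_score(score)
    print(f"score {score:.2f} -> label {hs_score.label:9} level {hs_score.level}")
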