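"""Train skip-gram word vectors on a toy corpus and build an abstract matrix.

Words that co-occur end up with similar vectors; words absent from the
table resolve to the zero vector, which is also how padding rows appear in
the m-by-k abstract matrix fed to the classifier.
"""

import tempfile
from pathlib import Path

import numpy as np

from venuerec.embeddings import embed_abstract, load_word_vectors, save_word_vectors, train_skipgram
from venuerec.text_prep import encode_sequence

rng = np.random.default_rng(0)
corpus = []
for _ in range(400):
    filler = [f"filler{rng.integers(0, 40)}" for _ in range(4)]
    corpus.append(filler[:2] + ["kinase", "phosphorylation"] + filler[2:])
    corpus.append([f"filler{rng.integers(0, 40)}", "sediment"])

table = train_skipgram(corpus, k=16, window=2, epochs=8, seed=1)
print(f"trained {len(table)} vectors of dimension {table.k}")
print(f"cosine(kinase, phosphorylation) = {table.cosine('kinase', 'phosphorylation'):+.3f}")
print(f"cosine(kinase, sediment)        = {table.cosine('kinase', 'sediment'):+.3f}")
# The adjacent pair should score clearly higher than the unrelated word.

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "vectors.bin"
    save_word_vectors(table, path, binary=True)
    reloaded = load_word_vectors(path, expected_k=16)
    print(f"word2vec binary round-trip: {len(reloaded)} vectors preserved")

vocab = {tok: i + 1 for i, tok in enumerate(sorted(table.vectors))}
seq = encode_sequence(["kinase", "phosphorylation", "unseen-token"], vocab, m=10)
mat = embed_abstract(seq, reloaded, vocab)
print(f"abstract matrix shape: {mat.V.shape}; "
      f"zero rows (OOV + padding): {int((~mat.V.any(axis=1)).sum())}")
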