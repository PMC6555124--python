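"""Rank journals for a single abstract with a trained model.

The recommendation path is the deployment path: tokenize the query
abstract, encode it to the fixed-length id sequence, embed, run the
network, and rank the softmax probabilities (ties broken by label).
"""

from venuerec.cnn_model import ModelConfig
from venuerec.pipeline import fit_model
from venuerec.recommender import recommend
from venuerec.synthetic import SyntheticSpec, generate_corpus

records, _ = generate_corpus(SyntheticSpec(
    n_classes=5, class_sizes=(40,) * 5, vocab_size=600,
    topic_sharpness=1.0, seed=3,
))
config = ModelConfig(
    m=100, k=24, conv_stages=((16, 3), (16, 4), (16, 5)),
    hidden_sizes=(64, 32), n_classes=5, batch_size=32,
    max_epochs=60, learning_rate=2e-3, seed=1,
)
model, vocab = fit_model(records, config=config, stop_at_train_acc=0.995)

query = records[17]  # pretend this abstract arrives from a user
result = recommend(model, vocab, query.abstract_text, N=3)
print(f"true journal: {query.journal_label}")
print(result.to_tsv())

# a very short query is still scored, with a warning attached
short = recommend(model, vocab, "lexeme00420 lexeme00421", N=2)
print("short-query warnings:", *short.warnings)
# The top-ranked journal should be the query's true venue; the probability
# column is the softmax confidence over all five candidate journals.
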