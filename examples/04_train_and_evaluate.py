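"""Train the convolutional classifier on a synthetic corpus and evaluate it.

A small study condition: 5 journals, 80 abstracts each, topic sharpness
0.9. The network — three conv/ReLU/max-pool stages over the token-vector
matrix, then two hidden layers and a softmax — is scaled down from the
reference geometry (m=350, k=200, kernels 256/128/96) to run in seconds.
"""

from venuerec.cnn_model import ModelConfig
from venuerec.corpus_io import build_journal_catalog, split_corpus
from venuerec.evaluation import evaluate_rankings
from venuerec.pipeline import fit_model, predict_rankings
from venuerec.synthetic import SyntheticSpec, generate_corpus

records, _ = generate_corpus(SyntheticSpec(
    n_classes=5, class_sizes=(80,) * 5, vocab_size=1500,
    topic_sharpness=0.9, seed=3,
))
split = split_corpus(records, (0.8, 0.1, 0.1), seed=3)
catalog = build_journal_catalog(records)

config = ModelConfig(
    m=100, k=24, conv_stages=((16, 3), (16, 4), (16, 5)),
    hidden_sizes=(64, 32), n_classes=5, batch_size=32,
    max_epochs=15, learning_rate=2e-3, seed=1,
)
model, vocab = fit_model(split.train, split.validation, config)
for h in model.history[-3:]:
    print(f"epoch {h['epoch']:2d}: loss {h['loss']:.4f}  "
          f"train acc {h['train_acc']:.3f}  val acc {h['val_acc']:.3f}")

ranked, truth = predict_rankings(model, vocab, split.test)
report = evaluate_rankings(ranked, truth, catalog=catalog, n_values=(1, 3, 5))
print()
print(report.to_tsv())
# acc@N is the fraction of held-out abstracts whose true journal appears in
# the top N recommendations; it is non-decreasing in N by construction and
# reaches 1.0 at N = number of journals.
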