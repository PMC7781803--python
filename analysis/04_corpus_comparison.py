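"""Corpus 1 vs corpus 2: does the modern-medicine diagnosis token help?

Pairs two Word2Vec-CNN arms on identical records, split and seeds; the
only difference is the diagnosis token appended to every document in
corpus 2.  The comparison regime uses an ambiguous element lexicon
(overlap 0.8) and no disease-correlated symptom tokens, so the
diagnosis token is the only route by which the disease can inform the
pattern — the setting where its marginal value is identifiable.

Run from the repository root:  python analysis/04_corpus_comparison.py
"""

from pathlib import Path

from syndromedx.evaluation import compare_corpora
from syndromedx.pipeline import PipelineConfig, corpus_pipeline
from syndromedx.rulebase import load_rulebase
from syndromedx.synthetic import GeneratorConfig, Lexicon, generate_records

OUT = Path("results")
SEED = 22


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rb = load_rulebase()
    cfg = GeneratorConfig(n_records=2000, seed=SEED, noise_token_rate=0.2)
    lex = Lexicon.default(overlap=0.8, tokens_per_disease=0, seed=SEED)
    records = generate_records(cfg, rb, lex)

    pipe = corpus_pipeline(
        PipelineConfig(algorithm="cnn", path="mbr", dimension=32,
                       min_count=2, embed_epochs=3),
        rb,
    )
    cmp = compare_corpora(records, pipe, seed=SEED)
    cmp.table.to_csv(OUT / "corpus_comparison.csv")
    print(f"corpus 1 accuracy: {cmp.corpus1.accuracy:.4f}")
    print(f"corpus 2 accuracy: {cmp.corpus2.accuracy:.4f}")
    print(f"delta (corpus2 - corpus1): {cmp.delta_accuracy:+.4f}")
    print(f"per-pattern table written to {OUT/'corpus_comparison.csv'}")


if __name__ == "__main__":
    main()
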