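"""Benchmark the nine MBR+RBR arms: element prediction + rule combination.

Each arm predicts the syndrome-element set with a multilabel classifier
and combines it into a pattern through the rule knowledge base.  The
report pairs end-to-end pattern accuracy with element-level
precision/recall/F1 — element metrics typically exceed pattern accuracy
because a pattern is only right when the whole element set maps
exactly.  SVM is excluded from the multilabel roster.

Run after 01_simulate_emr.py:  python analysis/03_mbr_rbr_benchmark.py
"""

from pathlib import Path

import pandas as pd

from syndromedx.pipeline import PipelineConfig, run_pipeline
from syndromedx.rulebase import load_rulebase
from syndromedx.synthetic import read_records

DATA = Path("scratch/data")
OUT = Path("results")
SEED = 20

ARMS = [
    ("word", "rf", {"n_estimators": 200}),
    ("word", "xgboost", {}),
    ("word", "knn", {}),
    ("word", "mlp", {"hidden_layer_sizes": (256, 128, 64, 64, 64, 64), "max_iter": 400}),
    ("word", "cnn", {}),
    ("doc", "rf", {"n_estimators": 200}),
    ("doc", "xgboost", {}),
    ("doc", "knn", {}),
    ("doc", "mlp", {"hidden_layer_sizes": (256, 128, 64, 64, 64, 64), "max_iter": 400}),
]


def main() -> None:
    rb = load_rulebase()
    train = read_records(DATA / "train.jsonl")
    test = read_records(DATA / "test.jsonl")
    external = read_records(DATA / "external.jsonl")

    rows = []
    for embedding, algorithm, overrides in ARMS:
        cfg = PipelineConfig(
            embedding=embedding, algorithm=algorithm, path="mbr_rbr",
            dimension=32, min_count=2, embed_epochs=5,
            classifier_overrides=overrides,
        )
        for ds_name, ds in [("test", test), ("external", external)]:
            res = run_pipeline(train, ds, cfg, rb=rb, seed=SEED)
            statuses = pd.Series([d.match_status for d in res.diagnoses])
            rows.append(
                {
                    "embedding": embedding, "algorithm": algorithm,
                    "dataset": ds_name, **res.report.to_dict(),
                    "exact_matches": int((statuses == "exact").sum()),
                    "partial_matches": int((statuses == "partial").sum()),
                    "no_match": int((statuses == "none").sum()),
                }
            )
            print(
                f"{embedding:4s} {algorithm:8s} {ds_name:8s} "
                f"acc={res.report.accuracy:.4f} element-f1={res.report.f1:.4f}"
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "mbr_rbr_benchmark.csv", index=False)
    best = frame[frame.dataset == "test"].sort_values("accuracy", ascending=False).iloc[0]
    print(
        f"\nbest hybrid arm: {best.embedding} {best.algorithm} "
        f"(pattern acc {best.accuracy:.4f}, element F1 {best.f1:.4f})"
    )


if __name__ == "__main__":
    main()
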