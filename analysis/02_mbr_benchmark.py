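"""Benchmark the eleven MBR arms: direct pattern diagnosis.

Trains Word2Vec x {RF, XGBoost, SVM, KNN, MLP, CNN} and Doc2Vec x
{RF, XGBoost, SVM, KNN, MLP} on the simulated development set, scores
each on the held-out test split and the external set, and adds a
reduced repeated-CV confidence interval (5-fold x 2 repeats) for the
best word-level arm.  Desk-scale settings: 32-dimensional embeddings,
reduced tree counts and MLP widths.

Run after 01_simulate_emr.py:  python analysis/02_mbr_benchmark.py
"""

from pathlib import Path

import pandas as pd

from syndromedx.evaluation import repeated_cv
from syndromedx.pipeline import PipelineConfig, cv_pipeline, run_pipeline
from syndromedx.rulebase import load_rulebase
from syndromedx.synthetic import read_records

DATA = Path("scratch/data")
OUT = Path("results")
SEED = 20

ARMS = [
    ("word", "rf", {"n_estimators": 200}),
    ("word", "xgboost", {}),
    ("word", "svm", {}),
    ("word", "knn", {}),
    ("word", "mlp", {"hidden_layer_sizes": (256, 128, 64, 64, 64, 64), "max_iter": 400}),
    ("word", "cnn", {}),
    ("doc", "rf", {"n_estimators": 200}),
    ("doc", "xgboost", {}),
    ("doc", "svm", {}),
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
            embedding=embedding, algorithm=algorithm, path="mbr",
            dimension=32, min_count=2, embed_epochs=5,
            classifier_overrides=overrides,
        )
        for ds_name, ds in [("test", test), ("external", external)]:
            report = run_pipeline(train, ds, cfg, rb=rb, seed=SEED).report
            rows.append(
                {
                    "embedding": embedding, "algorithm": algorithm,
                    "dataset": ds_name, **report.to_dict(),
                }
            )
            print(
                f"{embedding:4s} {algorithm:8s} {ds_name:8s} "
                f"acc={report.accuracy:.4f} f1={report.f1:.4f}"
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "mbr_benchmark.csv", index=False)

    best = (
        frame[frame.dataset == "test"]
        .sort_values("accuracy", ascending=False)
        .iloc[0]
    )
    print(f"\nbest test arm: {best.embedding} {best.algorithm} (acc {best.accuracy:.4f})")

    cv_cfg = PipelineConfig(
        embedding="word", algorithm="cnn", path="mbr",
        dimension=32, min_count=2, embed_epochs=3,
    )
    cv = repeated_cv(cv_pipeline(cv_cfg, rb), train, folds=5, repeats=2, seed=SEED)
    cv_rows = [
        {"metric": m, "mean": r.mean, "ci_low": r.ci_low,
         "ci_high": r.ci_high, "n_scores": r.n_scores}
        for m, r in cv.items()
    ]
    pd.DataFrame(cv_rows).to_csv(OUT / "mbr_cnn_cv.csv", index=False)
    acc = cv["accuracy"]
    print(
        f"word-cnn repeated CV accuracy: {acc.mean:.4f} "
        f"(95% CI {acc.ci_low:.4f}-{acc.ci_high:.4f}, {acc.n_scores} folds)"
    )


if __name__ == "__main__":
    main()
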