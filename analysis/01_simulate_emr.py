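"""Simulate the working data sets.

Generates a desk-scale development set (2,000 records, 10 syndrome
patterns, 8 lung diseases) and an independent external set (500 records
from a different seed), both rule-consistent by construction, and
writes them as JSON-lines under scratch/data/.  A small per-class
summary table goes to results/.

Run from the repository root:  python analysis/01_simulate_emr.py
"""

from pathlib import Path

import pandas as pd

from syndromedx.rulebase import load_rulebase
from syndromedx.synthetic import (
    GeneratorConfig,
    Lexicon,
    expected_elements_per_record,
    generate_records,
    split_dataset,
    write_records,
)

OUT_DATA = Path("scratch/data")
OUT_RESULTS = Path("results")
DEV_SEED, EXT_SEED = 20, 21


def main() -> None:
    OUT_DATA.mkdir(parents=True, exist_ok=True)
    OUT_RESULTS.mkdir(exist_ok=True)
    rb = load_rulebase()
    lex = Lexicon.default()

    dev_cfg = GeneratorConfig(n_records=2000, seed=DEV_SEED)
    dev = generate_records(dev_cfg, rb, lex)
    ext = generate_records(GeneratorConfig(n_records=500, seed=EXT_SEED), rb, lex)
    train, test = split_dataset(dev, (4, 1), "pattern", seed=DEV_SEED)

    write_records(dev, OUT_DATA / "development.jsonl")
    write_records(ext, OUT_DATA / "external.jsonl")
    write_records(train, OUT_DATA / "train.jsonl")
    write_records(test, OUT_DATA / "test.jsonl")

    rows = []
    for name, records in [("development", dev), ("external", ext)]:
        frame = pd.DataFrame(
            {
                "pattern": [r.pattern for r in records],
                "disease": [r.disease for r in records],
                "n_elements": [len(r.elements) for r in records],
            }
        )
        summary = frame.groupby("pattern").agg(
            n=("pattern", "size"), mean_elements=("n_elements", "mean")
        )
        summary["dataset"] = name
        rows.append(summary.reset_index())
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(OUT_RESULTS / "dataset_summary.csv", index=False)

    mean_el = sum(len(r.elements) for r in dev) / len(dev)
    print(f"development set: {len(dev)} records ({len(train)} train / {len(test)} test)")
    print(f"external set:    {len(ext)} records")
    print(
        f"mean elements per record: {mean_el:.3f} "
        f"(table-implied expectation {expected_elements_per_record(dev_cfg, rb):.3f})"
    )
    print(f"per-pattern summary written to {OUT_RESULTS/'dataset_summary.csv'}")


if __name__ == "__main__":
    main()
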