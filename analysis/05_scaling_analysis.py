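"""Accuracy vs (per-class sample size x number of pattern types).

Fills the scaling grid in an estimation-limited regime (sparse evidence
per record, wide lexicon, 40% noise tokens) with a fast token-count
random-forest pipeline, finds the first threshold crossings per class
count, and fits the crossing-size line by OLS.  Also verifies, on
synthetic crossings from a known line (slope 35, intercept 110, noise
sd 20), that the crossing-then-OLS procedure recovers the slope.

Run from the repository root:  python analysis/05_scaling_analysis.py
"""

import json
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from syndromedx.rulebase import load_rulebase
from syndromedx.scaling import (
    first_crossing,
    fit_size_vs_classes,
    run_grid,
    synthesize_crossings,
)
from syndromedx.synthetic import GeneratorConfig, Lexicon

OUT = Path("results")
SEED = 23
SIZES = [16, 32, 64, 128, 256, 512]
COUNTS = [2, 4, 6, 8, 10]
THRESHOLDS = [0.7, 0.8]


def token_count_pipeline(lex):
    vocab = sorted({t for toks in lex.element_tokens.values() for t in toks})
    tindex = {t: i for i, t in enumerate(vocab)}

    def featurize(records):
        X = np.zeros((len(records), len(vocab)))
        for i, r in enumerate(records):
            for t in r.tokens:
                j = tindex.get(t)
                if j is not None:
                    X[i, j] += 1
        return X

    def pipeline(train, test, seed):
        clf = RandomForestClassifier(n_estimators=20, random_state=seed, n_jobs=1)
        clf.fit(featurize(train), [r.pattern for r in train])
        preds = clf.predict(featurize(test))
        return float(np.mean([p == r.pattern for p, r in zip(preds, test)]))

    return pipeline


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rb = load_rulebase()
    lex = Lexicon.default(tokens_per_element=40, overlap=0.0, seed=SEED)
    gen_cfg = GeneratorConfig(seed=SEED, noise_token_rate=0.4, tokens_per_element=1.5)
    grid = run_grid(
        gen_cfg, token_count_pipeline(lex), SIZES, COUNTS,
        rb=rb, lex=lex, class_subset_seed=SEED,
    )
    grid.to_csv(OUT / "scaling_grid.csv")
    pivot = grid.to_frame().pivot(
        index="per_class_n", columns="n_classes", values="accuracy"
    )
    print("accuracy grid:")
    print(pivot.round(3).to_string())

    fits = {}
    for th in THRESHOLDS:
        crossings = first_crossing(grid, th)
        entry = {"crossings": {str(k): v for k, v in crossings.items()}}
        try:
            fit = fit_size_vs_classes(crossings, threshold=th)
            entry["fit"] = {
                "slope": fit.slope, "intercept": fit.intercept,
                "p_value": fit.p_value, "censored": fit.censored,
            }
            print(
                f"threshold {th}: Y = {fit.slope:.2f} X + {fit.intercept:.2f} "
                f"(p={fit.p_value:.3g}, censored columns: {fit.censored})"
            )
        except ValueError as exc:
            entry["fit"] = {"error": str(exc)}
            print(f"threshold {th}: {exc}")
        fits[f"{th:g}"] = entry

    crossings = synthesize_crossings(35.0, 110.0, 20.0, range(2, 11), seed=SEED)
    recov = fit_size_vs_classes(crossings)
    fits["known_line_recovery"] = {
        "true_slope": 35.0, "true_intercept": 110.0,
        "recovered_slope": recov.slope, "recovered_intercept": recov.intercept,
        "p_value": recov.p_value,
    }
    print(
        f"known-line recovery: slope {recov.slope:.2f} (truth 35), "
        f"intercept {recov.intercept:.2f} (truth 110)"
    )
    (OUT / "scaling_fits.json").write_text(json.dumps(fits, indent=2))


if __name__ == "__main__":
    main()
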