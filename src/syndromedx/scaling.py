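"""Accuracy scaling over (per-class sample size × number of pattern types).

Reproduces the sample-size-planning procedure: fill an accuracy grid by
training the pipeline on balanced draws of ``per_class_n`` records for a
random subset of ``n_classes`` patterns (4:1 train/test split, one split
per cell), find for each class count the smallest per-class size whose
accuracy first reaches a threshold, and fit an ordinary-least-squares
line of that crossing size on the class count.  Class subsets are fixed
per column from the seed, and columns that never reach the threshold
are reported as censored rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import PipelineConfig, run_pipeline
from .rulebase import PATTERNS, RuleBase
from .synthetic import (
    ClinicalRecord,
    GeneratorConfig,
    Lexicon,
    generate_balanced,
    split_dataset,
)

__all__ = [
    "ScalingCell",
    "ScalingGrid",
    "LinearFit",
    "FitError",
    "run_grid",
    "first_crossing",
    "fit_size_vs_classes",
    "synthesize_crossings",
]


class FitError(ValueError):
    """Not enough non-censored crossing points for a linear fit."""


@dataclass
class ScalingCell:
    per_class_n: int
    n_classes: int
    accuracy: float
    seed: int
    classes: tuple[str, ...] = ()


@dataclass
class ScalingGrid:
    cells: list[ScalingCell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "per_class_n": c.per_class_n,
                    "n_classes": c.n_classes,
                    "accuracy": c.accuracy,
                    "seed": c.seed,
                }
                for c in self.cells
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    p_value: float
    threshold: float
    points: list[tuple[int, int]]
    censored: list[int] = field(default_factory=list)


def run_grid(
    gen_cfg: GeneratorConfig,
    pipeline_cfg: PipelineConfig | Callable[[list, list, int], float],
    per_class_sizes: Sequence[int],
    class_counts: Sequence[int],
    rb: RuleBase,
    lex: Optional[Lexicon] = None,
    class_subset_seed: int = 0,
) -> ScalingGrid:
    """Fill the accuracy grid; one balanced draw + 4:1 split per cell.

    ``pipeline_cfg`` is either a :class:`PipelineConfig` or a callable
    ``(train, test, seed) -> accuracy`` for custom/faster cells.
    """
    cells = []
    master = np.random.default_rng(class_subset_seed)
    for n_classes in class_counts:
        if not 2 <= n_classes <= len(PATTERNS):
            raise ValueError(f"n_classes must be in [2, {len(PATTERNS)}]")
        col_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        classes = tuple(
            np.array(PATTERNS)[col_rng.choice(len(PATTERNS), n_classes, replace=False)]
        )
        for size in per_class_sizes:
            cell_seed = int(col_rng.integers(0, 2**31 - 1))
            from dataclasses import replace

            cfg = replace(gen_cfg, seed=cell_seed)
            records = generate_balanced(cfg, rb, lex, classes, size)
            train, test = split_dataset(records, (4, 1), "pattern", seed=cell_seed)
            if callable(pipeline_cfg) and not isinstance(pipeline_cfg, PipelineConfig):
                acc = float(pipeline_cfg(train, test, cell_seed))
            else:
                acc = run_pipeline(train, test, pipeline_cfg, rb=rb, seed=cell_seed).report.accuracy
            cells.append(
                ScalingCell(
                    per_class_n=size, n_classes=n_classes,
                    accuracy=acc, seed=cell_seed, classes=classes,
                )
            )
    return ScalingGrid(cells)


def first_crossing(grid: ScalingGrid, threshold: float) -> dict[int, Optional[int]]:
    """Smallest per-class size whose accuracy first reaches ``threshold``.

    Returns one entry per class count; ``None`` marks a censored column
    (the threshold is never reached at the sizes probed).
    """
    frame = grid.to_frame()
    out: dict[int, Optional[int]] = {}
    for n_classes, col in frame.groupby("n_classes"):
        col = col.sort_values("per_class_n")
        hit = col[col["accuracy"] >= threshold]
        out[int(n_classes)] = int(hit["per_class_n"].iloc[0]) if len(hit) else None
    return out


def fit_size_vs_classes(
    crossings: dict[int, Optional[int]], threshold: float = float("nan")
) -> LinearFit:
    """OLS of minimal per-class size (Y) on the number of class types (X).

    Censored columns are excluded and reported; fewer than 3 usable
    points raises :class:`FitError`.  The slope p-value is the two-sided
    t-test of the regression slope.
    """
    points = sorted((x, y) for x, y in crossings.items() if y is not None)
    censored = sorted(x for x, y in crossings.items() if y is None)
    if len(points) < 3:
        raise FitError(f"need >= 3 non-censored crossings, got {len(points)}")
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    res = stats.linregress(xs, ys)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        threshold=threshold,
        points=points,
        censored=censored,
    )


def synthesize_crossings(
    slope: float,
    intercept: float,
    noise_sd: float,
    class_counts: Sequence[int],
    seed: int = 0,
) -> dict[int, int]:
    """Noisy crossings from a known line, for fit-recovery checks."""
    rng = np.random.default_rng(seed)
    return {
        int(x): int(round(slope * x + intercept + rng.normal(0, noise_sd)))
        for x in class_counts
    }
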