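"""Stability-based hyperparameter selection.

The similarity values carry no labels, so accuracy-style model selection is
impossible.  Instead, each candidate configuration is judged by the
dispersion of the full target x candidate cosine-similarity vector it
produces: the standard deviation (SD) and coefficient of variation
(CV = SD / mean).  One axis (hidden units or epochs) is varied at a time
while the other stays at its default, and the value minimizing CV wins
(ties broken by smaller SD, then by the smaller hyperparameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgi import TrainConfig, train
from .kg import KnowledgeGraph
from .similarity import pairwise_similarity

DEFAULT_HIDDEN_GRID = (32, 64, 128, 512)
DEFAULT_EPOCH_GRID = (9, 26, 47, 95, 97, 151)


def sd_cv(values) -> tuple[float, float]:
    """Sample standard deviation and coefficient of variation SD/mean.

    CV is scale-free; it is NaN (with a warning) when the mean is zero.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("sd/cv need at least two values")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    if mean == 0.0:
        warnings.warn("mean is zero; CV undefined, reported as NaN")
        return sd, float("nan")
    return sd, sd / mean


@dataclass
class StabilityReport:
    """One row per (axis, configuration, seed); rows carry sd/cv of the
    similarity vector produced by that configuration."""

    rows: pd.DataFrame
    recommendation: tuple[int, int] | None = None

    COLUMNS = ("axis", "hidden_units", "epochs", "seed", "sd", "cv", "n_values")


def sweep(
    graph: KnowledgeGraph,
    base_config: TrainConfig,
    hidden_grid=DEFAULT_HIDDEN_GRID,
    epoch_grid=DEFAULT_EPOCH_GRID,
    seeds=(0,),
    keep_values: bool = False,
) -> StabilityReport:
    """Single-axis hyperparameter sweep.

    Varies hidden units over ``hidden_grid`` (epochs at default), then
    epochs over ``epoch_grid`` (hidden units at default); trains one model
    per configuration x seed and records the dispersion of its full
    target x candidate cosine vector.  Deterministic given ``seeds``.
    """
    if not len(hidden_grid) or not len(epoch_grid):
        raise ValueError("hyperparameter grids must be non-empty")
    rows = []
    values_store = {}
    axes = [("hidden_units", h, base_config.epochs) for h in hidden_grid]
    axes += [("epochs", base_config.hidden_units, e) for e in epoch_grid]
    for axis, hidden, epochs in axes:
        for seed in seeds:
            config = TrainConfig(
                hidden_units=hidden,
                epochs=epochs,
                learning_rate=base_config.learning_rate,
                n_layers=base_config.n_layers,
                seed=seed,
                activation=base_config.activation,
            )
            try:
                emb = train(graph, config)
            except RuntimeError as err:
                raise RuntimeError(
                    f"sweep failed at hidden_units={hidden}, epochs={epochs}, seed={seed}"
                ) from err
            table = pairwise_similarity(graph, embeddings=emb, metric="cosine")
            sd, cv = sd_cv(table["value"].to_numpy())
            rows.append((axis, hidden, epochs, seed, sd, cv, len(table)))
            if keep_values:
                values_store[(axis, hidden, epochs, seed)] = table
    report = StabilityReport(rows=pd.DataFrame(rows, columns=StabilityReport.COLUMNS))
    report.recommendation = select_config(report)
    if keep_values:
        report.values = values_store
    return report


def _best(frame: pd.DataFrame, column: str) -> int:
    # min cv, tie -> min sd, tie -> smaller hyperparameter (parsimony)
    agg = frame.groupby(column)[["cv", "sd"]].mean().reset_index()
    agg = agg.sort_values(["cv", "sd", column], kind="mergesort")
    return int(agg.iloc[0][column])


def select_config(report: StabilityReport) -> tuple[int, int]:
    """Pick (hidden_units, epochs) minimizing CV per axis.

    This is the objective dispersion rule; a practitioner may still
    override it on expressiveness grounds (the shipped TrainConfig default
    of 128 units / 26 epochs reflects such a judgment).
    """
    rows = report.rows
    if rows.empty:
        raise ValueError("cannot select from an empty report")
    if "axis" in rows.columns and rows["axis"].nunique() > 1:
        hidden_rows = rows[rows["axis"] == "hidden_units"]
        epoch_rows = rows[rows["axis"] == "epochs"]
    else:
        hidden_rows = epoch_rows = rows
    return _best(hidden_rows, "hidden_units"), _best(epoch_rows, "epochs")
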