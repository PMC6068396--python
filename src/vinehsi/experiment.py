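"""The full factorial experiment: grid execution, factor summaries, Tukey tests.

The complete grid crosses 12 preprocessing cells x (18 SVM + 18 MLP)
model configurations x 5 cross-validation replicates = 2,160 rows.  Factor
influence (window size, derivative order, C, kernel, hidden size,
activation, warm start) is assessed by comparing level means with Tukey's
range test (honest significant difference) at p = 0.05, reported with a
compact letter display.  Replicate-level grid rows are the observations of
each comparison, pooled one-way per factor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_builder import SampleTable
from .models import ModelConfig, cross_validate, enumerate_model_grid
from .preprocess import PreprocessConfig, apply_preprocess, enumerate_preprocess_grid

__all__ = [
    "TukeyResult",
    "GRID_COLUMNS",
    "enumerate_grid_cells",
    "run_grid",
    "factor_summary",
    "tukey_hsd",
    "tukey_factor",
    "per_class_summary",
]

logger = logging.getLogger(__name__)

#: factor columns identifying one grid cell, plus metric columns
GRID_COLUMNS = [
    "scatter", "deriv_order", "sg_window", "algorithm",
    "svm_C", "svm_kernel", "mlp_hidden", "mlp_activation", "mlp_warm_start",
    "replicate", "recall", "f1", "auc", "converged", "per_class",
]
_CELL_KEY = GRID_COLUMNS[:10]


@dataclass
class TukeyResult:
    """All-pairs comparison of factor-level means at a family-wise alpha.

    Levels sharing a letter in ``groups`` are not significantly different;
    levels (and means) are reported sorted by descending mean.
    """

    factor: str
    levels: list
    means: list[float]
    groups: list[str]
    p_threshold: float
    significant_pairs: list[tuple]
    p_values: dict


def enumerate_grid_cells(preprocess_configs: Sequence[PreprocessConfig] | None = None,
                         model_configs: Sequence[ModelConfig] | None = None,
                         n_replicates: int = 5,
                         ) -> list[tuple[PreprocessConfig, ModelConfig, int]]:
    """All (preprocess, model, replicate) cells of the (possibly restricted) grid.

    The default grid has 12 x 36 x 5 = 2,160 cells.  Ordering is
    preprocess-major so each preprocessed table can be built once and
    re-used for every model configuration and replicate.
    """
    if preprocess_configs is None:
        preprocess_configs = enumerate_preprocess_grid()
    if model_configs is None:
        model_configs = enumerate_model_grid("svm") + enumerate_model_grid("mlp")
    return [(pp, mc, rep)
            for pp in preprocess_configs
            for mc in model_configs
            for rep in range(1, n_replicates + 1)]


def _row_key(pp: PreprocessConfig, mc: ModelConfig, replicate: int) -> tuple:
    return (bool(pp.scatter), int(pp.deriv_order), int(pp.sg_window), mc.algorithm,
            None if mc.svm_C is None else float(mc.svm_C), mc.svm_kernel,
            mc.mlp_hidden, mc.mlp_activation,
            None if mc.mlp_warm_start is None else bool(mc.mlp_warm_start),
            int(replicate))

def _df_key(row: pd.Series) -> tuple:
    return (bool(row["scatter"]), int(row["deriv_order"]), int(row["sg_window"]),
            row["algorithm"],
            None if pd.isna(row["svm_C"]) else float(row["svm_C"]),
            None if pd.isna(row["svm_kernel"]) else row["svm_kernel"],
            None if pd.isna(row["mlp_hidden"]) else row["mlp_hidden"],
            None if pd.isna(row["mlp_activation"]) else row["mlp_activation"],
            None if pd.isna(row["mlp_warm_start"]) else bool(row["mlp_warm_start"]),
            int(row["replicate"]))


def run_grid(table: SampleTable, seeds: Sequence[int],
             preprocess_configs: Sequence[PreprocessConfig] | None = None,
             model_configs: Sequence[ModelConfig] | None = None,
             k: int = 5, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Run every grid cell with replicated cross-validation.

    ``seeds`` gives one fold-split seed per replicate (5 for the full
    design).  Results are appended to ``out_csv`` (if given) one row per
    completed cell, and cells already present there are skipped on
    restart, making long runs resumable.  A failing cell is logged and the
    grid continues.  Deterministic given the seeds.
    """
    if preprocess_configs is None:
        preprocess_configs = enumerate_preprocess_grid()
    if model_configs is None:
        model_configs = enumerate_model_grid("svm") + enumerate_model_grid("mlp")
    n_replicates = len(seeds)

    done: set[tuple] = set()
    rows: list[dict] = []
    out_path = Path(out_csv) if out_csv else None
    if out_path is not None and out_path.exists():
        prior = pd.read_csv(out_path)
        rows = prior.to_dict("records")
        done = {_df_key(r) for _, r in prior.iterrows()}
        logger.info("run_grid: resuming, %d cells already complete", len(done))

    for pp in preprocess_configs:
        prepared = apply_preprocess(table, pp)
        for mc in model_configs:
            for rep_idx, seed in enumerate(seeds, start=1):
                key = _row_key(pp, mc, rep_idx)
                if key in done:
                    continue
                try:
                    result = cross_validate(prepared, None, mc, k=k,
                                            replicate_seed=int(seed), replicate=rep_idx)
                except Exception:
                    logger.exception("grid cell failed: %s / %s / replicate %d",
                                     pp.label(), mc.label(), rep_idx)
                    continue
                row = {
                    "scatter": pp.scatter, "deriv_order": pp.deriv_order,
                    "sg_window": pp.sg_window, "algorithm": mc.algorithm,
                    "svm_C": mc.svm_C, "svm_kernel": mc.svm_kernel,
                    "mlp_hidden": mc.mlp_hidden, "mlp_activation": mc.mlp_activation,
                    "mlp_warm_start": mc.mlp_warm_start, "replicate": rep_idx,
                    "recall": result.recall, "f1": result.f1, "auc": result.auc,
                    "converged": result.converged,
                    "per_class": json.dumps(result.per_class),
                }
                rows.append(row)
                done.add(key)
                if out_path is not None:
                    pd.DataFrame([row]).to_csv(out_path, mode="a", index=False,
                                               header=not out_path.exists())
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def factor_summary(rows: pd.DataFrame, factor: str, statistic: str = "recall",
                   by: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean of a performance statistic per factor level, optionally nested.

    ``by`` adds outer grouping columns (e.g. ``["algorithm", "deriv_order"]``
    for the window-size layout).  Levels are ordered by descending mean
    within each outer group.
    """
    if rows.empty:
        raise ValueError("no grid rows to summarize")
    for col in [factor, statistic, *(by or [])]:
        if col not in rows.columns:
            raise ValueError(f"unknown column {col!r}")
    keys = [*(by or []), factor]
    out = (rows.groupby(keys, dropna=True)[statistic]
           .agg(mean="mean", n="count").reset_index())
    sort_keys = [*(by or []), "mean"]
    ascending = [True] * len(by or []) + [False]
    return out.sort_values(sort_keys, ascending=ascending, ignore_index=True)


def tukey_hsd(groups: Mapping | Sequence, alpha: float = 0.05,
              factor: str = "") -> TukeyResult:
    """Tukey's range test (honest significant difference) over >= 2 groups.

    All pairwise mean comparisons use the studentized-range distribution
    on the pooled within-group variance, controlling family-wise error at
    ``alpha``.  The compact letter display is derived from the
    significant-pair set by insert-and-absorb.
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = list(range(len(arrays)))
    if len(arrays) < 2:
        raise ValueError("tukey_hsd needs at least 2 groups")
    for lab, arr in zip(labels, arrays):
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError(f"group {lab!r} needs at least 2 values")

    res = stats.tukey_hsd(*arrays)
    k = len(arrays)
    p_values = {}
    significant = []
    for i in range(k):
        for j in range(i + 1, k):
            p = float(res.pvalue[i, j])
            p_values[(labels[i], labels[j])] = p
            if p < alpha:
                significant.append((labels[i], labels[j]))

    means = [float(a.mean()) for a in arrays]
    order = np.argsort(means)[::-1]
    letters = _compact_letter_display(k, {(int(i), int(j)) for i in range(k)
                                          for j in range(i + 1, k)
                                          if res.pvalue[i, j] < alpha}, order)
    return TukeyResult(
        factor=factor,
        levels=[labels[i] for i in order],
        means=[means[i] for i in order],
        groups=[letters[i] for i in order],
        p_threshold=alpha,
        significant_pairs=significant,
        p_values=p_values,
    )


def _compact_letter_display(k: int, significant: set[tuple[int, int]],
                            order: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    Start from one letter covering all levels; for every significant pair
    split each letter containing both; absorb letters that became subsets.
    Returns one letter-string per original group index.
    """
    letter_sets: list[set[int]] = [set(range(k))]
    for i, j in sorted(significant):
        expanded: list[set[int]] = []
        for s in letter_sets:
            if i in s and j in s:
                expanded.extend((s - {i}, s - {j}))
            else:
                expanded.append(s)
        # absorb: keep only maximal, unique, non-empty sets
        letter_sets = []
        for s in expanded:
            if s and s not in letter_sets and not any(s < other for other in expanded):
                letter_sets.append(s)
    # assign letters in the order of the best-ranked member of each set
    rank = {int(g): r for r, g in enumerate(order)}
    letter_sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = ["" for _ in range(k)]
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            labels[g] += letter
    return labels


def tukey_factor(rows: pd.DataFrame, factor: str, statistic: str = "recall",
                 alpha: float = 0.05) -> TukeyResult:
    """Tukey comparison of one factor's levels, pooling all grid rows per level."""
    if factor not in rows.columns or statistic not in rows.columns:
        raise ValueError(f"unknown column {factor!r} or {statistic!r}")
    sub = rows.dropna(subset=[factor])
    groups = {level: g[statistic].to_numpy() for level, g in sub.groupby(factor)}
    return tukey_hsd(groups, alpha=alpha, factor=factor)


def per_class_summary(rows: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-variety mean recall/F1/AUC per algorithm, plus max-min spreads.

    Returns ``(table, spreads)`` where ``table`` has one row per
    (algorithm, variety) and ``spreads[algorithm][statistic]`` is the
    best-minus-worst gap across varieties.
    """
    if "per_class" not in rows.columns or rows.empty:
        raise ValueError("grid rows must carry per_class metrics")
    records = []
    for _, row in rows.iterrows():
        per_class = row["per_class"]
        if isinstance(per_class, str):
            per_class = json.loads(per_class)
        for variety, metrics in per_class.items():
            records.append({"algorithm": row["algorithm"], "variety": variety, **metrics})
    long = pd.DataFrame(records)
    table = (long.groupby(["algorithm", "variety"])[["recall", "f1", "auc"]]
             .mean().reset_index())
    spreads = {}
    for algo, g in table.groupby("algorithm"):
        spreads[algo] = {stat: float(g[stat].max() - g[stat].min())
                         for stat in ("recall", "f1", "auc")}
    return table, spreads
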