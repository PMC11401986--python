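"""Score thresholding and the call-rate / heterozygosity threshold sweep.

Raising a quality threshold trades call rate for purity: calls scoring
below the cut become no-calls.  Sweeping a threshold grid for two score
columns — the vendor GenCall score and the RF-GDA posterior — and tracking
the AB (spurious-heterozygote) fraction per individual reproduces the
standard performance comparison for haploid single-cell batches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .qc import callrate

SHADOW_COLUMN = "gtype_prethreshold"


def set_threshold(table: pd.DataFrame, score_col: str,
                  threshold: float) -> pd.DataFrame:
    """No-call every record whose score is strictly below ``threshold``.

    The original genotype is kept in the shadow column
    ``gtype_prethreshold``; records at or above the threshold (and records
    already NC) are unchanged.  Threshold 0.0 is therefore a no-op.
    """
    if score_col not in table.columns:
        raise ParameterError(f"unknown score column {score_col!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold {threshold} outside [0, 1]")
    out = table.copy()
    if SHADOW_COLUMN not in out.columns:
        out[SHADOW_COLUMN] = out["gtype"]
    below = out[score_col].to_numpy(dtype=float) < threshold
    out.loc[below, "gtype"] = "NC"
    return out


def threshold_sweep(table: pd.DataFrame, score_cols: list[str],
                    grid: list[float] | np.ndarray) -> pd.DataFrame:
    """Per-(individual, threshold, algorithm) genotype-class proportions.

    For each score column ("algorithm") and each grid value, applies
    :func:`set_threshold`, computes call rates grouped by individual,
    pivots the genotype classes to columns, and adds
    ``callrate = AA + AB + BB``.  Long format with ``thr`` and ``alg``
    columns; all algorithms concatenated.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty threshold grid")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ParameterError("grid values must lie in [0, 1]")
    pieces = []
    for col in score_cols:
        if col not in table.columns:
            raise ParameterError(f"unknown score column {col!r}")
        for thr in grid:
            thresholded = set_threshold(table, col, thr)
            rates = callrate(thresholded, ["individual"])
            wide = rates.pivot(index="individual", columns="gtype",
                               values="proportion").reset_index()
            for g in ("AA", "AB", "BB", "NC"):
                if g not in wide.columns:
                    wide[g] = 0.0
            wide["callrate"] = wide["AA"] + wide["AB"] + wide["BB"]
            wide["thr"] = thr
            wide["alg"] = col
            pieces.append(wide[["individual", "thr", "alg",
                                "AA", "AB", "BB", "NC", "callrate"]])
    out = pd.concat(pieces, ignore_index=True)
    out.columns.name = None
    return out


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error across individuals per (threshold, algorithm).

    SEM is sample SD / sqrt(n); with a single individual it is NaN.
    The AB fraction summarized here is the AB share of all records
    (call-rate denominator), matching the sweep's columns.
    """
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    agg = sweep.groupby(["thr", "alg"], sort=True).agg(
        callrate_mean=("callrate", "mean"),
        callrate_sem=("callrate", _sem),
        AB_mean=("AB", "mean"),
        AB_sem=("AB", _sem),
        n_individuals=("individual", "nunique"),
    ).reset_index()
    return agg
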