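"""Probe-level summarization and the Expression Ratio Index (ERI).

The ERI of an APA site in a sample is the ratio of its 5' probeset signal
(both isoforms hybridize) to its 3' probeset signal (long isoform only).
With probeset affinities a(5',L), a(5',S), a(3',L) and isoform levels L, S:

    signal_5p = a(5',L) * L + a(5',S) * S
    signal_3p = a(3',L) * L
    ERI       = signal_5p / signal_3p  — affine in S/L

so the ERI rises with the short/long ratio and is invariant to overall
expression changes.  It is computed and stored on the log2 scale as the
difference of the two probeset summaries; all downstream testing is
rank-based or uses differences, so the monotone log transform is neutral.

Two summarizers are provided: ``quantile_median_polish`` (across-sample
quantile normalization of log2 intensities followed by per-probeset median
polish — an RMA-style summary without the convolution background model) and
``median_log`` (per-probeset, per-sample median of log2 intensities; fast
and vectorized).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .probesets import ProbesetPair

__all__ = [
    "quantile_normalize",
    "median_polish",
    "summarize",
    "compute_eri",
    "probeset_index",
]

INTENSITY_FLOOR = 1.0


def probeset_index(apa_id: str, side: str) -> str:
    """Row label of a probeset in the expression matrix."""
    if side not in ("5p", "3p"):
        raise ValueError(f"side must be '5p' or '3p', got {side!r}")
    return f"{apa_id}/{side}"


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the mean empirical distribution.

    Ties within a column receive the mean of the reference values at their
    (average) ranks, via interpolation.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = np.apply_along_axis(sps.rankdata, 0, values)  # average ranks, 1..n
    return np.interp(ranks, np.arange(1, n + 1), reference)


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a probes x samples block.

    Returns ``(overall, row_effects, col_effects, residuals)``; the
    per-sample probeset summary is ``overall + col_effects``.
    """
    z = np.asarray(matrix, dtype=float).copy()
    n_r, n_c = z.shape
    overall = 0.0
    row = np.zeros(n_r)
    col = np.zeros(n_c)
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cshift = np.median(row)
        row -= cshift
        overall += cshift
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rshift = np.median(col)
        col -= rshift
        overall += rshift
        moved = np.abs(rmed).max(initial=0) + np.abs(cmed).max(initial=0)
        if moved < tol:
            break
    return overall, row, col, z


def summarize(
    intensity: pd.DataFrame,
    definitions: pd.DataFrame,
    method: str = "quantile_median_polish",
    floor: float = INTENSITY_FLOOR,
) -> pd.DataFrame:
    """Summarize probe intensities into per-probeset log2 expression.

    Parameters
    ----------
    intensity
        Linear-scale probe intensities, probes x samples.
    definitions
        Long-format probeset definitions with columns
        ``apa_id, side, probe_id``.
    method
        ``"quantile_median_polish"`` or ``"median_log"``.

    Returns
    -------
    DataFrame indexed by ``"{apa_id}/{side}"``, one row per probeset.
    """
    missing = set(definitions["probe_id"]) - set(intensity.index)
    if missing:
        raise KeyError(f"probes absent from the intensity matrix: {sorted(missing)[:5]}")
    if (definitions.groupby(["apa_id", "side"]).size() == 0).any():
        raise ValueError("probeset with zero matching probes")

    vals = intensity.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("non-finite intensities")
    logv = np.log2(np.maximum(vals, floor))
    if method == "quantile_median_polish":
        logv = quantile_normalize(logv)
        log_df = pd.DataFrame(logv, index=intensity.index, columns=intensity.columns)
        rows = {}
        for (aid, side), grp in definitions.groupby(["apa_id", "side"], sort=True):
            block = log_df.loc[grp["probe_id"].to_numpy()].to_numpy()
            overall, _, col, _ = median_polish(block)
            rows[probeset_index(aid, side)] = overall + col
        expr = pd.DataFrame.from_dict(rows, orient="index", columns=intensity.columns)
    elif method == "median_log":
        log_df = pd.DataFrame(logv, index=intensity.index, columns=intensity.columns)
        picked = log_df.loc[definitions["probe_id"].to_numpy()]
        keys = [probeset_index(a, s) for a, s in zip(definitions["apa_id"], definitions["side"])]
        expr = picked.groupby(pd.Index(keys, name="probeset"), sort=True).median()
    else:
        raise ValueError(f"unknown summarization method {method!r}")
    expr = expr.sort_index()
    expr.index.name = "probeset"
    expr.attrs["method"] = method
    return expr


def compute_eri(expr: pd.DataFrame, pairs: Sequence[ProbesetPair]) -> pd.DataFrame:
    """Per-APA, per-sample log2 ERI: expr(5' probeset) - expr(3' probeset).

    APA sites whose probesets are missing from ``expr`` are omitted with a
    warning.
    """
    rows = {}
    skipped = []
    for pair in pairs:
        k5, k3 = probeset_index(pair.apa_id, "5p"), probeset_index(pair.apa_id, "3p")
        if k5 not in expr.index or k3 not in expr.index:
            skipped.append(pair.apa_id)
            continue
        rows[pair.apa_id] = expr.loc[k5] - expr.loc[k3]
    if skipped:
        warnings.warn(f"{len(skipped)} APA sites missing probeset rows were omitted: "
                      f"{skipped[:5]}", stacklevel=2)
    eri = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    eri.index.name = "apa_id"
    eri.attrs["skipped"] = skipped
    return eri
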