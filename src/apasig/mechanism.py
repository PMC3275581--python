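"""Mechanism discrimination, microRNA-relevance enrichment, gene-set overlap.

Mechanism: for each transcript (5'-most accepted APA site only), correlate
the poor-minus-good difference in median 5'-probeset expression with the
poor-minus-good difference in median ERI across transcripts.  If higher ERI
in the poor group comes from synthesizing relatively more short isoform,
total expression (the 5' probeset sees both isoforms) rises with the ERI
and the Spearman correlation is positive; if it comes from selective decay
of the long isoform, total expression falls and the correlation is negative.

microRNA relevance: an APA site is relevant to a microRNA when the segment
3' of the site carries at least one predicted binding site, so short-isoform
use removes that regulation.  Relevant and irrelevant sites' shortening
(poor-minus-good difference in mean ERI) are compared with Mann-Whitney
tests, globally and per microRNA family with BH control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differential import GroupAssignment
from .expression import probeset_index
from .probesets import ProbesetPair
from .stats import bh_adjust, mann_whitney

__all__ = [
    "MechanismResult",
    "mechanism_correlation",
    "delta_mean_eri",
    "mirna_relevance_test",
    "per_mirna_tests",
    "gene_set_overlap",
    "overlap_pvalue",
    "spearman",
]

SPEARMAN_EXACT_MAX_N = 10


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(permutations(range(n))), dtype=np.int8)
    rys = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = rys - rys.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation null for n <= 10, t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if len(x) <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(x, y, rho)
    return rho, float(p)


@dataclass
class MechanismResult:
    """Per-transcript deltas and the cohort-level correlation verdict."""

    frame: pd.DataFrame  # transcript_id, apa_id, delta_expr_5p, delta_eri
    rho: float
    pvalue: float
    n: int

    @property
    def verdict(self) -> str:
        if self.pvalue > 0.05:
            return "indeterminate"
        return "synthesis" if self.rho > 0 else "degradation"


def mechanism_correlation(
    expr: pd.DataFrame,
    eri: pd.DataFrame,
    pairs: Sequence[ProbesetPair],
    groups: GroupAssignment,
) -> MechanismResult:
    """Differential-synthesis vs differential-degradation discrimination.

    Uses the 5'-most accepted APA site of each transcript to avoid counting
    multi-site transcripts more than once.
    """
    poor = list(groups.samples("poor"))
    good = list(groups.samples("good"))
    if len(poor) < 1 or len(good) < 1:
        raise ValueError("both groups must be non-empty")

    # 5'-most accepted site per transcript
    first: dict[str, ProbesetPair] = {}
    for pair in pairs:
        cur = first.get(pair.transcript_id)
        if cur is None or pair.position < cur.position:
            first[pair.transcript_id] = pair

    rows = []
    for tid, pair in sorted(first.items()):
        k5 = probeset_index(pair.apa_id, "5p")
        if k5 not in expr.index or pair.apa_id not in eri.index:
            continue
        e5 = expr.loc[k5]
        er = eri.loc[pair.apa_id]
        rows.append({
            "transcript_id": tid,
            "apa_id": pair.apa_id,
            "delta_expr_5p": float(e5[poor].median() - e5[good].median()),
            "delta_eri": float(er[poor].median() - er[good].median()),
        })
    frame = pd.DataFrame(rows, columns=["transcript_id", "apa_id", "delta_expr_5p", "delta_eri"])
    if len(frame) < 3:
        raise ValueError("need at least 3 transcripts for the mechanism correlation")
    rho, p = spearman(frame["delta_expr_5p"], frame["delta_eri"])
    return MechanismResult(frame, rho, p, len(frame))


def delta_mean_eri(eri: pd.DataFrame, groups: GroupAssignment) -> pd.Series:
    """Per-APA poor-minus-good difference in mean ERI (shortening measure)."""
    poor = list(groups.samples("poor"))
    good = list(groups.samples("good"))
    if len(poor) < 1 or len(good) < 1:
        raise ValueError("both groups must be non-empty")
    d = eri[poor].mean(axis=1) - eri[good].mean(axis=1)
    d.name = "delta_mean_eri"
    return d


def relevance_labels(apa_ids: Sequence[str], sites: pd.DataFrame) -> pd.Series:
    """True where an APA site has at least one downstream miRNA site record."""
    relevant = set(sites["apa_id"])
    return pd.Series([a in relevant for a in apa_ids], index=pd.Index(apa_ids, name="apa_id"),
                     name="mirna_relevant")


def mirna_relevance_test(deltas: pd.Series, sites: pd.DataFrame):
    """Do microRNA-relevant APA sites show more shortening than irrelevant ones?

    Two-sided Mann-Whitney on the per-APA shortening deltas; returns
    ``(U, p, direction)`` where the U statistic is for the relevant group.
    """
    labels = relevance_labels(deltas.index, sites)
    rel = deltas[labels].to_numpy(dtype=float)
    irr = deltas[~labels].to_numpy(dtype=float)
    if len(rel) == 0 or len(irr) == 0:
        raise ValueError("need both relevant and irrelevant APA sites")
    res = mann_whitney(rel, irr)
    direction = "relevant_more_shortened" if np.median(rel) > np.median(irr) \
        else "relevant_less_shortened"
    return res.u, res.pvalue, direction


def per_mirna_tests(
    deltas: pd.Series,
    sites: pd.DataFrame,
    fdr: float = 0.10,
    min_relevant: int = 5,
    comparison: str = "per_mirna",
) -> pd.DataFrame:
    """Per-microRNA shortening enrichment with BH control.

    For each microRNA family, its relevant APA sites' deltas are compared
    against the comparison set: APA sites carrying no site for *that*
    family (``comparison="per_mirna"``, default) or sites carrying no miRNA
    site at all (``comparison="global_irrelevant"``).  Families with fewer
    than ``min_relevant`` relevant sites are listed as skipped.
    """
    if comparison not in ("per_mirna", "global_irrelevant"):
        raise ValueError(f"unknown comparison {comparison!r}")
    apa_index = deltas.index
    any_relevant = relevance_labels(apa_index, sites)
    rows = []
    for fam, grp in sites.groupby("mirna_family", sort=True):
        rel_ids = [a for a in apa_index if a in set(grp["apa_id"])]
        if len(rel_ids) < min_relevant:
            rows.append({"mirna_family": fam, "n_relevant": len(rel_ids), "statistic": np.nan,
                         "pvalue": np.nan, "direction": "none", "skipped": True})
            continue
        rel = deltas.loc[rel_ids].to_numpy(dtype=float)
        if comparison == "per_mirna":
            irr_mask = ~apa_index.isin(set(grp["apa_id"]))
        else:
            irr_mask = ~any_relevant.to_numpy()
        irr = deltas[irr_mask].to_numpy(dtype=float)
        if len(irr) == 0:
            rows.append({"mirna_family": fam, "n_relevant": len(rel_ids), "statistic": np.nan,
                         "pvalue": np.nan, "direction": "none", "skipped": True})
            continue
        res = mann_whitney(rel, irr)
        direction = "shortened_in_poor" if np.median(rel) > np.median(irr) else "shortened_in_good"
        rows.append({"mirna_family": fam, "n_relevant": len(rel_ids), "statistic": res.u,
                     "pvalue": res.pvalue, "direction": direction, "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    if not tested.any():
        raise ValueError(f"no microRNA family has >= {min_relevant} relevant APA sites")
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = bh_adjust(out.loc[tested, "pvalue"])
    out["qvalue"] = q
    out["significant"] = (out["qvalue"] <= fdr).fillna(False)
    out.attrs["fdr"] = fdr
    out.attrs["comparison"] = comparison
    return out


def overlap_pvalue(k, n, n_a, n_b):
    """One-sided (enrichment) Fisher exact p for an overlap of ``k`` genes
    between sets of sizes ``n_a`` and ``n_b`` in a universe of ``n``: the
    upper hypergeometric tail P(X >= k).  Accepts arrays."""
    return np.minimum(sps.hypergeom.sf(np.asarray(k) - 1, n, n_a, n_b), 1.0)


def gene_set_overlap(set_a, set_b, universe):
    """Observed vs expected overlap of two gene sets and a one-sided Fisher p.

    Expected overlap is the hypergeometric mean |A||B|/N; the p-value is
    the one-sided (enrichment) Fisher exact probability, i.e. the upper
    hypergeometric tail of the observed overlap.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not universe:
        raise ValueError("empty universe")
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(a & b)
    expected = len(a) * len(b) / n
    if a == universe and b == universe:
        return k, expected, 1.0  # saturated table: no enrichment information
    return k, expected, float(overlap_pvalue(k, n, len(a), len(b)))
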