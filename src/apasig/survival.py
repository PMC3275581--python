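"""Cox-weighted prognostic APA score and its survival validation.

The signature weight of each APA site is its Cox univariate score: the Wald
z-statistic of the site's ERI as the single covariate of a proportional-
hazards model (Breslow tie handling, Newton-Raphson).  A patient's
prognostic score is the weight-ERI inner product

    P = sum_a z_a * ERI_a

so high scores mean high prevalence of the isoform associated with poor
survival at the sites most correlated with outcome.  Validation applies the
frozen weights to an independent cohort, splits at the median score, and
compares the two risk classes with a log-rank test (Kaplan-Meier curves are
returned for plotting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "CoxUnivariateResult",
    "cox_univariate",
    "cox_univariate_z",
    "PrognosticSignature",
    "SignatureResults",
    "ScoreVector",
    "score_cohort",
    "LogrankResult",
    "logrank_compare",
]

_BETA_CAP = 20.0


@dataclass(frozen=True)
class CoxUnivariateResult:
    beta: float
    se: float
    z: float
    n: int
    n_events: int
    converged: bool


def _clinical_arrays(clinical: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    cl = clinical.set_index("sample_id").loc[list(sample_ids)]
    time = cl["time"].to_numpy(dtype=float)
    event = cl["event"].to_numpy(dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    return time, event


def cox_univariate(x, time, event, tol: float = 1e-8, max_iter: int = 50) -> CoxUnivariateResult:
    """Single-covariate Cox proportional-hazards fit (Breslow ties).

    Newton-Raphson on the partial likelihood to gradient tolerance ``tol``.
    Monotone likelihood (perfect separation) is detected by the estimate
    running away; beta is then capped at +/-20 with a warning.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: no information for a Cox score")
    if event.sum() < 2:
        raise ValueError("need at least 2 events")

    # sort descending by time so risk sets are cumulative prefixes
    order = np.argsort(-time, kind="mergesort")
    x_s, t_s, e_s = x[order], time[order], event[order]

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        r = np.exp(beta * x_s)
        s0 = np.cumsum(r)
        s1 = np.cumsum(r * x_s)
        s2 = np.cumsum(r * x_s * x_s)
        # Breslow: all tied events share the full risk set at their time ->
        # use the last index among ties (largest prefix)
        idx = np.arange(len(t_s))
        last_tie = np.searchsorted(-t_s, -t_s, side="right") - 1
        d0, d1, d2 = s0[last_tie], s1[last_tie], s2[last_tie]
        ev = e_s == 1
        grad = float(np.sum(x_s[ev] - d1[ev] / d0[ev]))
        info = float(np.sum(d2[ev] / d0[ev] - (d1[ev] / d0[ev]) ** 2))
        if info <= 0:
            break
        step = grad / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > _BETA_CAP:
            warnings.warn("monotone partial likelihood (perfect separation): "
                          "beta capped at +/-20", stacklevel=2)
            beta = float(np.sign(beta) * _BETA_CAP)
            break
        if abs(grad) < tol:
            converged = True
            break
    r = np.exp(beta * x_s)
    s0 = np.cumsum(r)
    s1 = np.cumsum(r * x_s)
    s2 = np.cumsum(r * x_s * x_s)
    last_tie = np.searchsorted(-t_s, -t_s, side="right") - 1
    d0, d1, d2 = s0[last_tie], s1[last_tie], s2[last_tie]
    ev = e_s == 1
    info = float(np.sum(d2[ev] / d0[ev] - (d1[ev] / d0[ev]) ** 2))
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    return CoxUnivariateResult(float(beta), float(se), float(z),
                               int(len(x)), int(event.sum()), converged)


def cox_univariate_z(x, time, event) -> float:
    """Wald z of a single-covariate Cox fit (the conventional Cox univariate score)."""
    return cox_univariate(x, time, event).z


@dataclass
class ScoreVector:
    """Per-sample prognostic scores with a cutoff-based risk split."""

    scores: pd.Series
    cutoff: float
    risk_class: pd.Series  # "high" | "low"
    degenerate: bool = False


@dataclass
class SignatureResults:
    """Frozen APA signature: ordered weights plus training metadata."""

    weights: pd.Series  # index apa_id, values Cox z
    metadata: dict = field(default_factory=dict)
    cox_details: pd.DataFrame | None = None

    def score(self, eri: pd.DataFrame, cutoff="median", missing: str = "error",
              standardize: bool = False) -> ScoreVector:
        return score_cohort(self, eri, cutoff=cutoff, missing=missing, standardize=standardize)

    def summary(self) -> str:
        lines = [
            "APA prognostic signature",
            "========================",
            f"sites: {len(self.weights)}",
        ]
        for k, v in self.metadata.items():
            lines.append(f"{k}: {v}")
        lines.append("")
        lines.append(self.weights.rename("cox_z").to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("apa_id\tweight\n")
            for aid, w in self.weights.items():
                fh.write(f"{aid}\t{w:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SignatureResults":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition(":")
                    meta[k.strip()] = v.strip()
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "apa_id":
                    continue
                rows.append((parts[0], float(parts[1])))
        w = pd.Series(dict(rows), name="weight")
        w.index.name = "apa_id"
        return cls(w, meta)


class PrognosticSignature:
    """Trainable ERI-based prognostic signature model.

    Parameters
    ----------
    eri
        Training log2 ERI matrix, APA sites x samples.
    clinical
        Clinical table with ``sample_id, time, event``.
    apa_ids
        The signature sites (e.g. the significant set of a
        :class:`~apasig.differential.DifferentialUsageModel` fit).
    """

    def __init__(self, eri: pd.DataFrame, clinical: pd.DataFrame, apa_ids):
        missing = [a for a in apa_ids if a not in eri.index]
        if missing:
            raise KeyError(f"signature APAs absent from the ERI matrix: {missing[:5]}")
        self.eri = eri
        self.clinical = clinical
        self.apa_ids = list(apa_ids)

    def fit(self, metadata: dict | None = None) -> SignatureResults:
        """Weight each signature site by its Cox univariate Wald z."""
        time, event = _clinical_arrays(self.clinical, self.eri.columns)
        weights = {}
        details = []
        for aid in self.apa_ids:
            vals = self.eri.loc[aid].to_numpy(dtype=float)
            res = cox_univariate(vals, time, event)
            weights[aid] = res.z
            details.append({"apa_id": aid, "beta": res.beta, "se": res.se,
                            "z": res.z, "n_events": res.n_events})
        w = pd.Series(weights, name="weight")
        w.index.name = "apa_id"
        meta = {"n_sites": len(w), "weighting": "cox_univariate_wald_z",
                "ties": "breslow", **(metadata or {})}
        return SignatureResults(w, meta, pd.DataFrame(details))


def score_cohort(model: SignatureResults, eri: pd.DataFrame, cutoff="median",
                 missing: str = "error", standardize: bool = False) -> ScoreVector:
    """Apply frozen signature weights to a cohort's ERI matrix.

    ``missing="error"`` (default) requires every signature APA in the
    cohort; ``missing="subset"`` renormalizes to the available subset with
    a warning.  ``standardize`` z-scores each APA's ERI within the cohort
    before weighting (for cross-platform transfer; off by default so the
    score is the literal weighted sum).
    """
    present = [a for a in model.weights.index if a in eri.index]
    if not present:
        raise KeyError("no signature APA present in the cohort ERI matrix")
    if len(present) < len(model.weights):
        if missing == "error":
            absent = [a for a in model.weights.index if a not in eri.index]
            raise KeyError(f"signature APAs missing from cohort: {absent[:5]}")
        warnings.warn(
            f"scoring on {len(present)}/{len(model.weights)} signature APAs "
            "(renormalized subset)", stacklevel=2)
    w = model.weights.loc[present]
    if missing == "subset" and len(present) < len(model.weights):
        w = w * (len(model.weights) / len(present))
    block = eri.loc[present]
    if block.isna().any().any():
        raise ValueError("NaN ERI entries in signature rows")
    vals = block.to_numpy(dtype=float)
    if standardize:
        sd = vals.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant ERI row cannot be standardized")
        vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = pd.Series(w.to_numpy() @ vals, index=eri.columns, name="score")

    degenerate = False
    if cutoff == "median":
        if len(scores) < 2:
            raise ValueError("median split needs at least 2 samples")
        cut = float(np.median(scores))
    else:
        cut = float(cutoff)
    if np.ptp(scores.to_numpy()) == 0:
        degenerate = True
        warnings.warn("all scores identical: degenerate risk split", stacklevel=2)
    # lower-or-equal goes to the low-risk class (deterministic tie rule)
    risk = pd.Series(np.where(scores > cut, "high", "low"), index=scores.index, name="risk_class")
    return ScoreVector(scores, cut, risk, degenerate)


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    pvalue: float
    km_curves: pd.DataFrame  # class, time, at_risk, survival

    def plot(self, ax=None):
        """Kaplan-Meier step curves per risk class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls, grp in self.km_curves.groupby("class"):
            ax.step(grp["time"], grp["survival"], where="post", label=str(cls))
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank p = {self.pvalue:.3g}")
        return ax


def logrank_compare(classes: ScoreVector | pd.Series, clinical: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test (1 df) with Kaplan-Meier curves per class."""
    labels = classes.risk_class if isinstance(classes, ScoreVector) else pd.Series(classes)
    time, event = _clinical_arrays(clinical, labels.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 classes, got {uniq}")
    if event.sum() < 1:
        raise ValueError("no events observed")
    mask = (labels == uniq[1]).to_numpy()
    res = logrank_test(time[mask], time[~mask], event_observed_A=event[mask],
                       event_observed_B=event[~mask])
    curves = []
    kmf = KaplanMeierFitter()
    for cls in uniq:
        sel = (labels == cls).to_numpy()
        kmf.fit(time[sel], event[sel], label=str(cls))
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves.append(pd.DataFrame({
            "class": cls,
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        }))
    km = pd.concat(curves, ignore_index=True)
    return LogrankResult(float(res.test_statistic), float(res.p_value), km)
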