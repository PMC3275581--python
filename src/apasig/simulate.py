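"""Synthetic microarray cohorts with planted alternative-polyadenylation structure.

The generator emulates the statistical structure the downstream analysis
assumes: each transcript carries one or more APA sites in its 3'UTR; a
sample expresses a mixture of the full-length isoform and short isoforms
cleaved at the APA sites; probes hybridize to every isoform that covers
them, so the linear probe signal is

    intensity = background + affinity * (covering isoform concentration) * noise

with multiplicative lognormal noise.  For a single-site transcript this is
exactly the two-isoform signal model of the Expression Ratio Index: the 5'
probeset sees a(5',L)*L + a(5',S)*S while the 3' probeset sees a(3',L)*L.

Two disease mechanisms can be planted in the poor-outcome group:

``synthesis``
    the short isoform is synthesized in a higher proportion (logit shift
    ``delta``); because the long isoform is partly degraded by microRNAs
    (survival factor ``m`` < 1 in both groups), the observed total
    expression *rises* in the poor group.
``degradation``
    synthesis ratios are identical, but the long isoform survives
    degradation less in the poor group (``m_poor`` < ``m_good``), so total
    expression *falls* while the short/long ratio still rises.

Survival times follow an exponential baseline whose log-hazard is linear in
a sample's planted shortening burden (mean realized short-fraction logit
over planted sites), with uniform administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AffinityModel",
    "SimulationTruth",
    "Universe",
    "Cohort",
    "generate_universe",
    "generate_cohort",
]


@dataclass(frozen=True)
class AffinityModel:
    """Probe response model: positive affinities, additive background,
    multiplicative lognormal noise (sd on the natural-log scale)."""

    affinity_log_sd: float = 0.4
    background: float = 20.0
    noise_sd: float = 0.25

    def __post_init__(self):
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.noise_sd < 0 or self.affinity_log_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted per-group isoform parameters and the survival link.

    ``delta`` shifts the short-fraction logit of planted APA sites in the
    poor group (synthesis mechanism); ``m_good``/``m_poor`` are the
    long-isoform degradation survival factors per group, in (0, 1].
    ``gamma`` couples the per-sample shortening burden to the log-hazard.
    """

    mechanism: str = "synthesis"  # synthesis | degradation | null
    logit_mean: float = -0.6
    apa_logit_sd: float = 0.7
    sample_logit_sd: float = 0.5
    delta: float = 1.5
    m_good: float = 0.5
    m_poor: float = 0.5
    gamma: float = 1.0
    baseline_hazard: float = math.log(2) / 60.0  # per month; median ~5 years
    censoring_time: float = 120.0  # months, uniform administrative censoring
    #: half-width of the uniform per-site multiplier on the planted effect
    #: (delta, or the log m ratio); heterogeneous effect strength is what
    #: spreads transcripts along the mechanism-correlation axes
    effect_heterogeneity: float = 0.9

    def __post_init__(self):
        if self.mechanism not in ("synthesis", "degradation", "null"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0 < self.m_good <= 1) or not (0 < self.m_poor <= 1):
            raise ValueError("degradation survival factor m must lie in (0, 1]")
        if not math.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.baseline_hazard <= 0 or self.censoring_time <= 0:
            raise ValueError("baseline hazard and censoring time must be positive")
        if not (0 <= self.effect_heterogeneity < 1):
            raise ValueError("effect_heterogeneity must lie in [0, 1)")

    @classmethod
    def synthesis(cls, delta: float = 1.5, m: float = 0.5, **kw) -> "SimulationTruth":
        return cls(mechanism="synthesis", delta=delta, m_good=m, m_poor=m, **kw)

    @classmethod
    def degradation(cls, m_good: float = 0.9, m_poor: float = 0.45, **kw) -> "SimulationTruth":
        return cls(mechanism="degradation", delta=0.0, m_good=m_good, m_poor=m_poor, **kw)

    @classmethod
    def null(cls, **kw) -> "SimulationTruth":
        kw.setdefault("gamma", 0.0)
        return cls(mechanism="null", delta=0.0, m_good=1.0, m_poor=1.0, **kw)


@dataclass
class Universe:
    """Annotation tables shared by every cohort drawn from them."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, length, utr3_start, apa_positions
    probes: pd.DataFrame       # probe_id, transcript_id, start, length
    mirna_sites: pd.DataFrame  # apa_id, mirna_family, n_sites
    meta: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """One simulated patient cohort plus its ground truth."""

    intensity: pd.DataFrame    # probes x samples, linear scale
    clinical: pd.DataFrame     # sample_id, time, event, group
    truth_apa: pd.DataFrame    # planted direction per APA site
    truth_sample: pd.DataFrame # per-sample shortening burden
    true_logit: pd.DataFrame   # realized short-fraction logits, APA x sample
    meta: dict = field(default_factory=dict)


def generate_universe(
    n_transcripts: int,
    multi_apa_fraction: float = 0.25,
    probes_per_transcript: int | tuple[int, int] = 11,
    seed: int = 0,
    mirna_relevant_fraction: float = 0.5,
    n_mirna_families: int = 20,
    probe_length: int = 25,
) -> Universe:
    """Draw a transcript/probe/miRNA-site annotation universe.

    Probe start positions are 3'-biased (Beta(3, 1) along the mRNA), mRNA
    lengths 1500-4000 nt with the 3'UTR starting at 60% of the length, and
    every APA site lies strictly inside the 3'UTR.  A fraction
    ``multi_apa_fraction`` of transcripts carries two APA sites; a fraction
    ``mirna_relevant_fraction`` of sites receives at least one microRNA
    binding-site record downstream of the cleavage position.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if not (0 <= multi_apa_fraction <= 1):
        raise ValueError("multi_apa_fraction must lie in [0, 1]")
    if isinstance(probes_per_transcript, (tuple, list)):
        lo, hi = probes_per_transcript
    else:
        lo = hi = int(probes_per_transcript)
    if lo < 1 or hi < lo:
        raise ValueError("probes_per_transcript must be a positive count or (lo, hi) range")

    rng = np.random.default_rng(seed)
    t_rows, p_rows, m_rows = [], [], []
    families = [f"miR-{i + 1:02d}" for i in range(n_mirna_families)]
    for i in range(n_transcripts):
        tid = f"T{i:05d}"
        gid = f"G{i:05d}"
        length = int(rng.integers(1500, 4001))
        utr3_start = int(0.6 * length)
        n_apa = 2 if rng.random() < multi_apa_fraction else 1
        # keep room downstream of the last site for distal probes
        span_lo, span_hi = utr3_start + 30, length - 120
        pos = np.sort(rng.choice(np.arange(span_lo, span_hi), size=n_apa, replace=False))
        # enforce a minimal inter-site gap so both splits can succeed
        while len(pos) > 1 and np.any(np.diff(pos) < 120):
            pos = np.sort(rng.choice(np.arange(span_lo, span_hi), size=n_apa, replace=False))
        t_rows.append((tid, gid, length, utr3_start, ",".join(str(int(p)) for p in pos)))

        n_probes = int(rng.integers(lo, hi + 1))
        starts = np.unique(
            np.round(rng.beta(3.0, 1.0, size=n_probes) * (length - probe_length)).astype(int)
        )
        for j, s in enumerate(np.sort(starts)):
            p_rows.append((f"{tid}_p{j:02d}", tid, int(s), probe_length))

        for p in pos:
            if rng.random() < mirna_relevant_fraction:
                fams = rng.choice(families, size=int(rng.integers(1, 4)), replace=False)
                for fam in fams:
                    m_rows.append((f"{tid}:{int(p)}", str(fam), int(rng.integers(1, 3))))

    transcripts = pd.DataFrame(
        t_rows, columns=["transcript_id", "gene_id", "length", "utr3_start", "apa_positions"]
    )
    probes = pd.DataFrame(p_rows, columns=["probe_id", "transcript_id", "start", "length"])
    mirna = pd.DataFrame(m_rows, columns=["apa_id", "mirna_family", "n_sites"])
    meta = {
        "seed": int(seed),
        "n_transcripts": int(n_transcripts),
        "multi_apa_fraction": float(multi_apa_fraction),
        "mirna_relevant_fraction": float(mirna_relevant_fraction),
    }
    return Universe(transcripts, probes, mirna, meta)


def _segment_starts(seg_ids: np.ndarray) -> np.ndarray:
    """Indices where a new segment begins in a sorted segment-id array."""
    return np.flatnonzero(np.r_[True, seg_ids[1:] != seg_ids[:-1]])


def generate_cohort(
    universe: Universe,
    truth: SimulationTruth,
    n_samples: int,
    planted_fraction: float = 0.15,
    seed: int = 0,
    affinity: AffinityModel | None = None,
    base_expr_log_mean: float = math.log(200.0),
    base_expr_log_sd: float = 0.8,
    sample_expr_sd: float = 0.3,
    relevance_bias: float = 1.0,
) -> Cohort:
    """Draw probe intensities, clinical outcomes and truth tables for one cohort.

    Half the samples are labelled ``good`` and half ``poor``; planted APA
    sites differ between the groups according to ``truth.mechanism``.
    Isoform mixing is sequential along each transcript's sites (5' to 3'):
    a fraction ``f_k`` of molecules still intact at site k is cleaved there,
    and molecules extending past a planted site are degraded down to a
    surviving fraction ``m``.  Each planted site scales its group effect by
    a per-site heterogeneity factor (see
    :attr:`SimulationTruth.effect_heterogeneity`).  ``relevance_bias`` > 1
    makes microRNA-relevant sites proportionally more likely to be planted
    (shortening preferentially removes microRNA regulation).
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not (0 <= planted_fraction <= 1):
        raise ValueError("planted_fraction must lie in [0, 1]")
    affinity = affinity or AffinityModel()
    rng = np.random.default_rng(seed)

    tr = universe.transcripts
    n_tr = len(tr)
    tid_to_idx = {t: i for i, t in enumerate(tr["transcript_id"])}

    # --- flatten APA sites, sorted by (transcript, position)
    site_t_idx, site_pos = [], []
    for i, pos_str in enumerate(tr["apa_positions"]):
        for p in str(pos_str).split(","):
            site_t_idx.append(i)
            site_pos.append(int(p))
    site_t_idx = np.asarray(site_t_idx, dtype=np.int64)
    site_pos = np.asarray(site_pos, dtype=np.int64)
    order = np.lexsort((site_pos, site_t_idx))
    site_t_idx, site_pos = site_t_idx[order], site_pos[order]
    n_sites = len(site_pos)
    apa_ids = np.array(
        [f"{tr['transcript_id'].iat[t]}:{p}" for t, p in zip(site_t_idx, site_pos)]
    )

    seg_start = _segment_starts(site_t_idx)                       # per segment
    start_of_site = seg_start[np.searchsorted(seg_start, np.arange(n_sites), side="right") - 1]
    next_start = np.r_[seg_start[1:], n_sites]
    end_of_site = next_start[np.searchsorted(seg_start, np.arange(n_sites), side="right") - 1]

    # --- groups: balanced random assignment
    g = np.zeros(n_samples, dtype=int)
    g[rng.permutation(n_samples)[: n_samples // 2]] = 1  # 1 = poor
    sample_ids = np.array([f"S{i:04d}" for i in range(n_samples)])

    # --- planted sites and per-site parameters
    if relevance_bias <= 0:
        raise ValueError("relevance_bias must be positive")
    weight = np.ones(n_sites)
    if relevance_bias != 1.0 and len(universe.mirna_sites):
        relevant = np.isin(apa_ids, universe.mirna_sites["apa_id"].unique())
        weight[relevant] = relevance_bias
    p_plant = np.minimum(planted_fraction * weight / weight.mean(), 1.0)
    planted = rng.random(n_sites) < p_plant
    if truth.mechanism == "null":
        planted = np.zeros(n_sites, dtype=bool)
    base_logit = truth.logit_mean + truth.apa_logit_sd * rng.standard_normal(n_sites)
    # per-site effect-strength multiplier (1 where unplanted)
    h = rng.uniform(1.0 - truth.effect_heterogeneity,
                    1.0 + truth.effect_heterogeneity, size=n_sites)
    h = np.where(planted, h, 0.0)
    delta_site = truth.delta * h if truth.mechanism == "synthesis" else np.zeros(n_sites)

    # short-fraction logits: (n_sites, n_samples)
    logit = base_logit[:, None] + truth.sample_logit_sd * rng.standard_normal((n_sites, n_samples))
    if truth.mechanism == "synthesis":
        logit += delta_site[:, None] * (g[None, :] == 1)
    f = 1.0 / (1.0 + np.exp(-logit))

    # degradation survival factor per (site, sample)
    m_site_good = np.where(planted, truth.m_good, 1.0)
    if truth.mechanism == "degradation":
        log_ratio = math.log(truth.m_poor) - math.log(truth.m_good)
        m_site_poor = np.where(planted, truth.m_good * np.exp(h * log_ratio), 1.0)
    elif truth.mechanism == "synthesis":
        m_site_poor = m_site_good  # microRNA pressure identical across groups
    else:
        m_site_poor = np.ones(n_sites)
        m_site_good = np.ones(n_sites)
    m = np.where(g[None, :] == 1, m_site_poor[:, None], m_site_good[:, None])

    # --- sequential cleavage mixing with segmented cumulative products
    logq = np.log1p(-f)                       # log(1 - f_k)
    logm = np.log(m)
    cs_q = np.cumsum(logq, axis=0)
    cs_m = np.cumsum(logm, axis=0)
    zero = np.zeros((1, n_samples))
    cs_q_prev = np.vstack([zero, cs_q[:-1]])
    cs_m_prev = np.vstack([zero, cs_m[:-1]])
    off_q = cs_q_prev[start_of_site]
    off_m = cs_m_prev[start_of_site]
    prev_q = cs_q_prev - off_q                # sum log(1-f) over earlier sites, same transcript
    prev_m = cs_m_prev - off_m
    w = f * np.exp(prev_q)                    # proportion cleaved at site k
    surv = np.exp(prev_m)                     # survival of the isoform ending at site k
    v = w * surv

    # full-length isoform per transcript: proportion * survival
    last = end_of_site - 1
    total_q = cs_q[last] - off_q              # per site row; identical within a transcript
    total_m = cs_m[last] - off_m
    v_full_site = np.exp(total_q + total_m)   # gatherable per site
    v_full_tr = np.zeros((n_tr, n_samples))
    v_full_tr[site_t_idx[seg_start]] = v_full_site[seg_start]

    # suffix sums of v within each transcript segment
    rc = np.cumsum(v[::-1], axis=0)[::-1]
    after = np.zeros_like(rc)
    has_next = end_of_site < n_sites
    after[has_next] = rc[end_of_site[has_next]]
    suffix = rc - after                       # sum of v over sites >= k, same transcript

    # --- total synthesized transcript level per (transcript, sample)
    base_expr = np.exp(base_expr_log_mean + base_expr_log_sd * rng.standard_normal(n_tr))
    T = base_expr[:, None] * np.exp(sample_expr_sd * rng.standard_normal((n_tr, n_samples)))

    # --- probe concentrations: isoforms whose 3' end reaches the probe's end
    pr = universe.probes
    probe_t = pr["transcript_id"].map(tid_to_idx).to_numpy()
    probe_end = (pr["start"] + pr["length"]).to_numpy()
    BIG = int(site_pos.max(initial=1)) + int(probe_end.max(initial=1)) + 2
    site_key = site_t_idx * BIG + site_pos
    probe_key = probe_t * BIG + probe_end
    k_star = np.searchsorted(site_key, probe_key, side="left")
    in_seg = (k_star < n_sites) & (site_t_idx[np.minimum(k_star, n_sites - 1)] == probe_t)
    conc_factor = v_full_tr[probe_t]
    conc_factor = conc_factor + np.where(
        in_seg[:, None], suffix[np.minimum(k_star, n_sites - 1)], 0.0
    )
    conc = T[probe_t] * conc_factor

    a = np.exp(affinity.affinity_log_sd * rng.standard_normal(len(pr)))
    noise = np.exp(affinity.noise_sd * rng.standard_normal(conc.shape)) if affinity.noise_sd > 0 else 1.0
    intensity = affinity.background + a[:, None] * conc * noise
    intensity_df = pd.DataFrame(intensity, index=pr["probe_id"].to_numpy(), columns=sample_ids)
    intensity_df.index.name = "probe_id"

    # --- survival from the planted shortening burden
    if planted.any():
        burden = logit[planted].mean(axis=0)
        burden = burden - burden.mean()
    else:
        burden = np.zeros(n_samples)
    hazard = truth.baseline_hazard * np.exp(truth.gamma * burden)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(1.0, truth.censoring_time, size=n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "group": np.where(g == 1, "poor", "good"),
        }
    )
    truth_apa = pd.DataFrame(
        {
            "apa_id": apa_ids,
            "transcript_id": tr["transcript_id"].to_numpy()[site_t_idx],
            "position": site_pos,
            "planted": planted,
            "mechanism": truth.mechanism,
            "effect_size": h,
            "delta": delta_site,
            "m_good": m_site_good,
            "m_poor": m_site_poor,
            "base_logit": base_logit,
        }
    )
    truth_sample = pd.DataFrame(
        {"sample_id": sample_ids, "group": clinical["group"], "burden": burden}
    )
    true_logit = pd.DataFrame(logit, index=apa_ids, columns=sample_ids)
    true_logit.index.name = "apa_id"

    meta = {"seed": int(seed), "n_samples": int(n_samples),
            "planted_fraction": float(planted_fraction), "truth": asdict(truth),
            "affinity": asdict(affinity)}
    return Cohort(intensity_df, clinical, truth_apa, truth_sample, true_logit, meta)
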