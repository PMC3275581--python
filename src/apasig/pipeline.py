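"""End-to-end pipeline: simulate -> probesets -> ERI -> differential ->
signature -> validation -> mechanism -> miRNA -> overlap.

The workflow mirrors the train/validate study design: a signature is
selected and weighted on one cohort, then applied with frozen coefficients
to an independent cohort, where the median-score split is assessed with a
log-rank test.  All randomness flows from the single config seed through
named substreams, and every output TSV carries the config hash, seed and
package version in '#' header lines, so a rerun with identical config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .differential import DifferentialUsageModel, assign_groups
from .expression import compute_eri, summarize
from .io import write_tsv
from .mechanism import (delta_mean_eri, gene_set_overlap, mechanism_correlation,
                        mirna_relevance_test, per_mirna_tests)
from .probesets import build_all, pairs_to_frame
from .simulate import AffinityModel, SimulationTruth, generate_cohort, generate_universe
from .survival import PrognosticSignature, logrank_compare

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_SIM_KEYS = {
    "n_transcripts", "multi_apa_fraction", "probes_per_transcript",
    "mirna_relevant_fraction", "n_mirna_families",
    "n_samples", "planted_fraction", "mechanism", "delta", "gamma",
    "m_good", "m_poor", "noise_sd", "background", "relevance_bias",
}
_TOP_KEYS = {
    "seed", "simulate", "min_probes", "summarization", "test",
    "fdr", "mirna_fdr", "min_relevant", "horizon", "cutoff",
}


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and the offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline parameters; unknown keys are rejected."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)
    min_probes: int = 3
    summarization: str = "quantile_median_polish"
    test: str = "mann_whitney"
    fdr: float = 0.05
    mirna_fdr: float = 0.10
    min_relevant: int = 5
    horizon: float = 60.0
    cutoff: str = "median"

    def __post_init__(self):
        unknown = set(self.simulate) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        for name in ("fdr", "mirna_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.summarization not in ("quantile_median_polish", "median_log"):
            raise ValueError(f"unknown summarization {self.summarization!r}")
        if self.test not in ("mann_whitney", "welch_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.cutoff != "median":
            float(self.cutoff)  # must parse as a number

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in sorted(_TOP_KEYS)}
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _substream(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages into ``out_dir``; returns the headline metrics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed,
            "version": __version__}
    (out / "config.yaml").write_text(config.to_yaml())

    sim = dict(config.simulate)
    truth_kw = {}
    for k in ("delta", "gamma"):
        if k in sim:
            truth_kw[k] = sim.pop(k)
    mechanism = sim.pop("mechanism", "synthesis")
    m_good = sim.pop("m_good", None)
    m_poor = sim.pop("m_poor", None)
    if mechanism == "synthesis":
        truth = SimulationTruth.synthesis(m=m_good if m_good is not None else 0.5, **truth_kw)
    elif mechanism == "degradation":
        truth_kw.pop("delta", None)
        truth = SimulationTruth.degradation(
            m_good=m_good if m_good is not None else 0.9,
            m_poor=m_poor if m_poor is not None else 0.45, **truth_kw)
    elif mechanism == "null":
        truth_kw.pop("delta", None)
        truth = SimulationTruth.null(**truth_kw)
    else:
        raise PipelineError("simulate", f"unknown mechanism {mechanism!r}")
    affinity = AffinityModel(
        noise_sd=sim.pop("noise_sd", AffinityModel.noise_sd),
        background=sim.pop("background", AffinityModel.background),
    )
    n_samples = sim.pop("n_samples", 150)
    planted_fraction = sim.pop("planted_fraction", 0.15)
    relevance_bias = sim.pop("relevance_bias", 1.0)
    universe_kw = {k: sim[k] for k in sim}
    universe_kw.setdefault("n_transcripts", 300)

    # --- simulate
    universe = generate_universe(seed=_substream(config.seed, 0), **universe_kw)
    cohorts = {
        "train": generate_cohort(universe, truth, n_samples, planted_fraction,
                                 seed=_substream(config.seed, 1), affinity=affinity,
                                 relevance_bias=relevance_bias),
        "validate": generate_cohort(universe, truth, n_samples, planted_fraction,
                                    seed=_substream(config.seed, 2), affinity=affinity,
                                    relevance_bias=relevance_bias),
    }
    write_tsv(universe.transcripts, out / "transcripts.tsv", meta)
    write_tsv(universe.probes, out / "probes.tsv", meta)
    write_tsv(universe.mirna_sites, out / "mirna_sites.tsv", meta)
    for name, cohort in cohorts.items():
        write_tsv(cohort.intensity.reset_index(), out / f"intensity_{name}.tsv", meta)
        write_tsv(cohort.clinical, out / f"clinical_{name}.tsv", meta)
        write_tsv(cohort.truth_apa, out / f"truth_apa_{name}.tsv", meta)

    # --- probesets
    pairs, report = build_all(universe.transcripts, universe.probes, config.min_probes)
    if not pairs:
        raise PipelineError("build-probesets", "no probeset pair passed the min-probes rule")
    write_tsv(pairs_to_frame(pairs), out / "probesets.tsv", meta)
    write_tsv(report.rejections_frame(), out / "probeset_rejections.tsv", meta)

    defs = pairs_to_frame(pairs)
    results: dict = {"n_probeset_pairs": report.n_pairs,
                     "n_transcripts_with_pair": report.n_transcripts_with_pair}

    # --- expression, ERI, groups per cohort
    expr, eri, groups = {}, {}, {}
    for name, cohort in cohorts.items():
        expr[name] = summarize(cohort.intensity, defs, method=config.summarization)
        eri[name] = compute_eri(expr[name], pairs)
        write_tsv(expr[name].reset_index(), out / f"expression_{name}.tsv", meta)
        write_tsv(eri[name].reset_index(), out / f"eri_{name}.tsv", meta)
        groups[name] = assign_groups(cohort.clinical, config.horizon)

    # --- differential usage (both cohorts; signature selection on train)
    diff = {}
    for name in cohorts:
        fit = DifferentialUsageModel(eri[name], groups[name]).fit(test=config.test, fdr=config.fdr)
        diff[name] = fit
        write_tsv(fit.frame, out / f"differential_{name}.tsv", meta)
    results["n_significant_train"] = int(diff["train"].frame["significant"].sum())
    results["n_shortened_train"] = diff["train"].n_shortened
    results["n_lengthened_train"] = diff["train"].n_lengthened

    # --- signature training on the train cohort, frozen transfer
    selected = diff["train"].significant["apa_id"].tolist()
    if not selected:
        raise PipelineError("train-signature", "no significant APA site to build a signature from")
    model = PrognosticSignature(eri["train"], cohorts["train"].clinical, selected)
    signature = model.fit(metadata={"dataset": "train", "horizon": config.horizon,
                                    "fdr": config.fdr, **meta})
    signature.to_tsv(out / "signature.tsv")

    cutoff = "median" if config.cutoff == "median" else float(config.cutoff)
    scores = signature.score(eri["validate"], cutoff=cutoff)
    write_tsv(scores.scores.rename("score").reset_index().rename(columns={"index": "sample_id"}),
              out / "scores_validate.tsv", meta)
    lr = logrank_compare(scores, cohorts["validate"].clinical)
    write_tsv(lr.km_curves, out / "km_validate.tsv", meta)
    results["validation_logrank_chi2"] = lr.statistic
    results["validation_logrank_p"] = lr.pvalue

    # --- mechanism correlation (train cohort)
    mech = mechanism_correlation(expr["train"], eri["train"], pairs, groups["train"])
    write_tsv(mech.frame, out / "mechanism.tsv", meta)
    results["mechanism_rho"] = mech.rho
    results["mechanism_p"] = mech.pvalue

    # --- microRNA relevance (train cohort deltas)
    deltas = delta_mean_eri(eri["train"], groups["train"])
    if len(universe.mirna_sites):
        u_stat, p_rel, direction = mirna_relevance_test(deltas, universe.mirna_sites)
        results["mirna_relevance_p"] = p_rel
        results["mirna_relevance_direction"] = direction
        per = per_mirna_tests(deltas, universe.mirna_sites, fdr=config.mirna_fdr,
                              min_relevant=config.min_relevant)
        write_tsv(per, out / "per_mirna.tsv", meta)
        results["n_mirna_significant"] = int(per["significant"].sum())

    # --- gene-set overlap of shortened genes, train vs validate
    apa_gene = dict(zip(universe.transcripts["transcript_id"], universe.transcripts["gene_id"]))
    def shortened_genes(fit):
        sig = fit.significant
        ids = sig.loc[sig["direction"] == "shortened", "apa_id"]
        return {apa_gene[a.rsplit(":", 1)[0]] for a in ids}
    gene_universe = {apa_gene[p.transcript_id] for p in pairs}
    set_a, set_b = shortened_genes(diff["train"]), shortened_genes(diff["validate"])
    obs, exp, p_overlap = gene_set_overlap(set_a, set_b, gene_universe)
    results["overlap_observed"] = obs
    results["overlap_expected"] = exp
    results["overlap_p"] = p_overlap

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results
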