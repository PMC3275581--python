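# Methods

## The probe signal model and the Expression Ratio Index

A transcript with an APA site at mRNA coordinate `s` (0-based, half-open;
`s` is the first base of the distal fragment) is expressed as a mixture of
a long isoform (full 3′UTR) and a short isoform ending at `s`. Probes whose
interval ends at or before `s` hybridize both isoforms; probes starting at
or after `s` hybridize the long isoform only; probes straddling `s`
hybridize the short isoform with partial affinity and are excluded from
both probesets. With isoform levels L and S and probeset affinities `a`:

    signal_5′ = a(5′,L)·L + a(5′,S)·S
    signal_3′ = a(3′,L)·L

The Expression Ratio Index is their ratio — affine in S/L, invariant to
overall expression changes, increasing in the prevalence of the short
isoform. We compute and store it on the log2 scale,
`logERI = log2(summary_5′) − log2(summary_3′)`, because array summaries are
conventionally log2. Whether one takes a log-ratio of linear summaries or a
ratio of log summaries is a monotone choice; every downstream test here is
rank-based or a difference, so results are unaffected.

Assumptions inherited from the model: probe response linear in target
concentration after background subtraction; no cross-hybridization; probe
affinities stable across samples. Multi-site transcripts get one
independent binary split per site (all downstream probes in that site's 3′
probeset), i.e. a per-site two-isoform approximation; probes shared between
the resulting pairs are recorded in the build report. A consequence worth
knowing: a strong shortening event at a *distal* site perturbs the 3′
probeset of the *proximal* pair of the same transcript, so per-site
direction calls on multi-site transcripts are less reliable than on
single-site transcripts (visible in the synthetic pipeline runs, where
direction consistency is near-perfect with single-site universes and drops
to ~80–90% when a quarter of transcripts carry two sites).

## Summarization

`quantile_median_polish` quantile-normalizes log2 probe intensities across
samples (columns mapped onto the mean empirical distribution; ties resolved
by average-rank interpolation) and then median-polishes each probeset's
probes × samples block, reporting `overall + column effect` per sample.
This is the RMA summary scheme without the convolution background
correction, which needs mismatch/background probe data we do not model.
`median_log` (per-probeset, per-sample median of log2 intensities) is an
exact summary under the noiseless generator and is used in simulations
where tens of thousands of summaries are needed. Intensities are floored at
1.0 before log2 so backgrounds cannot produce −∞.

## Differential APA usage

Patients are classified at a horizon (default 60 months; the lung-cancer
convention in the literature is 30): event before the horizon → poor,
event-free follow-up past it → good, censored earlier → unassigned.
Unassigned patients are excluded from the two-group comparison — their
class is simply unknown — but still participate in survival analyses. The
per-site test is two-sided Mann–Whitney (exact enumeration of the
permutation null when both groups have ≤ 8 samples, which remains correct
under ties; tie-corrected normal approximation otherwise) or Welch t for
cell-line-sized designs. BH q-values are computed over all tested sites;
`delta` is the poor-minus-good difference of group medians (means under
Welch), and the direction call `shortened`/`lengthened` is its sign.
Constant rows get p = 1 and a flag rather than an error.

## Prognostic signature (Cox-weighted ERI score)

The weight of signature site `a` is its Cox univariate score: the Wald z of
a single-covariate proportional-hazards fit of ERI_a against survival
(Newton–Raphson on the Breslow partial likelihood, gradient tolerance
1e-8, ≤ 50 iterations, steps clipped to ±2; monotone likelihood is detected
by the estimate running away and capped at |β| = 20 with a warning). Wald
z rather than the score or likelihood-ratio statistic is the conventional
reading of "univariate Cox score"; the choice is recorded in the model
metadata. A patient's prognostic score is

    P = Σ_a z_a · ERI_a

so high scores mean high short-isoform prevalence at the sites most
associated with poor survival. Validation freezes the weights, scores a new
cohort, splits at the median score (lower-or-equal goes to low risk — a
stated convention; the split is flagged degenerate if all scores tie), and
compares the classes with a two-group log-rank test; Kaplan–Meier curves
are returned for plotting. ERI values enter the score raw, matching the
linear-combination definition literally; a `standardize` flag z-scores each
site within the cohort first, for transfers across platforms where ERI
scales may differ.

## Mechanism discrimination

For each transcript (5′-most accepted site only, to count each transcript
once) we compute the poor-minus-good difference in median 5′-probeset
expression and in median ERI, and correlate the two vectors across
transcripts (Spearman; exact permutation p for n ≤ 10, t approximation
otherwise). Because the 5′ probeset sees both isoforms, it tracks total
transcript output: if poor tumors *synthesize* relatively more short
isoform, they also degrade less (the short form escapes microRNA decay), so
total output rises with ERI — positive correlation. If isoform synthesis is
unchanged but the long isoform is *degraded* faster in poor tumors, total
output falls while ERI rises — negative correlation. The discrimination
relies on across-transcript variation in the strength of the planted
mechanism; it is not identified if every transcript is affected identically.

## microRNA relevance and overlaps

An APA site is microRNA-relevant when the segment 3′ of it carries at least
one predicted binding site (site tables are consumed as input; no site
prediction is performed). Shortening is measured as the poor-minus-good
difference in mean ERI — means rather than the medians used elsewhere, to
match the estimand of the global relevance comparison; both are computed by
the library. The global test compares relevant vs irrelevant site deltas by
Mann–Whitney; per-family tests compare each family's relevant sites against
sites carrying no site *for that family* (comparison against globally
irrelevant sites is available behind a flag), require ≥ 5 relevant sites
(families below the floor are listed as skipped, preventing vacuous tests),
and are BH-controlled at 10% FDR with both directions reported. Gene-set
overlap reports the observed intersection, the hypergeometric expectation
|A||B|/N, and the one-sided (enrichment) Fisher exact p, computed as the
upper hypergeometric tail.

## The synthetic-data generator

The generator draws what the analysis assumes and nothing more:

- **Universe**: mRNA lengths uniform on 1500–4000 nt; 3′UTR starting at 60%
  of the length; one APA site per transcript (two for a configurable
  fraction, ≥ 120 nt apart) strictly inside the 3′UTR; 25-mer probes with
  Beta(3,1)-distributed (3′-biased) start positions, ~11 per transcript;
  a configurable fraction of sites receives microRNA binding-site records
  from a pool of 20 families.
- **Isoform mixing**: sequential cleavage 5′→3′ — a fraction `f_k` of
  molecules intact at site k is cleaved there; `f_k` is parameterized on
  the logit scale (site-level mean −0.6 ± 0.7 SD across sites; sample-level
  biological noise 0.5 SD) so that group shifts compose additively.
- **Mechanisms**: under *synthesis*, planted sites shift the poor group's
  logit by `delta` (default 1.5) while the long isoform survives microRNA
  decay with factor `m = 0.5` in both groups; under *degradation*, synthesis
  is identical but `m` drops from 0.9 (good) to 0.45 (poor). Each planted
  site scales its effect by a uniform multiplier on [0.1, 1.9]
  (`effect_heterogeneity = 0.9`): biological effect sizes are not uniform,
  and this across-transcript spread is precisely what the mechanism
  correlation measures — with homogeneous effects the correlation is
  dominated by baseline short-fraction variation and loses its sign
  information. Planting can be biased toward microRNA-relevant sites
  (`relevance_bias`), reflecting selection for escape from microRNA control.
- **Probe intensities**: `background + affinity · concentration · noise`
  with per-probe lognormal affinities (0.4 log-SD), background 20 intensity
  units against typical signals of ~200, and multiplicative lognormal noise
  (0.25 log-SD, ≈ 28% CV) — chosen once as a realistic array noise scale;
  the literature gives no calibrated magnitudes, so these are scenario
  parameters, not estimates.
- **Survival**: exponential baseline (median 60 months) with log-hazard
  `γ ·` (per-sample mean planted logit, centered), uniform administrative
  censoring on 1–120 months. This is the simplest model under which the
  weighted ERI score is well-specified.

Identical seeds give byte-identical outputs; every cohort ships truth
tables (planted directions, effect sizes, per-sample burden, realized
logits) for recovery tests.

What the generator does **not** emulate: optical/spatial CEL-level
artifacts, cross-hybridization, GC-dependent probe behavior, batch effects,
correlated expression between genes, non-proportional hazards, or
informative censoring. Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to every failure mode
of real arrays.

## Numerical and testing choices

- Exact Mann–Whitney switches on at group sizes ≤ 8 (≤ 12,870 assignments);
  the exact two-sided p counts assignments with |U − nm/2| at least as
  extreme, which agrees with the doubled-tail convention under the
  symmetric null.
- BH q-values use the step-up formula `q_(i) = min_{j≥i} m·p_(j)/j` clipped
  at 1; rejection at `q ≤ α` is identical to the classic step-up rule.
- Median polish runs ≤ 10 sweeps or until row/column medians move < 1e-6.
- Spearman exact permutation p at n ≤ 10 enumerates all n! rank
  permutations vectorized.
- Simulation-based test sizes were chosen to estimate each property with
  comfortable Monte-Carlo margins at interactive runtimes: FDR control uses
  ~2,000 accepted sites × 40+40 samples × 200 replicates; signature
  transfer 2 × 200 patients × 50 replicates; mechanism discrimination ~200
  planted transcripts × 80 samples × 100 replicates per mechanism;
  microRNA recovery 2,000 sites, 20 families, 100 replicates.

## Known limitations

- The per-site two-isoform approximation mixes isoform pools in the 3′
  probesets of proximal sites on multi-site transcripts (discussed above).
- The summarizer is not full RMA; absolute expression levels are not
  comparable to RMA output, though rank-based downstream results are
  insensitive to this.
- Group assignment discards patients censored before the horizon; with
  heavy early censoring the two-group test loses power (the survival
  analyses still use everyone).
- The score transfer assumes comparable ERI scales across cohorts; use
  `standardize=True` when that is doubtful.
- Monotone-likelihood Cox fits (tiny strata, perfect separation) are capped
  rather than refit with penalization.
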