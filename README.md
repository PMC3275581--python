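# apasig

Inference of 3′UTR shortening from 3′-biased expression microarrays, and
survival analysis of its clinical impact.

Many transcripts carry alternative polyadenylation (APA) sites in their
3′UTR: cleavage at a proximal site produces a **short isoform** lacking the
distal UTR segment — and with it, any microRNA binding sites that segment
contains. On 3′-biased expression arrays (HG-U133-style designs) the probes
of a transcript can be re-partitioned around an APA site into a **5′
probeset** (hybridizing both isoforms) and a **3′ probeset** (hybridizing
the long isoform only). Writing L and S for the expression of the long and
short isoform and a(·,·) for probeset affinities,

```
signal_5′ = a(5′,L)·L + a(5′,S)·S
signal_3′ = a(3′,L)·L
ERI       = signal_5′ / signal_3′          (Expression Ratio Index)
```

The ERI is affine in S/L and invariant to overall expression changes: a
higher ERI means a higher prevalence of the short 3′UTR isoform. `apasig`
implements the full analysis chain built on this index:

1. **Probeset construction** — split each transcript's probes around every
   APA site (0-based, half-open mRNA coordinates; probes spanning the site
   are excluded; both sides need ≥ 3 probes).
2. **Summarization & ERI** — quantile normalization + median-polish
   summarization of log2 probe intensities (RMA-style, without the
   convolution background model) or a fast per-probeset median; log2 ERI =
   5′ summary − 3′ summary.
3. **Differential APA usage** — Mann–Whitney (exact for small groups) or
   Welch t comparison of ERI between poor- and good-outcome patients, with
   Benjamini–Hochberg FDR control and direction calls
   (shortened/lengthened in poor outcome).
4. **Prognostic signature** — each selected APA site is weighted by its Cox
   univariate Wald z; a patient's score is the weighted sum of ERI values.
   Frozen weights transfer to independent cohorts, where a median-score
   split is evaluated with a log-rank test and Kaplan–Meier curves.
5. **Mechanism & microRNA analyses** — Spearman correlation between
   per-transcript group differences in total (5′) expression and in ERI
   separates differential isoform *synthesis* (positive) from differential
   long-isoform *degradation* (negative); Mann–Whitney enrichment tests ask
   whether microRNA-relevant APA sites (those whose distal segment carries
   predicted binding sites) are preferentially shortened, globally and per
   microRNA family; hypergeometric/Fisher statistics quantify gene-set
   overlaps between analyses.
6. **Synthetic cohorts** — a generator that draws probe-level intensities
   from the exact two-isoform signal model above (sequential cleavage for
   multi-site transcripts, planted group effects under either mechanism,
   survival times with log-hazard linear in the shortening burden), with
   full ground-truth tables for power and calibration studies.

The package is aimed at computational biologists re-analyzing legacy
3′-biased array cohorts with survival annotation, and at methodologists who
need a controlled testbed for APA-detection statistics.

## Worked example

```python
import apasig as ap
from apasig.probesets import pairs_to_frame

universe = ap.generate_universe(n_transcripts=120, multi_apa_fraction=0.25, seed=0)
truth = ap.SimulationTruth.synthesis(gamma=1.5)   # shortening raises the hazard
cohort = ap.generate_cohort(universe, truth, n_samples=100, planted_fraction=0.3, seed=1)

pairs, report = ap.build_all(universe.transcripts, universe.probes)
defs = pairs_to_frame(pairs)
expr = ap.summarize(cohort.intensity, defs)       # quantile norm + median polish
eri = ap.compute_eri(expr, pairs)

groups = ap.assign_groups(cohort.clinical, horizon=60)   # outcome at 5 years
fit = ap.DifferentialUsageModel(eri, groups).fit(test="mann_whitney", fdr=0.05)
print(fit.summary())

sig = ap.PrognosticSignature(eri, cohort.clinical, fit.significant["apa_id"]).fit()
validation = ap.generate_cohort(universe, truth, 100, 0.3, seed=2)
eri_val = ap.compute_eri(ap.summarize(validation.intensity, defs), pairs)
scores = sig.score(eri_val)                       # frozen weights, median split
lr = ap.logrank_compare(scores, validation.clinical)
print(f"validation log-rank chi2 = {lr.statistic:.2f}, p = {lr.pvalue:.2e}")
```

Output:

```
Differential APA usage
======================
test: mann_whitney    FDR cutoff: 0.05
APA sites tested: 102   (flagged degenerate: 0)
significant at q <= 0.05: 16
  shortened in poor outcome: 16
  lengthened in poor outcome: 0
...
validation log-rank chi2 = 53.12, p = 3.14e-13
```

All 16 discoveries are planted shortening events read in the correct
direction; the signature trained on the first cohort cleanly separates
survival in the independent second cohort (`lr.plot()` draws the
Kaplan–Meier curves).

## Command line

Every stage is also a subcommand of the `apasig` CLI operating on plain TSV
files — `simulate`, `build-probesets`, `summarize`, `eri`, `diff-apa`,
`train-signature`, `score`, `survival`, `mechanism`, `mirna`, `overlap` —
and `run-all` drives the whole train/validate workflow from a YAML config:

```sh
apasig run-all --config config.yaml --out runs/demo
```

Outputs carry the config hash, seed and package version in header comments;
a rerun with an identical config is byte-identical.

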