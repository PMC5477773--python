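# Methods

## Growth model and metric extraction

Simulated curves are baseline-shifted logistics with an explicit lag:

    OD(t) = baseline_od + capacity / (1 + exp(-rate * (t - t_mid))) + noise,

with `t_mid` placed so the logistic sits at 1% of capacity at the end of
the lag. This is the minimal model that lets the three observables used
downstream — asymptotic density (baseline + capacity), saturation time
and log-phase rate — be set independently. OD values are clipped at
1e-4 so log transforms stay defined.

Metric extraction works on a smoothed curve (running median then running
mean, default window 5 points, truncated at the ends; window 1 is the
identity):

- `max_od`: maximum of the smoothed series (earliest index wins ties);
- `time_to_max_od`: earliest time the smoothed series reaches
  `saturation_fraction * max_od`. The saturation time of a batch culture
  has no unique definition; the default fraction is 0.95, and 1.0 means
  the time of the maximum itself. Because the fraction is applied to the
  observed maximum, runs should extend well past the inflection.
- `log_growth_rate`: maximum over sliding windows (default 5 points) of
  the least-squares slope of ln OD vs time. On a baseline-shifted
  logistic this is a lower bound on the logistic `rate` parameter — the
  additive baseline flattens early ln-OD slopes — so rate-recovery
  checks subtract the known baseline first. No lag-time or diauxic-shift
  estimation is attempted.
- `effective_growth_rate = max_od / time_to_max_od`, exact by
  construction.

Curves with no net growth (smoothed maximum not above the first value)
are flagged and reported rather than raised, so batch runs complete.
Replicates are averaged per metric before fold changes; the
effective-rate identity is re-imposed after averaging. A strain counts
as improved iff its effective-rate fold is strictly above 1.

Paired wt/evolved panels are generated backwards from per-strain fold
targets for (max OD, saturation time): the evolved capacity follows
directly from the target asymptote; the saturation-time target is hit by
shifting the lag at fixed rate, or, if that would need a negative lag,
by pinning lag at 0 and raising the rate. Noiseless panel curves are
sampled at 0.02 h so grid quantization of the saturation time stays well
below the 2-decimal precision at which folds are compared.

## Expression generator

The design is strains × {wt, evolved} × {glucose, xylulose} ×
replicates (default 12 × 2 × 2 × 2 = 96 samples). Per-gene baselines are
log-normal (ln-scale mean 4, sd 1). On xylulose a gene's mean is
multiplied by 2^effect:

| group        | wt effect                  | evolved effect        |
|--------------|----------------------------|-----------------------|
| aa module    | a − b·g (growth rate g)    | residual (default 0)  |
| RP/Ribi      | c·g                        | c·g                   |
| background   | 0                          | 0                     |

with defaults a = 1.5 log2, b = 4 log2/(OD·h⁻¹), c = 2 log2/(OD·h⁻¹).
All numeric defaults are invented fixture values chosen to be plausible
for a yeast transcriptome — none are measurements. Default group sizes
are 60 aa + 60 RP genes out of 3000, keeping the induced mass a few
percent of the library, as for a real transcriptome.

Per-sample means are rescaled so every sample's expected total equals
`library_size` (default 10⁶); counts are gamma-Poisson
(negative-binomial) with one shared dispersion (default 0.05; 0 gives
Poisson). Because of the per-sample rescaling, the realized log2
xylulose/glucose ratio of a group differs from the injected effect by a
small compositional term (the log2 ratio of total transcriptional
output); the truth table emitted with every simulation records both the
injected effect and the composition-corrected expectation, and recovery
tests compare against the latter. The same compositional coupling is an
intrinsic property of total-count normalization, which is why the null
group in the calibration runs shows a mildly non-zero expected
correlation; at the default effect sizes it stays far below the
detection threshold at n = 12.

Wild-type effective growth rates are spread over 0.08–0.30 OD/h and
evolved rates converge near 0.30 OD/h: slower ancestors induce the aa
module more strongly (a − b·g) *and* improve more (fold ≈ 0.3/g), which
is exactly the convergent-adaptation structure the correlation analysis
is meant to detect. The generator does not emulate: gene-length or GC
biases, replicate batch effects, correlated gene-gene noise, UMI/PCR
artifacts, or condition-dependent library quality — so passing recovery
tests demonstrate correctness of the estimators under the stated
negative-binomial model, not robustness to every artifact of real
RNA-seq data.

## Expression analysis choices

- Normalization: each sample scaled to exactly 10⁶ total counts.
  All-zero samples are an error naming the sample.
- Replicates are arithmetically averaged after normalization; ratios use
  a pseudocount of 1 normalized count on both sugars (log base 2
  throughout).
- Changed genes: |median ratio across strains| ≥ threshold (default 1.0
  log2) with the median's sign in ≥ 2/3 of strains. With two replicates
  there is no basis for per-gene variance modelling, so a robust
  consensus rule is used instead of a formal test; both knobs are
  configurable.
- Enrichment: one-sided (upper-tail) hypergeometric per group against
  the matrix's gene universe, Benjamini–Hochberg across groups. Genes in
  a set but absent from the matrix are dropped and logged, never imputed.
- Group summaries average genes within a strain first, then strains;
  SE = SD/√n over strains (ddof = 1); a single strain yields SE 0 with a
  flag.
- The per-gene wt/evolved profile divides each gene's two strain-mean
  values (on xylulose) by the gene's total reads across all samples of
  the matrix, putting every gene on its own relative scale.
- Expression change for the correlation is evolved/wt of the group-mean
  expression on xylulose (the sugar under selection); the per-strain
  ratio-of-ratios variant can be obtained by correlating the ratio
  tables directly.
- Correlation: Pearson r; two-sided p via the t transform with n − 2 df;
  a seeded permutation p (default 10,000 shuffles, add-one corrected,
  two-sided on |r|) is always reported alongside as a robustness column.

## Problem sizes and numerical details

Default analysis scale is 12 strains, 3000 genes, 2 replicates; the
Monte-Carlo calibration uses 100 panels at those defaults (about half a
minute) and a 30-gene null group. The panel simulation samples curves at
0.02 h; metric agreement between coarse (0.1 h) and dense (0.001 h)
grids is within 2%. Ties in the smoothed maximum resolve to the earliest
timepoint. Degenerate inputs (no growth, zero-variance correlation
axes, empty group intersections, all-zero samples) are either flagged or
raised with the offending name, as documented per function.

## Known limitations

- The effective growth rate conflates yield and speed by design; strains
  can trade one for the other at equal effective rates.
- Total-count normalization is compositional: large induced modules bleed
  into all other groups' apparent ratios. The truth record quantifies
  this exactly for simulated data; for real data a ratio-robust
  normalization would be needed to remove it.
- The changed-gene rule is a consensus heuristic, not an error-controlled
  test; its threshold should be matched to the effect sizes of interest
  (the bundled drivers use 0.5 log2 against the generator's ~0.7 log2
  median induction).
- Correlation at n = 12 has limited power and the parametric p assumes
  bivariate normality; the permutation p is the safer of the two at this
  sample size.
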