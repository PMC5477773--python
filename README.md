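# xylevo

Analysis pipeline for laboratory evolution of budding yeast on
**xylulose** — the one pentose *S. cerevisiae* can metabolize, and a
carbon source it has had essentially no evolutionary exposure to. The
package quantifies, for a panel of wild-isolate strains propagated by
serial dilution, (i) how growth on xylulose improved during evolution
and (ii) how the transcriptional response to xylulose — in particular
the GCN4-driven amino-acid-biosynthesis (aa) module and the
growth-rate-coupled ribosomal-protein/biogenesis (RP/Ribi) modules —
changed alongside that improvement. A seedable synthetic-data generator
reproduces the study's statistical structure so every stage is testable
without any external download.

## The quantities at the core

For an OD600 growth curve the pipeline extracts four metrics:

- log-phase growth rate: max over sliding windows of the least-squares
  slope of ln OD vs time (h⁻¹);
- maximum OD and the time to reach a saturation fraction (default 0.95)
  of it;
- **effective growth rate** = max OD / time to max OD (OD·h⁻¹), a single
  number combining yield and speed;

and per strain the evolved/wild-type **fold change** of each metric.
Generations under serial dilution are `n_dilutions * log2(dilution factor)`
(1:64 daily ⇒ 6 generations/day).

For expression, counts are scaled to 10⁶ per sample (CPM), replicates
averaged, and per strain/status the per-gene ratio
`log2((xyl + 1)/(glu + 1))` computed. Changed genes (median threshold +
sign consistency across strains) are projected onto gene groups with a
one-sided hypergeometric test (BH-corrected). Per strain, the group-level
expression change `log2(mean evolved / mean wt)` on xylulose is
correlated with the effective-growth-rate fold (Pearson r, two-sided
t-based p, plus a seeded permutation p).

## Worked example

Run the numbered drivers from the repository root:

```sh
python analysis/01_simulate_panel.py
python analysis/02_growth_fold_changes.py
python analysis/03_expression_ratios.py
python analysis/04_correlate_adaptation.py
python analysis/05_sign_recovery.py
```

Step 02 extracts metrics from the simulated plate CSV (whose curves were
generated to hit the published per-strain max-OD and time fold changes)
and prints

```
11 of 12 strains improved their effective growth rate
  strain01: computed 1.961, reference 1.96 (match)
  ...
12/12 effective-rate folds match the reference table at printed precision
```

i.e. the pipeline's effective-growth-rate folds reproduce the reference
table at its printed precision, with strain 10 the single non-improver.
Step 03 shows the generator's ancestral induction of the aa module on
xylulose and its loss after evolution (group mean log2 xyl/glu
+0.71 ± 0.08 in wt vs −0.02 ± 0.01 evolved; the aa module carries 56 of
59 called changed genes, hypergeometric p ≈ 4e-110), and step 04 the
adaptation signature:

```
aa_module: r = -0.599, p = 0.0395, permutation p = 0.0412 (n = 12 strains)
rp_module: r = +0.615, p = 0.0335, permutation p = 0.0349 (n = 12 strains)
evolution displacement vector (aa, RP) = (-0.728, +0.249) log2 units
```

— the more a strain improved, the more aa-module induction it lost,
while RP expression moved with growth. Step 05 repeats this over 100
simulated panels: the aa correlation is negative in 100/100, a 30-gene
null group reaches p < 0.05 in 6/100.

A `xylevo` CLI wraps the same stages
(`xylevo run-all | simulate | growth | expr | correlate`, see `--help`).

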