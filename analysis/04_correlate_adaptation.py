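#!/usr/bin/env python
"""Correlate per-strain expression change with growth improvement.

For each gene group, the per-strain log2 change (evolved/wt on xylulose)
of group-mean expression is correlated with the effective-growth-rate
fold from step 02. Reports Pearson r with the parametric two-sided p and
a seeded 10,000-draw permutation p, plus the aa-vs-RP displacement
vector of the panel during evolution.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from xylevo import adaptation_analysis as aa
from xylevo import expression_pipeline as ep
from xylevo import io as xio

DATA = Path("results/data")
OUT = Path("results/adaptation")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = xio.read_counts_tsv(DATA / "counts.tsv")
    design = xio.read_sample_sheet(DATA / "samples.tsv")
    gene_sets = xio.read_gmt(DATA / "groups.gmt")
    folds = pd.read_csv("results/growth/fold_changes.tsv", sep="\t").set_index("strain_id")

    norm = ep.normalize_to_million(counts)
    averaged, avg_design = ep.average_replicates(norm, design)
    strains = [s for s in avg_design["strain"].unique() if s in folds.index]

    rows = []
    for name, members in gene_sets.items():
        records = [
            aa.StrainChangeRecord(
                s, name,
                aa.expression_change(averaged, avg_design, members, s),
                float(folds.loc[s, "effective_growth_rate"]),
            )
            for s in strains
        ]
        res = aa.correlate_change_with_growth(records, permutations=10_000, seed=SEED)
        rows.append(dataclasses.asdict(res))
        print(f"{name}: r = {res.r:+.3f}, p = {res.p:.4f}, "
              f"permutation p = {res.p_permutation:.4f} (n = {res.n} strains)")
    pd.DataFrame(rows).to_csv(OUT / "correlations.tsv", sep="\t", index=False)

    coords, disp = aa.group_vs_group_coordinates(
        averaged, avg_design, gene_sets["aa_module"], gene_sets["rp_module"]
    )
    coords.to_csv(OUT / "aa_vs_rp_coordinates.tsv", sep="\t", index=False)
    print(f"evolution displacement vector (aa, RP) = "
          f"({disp['displacement_a']:+.3f}, {disp['displacement_b']:+.3f}) log2 units")


if __name__ == "__main__":
    main()
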