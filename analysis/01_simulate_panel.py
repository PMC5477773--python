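#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes, under results/data/: a plate-reader CSV for the 12-strain
wt/evolved growth panel (noiseless logistic curves whose analytic fold
changes hit the published max-OD and time-to-saturation fold targets),
an expression count matrix over the 12 x {wt, evolved} x {glucose,
xylulose} x 2 design (96 samples), the sample sheets, the gene-set GMT
and the truth table of injected effects.
"""

from pathlib import Path

from xylevo import io as xio
from xylevo import synthetic_data as sd
from xylevo.reference_data import TWELVE_STRAIN_FOLDS

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    targets = list(
        zip(TWELVE_STRAIN_FOLDS["max_od_fold"], TWELVE_STRAIN_FOLDS["time_to_max_od_fold"])
    )
    wt_curves, ev_curves, panel = sd.simulate_strain_panel(
        12, sd.default_wt_growth_params(12), targets, seed=SEED
    )
    wells = xio.write_plate_csv(wt_curves + ev_curves, OUT / "plates.csv")
    xio.write_sample_sheet(wells, OUT / "wells.tsv")
    panel.to_csv(OUT / "panel_parameters.tsv", sep="\t", index=False)

    params = sd.default_expression_params(n_strains=12, seed=SEED + 1)
    counts, design, truth = sd.simulate_expression(params)
    xio.write_counts_tsv(counts, OUT / "counts.tsv")
    xio.write_sample_sheet(design, OUT / "samples.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    xio.write_gmt(sd.group_gmt_sets(params), OUT / "groups.gmt")

    print(f"wrote {len(wt_curves) + len(ev_curves)} growth curves "
          f"({len(wt_curves[0])} timepoints each) and a "
          f"{counts.shape[0]} x {counts.shape[1]} count matrix to {OUT}")


if __name__ == "__main__":
    main()
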