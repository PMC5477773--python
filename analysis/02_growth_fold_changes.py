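#!/usr/bin/env python
"""Growth metrics, evolved/wt fold changes and the improvement count.

Reads the plate CSV from step 01, extracts per-curve metrics (log-phase
rate, max OD, time to saturation, effective growth rate = max OD / time),
forms evolved/wt fold changes per strain and classifies improvement.
The computed effective-rate folds are compared against the published
twelve-strain reference values.
"""

from pathlib import Path

import pandas as pd

from xylevo import growth_metrics as gm
from xylevo import io as xio
from xylevo.reference_data import PRINTED_DECIMALS, TWELVE_STRAIN_FOLDS

DATA = Path("results/data")
OUT = Path("results/growth")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curves = xio.read_plate_csv(DATA / "plates.csv", xio.read_sample_sheet_growth(DATA / "wells.tsv"))
    cfg = gm.MetricsConfig()

    metrics = {}
    rows = []
    for c in curves:
        m = gm.compute_metrics(c, cfg)
        metrics[(c.strain_id, c.status)] = m
        rows.append({"strain_id": c.strain_id, "status": c.status, **m.as_dict()})
    pd.DataFrame(rows).to_csv(OUT / "growth_metrics.tsv", sep="\t", index=False)

    strains = sorted({s for s, _ in metrics})
    records = [gm.fold_change(metrics[(s, "evolved")], metrics[(s, "wt")], s) for s in strains]
    folds = pd.DataFrame([{"strain_id": r.strain_id, **r.as_dict()} for r in records])
    folds.to_csv(OUT / "fold_changes.tsv", sep="\t", index=False)

    labels, n_improved = gm.classify_improvement(records)
    pd.DataFrame([{"strain_id": s, "label": labels[s]} for s in strains]).to_csv(
        OUT / "improvement.tsv", sep="\t", index=False
    )

    print(f"{n_improved} of {len(strains)} strains improved their effective growth rate")
    matches = 0
    for rec, printed, dec in zip(
        records, TWELVE_STRAIN_FOLDS["effective_growth_rate_fold"], PRINTED_DECIMALS
    ):
        ok = round(rec.effective_growth_rate, dec) == printed
        matches += ok
        print(f"  {rec.strain_id}: computed {rec.effective_growth_rate:.3f}, "
              f"reference {printed} {'(match)' if ok else '(MISMATCH)'}")
    print(f"{matches}/12 effective-rate folds match the reference table at printed precision")


if __name__ == "__main__":
    main()
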