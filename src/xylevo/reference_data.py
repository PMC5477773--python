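"""Published growth-parameter fold changes for the twelve-strain panel.

Measured evolved/wild-type fold changes in growth parameters for twelve
wild-isolate budding-yeast strains after ~300 generations of serial
dilution on xylulose: maximal specific growth rate, maximum OD, time to
maximum OD, and the effective growth rate (maximum OD divided by time to
maximum OD). ``PRINTED_DECIMALS`` records the precision each effective
fold was reported at (the published table mixes 1- and 2-decimal rows).
"""

from __future__ import annotations

import pandas as pd

TWELVE_STRAIN_FOLDS = pd.DataFrame(
    {
        "strain_id": [f"strain{i:02d}" for i in range(1, 13)],
        "growth_rate_fold": [1.32, 1.03, 1.78, 1.13, 1.38, 0.78, 1.11, 1.36, 1.14, 1.40, 1.14, 0.92],
        "max_od_fold": [3.00, 1.39, 3.27, 1.36, 1.80, 1.15, 1.07, 1.41, 1.29, 1.14, 1.38, 0.97],
        "time_to_max_od_fold": [1.53, 1.20, 1.36, 0.82, 0.76, 0.79, 0.73, 0.80, 1.21, 1.19, 0.94, 0.88],
        "effective_growth_rate_fold": [1.96, 1.16, 2.4, 1.66, 2.37, 1.46, 1.47, 1.76, 1.07, 0.96, 1.47, 1.1],
    }
).set_index("strain_id")

# decimals at which the effective fold was printed, per strain
PRINTED_DECIMALS = [2, 2, 1, 2, 2, 2, 2, 2, 2, 2, 2, 1]

STUDY_N_STRAINS = 12
STUDY_N_REPLICATES = 2
STUDY_DILUTION_FACTOR = 64
STUDY_GENERATIONS = 300
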