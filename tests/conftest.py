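import numpy as np
import pytest

from xylevo import synthetic_data as sd
from xylevo import expression_pipeline as ep
from xylevo.reference_data import TWELVE_STRAIN_FOLDS


@pytest.fixture(scope="session")
def twelve_strain_panel():
    """Noiseless 12-strain growth panel hitting the published fold targets."""
    targets = list(
        zip(TWELVE_STRAIN_FOLDS["max_od_fold"], TWELVE_STRAIN_FOLDS["time_to_max_od_fold"])
    )
    wt_curves, ev_curves, table = sd.simulate_strain_panel(
        12, sd.default_wt_growth_params(12), targets, seed=11
    )
    return wt_curves, ev_curves, table


@pytest.fixture(scope="session")
def expression_dataset():
    """One default-parameter expression simulation with its truth record."""
    params = sd.default_expression_params(seed=20)
    counts, design, truth = sd.simulate_expression(params)
    return params, counts, design, truth


@pytest.fixture(scope="session")
def analyzed_expression(expression_dataset):
    """CPM-normalized, replicate-averaged matrix and per-status ratio tables."""
    params, counts, design, truth = expression_dataset
    norm = ep.normalize_to_million(counts)
    averaged, avg_design = ep.average_replicates(norm, design)
    ratios = {
        status: ep.ratio_table(averaged, avg_design, status, pseudocount=1.0)
        for status in ("wt", "evolved")
    }
    return averaged, avg_design, ratios


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
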