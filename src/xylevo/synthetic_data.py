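"""Seeded generators for growth curves and expression count matrices.

The generators emulate the statistical structure of a serial-dilution
adaptation experiment on xylulose:

* growth: baseline-shifted logistic OD curves with strain-specific rate,
  carrying capacity and lag, plus Gaussian measurement noise;
* expression: negative-binomial counts over a gene x sample design
  (strain x {wt, evolved} x {glucose, xylulose} x replicate) in which an
  amino-acid-biosynthesis module is induced on xylulose in ancestral
  strains with a magnitude anti-correlated with growth rate
  (``a - b * growth_rate`` in log2 units), that induction collapses to a
  residual after evolution, and ribosomal-protein/biogenesis genes track
  growth rate in both states.

Every simulation emits a truth record of the injected effects so
recovery tests never re-derive them. All numeric defaults are invented
fixture values, not measurements; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_metrics import GrowthCurve

__all__ = [
    "GrowthSimParams",
    "ExpressionSimParams",
    "simulate_growth_curve",
    "simulate_strain_panel",
    "simulate_expression",
    "analytic_growth_metrics",
    "default_wt_growth_params",
    "default_expression_params",
]

# logistic fraction treated as "still at baseline" at the end of the lag
_LAG_DEPARTURE = 0.01
_OD_FLOOR = 1e-4


@dataclass(frozen=True)
class GrowthSimParams:
    """Parameters of one simulated growth curve.

    OD(t) = baseline_od + capacity / (1 + exp(-rate * (t - t_mid))) + noise,
    with t_mid placed so the logistic sits at 1% of capacity at t = lag.
    Units: OD is dimensionless optical density, times are hours.
    """

    baseline_od: float = 0.05
    capacity: float = 1.0
    rate: float = 0.3
    lag: float = 2.0
    noise_sd: float = 0.0
    sampling_interval: float = 0.1
    duration: float = 72.0

    def __post_init__(self):
        if self.baseline_od <= 0:
            raise ValueError("baseline_od must be > 0")
        if self.capacity <= 0:
            raise ValueError("capacity must be > 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.duration <= self.lag:
            raise ValueError("duration must exceed lag")

    @property
    def t_mid(self) -> float:
        """Inflection time implied by the lag convention."""
        return self.lag + math.log((1 - _LAG_DEPARTURE) / _LAG_DEPARTURE) / self.rate


def simulate_growth_curve(
    params: GrowthSimParams,
    seed: int,
    strain_id: str = "sim",
    status: str = "wt",
    replicate: int = 1,
) -> GrowthCurve:
    """Simulate one OD600 time series; deterministic given ``seed``.

    OD values are clipped at a small positive floor so downstream log
    transforms stay defined.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, params.duration + 0.5 * params.sampling_interval, params.sampling_interval)
    logistic = params.capacity / (1.0 + np.exp(-params.rate * (times - params.t_mid)))
    ods = params.baseline_od + logistic
    if params.noise_sd > 0:
        ods = ods + rng.normal(0.0, params.noise_sd, size=ods.shape)
    ods = np.maximum(ods, _OD_FLOOR)
    return GrowthCurve(strain_id=strain_id, status=status, replicate=replicate, times=times, ods=ods)


def analytic_growth_metrics(params: GrowthSimParams, saturation_fraction: float = 0.95) -> dict[str, float]:
    """Noise-free closed-form metrics of a simulated curve.

    max_od is the asymptote baseline + capacity; time_to_max_od is where
    the curve crosses ``saturation_fraction`` of that asymptote.
    """
    max_od = params.baseline_od + params.capacity
    theta = (saturation_fraction * max_od - params.baseline_od) / params.capacity
    if not 0 < theta < 1:
        raise ValueError("saturation_fraction does not intersect the curve")
    t_sat = params.t_mid + math.log(theta / (1 - theta)) / params.rate
    return {
        "max_od": max_od,
        "time_to_max_od": t_sat,
        "rate": params.rate,
        "effective_growth_rate": max_od / t_sat,
    }


def _evolved_params_for_targets(
    wt: GrowthSimParams,
    capacity_fold: float,
    time_fold: float,
    saturation_fraction: float,
) -> GrowthSimParams:
    """Derive evolved-curve parameters hitting the analytic fold targets.

    The evolved asymptote is capacity_fold x the wild-type asymptote and
    the analytic saturation time is time_fold x the wild-type one. The
    lag is adjusted first; if the target demands a negative lag the rate
    is raised instead (lag pinned at 0).
    """
    if capacity_fold <= 0 or time_fold <= 0:
        raise ValueError("fold targets must be > 0")
    wt_m = analytic_growth_metrics(wt, saturation_fraction)
    new_max = capacity_fold * wt_m["max_od"]
    new_capacity = new_max - wt.baseline_od
    if new_capacity <= 0:
        raise ValueError("capacity fold target drives capacity below zero")
    t_sat_target = time_fold * wt_m["time_to_max_od"]

    theta = (saturation_fraction * new_max - wt.baseline_od) / new_capacity
    logit = math.log(theta / (1 - theta))
    depart = math.log((1 - _LAG_DEPARTURE) / _LAG_DEPARTURE)

    t_mid = t_sat_target - logit / wt.rate
    lag = t_mid - depart / wt.rate
    if lag >= 0:
        rate = wt.rate
    else:
        lag = 0.0
        rate = (depart + logit) / t_sat_target
    duration = max(wt.duration, t_sat_target + 14.0 / rate)
    return replace(wt, capacity=new_capacity, rate=rate, lag=lag, duration=duration)


def simulate_strain_panel(
    n_strains: int,
    wt_params: list[GrowthSimParams],
    fold_targets: list[tuple[float, float]],
    seed: int,
    n_replicates: int = 1,
    saturation_fraction: float = 0.95,
) -> tuple[list[GrowthCurve], list[GrowthCurve], pd.DataFrame]:
    """Paired wt/evolved growth curves for a panel of strains.

    ``fold_targets`` holds per-strain (max-OD fold, time-to-saturation
    fold) pairs; evolved parameters are derived so the noiseless analytic
    folds equal the targets exactly, hence the effective-growth-rate fold
    equals (max-OD fold) / (time fold).

    Returns (wt curves, evolved curves, per-strain parameter table).
    """
    if len(wt_params) != n_strains or len(fold_targets) != n_strains:
        raise ValueError("wt_params and fold_targets must have length n_strains")
    rng = np.random.default_rng(seed)
    wt_curves: list[GrowthCurve] = []
    ev_curves: list[GrowthCurve] = []
    rows = []
    for i, (wp, (cap_fold, time_fold)) in enumerate(zip(wt_params, fold_targets)):
        strain = f"strain{i + 1:02d}"
        ep = _evolved_params_for_targets(wp, cap_fold, time_fold, saturation_fraction)
        # evolved curves share the (possibly longer) evolved duration so
        # both statuses are observed to saturation
        wp_run = replace(wp, duration=ep.duration)
        for rep in range(1, n_replicates + 1):
            wt_curves.append(
                simulate_growth_curve(wp_run, int(rng.integers(2**31)), strain, "wt", rep)
            )
            ev_curves.append(
                simulate_growth_curve(ep, int(rng.integers(2**31)), strain, "evolved", rep)
            )
        rows.append(
            {
                "strain_id": strain,
                "capacity_fold_target": cap_fold,
                "time_fold_target": time_fold,
                "effective_fold_target": cap_fold / time_fold,
                "wt_rate": wp.rate,
                "evolved_rate": ep.rate,
                "wt_capacity": wp.capacity,
                "evolved_capacity": ep.capacity,
            }
        )
    return wt_curves, ev_curves, pd.DataFrame(rows)


def default_wt_growth_params(n_strains: int) -> list[GrowthSimParams]:
    """Deterministically varied wild-type growth parameters for a panel."""
    params = []
    for i in range(n_strains):
        params.append(
            GrowthSimParams(
                baseline_od=0.05,
                capacity=0.4 + 0.05 * (i % 6),
                rate=0.20 + 0.02 * (i % 5),
                lag=2.0 + 0.5 * (i % 4),
                noise_sd=0.0,
                sampling_interval=0.02,
                duration=120.0,
            )
        )
    return params


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

AA_MODULE = "aa_module"
RP_MODULE = "rp_module"
BACKGROUND = "background"
_GROUPS = (AA_MODULE, RP_MODULE, BACKGROUND)


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of the expression-count simulation.

    Per-gene baselines are log-normal (natural-log mean/sd
    ``baseline_log_mean`` / ``baseline_log_sd``). On xylulose each gene's
    mean is multiplied by 2**effect, where the effect is
    ``aa_induction_intercept - aa_induction_slope * growth_rate`` for
    aa-module genes in wild-type strains, ``evolved_aa_residual`` for
    aa-module genes in evolved strains, ``rp_coupling * growth_rate``
    for RP/Ribi genes in both states and 0 for background genes.
    Per-sample means are scaled so every sample's expected total equals
    ``library_size``; counts are negative-binomial with a shared
    ``dispersion`` (0 means Poisson).

    All defaults are invented fixture values.
    """

    n_genes: int = 3000
    n_strains: int = 12
    strain_growth_rates: dict = field(default_factory=dict)  # {"wt": [...], "evolved": [...]}
    n_replicates: int = 2
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    aa_induction_intercept: float = 1.5
    aa_induction_slope: float = 4.0
    rp_coupling: float = 2.0
    evolved_aa_residual: float = 0.0
    dispersion: float = 0.05
    library_size: float = 1e6
    group_assignment: dict = field(default_factory=dict)  # gene -> group name
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 3 or self.n_strains < 1 or self.n_replicates < 1:
            raise ValueError("n_genes >= 3, n_strains >= 1, n_replicates >= 1 required")
        if self.dispersion < 0 or self.library_size <= 0:
            raise ValueError("dispersion must be >= 0 and library_size > 0")
        for status in ("wt", "evolved"):
            rates = self.strain_growth_rates.get(status)
            if rates is None or len(rates) != self.n_strains:
                raise ValueError(f"strain_growth_rates[{status!r}] must list {self.n_strains} rates")
        if self.group_assignment:
            bad = set(self.group_assignment.values()) - set(_GROUPS)
            if bad:
                raise ValueError(f"unknown groups in assignment: {sorted(bad)}")


def default_expression_params(n_strains: int = 12, seed: int = 0, **overrides) -> ExpressionSimParams:
    """Fixture defaults: 3000 genes, a 60-gene aa module and a 60-gene
    RP module, wild-type growth rates spread over 0.08-0.30 OD/h and
    evolved strains converging near 0.30 OD/h (so slower ancestors both
    induce more and improve more).
    """
    wt_rates = np.linspace(0.08, 0.30, n_strains)
    ev_rates = 0.30 + 0.002 * np.arange(n_strains)
    genes = [f"g{i:04d}" for i in range(overrides.get("n_genes", 3000))]
    n_mod = overrides.pop("module_size", 60)
    assignment = {g: BACKGROUND for g in genes}
    for g in genes[:n_mod]:
        assignment[g] = AA_MODULE
    for g in genes[n_mod : 2 * n_mod]:
        assignment[g] = RP_MODULE
    defaults = dict(
        n_strains=n_strains,
        strain_growth_rates={"wt": wt_rates.tolist(), "evolved": ev_rates.tolist()},
        group_assignment=assignment,
        seed=seed,
    )
    defaults.update(overrides)
    return ExpressionSimParams(**defaults)


def _effect_log2(group: str, status: str, growth_rate: float, p: ExpressionSimParams) -> float:
    if group == AA_MODULE:
        if status == "wt":
            return p.aa_induction_intercept - p.aa_induction_slope * growth_rate
        return p.evolved_aa_residual
    if group == RP_MODULE:
        return p.rp_coupling * growth_rate
    return 0.0


def simulate_expression(
    params: ExpressionSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample count matrix plus design and truth record.

    Returns ``(counts, design, truth)`` where ``counts`` is genes x
    samples (integer), ``design`` has one row per sample
    (sample_id, strain, status, sugar, replicate) and ``truth`` records,
    per (strain, status, group), the injected xylulose/glucose log2
    effect, the expected log2 ratio after per-sample total-count
    normalization (which differs by the compositional term), the growth
    rate used, and per-strain growth-improvement folds.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    if p.group_assignment:
        genes = list(p.group_assignment)
        if len(genes) != p.n_genes:
            raise ValueError("group_assignment must cover exactly n_genes genes")
    else:
        genes = [f"g{i:04d}" for i in range(p.n_genes)]
    assignment = p.group_assignment or {g: BACKGROUND for g in genes}
    unknown = [g for g in assignment if g not in set(genes)]
    if unknown:
        raise ValueError(f"group_assignment references unknown genes: {unknown[:5]}")

    group_arr = np.array([assignment[g] for g in genes])
    baseline = rng.lognormal(p.baseline_log_mean, p.baseline_log_sd, size=p.n_genes)

    strains = [f"strain{i + 1:02d}" for i in range(p.n_strains)]
    design_rows = []
    mean_cols: dict[str, np.ndarray] = {}
    truth_rows = []
    for si, strain in enumerate(strains):
        for status in ("wt", "evolved"):
            g_rate = float(p.strain_growth_rates[status][si])
            effects = np.array([_effect_log2(grp, status, g_rate, p) for grp in _GROUPS])
            eff_per_gene = np.zeros(p.n_genes)
            for grp, eff in zip(_GROUPS, effects):
                eff_per_gene[group_arr == grp] = eff
            for sugar in ("glucose", "xylulose"):
                w = baseline * (2.0**eff_per_gene if sugar == "xylulose" else 1.0)
                mu = p.library_size * w / w.sum()
                for rep in range(1, p.n_replicates + 1):
                    sid = f"{strain}_{status}_{sugar}_r{rep}"
                    mean_cols[sid] = mu
                    design_rows.append(
                        {"sample_id": sid, "strain": strain, "status": status, "sugar": sugar, "replicate": rep}
                    )
            # compositional term: total xylulose weight vs glucose weight
            s_ratio = float((baseline * 2.0**eff_per_gene).sum() / baseline.sum())
            for grp, eff in zip(_GROUPS, effects):
                truth_rows.append(
                    {
                        "strain": strain,
                        "status": status,
                        "group": grp,
                        "growth_rate": g_rate,
                        "injected_log2": eff,
                        "expected_log2_cpm": eff - math.log2(s_ratio),
                        "log2_composition": math.log2(s_ratio),
                    }
                )

    mean_mat = np.column_stack([mean_cols[r["sample_id"]] for r in design_rows])
    if p.dispersion > 0:
        shape = 1.0 / p.dispersion
        lam = rng.gamma(shape, mean_mat * p.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean_mat)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=[r["sample_id"] for r in design_rows])
    design_df = pd.DataFrame(design_rows)
    truth_df = pd.DataFrame(truth_rows)

    # per-strain growth improvement and expected expression change on xylulose
    fold = {
        s: float(p.strain_growth_rates["evolved"][i]) / float(p.strain_growth_rates["wt"][i])
        for i, s in enumerate(strains)
    }
    truth_df["growth_fold"] = truth_df["strain"].map(fold)
    wt_part = truth_df[truth_df.status == "wt"].set_index(["strain", "group"])
    ev_part = truth_df[truth_df.status == "evolved"].set_index(["strain", "group"])
    change = (ev_part["expected_log2_cpm"] - wt_part["expected_log2_cpm"]).rename("expected_change_log2")
    truth_df = truth_df.merge(change.reset_index(), on=["strain", "group"], how="left")
    return counts_df, design_df, truth_df


def group_gmt_sets(params: ExpressionSimParams) -> dict[str, set[str]]:
    """Gene sets implied by the simulation's group assignment."""
    sets: dict[str, set[str]] = {AA_MODULE: set(), RP_MODULE: set(), BACKGROUND: set()}
    assignment = params.group_assignment
    if not assignment:
        return {BACKGROUND: {f"g{i:04d}" for i in range(params.n_genes)}}
    for gene, grp in assignment.items():
        sets[grp].add(gene)
    return {k: v for k, v in sets.items() if v}
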