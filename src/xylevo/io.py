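"""Readers and writers for the interchange formats, run configuration
and the end-to-end pipeline driver.

Formats (all plain text):

* plate-reader CSV — wide, first column ``time_h``, one column per well;
* sample sheets — TSV; growth: ``well, strain, status, replicate``,
  expression: ``sample_id, strain, status, sugar, replicate``;
* counts — TSV, gene IDs in the first column, samples in the header;
* gene sets — GMT (set name, description, tab-separated members);
* configuration — YAML; run manifest — JSON with sha256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation_analysis as aa
from . import expression_pipeline as ep
from . import synthetic_data as sd
from .growth_metrics import GrowthCurve, MetricsConfig, classify_improvement, compute_metrics, fold_change
from .reference_data import TWELVE_STRAIN_FOLDS

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_plate_csv",
    "write_plate_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "run_all",
]


# ---------------------------------------------------------------------------
# plate-reader CSV
# ---------------------------------------------------------------------------

def write_plate_csv(curves: list[GrowthCurve], path: str | Path) -> pd.DataFrame:
    """Write curves as a wide CSV; wells with shorter series leave blanks.

    Well names are ``strain_status_rN``. Returns the well sample sheet.
    """
    all_times = np.unique(np.concatenate([c.times for c in curves]))
    data = {"time_h": all_times}
    sheet = []
    for c in curves:
        well = f"{c.strain_id}_{c.status}_r{c.replicate}"
        col = np.full(all_times.shape, np.nan)
        col[np.searchsorted(all_times, c.times)] = c.ods
        data[well] = col
        sheet.append({"well": well, "strain": c.strain_id, "status": c.status, "replicate": c.replicate})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return pd.DataFrame(sheet)


def read_plate_csv(path: str | Path, sample_sheet: pd.DataFrame) -> list[GrowthCurve]:
    """Read a wide plate CSV into validated growth curves.

    The sample sheet maps well names to strain/status/replicate. Rows
    with non-monotone time, negative OD or unknown wells are reported
    with their offending values.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "time_h":
        raise ValueError(f"{path}: first column must be 'time_h', got {df.columns[0]!r}")
    times_all = df["time_h"].to_numpy(dtype=float)
    if not np.all(np.diff(times_all) > 0):
        bad = int(np.argmin(np.diff(times_all) > 0)) + 2  # +2: 1-based, header row
        raise ValueError(f"{path}: time_h not strictly increasing at data line {bad}")
    sheet = sample_sheet.set_index("well")
    unknown = [w for w in df.columns[1:] if w not in sheet.index]
    if unknown:
        raise ValueError(f"{path}: wells missing from sample sheet: {unknown}")
    curves = []
    for well in df.columns[1:]:
        ods = df[well].to_numpy(dtype=float)
        mask = ~np.isnan(ods)
        if (ods[mask] <= 0).any():
            raise ValueError(f"{path}: non-positive OD values in well {well}")
        row = sheet.loc[well]
        curves.append(
            GrowthCurve(
                strain_id=str(row["strain"]),
                status=str(row["status"]),
                replicate=int(row["replicate"]),
                times=times_all[mask],
                ods=ods[mask],
            )
        )
    return curves


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    ep.validate_counts(counts)
    return counts


def write_sample_sheet(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    ep.validate_design(design)
    return design


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets with validation.

    Duplicate set names are an error; duplicate members within a set are
    deduplicated with a warning; empty sets are rejected.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no members")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated",
                              stacklevel=2)
            sets[name] = unique
    return sets


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything an end-to-end run needs; round-trips through YAML.

    With ``simulate=True`` all inputs are generated; otherwise paths to
    a plate CSV + well sheet, counts TSV + sample sheet and a GMT file
    must be supplied.
    """

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    # simulation scale
    n_strains: int = 12
    n_growth_replicates: int = 1
    n_genes: int = 3000
    module_size: int = 60
    dispersion: float = 0.05
    library_size: float = 1e6
    # external inputs (used when simulate=False)
    plates_csv: str | None = None
    wells_tsv: str | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    gmt: str | None = None
    growth_folds_tsv: str | None = None
    # stage parameters
    smoothing_window: int = 5
    slope_window: int = 5
    saturation_fraction: float = 0.95
    pseudocount: float = 1.0
    changed_threshold: float = 1.0
    min_sign_fraction: float = 2.0 / 3.0
    permutations: int = 10_000
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            needed = {"plates_csv": self.plates_csv, "wells_tsv": self.wells_tsv,
                      "counts_tsv": self.counts_tsv, "samples_tsv": self.samples_tsv,
                      "gmt": self.gmt}
            missing = [k for k, v in needed.items() if not v]
            if missing:
                raise ValueError(f"simulate=False but inputs missing: {missing}")
        MetricsConfig(self.smoothing_window, self.slope_window, self.saturation_fraction)
        if self.pseudocount < 0 or self.permutations < 1:
            raise ValueError("pseudocount must be >= 0 and permutations >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write a checksummed manifest.

    Stages: (simulate) -> growth metrics -> fold changes & improvement
    classification -> CPM normalization -> replicate averaging ->
    xylulose/glucose ratios -> changed genes -> enrichment -> group
    summaries & per-gene profile -> expression-change vs growth
    correlation. Deterministic given the seed.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcfg = MetricsConfig(config.smoothing_window, config.slope_window, config.saturation_fraction)

    stage = "simulate"
    try:
        if config.simulate:
            folds = TWELVE_STRAIN_FOLDS if config.n_strains == 12 else None
            if folds is not None:
                targets = list(zip(folds["max_od_fold"], folds["time_to_max_od_fold"]))
            else:
                targets = [(1.5 + 0.1 * i, 1.0 - 0.02 * i) for i in range(config.n_strains)]
            wt_curves, ev_curves, _ = sd.simulate_strain_panel(
                config.n_strains,
                sd.default_wt_growth_params(config.n_strains),
                targets,
                seed=config.seed,
                n_replicates=config.n_growth_replicates,
                saturation_fraction=config.saturation_fraction,
            )
            curves = wt_curves + ev_curves
            wells = write_plate_csv(curves, out / "plates.csv")
            write_sample_sheet(wells, out / "wells.tsv")
            xp = sd.default_expression_params(
                n_strains=config.n_strains,
                seed=config.seed + 1,
                n_genes=config.n_genes,
                module_size=config.module_size,
                dispersion=config.dispersion,
                library_size=config.library_size,
            )
            counts, design, truth = sd.simulate_expression(xp)
            write_counts_tsv(counts, out / "counts.tsv")
            write_sample_sheet(design, out / "samples.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            gene_sets = sd.group_gmt_sets(xp)
            write_gmt(gene_sets, out / "groups.gmt")
        else:
            curves = read_plate_csv(config.plates_csv, read_sample_sheet_growth(config.wells_tsv))
            counts = read_counts_tsv(config.counts_tsv)
            design = read_sample_sheet(config.samples_tsv)
            gene_sets = read_gmt(config.gmt)

        stage = "growth_metrics"
        metrics_rows = []
        per_strain: dict[tuple[str, str], list] = {}
        for c in curves:
            m = compute_metrics(c, mcfg)
            metrics_rows.append({"strain_id": c.strain_id, "status": c.status,
                                 "replicate": c.replicate, **m.as_dict(),
                                 "degenerate": m.degenerate})
            per_strain.setdefault((c.strain_id, c.status), []).append(m)
        metrics_df = pd.DataFrame(metrics_rows)
        metrics_df.to_csv(out / "growth_metrics.tsv", sep="\t", index=False)

        stage = "fold_change"
        strains = sorted({k[0] for k in per_strain})
        fold_rows = []
        fold_records = []
        for s in strains:
            wt_mean = _mean_metrics(per_strain[(s, "wt")])
            ev_mean = _mean_metrics(per_strain[(s, "evolved")])
            rec = fold_change(ev_mean, wt_mean, strain_id=s)
            fold_records.append(rec)
            fold_rows.append({"strain_id": s, **rec.as_dict()})
        folds_df = pd.DataFrame(fold_rows)
        folds_df.to_csv(out / "fold_changes.tsv", sep="\t", index=False)

        labels, n_improved = classify_improvement(fold_records)
        pd.DataFrame(
            [{"strain_id": s, "label": labels[s]} for s in strains]
        ).to_csv(out / "improvement.tsv", sep="\t", index=False)
        logger.info("%d of %d strains improved", n_improved, len(strains))

        stage = "normalize"
        norm = ep.normalize_to_million(counts)
        write_counts_tsv(norm, out / "normalized_counts.tsv")

        stage = "ratios"
        averaged, avg_design = ep.average_replicates(norm, design)
        ratios = {st: ep.ratio_table(averaged, avg_design, st, config.pseudocount)
                  for st in ("wt", "evolved")}
        ratios["wt"].rename_axis("gene_id").to_csv(out / "ratios_wt.tsv", sep="\t")
        ratios["evolved"].rename_axis("gene_id").to_csv(out / "ratios_evolved.tsv", sep="\t")

        stage = "changed_genes"
        up, down, table = ep.identify_changed_genes(
            ratios["wt"], config.changed_threshold, config.min_sign_fraction
        )
        table.rename_axis("gene_id").to_csv(out / "changed_genes.tsv", sep="\t")

        stage = "enrichment"
        enrich = ep.enrichment_test(up | down, gene_sets, set(counts.index))
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "group_summary"
        summaries = []
        for name, members in gene_sets.items():
            summaries.extend(ep.group_summary(ratios, name, members))
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / "group_summaries.tsv", sep="\t", index=False
        )
        first_group = next(iter(gene_sets))
        profile = ep.per_gene_group_profile(averaged, avg_design, sorted(gene_sets[first_group]))
        profile.to_csv(out / "group_profile.tsv", sep="\t", index=False)

        stage = "correlation"
        growth_fold = {r.strain_id: r.effective_growth_rate for r in fold_records}
        corr_rows = []
        expr_strains = [s for s in design["strain"].unique() if s in growth_fold]
        for name, members in gene_sets.items():
            records = [
                aa.StrainChangeRecord(
                    s, name,
                    aa.expression_change(averaged, avg_design, members, s,
                                         pseudocount=config.pseudocount),
                    growth_fold[s],
                )
                for s in expr_strains
            ]
            if len(records) >= 3:
                res = aa.correlate_change_with_growth(records, config.permutations,
                                                      seed=config.seed + 2)
                corr_rows.append(dataclasses.asdict(res))
        pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "n_improved": n_improved,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".tsv", ".csv", ".gmt") and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_sample_sheet_growth(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = {"well", "strain", "status", "replicate"} - set(sheet.columns)
    if missing:
        raise ValueError(f"growth sample sheet missing columns: {sorted(missing)}")
    return sheet


def _mean_metrics(metric_sets):
    from .growth_metrics import METRIC_NAMES, GrowthMetricSet

    vals = {name: float(np.mean([getattr(m, name) for m in metric_sets])) for name in METRIC_NAMES}
    # keep the defining identity exact after averaging replicates
    vals["effective_growth_rate"] = vals["max_od"] / vals["time_to_max_od"]
    return GrowthMetricSet(**vals, degenerate=any(m.degenerate for m in metric_sets))
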