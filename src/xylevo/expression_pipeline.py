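"""Count normalization, xylulose/glucose ratios, changed-gene calling,
gene-group projection and enrichment.

Counts are held as a pandas DataFrame (genes as index, samples as
columns); the sample design is a DataFrame with one row per sample
(sample_id, strain, status, sugar, replicate). The analysis sequence is:

1. scale every sample to one million total counts (CPM);
2. average replicates per (strain, status, sugar);
3. per strain and status, log2 ratio of xylulose vs glucose expression;
4. call changed genes by a robust median-threshold + sign-consistency
   rule across strains;
5. project changed genes onto named gene groups with one-sided
   hypergeometric enrichment and Benjamini-Hochberg correction;
6. summarise per-group mean ratios (mean over genes per strain, then
   mean +/- SE over strains).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "validate_counts",
    "validate_design",
    "normalize_to_million",
    "average_replicates",
    "log_ratio_xyl_glu",
    "ratio_table",
    "identify_changed_genes",
    "enrichment_test",
    "group_summary",
    "per_gene_group_profile",
]

TARGET_TOTAL = 1e6
SUGARS = ("glucose", "xylulose")
STATUSES = ("wt", "evolved")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    status: str
    mean: float
    se: float
    n_genes: int
    n_strains: int
    single_strain: bool = False


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")


def validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "strain", "status", "sugar", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    keys = design[["strain", "status", "sugar", "replicate"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (strain, status, sugar, replicate) in design")
    bad_status = set(design["status"]) - set(STATUSES)
    bad_sugar = set(design["sugar"]) - set(SUGARS)
    if bad_status or bad_sugar:
        raise ValueError(f"unknown status/sugar labels: {bad_status | bad_sugar}")


def normalize_to_million(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its total equals 1e6 (CPM normalization)."""
    validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cannot normalize all-zero sample(s): {list(zero.index)}")
    return counts * (TARGET_TOTAL / totals)


def average_replicates(counts: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arithmetic mean across replicates per (strain, status, sugar).

    Returns the collapsed matrix (columns named strain_status_sugar) and
    the collapsed design without the replicate column.
    """
    validate_design(design)
    missing = set(design["sample_id"]) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)[:5]}")
    groups = design.groupby(["strain", "status", "sugar"], sort=False)["sample_id"].agg(list)
    if groups.map(len).min() == 0:  # pragma: no cover - groupby cannot emit empties
        raise ValueError("condition with zero replicates")
    cols = {}
    rows = []
    for (strain, status, sugar), sample_ids in groups.items():
        cid = f"{strain}_{status}_{sugar}"
        cols[cid] = counts[sample_ids].mean(axis=1)
        rows.append({"sample_id": cid, "strain": strain, "status": status, "sugar": sugar})
    return pd.DataFrame(cols, index=counts.index), pd.DataFrame(rows)


def _condition_column(design: pd.DataFrame, strain: str, status: str, sugar: str) -> str:
    sel = design[(design.strain == strain) & (design.status == status) & (design.sugar == sugar)]
    if sel.empty:
        raise ValueError(f"no sample for ({strain}, {status}, {sugar})")
    return sel["sample_id"].iloc[0]


def log_ratio_xyl_glu(
    averaged: pd.DataFrame,
    design: pd.DataFrame,
    strain: str,
    status: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((xylulose + pc) / (glucose + pc)) for one strain/status."""
    xyl = averaged[_condition_column(design, strain, status, "xylulose")]
    glu = averaged[_condition_column(design, strain, status, "glucose")]
    return np.log2((xyl + pseudocount) / (glu + pseudocount)).rename(f"{strain}_{status}")


def ratio_table(averaged: pd.DataFrame, design: pd.DataFrame, status: str, pseudocount: float = 1.0) -> pd.DataFrame:
    """Genes x strains table of xylulose/glucose log2 ratios for one status."""
    strains = design["strain"].unique()
    return pd.DataFrame(
        {s: log_ratio_xyl_glu(averaged, design, s, status, pseudocount) for s in strains}
    )


def identify_changed_genes(
    ratios: pd.DataFrame,
    threshold: float = 1.0,
    min_sign_fraction: float = 2.0 / 3.0,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Call changed genes across strains.

    A gene is changed when |median ratio across strains| >= ``threshold``
    (log2) and the median's sign holds in at least ``min_sign_fraction``
    of strains. Returns (up set, down set, per-gene table with direction
    and median ratio).
    """
    med = ratios.median(axis=1)
    n = ratios.shape[1]
    sign_frac = np.where(
        med >= 0,
        (ratios > 0).sum(axis=1) / n,
        (ratios < 0).sum(axis=1) / n,
    )
    changed = (med.abs() >= threshold) & (sign_frac >= min_sign_fraction)
    direction = np.where(~changed, "unchanged", np.where(med > 0, "up", "down"))
    table = pd.DataFrame({"median_log2_ratio": med, "direction": direction}, index=ratios.index)
    up = set(table.index[table.direction == "up"])
    down = set(table.index[table.direction == "down"])
    return up, down, table


def enrichment_test(
    changed: set[str],
    groups: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``changed`` in each group.

    p is the upper-tail probability of an overlap at least as large as
    observed when drawing |changed| genes from the universe; q is the
    Benjamini-Hochberg adjustment across the tested groups.
    """
    if not universe:
        raise ValueError("empty universe")
    changed_in = changed & universe
    if changed - universe:
        logger.warning("%d changed genes outside universe dropped", len(changed - universe))
    rows = []
    for name, members in groups.items():
        present = members & universe
        dropped = len(members) - len(present)
        if dropped:
            logger.warning("group %s: %d members absent from universe", name, dropped)
        if not present:
            warnings.warn(f"group {name!r} has no genes in universe; skipped", stacklevel=2)
            continue
        overlap = len(changed_in & present)
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|group|, N=|changed|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(present), len(changed_in)))
        rows.append(
            {"group": name, "overlap": overlap, "group_size": len(present),
             "changed_size": len(changed_in), "universe_size": len(universe), "p": min(p, 1.0)}
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result


def group_summary(
    ratios_by_status: dict[str, pd.DataFrame],
    group_name: str,
    group_genes: set[str],
) -> list[GroupSummary]:
    """Mean +/- SE of a group's xylulose/glucose log2 ratio per status.

    Per strain the group mean over genes is taken first, then the mean
    and standard error (SD / sqrt(n_strains), ddof=1) over strains. With
    a single strain the SE is undefined and reported as 0 with a flag.
    """
    out = []
    for status, ratios in ratios_by_status.items():
        present = [g for g in ratios.index if g in group_genes]
        if not present:
            warnings.warn(f"group {group_name!r} has no genes in the matrix; skipped", stacklevel=2)
            continue
        per_strain = ratios.loc[present].mean(axis=0)
        n_strains = len(per_strain)
        if n_strains == 1:
            out.append(GroupSummary(group_name, status, float(per_strain.iloc[0]), 0.0,
                                    len(present), 1, single_strain=True))
        else:
            se = float(per_strain.std(ddof=1) / math.sqrt(n_strains))
            out.append(GroupSummary(group_name, status, float(per_strain.mean()), se,
                                    len(present), n_strains))
    return out


def per_gene_group_profile(
    averaged: pd.DataFrame,
    design: pd.DataFrame,
    group_genes: list[str],
    sugar: str = "xylulose",
) -> pd.DataFrame:
    """Per-gene (wt, evolved) expression pair, normalized per gene.

    For each group gene: mean over strains of its expression on
    ``sugar`` before and after evolution; both values are then divided
    by the gene's total reads over all samples of the matrix, so each
    gene is on its own relative scale. Genes with zero total are
    excluded with a warning; input gene order is preserved.
    """
    validate_counts(averaged)
    rows = []
    for status in STATUSES:
        cols = design[(design.status == status) & (design.sugar == sugar)]["sample_id"]
        if cols.empty:
            raise ValueError(f"matrix lacks {status} samples on {sugar}")
        rows.append(averaged[list(cols)].mean(axis=1))
    wt_mean, ev_mean = rows
    totals = averaged.sum(axis=1)
    out = []
    for gene in group_genes:
        if gene not in averaged.index:
            logger.warning("gene %s absent from matrix; dropped from profile", gene)
            continue
        if totals[gene] == 0:
            warnings.warn(f"gene {gene!r} has zero total reads; excluded", stacklevel=2)
            continue
        out.append(
            {"gene_id": gene,
             "wt_value": float(wt_mean[gene] / totals[gene]),
             "evolved_value": float(ev_mean[gene] / totals[gene])}
        )
    return pd.DataFrame(out)
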