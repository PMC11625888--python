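"""Relative gene expression by the 2^-ddCt method.

Per sample, replicate Ct values (threshold cycles) are averaged within each
gene; dCt = mean Ct(target) - mean Ct(reference gene); ddCt subtracts the
mean dCt of the calibrator group; fold change = 2^(-ddCt), which assumes an
amplification efficiency of exactly 2 per cycle.

The calibrator is a group (not a single sample): ddCt is taken relative to
the calibrator group's mean dCt, so the geometric mean of fold changes over
calibrator samples is exactly 1.  When a ``timepoint`` column is present,
calibration is stratified: each timepoint uses its own calibrator mean.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

CT_COLUMNS = ["sample_id", "group", "timepoint", "gene", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema and finiteness checks on a long-format Ct table."""
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"Ct table missing columns: {sorted(missing)}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
        raise InvalidInputError("Ct values must be finite and > 0")
    out = table.copy()
    out["ct"] = ct
    return out


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per sample x gene, with the contributing replicate count.

    Every sample must carry every gene that appears in the table (a sample
    missing its reference gene would silently drop downstream otherwise).
    """
    table = validate_ct_table(table)
    keys = ["sample_id", "group", "gene"]
    if "timepoint" in table.columns:
        keys = ["sample_id", "group", "timepoint", "gene"]
    out = (
        table.groupby(keys, sort=True)["ct"]
        .agg(mean_ct="mean", n_replicates="size")
        .reset_index()
    )
    genes = set(table["gene"])
    per_sample = out.groupby("sample_id")["gene"].agg(set)
    incomplete = per_sample[per_sample != genes]
    if len(incomplete):
        raise InvalidInputError(
            f"samples missing genes: {sorted(incomplete.index.tolist())}"
        )
    return out


def relative_expression(
    mean_cts: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Per-sample dCt, ddCt and fold change for one target gene.

    ``mean_cts`` is the output of :func:`average_replicates`.  Calibration is
    per timepoint when a ``timepoint`` column is present.
    """
    for gene, role in ((target_gene, "target"), (reference_gene, "reference")):
        if gene not in set(mean_cts["gene"]):
            raise InvalidInputError(f"{role} gene {gene!r} not in table")
    if calibrator_group not in set(mean_cts["group"]):
        raise InvalidInputError(f"calibrator group {calibrator_group!r} not in table")

    has_tp = "timepoint" in mean_cts.columns
    idx = ["sample_id", "group"] + (["timepoint"] if has_tp else [])
    wide = mean_cts.pivot_table(
        index=idx, columns="gene", values="mean_ct", aggfunc="mean"
    ).reset_index()
    if wide[reference_gene].isna().any() or wide[target_gene].isna().any():
        raise InvalidInputError("reference or target Ct missing for some samples")
    wide["delta_ct"] = wide[target_gene] - wide[reference_gene]

    strata = [wide] if not has_tp else [g for _, g in wide.groupby("timepoint", sort=True)]
    parts = []
    for stratum in strata:
        cal = stratum.loc[stratum["group"] == calibrator_group, "delta_ct"]
        if cal.empty:
            raise InvalidInputError(
                f"calibrator group {calibrator_group!r} empty in a timepoint stratum"
            )
        s = stratum.copy()
        s["delta_delta_ct"] = s["delta_ct"] - cal.mean()
        parts.append(s)
    out = pd.concat(parts, ignore_index=True)
    out["fold_change"] = np.exp2(-out["delta_delta_ct"])
    out["gene"] = target_gene
    cols = idx + ["gene", "delta_ct", "delta_delta_ct", "fold_change"]
    return out[cols]


def expression_table(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    target_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate-average then compute fold changes for every target gene."""
    mean_cts = average_replicates(table)
    genes = target_genes or sorted(set(mean_cts["gene"]) - {reference_gene})
    parts = [
        relative_expression(mean_cts, g, reference_gene, calibrator_group)
        for g in genes
    ]
    return pd.concat(parts, ignore_index=True)


def read_ct_table(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path))


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, index=False)
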