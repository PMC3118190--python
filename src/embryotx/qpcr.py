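"""ddCt relative quantification for TaqMan-array and RT-PCR validation.

Ct values in long format (stage, replicate, assay, ct) are normalized
against the mean Ct of the control assays within each stage/replicate
(dCt), referenced to a baseline stage (ddCt = dCt_stage - dCt_reference,
paired within replicate), and converted to relative quantities
RQ = 2^(-ddCt); the fold change at the reference stage is 1 by
construction.  Replicates are aggregated as mean +/- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtTable", "RelativeQuant", "delta_ct", "ddct_rq", "read_ct_tsv"]

CT_COLUMNS = ["stage", "replicate", "assay", "ct"]


@dataclass
class CtTable:
    """Long-format Ct measurements with named control assays.

    ``orientation`` controls the dCt subtraction direction:
    ``target_minus_control`` (the convention that makes RQ = 2^-ddCt read as
    fold change, the default) or ``control_minus_target``.
    """

    data: pd.DataFrame
    control_assays: list[str]
    reference_stage: str
    orientation: str = "target_minus_control"

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        if len(self.control_assays) < 1:
            raise ValueError("at least one control assay is required")
        if self.orientation not in ("target_minus_control", "control_minus_target"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        ct = self.data["ct"]
        if not (np.isfinite(ct).all() and (ct > 0).all()):
            raise ValueError("Ct values must be finite and positive")
        assays = set(self.data["assay"])
        absent = set(self.control_assays) - assays
        if absent:
            raise ValueError(f"control assay(s) never measured: {sorted(absent)}")
        if self.reference_stage not in set(self.data["stage"]):
            raise ValueError(f"reference stage {self.reference_stage!r} absent from table")

    @property
    def target_assays(self) -> list[str]:
        return sorted(set(self.data["assay"]) - set(self.control_assays))


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per stage/replicate/assay dCt against the mean control Ct.

    Fails naming the stage/replicate when a control Ct is missing there.
    """
    controls = table.data[table.data["assay"].isin(table.control_assays)]
    ctrl_mean = controls.groupby(["stage", "replicate"])["ct"].agg(["mean", "size"])
    n_controls = len(table.control_assays)
    for (stage, rep), row in ctrl_mean.iterrows():
        if row["size"] < n_controls:
            raise ValueError(f"missing control Ct for stage {stage!r} replicate {rep!r}")
    targets = table.data[~table.data["assay"].isin(table.control_assays)].copy()
    merged = targets.merge(
        ctrl_mean["mean"].rename("ctrl_ct"), left_on=["stage", "replicate"], right_index=True, how="left"
    )
    if merged["ctrl_ct"].isna().any():
        bad = merged.loc[merged["ctrl_ct"].isna(), ["stage", "replicate"]].iloc[0]
        raise ValueError(
            f"missing control Ct for stage {bad['stage']!r} replicate {bad['replicate']!r}"
        )
    if table.orientation == "target_minus_control":
        merged["dct"] = merged["ct"] - merged["ctrl_ct"]
    else:
        merged["dct"] = merged["ctrl_ct"] - merged["ct"]
    return merged[["stage", "replicate", "assay", "dct"]]


@dataclass
class RelativeQuant:
    """Per stage/assay ddCt, RQ and fold change with replicate mean +/- SE."""

    table: pd.DataFrame  # stage, assay, dct, ddct, rq, rq_se, fold_change
    reference_stage: str

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ddct_rq(dct: pd.DataFrame, reference_stage: str) -> RelativeQuant:
    """ddCt, RQ = 2^(-ddCt) and reference-anchored fold change.

    ddCt subtracts the same replicate's dCt at the reference stage (paired
    within replicate); RQ is computed per replicate and aggregated as mean
    +/- SE over replicates.  Fold change equals mean RQ, and is exactly 1 at
    the reference stage.
    """
    if reference_stage not in set(dct["stage"]):
        raise ValueError(f"reference stage {reference_stage!r} absent")
    ref = (
        dct[dct["stage"] == reference_stage]
        .set_index(["replicate", "assay"])["dct"]
        .rename("dct_ref")
    )
    merged = dct.merge(ref, left_on=["replicate", "assay"], right_index=True, how="left")
    if merged["dct_ref"].isna().any():
        bad = merged.loc[merged["dct_ref"].isna()].iloc[0]
        raise ValueError(
            f"assay {bad['assay']!r} replicate {bad['replicate']!r} lacks a reference-stage dCt"
        )
    merged["ddct"] = merged["dct"] - merged["dct_ref"]
    merged["rq"] = 2.0 ** (-merged["ddct"])
    agg = (
        merged.groupby(["stage", "assay"], sort=True)
        .agg(
            dct=("dct", "mean"),
            ddct=("ddct", "mean"),
            rq=("rq", "mean"),
            rq_se=("rq", lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0),
            n_replicates=("rq", "size"),
        )
        .reset_index()
    )
    agg["fold_change"] = agg["rq"]
    return RelativeQuant(table=agg, reference_stage=reference_stage)


def read_ct_tsv(
    path: str,
    control_assays: list[str],
    reference_stage: str,
    orientation: str = "target_minus_control",
) -> CtTable:
    """Read a long-format Ct TSV (stage, replicate, assay, ct)."""
    df = pd.read_csv(path, sep="\t", dtype={"stage": str, "assay": str})
    return CtTable(
        data=df,
        control_assays=list(control_assays),
        reference_stage=reference_stage,
        orientation=orientation,
    )
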