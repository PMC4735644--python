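"""Relative qPCR quantification by the ddCt (2^-ddCt) method.

Each sample's target-gene Ct is normalized to its reference-gene Ct
(dCt = Ct_target - Ct_reference, removing per-sample loading offsets),
referenced to the control group's mean dCt (ddCt), and converted to a fold
change 2^-ddCt. Technical replicates of a sample are averaged at the Ct
level first; group results are the arithmetic mean +/- s.e.m. of the
per-sample folds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FoldChangeResult", "delta_delta_ct"]


@dataclass
class FoldChangeResult:
    """Fold changes per (group, gene) plus the per-sample detail table.

    ``summary`` columns: group, gene, fold_mean, fold_sem, n.
    ``per_sample`` columns: sample_id, group, gene, dct, ddct, fold.
    """

    summary: pd.DataFrame
    per_sample: pd.DataFrame
    reference_gene: str
    control_group: str

    def fold(self, group: str, gene: str) -> float:
        row = self.summary[(self.summary.group == group) & (self.summary.gene == gene)]
        if row.empty:
            raise KeyError((group, gene))
        return float(row.fold_mean.iloc[0])


def delta_delta_ct(table: pd.DataFrame, reference_gene: str,
                   control_group: str) -> FoldChangeResult:
    """Compute 2^-ddCt fold changes from a long-format Ct table.

    ``table`` needs columns (sample_id, group, gene, ct). Samples missing a
    reference-gene Ct are excluded with a warning; an empty control group
    is an error.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = table.copy()
    # technical replicates: average Ct per (sample, gene)
    df = (df.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean())

    ref = df[df.gene == reference_gene].set_index("sample_id")["ct"]
    missing = sorted(set(df.sample_id) - set(ref.index))
    if missing:
        warnings.warn(f"samples without reference-gene Ct excluded: {missing}",
                      stacklevel=2)
        df = df[~df.sample_id.isin(missing)]
    if df[df.group == control_group].empty:
        raise ValueError(f"control group {control_group!r} is empty")

    targets = df[df.gene != reference_gene].copy()
    targets["dct"] = targets.ct.to_numpy() - ref.loc[targets.sample_id].to_numpy()
    control_mean_dct = (targets[targets.group == control_group]
                        .groupby("gene")["dct"].mean())
    targets["ddct"] = targets.dct - control_mean_dct.loc[targets.gene].to_numpy()
    targets["fold"] = 2.0 ** (-targets.ddct)

    rows = []
    for (group, gene), sub in targets.groupby(["group", "gene"], sort=False):
        folds = sub.fold.to_numpy()
        rows.append({
            "group": group, "gene": gene,
            "fold_mean": folds.mean(),
            "fold_sem": folds.std(ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else np.nan,
            "n": len(folds),
        })
    summary = pd.DataFrame(rows)
    per_sample = targets[["sample_id", "group", "gene", "dct", "ddct", "fold"]]
    return FoldChangeResult(summary, per_sample.reset_index(drop=True),
                            reference_gene, control_group)
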