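"""Comparative-Ct (delta-delta-Ct) quantification for RT-qPCR validation.

Fold-changes are computed independently against each housekeeping gene and
then averaged: for housekeeper h, ``dCt = Ct_target - Ct_h`` per condition,
``ddCt = dCt_condition - dCt_reference`` and ``fc_h = 2**(-ddCt)``. Technical
replicates are averaged on the Ct scale before any delta is taken. The
per-housekeeper fold-changes are combined with the arithmetic mean by
default (averaging the normalized expression values themselves); the
geometric mean — equivalent to averaging on the ddCt scale — is available
behind ``average="geometric"``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, ValidationError

DEFAULT_HOUSEKEEPERS = ("RPLP0", "GAPDH", "B2M")


def comparative_ct(
    table: pd.DataFrame,
    targets: Sequence[str],
    housekeepers: Sequence[str] = DEFAULT_HOUSEKEEPERS,
    reference_condition: str = "VEHICLE",
    *,
    average: str = "arithmetic",
) -> pd.DataFrame:
    """Comparative-Ct fold-changes for each target gene and condition.

    Parameters
    ----------
    table : DataFrame
        Long-format Ct table with columns sample_id, condition, gene, ct,
        replicate.
    targets, housekeepers : sequences of gene names
        Every sample must provide Ct values for all housekeepers.
    reference_condition : str
        The condition fold-changes are expressed against (fold-change 1 for
        the reference itself by construction).
    average : {"arithmetic", "geometric"}
        How per-housekeeper fold-changes are combined into ``mean_fc``.

    Returns
    -------
    DataFrame with one row per (gene, condition): per-housekeeper
    fold-change columns ``fc_<housekeeper>``, ``mean_fc`` and
    ``log2_fc = log2(mean_fc)``.
    """
    if average not in ("arithmetic", "geometric"):
        raise ValidationError(f"average must be 'arithmetic' or 'geometric', got {average!r}")
    required = {"sample_id", "condition", "gene", "ct", "replicate"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValidationError(f"Ct table lacks required column(s): {sorted(missing_cols)}")
    t = table.copy()
    t["condition"] = t["condition"].astype(str).str.strip().str.upper()
    reference_condition = str(reference_condition).strip().upper()
    if reference_condition not in set(t["condition"]):
        raise ValidationError(f"reference condition {reference_condition!r} absent from Ct table")

    genes_present = set(t["gene"])
    for g in list(targets) + list(housekeepers):
        if g not in genes_present:
            raise ValidationError(f"gene {g!r} absent from Ct table")
    for sample, sub in t.groupby("sample_id"):
        for h in housekeepers:
            if h not in set(sub["gene"]):
                raise ValidationError(
                    f"sample {sample!r} lacks a Ct value for housekeeping gene {h!r}"
                )

    # technical replicates -> per (sample, gene) Ct, then per (condition, gene)
    per_sample = t.groupby(["sample_id", "condition", "gene"], as_index=False)["ct"].mean()
    ct = per_sample.groupby(["condition", "gene"])["ct"].mean()

    conditions = [c for c in CONDITIONS if c in set(t["condition"])]
    rows = []
    for gene in targets:
        for cond in conditions:
            fcs = {}
            for h in housekeepers:
                dct = ct[(cond, gene)] - ct[(cond, h)]
                dct_ref = ct[(reference_condition, gene)] - ct[(reference_condition, h)]
                fcs[h] = float(2.0 ** (-(dct - dct_ref)))
            vals = np.array(list(fcs.values()))
            mean_fc = float(vals.mean()) if average == "arithmetic" else float(
                np.exp(np.log(vals).mean())
            )
            row = {"gene": gene, "condition": cond}
            row.update({f"fc_{h}": fcs[h] for h in housekeepers})
            row["mean_fc"] = mean_fc
            row["log2_fc"] = float(np.log2(mean_fc))
            rows.append(row)
    return pd.DataFrame(rows)
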