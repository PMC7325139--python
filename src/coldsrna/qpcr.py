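"""Stem-loop qRT-PCR relative quantification by the delta-delta-Ct method.

Relative expression = 2^(-ddCt) with ddCt = (Ct_target - Ct_ref)_treated
- (Ct_target - Ct_ref)_control, technical replicates averaged on the Ct
scale, and the untreated control therefore equal to 1 by construction.
Amplification efficiency is fixed at 2 (plain ddCt); the SD over
technical replicates is propagated to the relative-expression scale by
first-order (delta-method) propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

LN2 = np.log(2.0)


@dataclass(frozen=True)
class QpcrRecord:
    assay: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    relative_expression: float
    sd: float


def ddct(
    assay: str,
    ct_target_treated: Sequence[float],
    ct_ref_treated: Sequence[float],
    ct_target_control: Sequence[float],
    ct_ref_control: Sequence[float],
) -> QpcrRecord:
    """Relative expression of one assay from technical-replicate Ct values."""
    arrays = {
        "ct_target_treated": np.asarray(ct_target_treated, dtype=float),
        "ct_ref_treated": np.asarray(ct_ref_treated, dtype=float),
        "ct_target_control": np.asarray(ct_target_control, dtype=float),
        "ct_ref_control": np.asarray(ct_ref_control, dtype=float),
    }
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"{name}: at least one replicate required")
        if not np.isfinite(arr).all():
            raise ValueError(f"{name}: Ct values must be finite")

    d_treated = arrays["ct_target_treated"].mean() - arrays["ct_ref_treated"].mean()
    d_control = arrays["ct_target_control"].mean() - arrays["ct_ref_control"].mean()
    ddct_value = d_treated - d_control
    rel = float(2.0 ** (-ddct_value))

    # first-order propagation: Var(ddCt) = sum of Ct SEM^2;
    # d(2^-x)/dx = -ln2 * 2^-x
    var = sum(
        (arr.std(ddof=1) ** 2 / arr.size) if arr.size > 1 else 0.0
        for arr in arrays.values()
    )
    sd = float(LN2 * rel * np.sqrt(var))
    return QpcrRecord(
        assay=assay,
        delta_ct_treated=float(d_treated),
        delta_ct_control=float(d_control),
        delta_delta_ct=float(ddct_value),
        relative_expression=rel,
        sd=sd,
    )


def ddct_table(records: pd.DataFrame) -> pd.DataFrame:
    """Run ddCt per assay on a tidy Ct table.

    ``records`` columns: (assay, condition, replicate, Ct_target, Ct_ref)
    with condition in {control, treated} (any non-control label counts as
    treated).
    """
    rows = []
    for assay, grp in records.groupby("assay", sort=True):
        control = grp[grp["condition"] == "control"]
        treated = grp[grp["condition"] != "control"]
        if control.empty or treated.empty:
            raise ValueError(f"assay {assay}: both control and treated Cts required")
        rec = ddct(
            assay,
            treated["Ct_target"].to_list(),
            treated["Ct_ref"].to_list(),
            control["Ct_target"].to_list(),
            control["Ct_ref"].to_list(),
        )
        rows.append({
            "assay": rec.assay,
            "delta_delta_ct": rec.delta_delta_ct,
            "relative_expression": rec.relative_expression,
            "sd": rec.sd,
        })
    return pd.DataFrame(rows)
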