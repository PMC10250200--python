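"""Specific growth rates from paired concentration measurements.

SGR is expressed in population doublings per day between two census points.
The default form is log2(N_t1 / N_t0) / (t1 - t0): it is zero at no growth
and invariant to concentration units. A published variant using the log of
the concentration difference, log2(N_t1 - N_t0) / (t1 - t0), is retained
behind ``mode="as_printed"`` for auditability -- note loudly that this form
DEPENDS ON THE CONCENTRATION UNITS and is undefined without net growth.
Relative SGR divides each record's SGR by the strain's mean SGR across all
environments, so per-strain mean RelSGR is identically 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sgr", "rel_sgr", "add_growth_columns"]


def sgr(N_t0, N_t1, t0, t1, mode: str = "ratio") -> float:
    """Specific growth rate (doublings per day) between two censuses."""
    if mode not in ("ratio", "as_printed"):
        raise ValueError(f"unknown SGR mode: {mode!r}")
    N_t0 = np.asarray(N_t0, dtype=float)
    N_t1 = np.asarray(N_t1, dtype=float)
    dt = np.asarray(t1, dtype=float) - np.asarray(t0, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("t1 must be greater than t0")
    if mode == "ratio":
        if np.any(N_t0 <= 0) or np.any(N_t1 <= 0):
            raise ValueError("ratio mode requires positive concentrations")
        out = np.log2(N_t1 / N_t0) / dt
    else:
        diff = N_t1 - N_t0
        if np.any(diff <= 0):
            raise ValueError(
                "as_printed mode requires N_t1 - N_t0 > 0 (log of a difference)"
            )
        out = np.log2(diff) / dt
    return float(out) if out.ndim == 0 else out


def rel_sgr(records: pd.DataFrame, strain_col: str = "strain",
            sgr_col: str = "sgr") -> pd.DataFrame:
    """Append relative SGR: each record's SGR over its strain's mean SGR."""
    if records[sgr_col].isna().any():
        raise ValueError("SGR column contains missing values")
    means = records.groupby(strain_col)[sgr_col].transform("mean")
    if (means == 0).any():
        bad = sorted(records.loc[means == 0, strain_col].unique())
        raise ZeroDivisionError(f"strain mean SGR is zero for: {bad}")
    out = records.copy()
    out["rel_sgr"] = records[sgr_col] / means
    return out


def add_growth_columns(
    table: pd.DataFrame,
    n0_col: str = "N_t0",
    n1_col: str = "N_t1",
    t0_col: str = "t0",
    t1_col: str = "t1",
    strain_col: str = "strain",
    mode: str = "ratio",
) -> pd.DataFrame:
    """Compute sgr and rel_sgr columns for an observation table."""
    out = table.copy()
    out["sgr"] = sgr(
        table[n0_col].to_numpy(), table[n1_col].to_numpy(),
        table[t0_col].to_numpy(), table[t1_col].to_numpy(), mode=mode,
    )
    return rel_sgr(out, strain_col=strain_col)
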