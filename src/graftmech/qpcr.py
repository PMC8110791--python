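"""Relative qPCR quantification: quality filtering and the 2^−ΔΔCt pipeline.

Ct tables carry one row per (sample, gene) reaction with technical
replicate Ct columns (``ct_rep1``, ``ct_rep2``, ...).  Rows are excluded
when the melting curve failed, when the technical replicates differ by
more than 0.5 Ct, or when the no-template control (blanco) amplifies too
close to the signal.  Expression is normalized to a housekeeping gene
(ΔCt, default GAPDH) and to the control condition (ΔΔCt, default the low
shear stress group), and reported as fold change 2^−ΔΔCt.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["filter_ct", "ddct", "replicate_columns"]

_REP_RE = re.compile(r"^ct_rep\d+$")


def replicate_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if _REP_RE.match(c)]
    if not cols:
        raise ValueError("no technical-replicate columns (ct_rep1, ct_rep2, ...)")
    return cols


def filter_ct(
    table: pd.DataFrame,
    max_replicate_spread: float = 0.5,
    blanco_margin: float = 3.0,
) -> pd.DataFrame:
    """Apply the datapoint-exclusion rules; returns the table with
    ``excluded`` and ``exclusion_reason`` columns.

    Rules (a row is excluded on the first failing rule, checked in order):

    1. ``melt-curve`` — ``melt_curve_ok`` is False;
    2. ``replicate-spread`` — max pairwise technical-replicate difference
       exceeds ``max_replicate_spread`` (0.5 Ct);
    3. ``blanco`` — the blanco Ct is less than ``blanco_margin`` cycles
       above the replicate-mean Ct (default 3 cycles).

    Filtering is total (never raises on content) and idempotent.
    """
    out = table.copy()
    reps = replicate_columns(out)
    vals = out[reps].to_numpy(dtype=float)
    spread = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
    mean_ct = np.nanmean(vals, axis=1)

    reason = np.full(len(out), "", dtype=object)
    if "melt_curve_ok" in out.columns:
        bad_melt = ~out["melt_curve_ok"].fillna(True).astype(bool).to_numpy()
        reason[bad_melt & (reason == "")] = "melt-curve"
    bad_spread = spread > max_replicate_spread
    reason[bad_spread & (reason == "")] = "replicate-spread"
    if "blanco_ct" in out.columns:
        blanco = out["blanco_ct"].to_numpy(dtype=float)
        bad_blanco = np.isfinite(blanco) & (blanco - mean_ct < blanco_margin)
        reason[bad_blanco & (reason == "")] = "blanco"

    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    return out


def ddct(
    table: pd.DataFrame,
    housekeeping: str = "GAPDH",
    control_group: str = "LSS",
    *,
    control_center: str = "mean",
) -> pd.DataFrame:
    """2^−ΔΔCt fold changes relative to the control group.

    Per sample, ΔCt = replicate-mean Ct of the gene minus that of the
    housekeeping gene; per gene, ΔΔCt = ΔCt − center of the control
    group's ΔCt (``control_center``: 'mean' or 'median').  Rows already
    flagged ``excluded`` are carried through unevaluated; samples whose
    housekeeping reaction is missing or excluded have all their genes
    excluded with reason ``no-housekeeping``.
    """
    if control_center not in ("mean", "median"):
        raise ValueError("control_center must be 'mean' or 'median'")
    if "excluded" not in table.columns:
        table = filter_ct(table)
    reps = replicate_columns(table)
    work = table.copy()
    work["ct_mean"] = work[reps].mean(axis=1)

    hk = work[(work["gene"] == housekeeping) & ~work["excluded"]]
    hk_ct = hk.set_index("sample_id")["ct_mean"]
    genes = work[work["gene"] != housekeeping].copy()
    has_hk = genes["sample_id"].isin(hk_ct.index)
    newly = ~has_hk & ~genes["excluded"]
    genes.loc[newly, "excluded"] = True
    genes.loc[newly, "exclusion_reason"] = "no-housekeeping"

    genes["delta_ct"] = genes["ct_mean"] - genes["sample_id"].map(hk_ct)
    ok = ~genes["excluded"]
    ctrl = genes[ok & (genes["group"] == control_group)]
    if ctrl.empty:
        raise ValueError(f"no usable control-group ({control_group!r}) rows")
    center = getattr(ctrl.groupby("gene")["delta_ct"], control_center)()
    genes["ddct"] = genes["delta_ct"] - genes["gene"].map(center)
    genes["fold"] = np.where(ok & genes["ddct"].notna(), 2.0 ** (-genes["ddct"]), np.nan)
    cols = ["sample_id", "group", "gene", "delta_ct", "ddct", "fold", "excluded", "exclusion_reason"]
    return genes[cols].reset_index(drop=True)
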