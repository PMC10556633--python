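"""Cross-dataset comparisons: phase delay, efficiency ratios, uORF dose.

Combines rhythm calls and abundance series from different assays:

* circular phase delay between ribosome-binding and protein-abundance
  rhythms (signed, in (-12, +12] hours for a 24-h period);
* protein production efficiency (protein copies/cell per ribosome RPKM)
  and translation efficiency (ribosome RPKM per RNA RPKM) per timepoint;
* stratification of CDS occupancy by uORF count, with a monotone-trend
  statistic (Kendall tau of k vs RPKM, normal-approximation p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def circular_delay(phase_from: float, phase_to: float, period: float = 24.0) -> float:
    """Signed circular difference phase_to - phase_from in (-period/2, period/2]."""
    d = (phase_to - phase_from) % period
    if d > period / 2:
        d -= period
    return float(d)


def phase_delay(
    ribo_results: pd.DataFrame, protein_results: pd.DataFrame
) -> pd.DataFrame:
    """Phase delay between ribosome-binding and protein rhythms.

    Both inputs are rhythm tables (feature_id, period, phase, ...) from
    the same period grid.  Features present in only one table get a
    missing delay.  Positive delay means the protein peaks after
    ribosome binding.
    """
    r = ribo_results.set_index("feature_id")
    p = protein_results.set_index("feature_id")
    shared = r.index.intersection(p.index)
    if len(shared):
        mismatched = r.loc[shared, "period"] != p.loc[shared, "period"]
        if mismatched.any():
            raise ValueError(
                "period mismatch between rhythm tables for "
                f"{list(shared[mismatched])[:5]}"
            )
    rows = []
    for fid in r.index.union(p.index):
        phase_r = float(r.loc[fid, "phase"]) if fid in r.index else float("nan")
        phase_p = float(p.loc[fid, "phase"]) if fid in p.index else float("nan")
        if fid in shared and not (np.isnan(phase_r) or np.isnan(phase_p)):
            delay = circular_delay(phase_r, phase_p, float(r.loc[fid, "period"]))
        else:
            delay = float("nan")
        rows.append(
            {
                "feature_id": fid,
                "phase_ribo": phase_r,
                "phase_protein": phase_p,
                "delay": delay,
            }
        )
    return pd.DataFrame(rows)


def _mean_by_time(tc: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Replicate-average a (feature_id, t, value) long table."""
    return tc.groupby(["feature_id", "t"], as_index=False)[value_col].mean()


def efficiency_ratios(
    protein_tc: pd.DataFrame,
    ribo_tc: pd.DataFrame,
    rna_tc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-timepoint efficiency ratios and 24-h means.

    Inputs are long tables with columns (feature_id, t, value); replicate
    measurements are averaged per timepoint first.  Returns
    ``(per_timepoint, means)`` where per_timepoint carries ``ppe``
    (protein copies/cell per ribosome RPKM) and, when an RNA table is
    supplied, ``te`` (ribosome RPKM per RNA RPKM).  Ratios with a zero
    denominator are missing, never infinite.
    """
    prot = _mean_by_time(protein_tc, "value").rename(columns={"value": "protein"})
    ribo = _mean_by_time(ribo_tc, "value").rename(columns={"value": "ribo"})
    merged = prot.merge(ribo, on=["feature_id", "t"], how="inner")
    if merged.empty:
        raise ValueError("no shared (feature, timepoint) pairs between inputs")
    n_union = len(prot.merge(ribo, on=["feature_id", "t"], how="outer"))
    if n_union > len(merged):
        import logging

        logging.getLogger(__name__).warning(
            "time grids only partially overlap; using the intersection"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ppe"] = np.where(
            merged["ribo"] > 0, merged["protein"] / merged["ribo"], np.nan
        )
    if rna_tc is not None:
        rna = _mean_by_time(rna_tc, "value").rename(columns={"value": "rna"})
        merged = merged.merge(rna, on=["feature_id", "t"], how="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            merged["te"] = np.where(
                merged["rna"] > 0, merged["ribo"] / merged["rna"], np.nan
            )
    means = merged.groupby("feature_id", as_index=False).agg(
        mean_protein=("protein", "mean"), mean_ribo=("ribo", "mean")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        means["mean_ppe"] = np.where(
            means["mean_ribo"] > 0, means["mean_protein"] / means["mean_ribo"], np.nan
        )
    return merged, means


def uorf_dose_stratification(
    feature_table: pd.DataFrame,
    cds_rpkm: pd.Series | pd.DataFrame,
    k_max: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """CDS occupancy stratified by uORF count.

    ``feature_table`` is the per-transcript uORF feature table (with
    ``n_uorfs``); ``cds_rpkm`` maps transcript_id to mean CDS RPKM.
    Transcripts with k >= ``k_max`` are pooled into a top bin.  Returns a
    per-bin summary (n, median and quartiles of CDS RPKM) plus a
    monotone-trend statistic: Kendall tau between k and RPKM with its
    normal-approximation p (one test across transcripts, not bins).
    """
    if isinstance(cds_rpkm, pd.DataFrame):
        cds_rpkm = cds_rpkm.set_index("transcript_id").iloc[:, 0]
    df = feature_table[["transcript_id", "n_uorfs"]].copy()
    df["rpkm"] = df["transcript_id"].map(cds_rpkm)
    df = df.dropna(subset=["rpkm"])
    df["k_bin"] = np.minimum(df["n_uorfs"], k_max)
    summary = (
        df.groupby("k_bin")["rpkm"]
        .agg(n="size", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    if df["k_bin"].nunique() < 2:
        trend = {"tau": float("nan"), "p": float("nan")}
    else:
        tau, p = stats.kendalltau(df["k_bin"], df["rpkm"])
        trend = {"tau": float(tau), "p": float(p)}
    return summary, trend


def linfit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r, p).

    p is the two-sided test of slope != 0.  Requires >= 3 finite pairs
    and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("linfit requires at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
    )
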