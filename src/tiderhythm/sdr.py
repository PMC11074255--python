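"""Differential rhythmicity score (S_DR) and transcriptome dominance ratio.

For each gene tested in the circatidal window in two conditions (control and
tidal-entrainment treatment) the change in periodicity is

    delta_P = log(p_control) - log(p_treatment)            (natural log)

and the change in amplitude is

    delta_R = log2(amp_treatment / amp_control),

with amplitude defined as max TPM - min TPM within a condition (distinct
from the peak/trough *ratio* used by the expression filter).  Both deltas
are standardized to Z-scores across the included genes and combined as

    S_DR = (Z_P + Z_R) / sqrt(2).

An empirical Gaussian null is fitted to all S_DR values by maximum
likelihood; each gene's upper-tail probability under that fit is its p-value
for increased circatidal rhythmicity, adjusted by Benjamini–Hochberg.

Dominance of one rhythm over the other across the transcriptome is the
per-gene log(p_circadian / p_circatidal): positive means the circatidal
rhythm dominates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "sdr_from_components",
    "compute_sdr_table",
    "gaussian_null_pvalues",
    "dominance_log_ratio",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sdr_from_components(
    gene_ids,
    p_control,
    p_treatment,
    amp_control,
    amp_treatment,
) -> pd.DataFrame:
    """S_DR table from per-gene circatidal p-values and amplitudes.

    Genes with zero amplitude in either condition are excluded (delta_R is
    undefined) with a logged reason.  Z-scores use the sample SD (ddof=1)
    across the included genes.
    """
    df = pd.DataFrame({
        "gene_id": np.asarray(gene_ids),
        "p_control": np.asarray(p_control, dtype=float),
        "p_treatment": np.asarray(p_treatment, dtype=float),
        "amp_control": np.asarray(amp_control, dtype=float),
        "amp_treatment": np.asarray(amp_treatment, dtype=float),
    })
    zero_amp = (df["amp_control"] <= 0) | (df["amp_treatment"] <= 0)
    if zero_amp.any():
        logger.info("excluding %d gene(s) with zero amplitude: %s",
                    zero_amp.sum(), list(df.loc[zero_amp, "gene_id"][:10]))
        df = df.loc[~zero_amp].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 genes with positive amplitudes")
    pc = np.clip(df["p_control"].to_numpy(), P_FLOOR, 1.0)
    pt = np.clip(df["p_treatment"].to_numpy(), P_FLOOR, 1.0)
    df["delta_P"] = np.log(pc) - np.log(pt)
    df["delta_R"] = np.log2(df["amp_treatment"] / df["amp_control"])
    for src, dst in (("delta_P", "Z_P"), ("delta_R", "Z_R")):
        sd = df[src].std(ddof=1)
        if sd == 0:
            raise ValueError(f"{src} has zero variance across genes")
        df[dst] = (df[src] - df[src].mean()) / sd
    df["S_DR"] = (df["Z_P"] + df["Z_R"]) / np.sqrt(2.0)
    return df


def compute_sdr_table(
    ctrl_results: pd.DataFrame,
    trt_results: pd.DataFrame,
    ctrl_matrix,
    trt_matrix,
    include: str = "either",
) -> pd.DataFrame:
    """S_DR per gene from circatidal rhythm results and TPM matrices.

    ``include`` controls the scope rule on the circatidal p-values:
    "either" (default) requires p < 1 in at least one condition — genes
    with p = 1 everywhere carry no rhythm evidence and are excluded, while
    genes that gain rhythmicity under entrainment (p = 1 in control only)
    stay in scope; "both" requires p < 1 in both conditions.
    """
    ctrl = ctrl_results[ctrl_results["window"] == "circatidal"]
    trt = trt_results[trt_results["window"] == "circatidal"]
    merged = ctrl[["gene_id", "p_value"]].merge(
        trt[["gene_id", "p_value"]], on="gene_id", suffixes=("_ctrl", "_trt"))
    if include == "both":
        scope = (merged["p_value_ctrl"] < 1.0) & (merged["p_value_trt"] < 1.0)
    elif include == "either":
        scope = (merged["p_value_ctrl"] < 1.0) | (merged["p_value_trt"] < 1.0)
    else:
        raise ValueError("include must be 'both' or 'either'")
    merged = merged.loc[scope]

    amp_c = _amplitudes(ctrl_matrix).reindex(merged["gene_id"])
    amp_t = _amplitudes(trt_matrix).reindex(merged["gene_id"])
    if amp_c.isna().any() or amp_t.isna().any():
        missing = merged["gene_id"][amp_c.isna().to_numpy()
                                    | amp_t.isna().to_numpy()].iloc[0]
        raise ValueError(f"gene {missing!r} missing from a TPM matrix")
    return sdr_from_components(
        merged["gene_id"].to_numpy(),
        merged["p_value_ctrl"].to_numpy(),
        merged["p_value_trt"].to_numpy(),
        amp_c.to_numpy(),
        amp_t.to_numpy(),
    )


def _amplitudes(matrix) -> pd.Series:
    tpm = matrix.tpm
    return tpm.max(axis=1) - tpm.min(axis=1)


def gaussian_null_pvalues(records: pd.DataFrame, tail: str = "upper") -> pd.DataFrame:
    """p-values from a Gaussian fitted to the empirical S_DR distribution.

    Maximum-likelihood moments (mean, SD with ddof=0) define the null;
    ``tail="upper"`` scores increased rhythmicity in the treatment (the
    default), ``"lower"`` decreased.  Adds ``p_sdr`` and BH-adjusted ``fdr``
    columns.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records for a stable Gaussian fit")
    s = records["S_DR"].to_numpy(dtype=float)
    mu, sigma = s.mean(), s.std(ddof=0)
    if sigma == 0:
        raise ValueError("S_DR has zero variance; Gaussian null undefined")
    z = (s - mu) / sigma
    if tail == "upper":
        p = norm.sf(z)
    elif tail == "lower":
        p = norm.cdf(z)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    out = records.copy()
    out["p_sdr"] = np.clip(p, P_FLOOR, 1.0)
    out["fdr"] = bh_adjust(out["p_sdr"].to_numpy())
    return out


def dominance_log_ratio(
    circadian_results: pd.DataFrame,
    circatidal_results: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene log(p_circadian / p_circatidal) and its group summary.

    Positive values mean the circatidal rhythm dominates.  Genes missing a
    result in either window are skipped with a log message.  The summary is
    the mean and SEM of the log-ratio across genes.
    """
    cir = circadian_results[circadian_results["window"] == "circadian"]
    tid = circatidal_results[circatidal_results["window"] == "circatidal"]
    merged = cir[["gene_id", "p_value"]].merge(
        tid[["gene_id", "p_value"]], on="gene_id",
        suffixes=("_circadian", "_circatidal"), how="outer", indicator=True)
    skipped = merged["_merge"] != "both"
    if skipped.any():
        logger.info("dominance: skipping %d gene(s) missing a window result",
                    skipped.sum())
        merged = merged.loc[~skipped]
    if merged.empty:
        raise ValueError("no genes with results in both windows")
    pc = np.clip(merged["p_value_circadian"].to_numpy(dtype=float), P_FLOOR, 1.0)
    pt = np.clip(merged["p_value_circatidal"].to_numpy(dtype=float), P_FLOOR, 1.0)
    table = pd.DataFrame({
        "gene_id": merged["gene_id"],
        "log_ratio": np.log(pc) - np.log(pt),
    })
    lr = table["log_ratio"].to_numpy()
    summary = {
        "mean": float(lr.mean()),
        "sem": float(lr.std(ddof=1) / np.sqrt(len(lr))) if len(lr) > 1 else float("nan"),
        "n": int(len(lr)),
    }
    return table, summary
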