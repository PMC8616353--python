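"""Quantification quality control, normalization, imputation, and scaling.

The quantification table carries one row per (sample, replicate, glycan)
peak with three quality metrics: a retention-time match flag, the isotope
dot product (idotp, spectral agreement of the observed isotope envelope
with the theoretical one), and the chromatographic signal-to-noise ratio.
A peak is quantifiable iff the retention time matches, idotp >= 0.85 and
S/N >= 6 — both thresholds inclusive.

Fractional abundance normalizes each glycan's area to the summed area of
all glycans of the same class (N or O) in that sample, x100, so N- and
O-glycomes are each closed to 100%. Missing values are imputed by a small
constant pseudo-abundance (0.01%) before multivariate statistics; observed
values are never touched and fractions are not renormalized afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QUANT_COLUMNS",
    "qc_filter",
    "to_fractional",
    "impute_missing",
    "replicate_rsd",
    "zscore_features",
    "pivot_areas",
]

QUANT_COLUMNS = ["sample", "replicate", "glycan", "area", "rt_match", "idotp", "snr"]

IDOTP_MIN_DEFAULT = 0.85
SNR_MIN_DEFAULT = 6.0
IMPUTE_VALUE_DEFAULT = 0.01


def qc_filter(
    records: pd.DataFrame,
    idotp_min: float = IDOTP_MIN_DEFAULT,
    snr_min: float = SNR_MIN_DEFAULT,
    require_rt: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep quantifiable peaks; log each rejection with the failed criteria.

    Returns ``(kept, rejection_log)``; the log has the rejected rows plus a
    ``reason`` column listing every violated criterion (comma-separated).
    The filter is idempotent: re-filtering the kept set changes nothing.
    """
    missing = set(QUANT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    rt_ok = records["rt_match"].astype(bool) | (not require_rt)
    idotp_ok = records["idotp"].astype(float) >= idotp_min
    snr_ok = records["snr"].astype(float) >= snr_min
    keep = rt_ok & idotp_ok & snr_ok

    rejected = records.loc[~keep].copy()
    reasons = []
    for i in rejected.index:
        r = []
        if not rt_ok.loc[i]:
            r.append("rt")
        if not idotp_ok.loc[i]:
            r.append("idotp")
        if not snr_ok.loc[i]:
            r.append("snr")
        reasons.append(",".join(r))
    rejected["reason"] = reasons
    return records.loc[keep].copy(), rejected


def pivot_areas(records: pd.DataFrame, average_replicates: bool = True) -> pd.DataFrame:
    """Long quant table -> (sample x glycan) area matrix.

    With ``average_replicates`` the mean area over a sample's replicates is
    taken; otherwise rows are (sample, replicate) pairs. Glycans absent
    from a sample become NaN (missing), to be imputed downstream.
    """
    df = records.copy()
    index = "sample" if average_replicates else ["sample", "replicate"]
    return df.pivot_table(index=index, columns="glycan", values="area", aggfunc="mean")


def glycan_class_of(columns: pd.Index) -> pd.Series:
    """Class of each class-qualified glycan column id (``N:...`` / ``O:...``)."""
    cls = pd.Series([str(c).split(":", 1)[0] for c in columns], index=columns)
    bad = cls[~cls.isin(["N", "O"])]
    if len(bad):
        raise ValueError(f"columns without N:/O: class prefix: {list(bad.index)}")
    return cls


def to_fractional(areas: pd.DataFrame, glycan_classes: pd.Series | None = None) -> pd.DataFrame:
    """Peak areas -> fractional abundances in percent, per glycan class.

    N- and O-glycans are normalized independently: each value becomes
    area / (summed area of observed same-class glycans in that sample) x100.
    Missing cells stay missing. A sample with zero total area in a class
    that has observed columns is an error (fractions would be undefined).
    """
    if glycan_classes is None:
        glycan_classes = glycan_class_of(areas.columns)
    out = areas.astype(float).copy()
    for cls in pd.unique(glycan_classes):
        cols = areas.columns[glycan_classes == cls]
        block = out[cols]
        totals = block.sum(axis=1, skipna=True)
        observed = block.notna().any(axis=1)
        bad = list(block.index[observed & (totals <= 0)])
        if bad:
            raise ValueError(f"zero total {cls}-glycan area for sample(s) {bad}")
        out[cols] = block.div(totals, axis=0) * 100.0
    return out


def impute_missing(matrix: pd.DataFrame, value: float = IMPUTE_VALUE_DEFAULT) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing cells by a constant pseudo-abundance (default 0.01%).

    Returns the completed matrix and a boolean mask of imputed cells.
    Observed cells pass through bit-for-bit.
    """
    mask = matrix.isna()
    return matrix.fillna(value), mask


def replicate_rsd(
    fractional: pd.DataFrame,
    min_mean: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-glycan relative standard deviation across replicates.

    ``fractional`` is a replicate x glycan matrix of fractional abundances
    (one biological sample, >=2 technical or biological replicates). RSD is
    the n-1 standard deviation over the mean, x100. The headline average is
    taken over glycans whose mean abundance is >= ``min_mean`` percent
    (low-abundance glycans have noisy, inflated RSDs).
    """
    if len(fractional) < 2:
        raise ValueError(f"replicate RSD needs >=2 replicates, got {len(fractional)}")
    mean = fractional.mean(axis=0)
    sd = fractional.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rsd = (sd / mean * 100.0).where(mean > 0)
    table = pd.DataFrame({"mean": mean, "sd": sd, "rsd": rsd})
    eligible = table.loc[table["mean"] >= min_mean, "rsd"].dropna()
    average = float(eligible.mean()) if len(eligible) else float("nan")
    return table, average


def zscore_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Independent z-transformation of each feature (column) across samples.

    Constant features cannot be scaled; their z-scores are set to 0 with a
    warning rather than raising, so downstream heatmaps keep the column.
    """
    if len(matrix) < 2:
        raise ValueError("z-scoring needs >=2 samples")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(f"constant features z-scored to 0: {list(matrix.columns[constant])}")
    sd_safe = sd.mask(constant, 1.0)
    z = (matrix - mean) / sd_safe
    z.loc[:, constant] = 0.0
    return z
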