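"""Relative qPCR quantification (2^-ddCt) and diurnal expression summaries.

The study design samples ZT0/6/12/18 over one light/dark cycle, so summaries
stay deliberately simple: peak/nadir are the argmax/argmin of per-ZT
replicate means, amplitude is max - min of those means (no cosinor fit is
attempted from four points; an optional cosinor diagnostic is provided),
and reciprocal-cross pairs are compared per ZT with a two-sided Welch
t-test annotated at the 0.05/0.01/0.001 star tiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

__all__ = [
    "ddct",
    "diurnal_summary",
    "reciprocal_timepoint_tests",
    "cosinor_fit",
    "ZT_POINTS",
]

ZT_POINTS = (0, 6, 12, 18)
STAR_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt subtracts the
    calibrator sample's dCt; the fold change is 2^-ddCt.  Normalizing a
    sample against itself gives exactly 1.
    """
    dct_sample = ct_target - ct_reference
    dct_cal = ct_target_calibrator - ct_reference_calibrator
    return float(2.0 ** -(dct_sample - dct_cal))


def _series_frame(series: pd.DataFrame) -> pd.DataFrame:
    for col in ("zt", "value"):
        if col not in series.columns:
            raise ValidationError(f"diurnal series needs a {col!r} column")
    if (series["value"] <= 0).any():
        raise ValidationError("relative expression values must be positive")
    return series


def diurnal_summary(series: pd.DataFrame) -> dict:
    """Peak/nadir/amplitude of one (gene, group) diurnal series.

    ``series`` is long-form with columns ``zt`` and ``value`` (replicates as
    repeated rows per ZT).  Peak and nadir are the ZTs of the largest and
    smallest per-ZT mean; amplitude = max - min of the means;
    relative_amplitude = amplitude / overall mean (scale-invariant).  Ties
    resolve toward the earlier ZT and set ``tied``.
    """
    series = _series_frame(series)
    means = series.groupby("zt")["value"].mean().sort_index()
    if means.empty:
        raise ValidationError("empty diurnal series")
    vmax, vmin = means.max(), means.min()
    peak_zt = int(means.index[np.argmax(means.to_numpy())])
    nadir_zt = int(means.index[np.argmin(means.to_numpy())])
    tied = bool(
        (means.to_numpy() == vmax).sum() > 1 or (means.to_numpy() == vmin).sum() > 1
    )
    return {
        "peak_zt": peak_zt,
        "nadir_zt": nadir_zt,
        "amplitude": float(vmax - vmin),
        "relative_amplitude": float((vmax - vmin) / means.mean()),
        "tied": tied,
    }


def _stars(p: float) -> str:
    for cut, mark in STAR_TIERS:
        if p < cut:
            return mark
    return "ns"


def reciprocal_timepoint_tests(
    series_a: pd.DataFrame, series_b: pd.DataFrame, test: str = "welch"
) -> pd.DataFrame:
    """Per-ZT comparison of two diurnal series (e.g. a reciprocal pair).

    Two-sided Welch t-test on replicate values at each shared ZT
    (``test='ranksum'`` switches to Mann-Whitney).  A side with fewer than
    2 replicates at a ZT yields a missing P annotated ``ns``.  Identical
    replicate sets give P = 1.

    Returns a DataFrame with columns zt, p, star, n_a, n_b.
    """
    series_a = _series_frame(series_a)
    series_b = _series_frame(series_b)
    zts = sorted(set(series_a["zt"]) & set(series_b["zt"]))
    rows = []
    for zt in zts:
        va = series_a.loc[series_a["zt"] == zt, "value"].to_numpy(dtype=float)
        vb = series_b.loc[series_b["zt"] == zt, "value"].to_numpy(dtype=float)
        if va.size < 2 or vb.size < 2:
            rows.append({"zt": zt, "p": np.nan, "star": "ns", "n_a": va.size, "n_b": vb.size})
            continue
        if np.array_equal(np.sort(va), np.sort(vb)) and np.ptp(va) == 0 and np.ptp(vb) == 0:
            p = 1.0
        elif test == "welch":
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            if np.isnan(p):  # zero variance on both sides with equal means
                p = 1.0 if va.mean() == vb.mean() else 0.0
        elif test == "ranksum":
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"zt": zt, "p": p, "star": _stars(p), "n_a": va.size, "n_b": vb.size})
    return pd.DataFrame(rows, columns=["zt", "p", "star", "n_a", "n_b"])


def cosinor_fit(series: pd.DataFrame, period: float = 24.0) -> dict:
    """Optional cosinor diagnostic: least-squares fit of
    mesor + A*cos(2*pi*(t - phase)/period) to the replicate values.

    With only four distinct timepoints this is a descriptive fit, not a
    rhythmicity test.  Returns mesor, amplitude and acrophase (hours).
    """
    series = _series_frame(series)
    t = series["zt"].to_numpy(dtype=float)
    y = series["value"].to_numpy(dtype=float)
    w = 2.0 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float((np.arctan2(gamma, beta) / w) % period)
    return {"mesor": float(mesor), "amplitude": amplitude, "acrophase": acrophase}
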