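"""Differential expression and the factorial POE/ploidy/hybridity summary.

The test is a negative-binomial Wald test with per-gene method-of-moments
dispersion: normalized group means are compared on the log scale, with the
delta-method variance (1/mu + dispersion)/n per group.  A gene is called
differentially expressed when |log2 fold change| >= 1 and the raw Wald
P-value < 0.05 (both configurable); no multiple-testing correction is
applied to DE P-values, matching the raw P threshold convention.

The factorial summary counts DEGs for the standard contrasts of a
reciprocal-ploidy design — parent-of-origin [3x(p) vs 3x(m)], ploidy (3x vs
2x parents and 3x vs 4x parents), hybridity at each ploidy level (hybrids
vs parental selfs), and optionally parental genetic distance — and ranks
the factors by DEG count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CrossDesign, ExpressionMatrix, GroupClass, ValidationError

__all__ = [
    "normalize_library",
    "test_differential",
    "standard_contrasts",
    "factorial_deg_summary",
    "DEFAULT_LFC_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
]

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.05
DISPERSION_FLOOR = 1e-8

#: contrast label -> factor class used for the factorial ranking
CONTRAST_FACTOR = {
    "poe": "poe",
    "ploidy2": "ploidy",
    "ploidy4": "ploidy",
    "hyb2": "hybridity",
    "hyb4": "hybridity",
    "distance": "distance",
}


def normalize_library(
    matrix: ExpressionMatrix, method: str = "median-of-ratios"
) -> tuple[ExpressionMatrix, pd.Series]:
    """Library-size normalization.

    ``median-of-ratios`` (default): per-sample size factor = median over
    genes of count / geometric-mean count, computed on genes expressed in
    every sample.  ``totals``: size factor proportional to the column sum.
    Factors are scaled to geometric mean 1; normalized value = count/factor.
    """
    counts = matrix.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = matrix.sample_ids[int(np.argmin(totals))]
        raise ValidationError(f"sample {bad!r} has zero total counts")
    if method == "totals":
        factors = totals
    elif method == "median-of-ratios":
        expressed = (counts > 0).all(axis=1)
        if not expressed.any():
            raise ValidationError("no gene is expressed in every sample; cannot take ratios")
        sub = counts[expressed]
        geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / geo, axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    normalized = ExpressionMatrix(
        values=matrix.values / factors, normalized=True
    )
    return normalized, pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def _mom_dispersion(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion pooled across both groups.

    For NB, Var = mu + disp*mu^2, so disp = (s^2 - mu)/mu^2 within a group;
    the two group estimates are pooled by degrees of freedom and floored.
    """
    est, dfs = [], []
    for grp in (a, b):
        n = grp.shape[1]
        if n < 2:
            continue
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        est.append(d * (n - 1))
        dfs.append(n - 1)
    disp = sum(est) / sum(dfs)
    return np.clip(disp, DISPERSION_FLOOR, None)


def test_differential(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    contrast: str = "B_vs_A",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """NB Wald test per gene between two normalized replicate sets.

    ``counts_a``/``counts_b`` are gene x replicate frames of normalized
    counts sharing the same gene index.  log2FC is B over A; when either
    group mean is zero a pseudocount of 1 is added to both means for the
    fold change.  With fewer than 2 replicates on either side the P-value
    is missing and nothing is called significant.

    Returns a DataFrame with columns gene_id, contrast, log2fc, p, significant.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValidationError("count frames must share the same gene index")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    zero = (mean_a == 0) | (mean_b == 0)
    log2fc = np.where(
        zero,
        np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0),
        np.log2(np.where(mean_b > 0, mean_b, 1.0)) - np.log2(np.where(mean_a > 0, mean_a, 1.0)),
    )

    if na < 2 or nb < 2:
        p = np.full(a.shape[0], np.nan)
        significant = np.zeros(a.shape[0], dtype=bool)
    else:
        disp = _mom_dispersion(a, b)
        # delta-method variance of log group mean; pseudocount guards zero means
        var_log = (1.0 / np.maximum(mean_a, 1.0) + disp) / na + (
            1.0 / np.maximum(mean_b, 1.0) + disp
        ) / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.log(np.maximum(mean_b, 1e-300)) - np.log(np.maximum(mean_a, 1e-300))) / np.sqrt(var_log)
        z = np.where(zero & (mean_a == mean_b), 0.0, z)
        p = 2.0 * stats.norm.sf(np.abs(z))
        significant = (np.abs(log2fc) >= lfc_threshold) & (p < p_threshold)

    return pd.DataFrame(
        {
            "gene_id": counts_a.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "significant": significant,
        }
    ).reset_index(drop=True)


def standard_contrasts(
    design: CrossDesign, distance_map: dict | None = None
) -> dict[str, tuple[list[str], list[str]]]:
    """Sample lists (side A, side B) for the factorial contrasts.

    * ``poe`` — maternal-excess triploids (A) vs paternal-excess (B)
    * ``ploidy2``/``ploidy4`` — diploid/tetraploid parental selfs (A) vs all triploids (B)
    * ``hyb2``/``hyb4`` — parental selfs (A) vs same-ploidy hybrids (B)
    * ``distance`` — low-relatedness (A) vs high-relatedness (B) triploids,
      from a user-supplied group -> {"high", "low"} map.

    Contrasts whose sides have no samples are omitted.
    """
    contrasts: dict[str, tuple[list[str], list[str]]] = {}
    tri = design.samples_of_class(GroupClass.TRIPLOID_MATERNAL, GroupClass.TRIPLOID_PATERNAL)
    m3 = design.samples_of_class(GroupClass.TRIPLOID_MATERNAL)
    p3 = design.samples_of_class(GroupClass.TRIPLOID_PATERNAL)
    selfs2 = [s for g in design.parental_self_groups(2) for s in design.samples_of(g)]
    selfs4 = [s for g in design.parental_self_groups(4) for s in design.samples_of(g)]
    hyb2 = design.samples_of_class(GroupClass.HYBRID_2X)
    hyb4 = design.samples_of_class(GroupClass.HYBRID_4X)
    if m3 and p3:
        contrasts["poe"] = (m3, p3)
    if tri and selfs2:
        contrasts["ploidy2"] = (selfs2, tri)
    if tri and selfs4:
        contrasts["ploidy4"] = (selfs4, tri)
    if hyb2 and selfs2:
        contrasts["hyb2"] = (selfs2, hyb2)
    if hyb4 and selfs4:
        contrasts["hyb4"] = (selfs4, hyb4)
    if distance_map:
        high = [s for g, v in distance_map.items() if v == "high" for s in design.samples_of(g)]
        low = [s for g, v in distance_map.items() if v == "low" for s in design.samples_of(g)]
        if high and low:
            contrasts["distance"] = (low, high)
    return contrasts


@dataclass
class FactorialSummary:
    """Per-contrast DEG counts plus a ranking of factors by DEG count."""

    table: pd.DataFrame          # contrast, factor, n_up, n_down, n_total
    ranking: list[str]           # factor classes, most DEGs first
    score_mode: str              # "max" or "sum" across contrasts within a factor


def factorial_deg_summary(results: pd.DataFrame, score_mode: str = "max") -> FactorialSummary:
    """Summarize DE results over the factorial contrasts.

    ``results`` concatenates :func:`test_differential` outputs over the
    contrasts of :func:`standard_contrasts`.  Per contrast, significant
    genes are split into up (log2FC > 0, side B over side A) and down.
    Factors are ranked by their score across member contrasts (``max`` by
    default, mirroring per-comparison DEG counts; ``sum`` pools them), ties
    broken alphabetically.
    """
    if score_mode not in ("max", "sum"):
        raise ValueError(f"score_mode must be 'max' or 'sum', got {score_mode!r}")
    rows = []
    for contrast, sub in results.groupby("contrast", sort=True):
        sig = sub[sub["significant"]]
        n_up = int((sig["log2fc"] > 0).sum())
        n_down = int((sig["log2fc"] < 0).sum())
        rows.append(
            {
                "contrast": contrast,
                "factor": CONTRAST_FACTOR.get(contrast, contrast),
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
            }
        )
    table = pd.DataFrame(rows, columns=["contrast", "factor", "n_up", "n_down", "n_total"])
    if table.empty:
        return FactorialSummary(table=table, ranking=[], score_mode=score_mode)
    agg = getattr(table.groupby("factor")["n_total"], score_mode)()
    ranking = list(agg.sort_index().sort_values(ascending=False, kind="stable").index)
    return FactorialSummary(table=table, ranking=ranking, score_mode=score_mode)


def run_contrasts(
    matrix: ExpressionMatrix,
    design: CrossDesign,
    distance_map: dict | None = None,
    normalization: str = "median-of-ratios",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Normalize once and run every standard contrast; concatenated results."""
    matrix.check_design(design)
    normalized, _ = normalize_library(matrix, method=normalization)
    out = []
    for name, (side_a, side_b) in standard_contrasts(design, distance_map).items():
        out.append(
            test_differential(
                normalized.values[side_a],
                normalized.values[side_b],
                contrast=name,
                lfc_threshold=lfc_threshold,
                p_threshold=p_threshold,
            )
        )
    if not out:
        raise ValidationError("design admits no factorial contrast")
    return pd.concat(out, ignore_index=True)
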