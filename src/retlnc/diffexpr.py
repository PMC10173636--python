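"""Negative-binomial differential expression for mutant-vs-WT count matrices.

The test follows the standard NB machinery for RNA-seq counts: median-of-
ratios size factors, gene-wise method-of-moments dispersion estimates shrunk
toward an a/mu + b mean-dispersion trend, and a Wald test of equal group
means against a standard-normal reference. The trend shrinkage is what
keeps the test calibrated at small replicate numbers: it removes most of
the sampling noise of the gene-wise dispersion estimate, after which the
Wald statistic is close to standard normal (see docs/methods.md). A gene is called differentially expressed when
|log2 fold change| >= 1 and the raw p-value is <= 0.05; a BH-adjusted
column is emitted for information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError


def normalize_median_of_ratios(counts: pd.DataFrame) -> Tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The per-sample factor is the median over all-positive genes of
    count / geometric-mean(count across samples); normalized counts are
    count / factor.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValidationError("need >= 2 samples to normalize")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; supply a pseudo-reference"
        )
    logs = np.log(arr[positive])
    loggeo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - loggeo, axis=0))
    size_factors = pd.Series(sf, index=counts.columns)
    normalized = counts / size_factors
    return size_factors, normalized


def _fit_dispersion_trend(base_mean: np.ndarray, disp_raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of dispersion = a/mu + b over informative genes.

    Raw (unclipped) moment estimates keep the fit unbiased; the fitted trend
    is floored at a small positive value.
    """
    ok = base_mean > 0
    x = 1.0 / base_mean[ok]
    y = disp_raw[ok]
    if x.size >= 2 and np.ptp(x) > 0:
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = coef
    else:
        a, b = 0.0, float(np.median(y)) if y.size else 0.0
    trend = np.zeros_like(base_mean)
    trend[ok] = a / base_mean[ok] + b
    return np.maximum(trend, 1e-8)


@dataclass
class NBTestConfig:
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    pseudocount: float = 0.5
    trend_weight: float = 0.8  # shrinkage toward the mean-dispersion trend


def nb_test(
    counts_wt: pd.DataFrame,
    counts_mut: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    trend_weight: float = 0.8,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test of mutant vs WT counts, per gene.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc`` (mutant over WT), ``p_value``, ``p_bh``, ``is_de`` and
    ``direction`` (up/down/none). All-zero genes get p = 1 and log2fc = 0.
    """
    if not counts_wt.index.equals(counts_mut.index):
        raise ValidationError("WT and mutant matrices must share the gene index")
    n1, n2 = counts_wt.shape[1], counts_mut.shape[1]
    if n1 < 1 or n2 < 1:
        raise ValidationError("each group needs >= 1 replicate")
    if n1 < 2 or n2 < 2:
        warnings.warn("fewer than 2 replicates in a group; dispersion is pooled", stacklevel=2)
    combined = pd.concat([counts_wt, counts_mut], axis=1)
    sf, norm = normalize_median_of_ratios(combined)
    q = norm.to_numpy(dtype=float)
    q1, q2 = q[:, :n1], q[:, n1:]
    inv_sf = (1.0 / sf.to_numpy())
    m1 = q1.mean(axis=1)
    m2 = q2.mean(axis=1)
    base_mean = q.mean(axis=1)

    # method-of-moments dispersion on normalized counts, pooled within groups
    df_within = max(n1 + n2 - 2, 1)
    ss = ((q1 - m1[:, None]) ** 2).sum(axis=1) + ((q2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_within
    mean_inv_sf = inv_sf.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_raw = (s2 - base_mean * mean_inv_sf) / base_mean**2
    disp_raw = np.where(base_mean > 0, disp_raw, 0.0)
    trend = _fit_dispersion_trend(base_mean, disp_raw)
    disp = np.maximum((1 - trend_weight) * disp_raw + trend_weight * trend, 1e-8)

    ps = pseudocount
    log2fc = np.log2((m2 + ps) / (m1 + ps))
    var_m1 = (base_mean * inv_sf[:n1].mean() + disp * base_mean**2) / n1
    var_m2 = (base_mean * inv_sf[n1:].mean() + disp * base_mean**2) / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_ln = np.sqrt(var_m1 / (m1 + ps) ** 2 + var_m2 / (m2 + ps) ** 2)
        wald = np.log((m2 + ps) / (m1 + ps)) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))
    zero = base_mean == 0
    p = np.where(zero | ~np.isfinite(p), 1.0, p)
    log2fc = np.where(zero, 0.0, log2fc)
    p_bh = stats.false_discovery_control(p, method="bh")
    is_de = (np.abs(log2fc) >= lfc_threshold) & (p <= alpha)
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p,
            "p_bh": p_bh,
            "is_de": is_de,
            "direction": direction,
        },
        index=combined.index,
    )


def de_intergenic(de_results: pd.DataFrame, classes: Dict[str, str]) -> pd.DataFrame:
    """Restrict a DE table to loci classified as (strict) intergenic.

    Non-stranded mutant libraries cannot separate overlapping transcription,
    so only intergenic lncRNAs are interpretable; genes without a class label
    are excluded with a warning.
    """
    missing = [g for g in de_results.index if g not in classes]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) without a positional class excluded", stacklevel=2
        )
    keep = [g for g in de_results.index if classes.get(g) == "intergenic"]
    return de_results.loc[keep]


def cross_mutant_summary(
    contrast_results: Dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Gene x contrast direction matrix ({up, down, none}) across mutants."""
    if len(contrast_results) < 2:
        raise ValueError("need >= 2 contrasts to summarize")
    genes: List[str] = []
    for df in contrast_results.values():
        genes.extend(g for g in df.index if g not in genes)
    out = pd.DataFrame("none", index=genes, columns=list(contrast_results))
    for name, df in contrast_results.items():
        out.loc[df.index, name] = df["direction"].to_numpy()
    return out


def shared_direction(summary: pd.DataFrame, direction: str) -> List[str]:
    """Genes called in ``direction`` in every contrast where they are DE, and
    DE in at least two contrasts."""
    hits = []
    for gene, row in summary.iterrows():
        called = [d for d in row if d != "none"]
        if len(called) >= 2 and all(d == direction for d in called):
            hits.append(gene)
    return hits


def discordant_genes(summary: pd.DataFrame) -> List[str]:
    """Genes called up in one contrast and down in another."""
    hits = []
    for gene, row in summary.iterrows():
        called = set(d for d in row if d != "none")
        if {"up", "down"} <= called:
            hits.append(gene)
    return hits
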