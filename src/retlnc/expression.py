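"""Expression analytics over developmental stages and tissues.

Covers FPKM computation from counts, expressed/not-expressed calls, the tau
specificity index, stage sharing and accumulation, correlation structure
(hierarchical clustering + PCA) and retina-vs-panel tissue specificity.

tau (Yanai's index) for a profile x over N conditions is
``sum_i (1 - x_i/max(x)) / (N - 1)``: 0 for a uniform profile, 1 when the
gene is expressed in a single condition. By default it is computed on
per-stage replicate means of log2(FPKM+1); the raw scale is available via
``transform="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .models import ExpressionMatrix, ValidationError


def fpkm_from_counts(counts: ExpressionMatrix, exonic_lengths: pd.Series) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (exonic_length * column_total)."""
    if counts.unit != "count":
        raise ValidationError("fpkm_from_counts expects a count matrix")
    lengths = exonic_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValidationError(f"no exonic length for gene(s) {missing[:5]}")
    if (lengths <= 0).any():
        raise ValidationError("exonic lengths must be > 0")
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("zero column total; cannot compute FPKM")
    fpkm = counts.values * 1e9
    fpkm = fpkm.div(totals, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(values=fpkm, samples=counts.samples, unit="FPKM")


def expressed_calls(
    fpkm: ExpressionMatrix, threshold: float = 1.0, min_samples: int = 2
) -> pd.DataFrame:
    """Per-stage boolean expressed table.

    A gene is expressed in a stage iff FPKM >= ``threshold`` in at least
    ``min_samples`` replicate columns of that stage (capped at the stage's
    replicate count, so the default demands every replicate of a 2-replicate
    stage).
    """
    out = {}
    for cond in fpkm.conditions:
        cols = fpkm.columns_of(cond)
        need = min(min_samples, len(cols))
        out[cond] = (fpkm.values[cols] >= threshold).sum(axis=1) >= need
    return pd.DataFrame(out, index=fpkm.values.index)


def tau(profile: Sequence[float]) -> float:
    """Yanai's specificity index of a per-condition expression vector.

    Returns NaN for an all-zero profile (specificity undefined).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-d profile with >= 2 conditions")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression values")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


@dataclass(frozen=True)
class SpecificityResult:
    gene_id: str
    tau: float
    peak_sample: Optional[str]
    is_specific: bool


def specificity_table(
    fpkm: ExpressionMatrix,
    threshold: float = 0.8,
    transform: str = "log2",
) -> pd.DataFrame:
    """tau per gene on per-stage means (default of log2(FPKM+1)).

    Returns a DataFrame with columns ``tau``, ``peak_sample``,
    ``is_specific`` (tau >= threshold; all-zero genes get NaN tau and
    False).
    """
    if transform not in ("log2", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    means = fpkm.condition_means(log2=(transform == "log2"))
    arr = means.to_numpy()
    maxv = arr.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        taus = (1.0 - arr / maxv[:, None]).sum(axis=1) / (arr.shape[1] - 1)
    taus = np.where(maxv == 0, np.nan, taus)
    peak = means.columns.to_numpy()[arr.argmax(axis=1)]
    peak = np.where(maxv == 0, None, peak)
    return pd.DataFrame(
        {
            "tau": taus,
            "peak_sample": peak,
            "is_specific": np.nan_to_num(taus, nan=-1.0) >= threshold,
        },
        index=means.index,
    )


@dataclass
class StageSharingReport:
    """Pairwise sharing of expressed genes between stages, plus accumulation.

    ``shared_fraction.loc[i, j]`` is shared(i, j) / count(i): the fraction of
    stage i's expressed genes also expressed in stage j, so the matrix is
    asymmetric while ``shared_counts`` is symmetric. ``cumulative_novel``
    counts genes first seen at each stage in chronological order;
    ``cumulative_total`` is its running union size.
    """

    stage_counts: pd.Series
    shared_counts: pd.DataFrame
    shared_fraction: pd.DataFrame
    cumulative_novel: pd.Series
    cumulative_total: pd.Series


def stage_sharing(calls: pd.DataFrame) -> StageSharingReport:
    """Set accounting over a genes x stages boolean expressed table."""
    if calls.shape[1] < 2:
        raise ValueError("stage_sharing needs >= 2 stages")
    m = calls.to_numpy(dtype=bool)
    stages = list(calls.columns)
    counts = pd.Series(m.sum(axis=0), index=stages)
    shared = m.T.astype(np.int64) @ m.astype(np.int64)
    shared_counts = pd.DataFrame(shared, index=stages, columns=stages)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = shared / counts.to_numpy()[:, None]
    shared_fraction = pd.DataFrame(np.nan_to_num(frac), index=stages, columns=stages)
    seen = np.zeros(m.shape[0], dtype=bool)
    novel, total = [], []
    for j in range(m.shape[1]):
        novel.append(int((m[:, j] & ~seen).sum()))
        seen |= m[:, j]
        total.append(int(seen.sum()))
    return StageSharingReport(
        stage_counts=counts,
        shared_counts=shared_counts,
        shared_fraction=shared_fraction,
        cumulative_novel=pd.Series(novel, index=stages),
        cumulative_total=pd.Series(total, index=stages),
    )


@dataclass
class CorrelationStructure:
    correlation: pd.DataFrame
    linkage: np.ndarray
    dendrogram_order: List[str]
    pca_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def correlation_structure(
    fpkm: ExpressionMatrix, method: str = "spearman", n_components: Optional[int] = None
) -> CorrelationStructure:
    """Sample-sample correlation, average-linkage dendrogram and sample PCA.

    Correlation (Pearson or Spearman) is computed between sample columns;
    hierarchical clustering uses average linkage on 1 - correlation. PCA is
    run on log2(FPKM+1) with genes centered, samples as observations.
    Zero-variance columns yield NaN correlations for their pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if fpkm.values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    cor = fpkm.values.corr(method=method)  # NaN marks zero-variance pairs
    dist = 1.0 - cor.to_numpy()
    dist = np.where(np.isnan(dist), 1.0, dist)  # treat undefined pairs as maximally distant
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [fpkm.values.columns[i] for i in hierarchy.leaves_list(Z)]
    logv = np.log2(fpkm.values.to_numpy().T + 1.0)  # samples x genes
    logv = logv - logv.mean(axis=0, keepdims=True)  # center each gene
    k = n_components or min(logv.shape)
    k = min(k, min(logv.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(logv)
    return CorrelationStructure(
        correlation=cor,
        linkage=Z,
        dendrogram_order=order,
        pca_scores=pd.DataFrame(
            scores, index=fpkm.values.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def tissue_specificity(
    retina_fpkm: ExpressionMatrix,
    tissue_panel: ExpressionMatrix,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Call genes retina-specific against a multi-tissue panel.

    A gene is retina-specific iff its FPKM stays strictly below ``threshold``
    in every non-retina tissue; otherwise the tissues reaching the threshold
    are listed. Genes absent from the panel are flagged (``in_panel=False``)
    and excluded from specificity denominators by callers.
    """
    genes = retina_fpkm.values.index
    in_panel = genes.isin(tissue_panel.values.index)
    tissues = tissue_panel.conditions
    panel_means = tissue_panel.condition_means()
    rows = []
    for gene, present in zip(genes, in_panel):
        if not present:
            rows.append({"in_panel": False, "retina_specific": False, "shared_tissues": ""})
            continue
        expr = panel_means.loc[gene]
        shared = [t for t in tissues if expr[t] >= threshold]
        rows.append(
            {
                "in_panel": True,
                "retina_specific": len(shared) == 0,
                "shared_tissues": ",".join(shared),
            }
        )
    return pd.DataFrame(rows, index=genes)
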