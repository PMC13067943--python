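"""Genome-ordered CNV inference from expression and tumor-cell calling.

A deliberately simplified expression-based CNV pipeline (no HMM, no
subcluster tree): library-size-normalized log expression, per-gene reference
subtraction (immune/stromal cells as the diploid reference), a genomic
moving average within each chromosome, per-cell median re-centering and
clipping.  The per-cell total CNV score is the sum of absolute processed
values; clusters that combine a low median score with cells mixed from
multiple samples are called normal, everything else tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CNVProfile:
    """Smoothed relative-expression profile: cells x genomically ordered
    genes, values clipped to [-clip, +clip] (log2 units)."""

    values: np.ndarray            # cells x genes
    cell_ids: pd.Index
    genes: pd.Index               # in genomic order
    chroms: np.ndarray
    window: int
    clip: float
    reference_ids: pd.Index


def _truncated_moving_average(arr: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 1 with truncated edge windows."""
    half = window // 2
    n = arr.shape[1]
    csum = np.cumsum(np.pad(arr, ((0, 0), (1, 0))), axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profile(adata: AnnData, reference_ids, window: int = 101,
                      clip: float = 1.0, target_depth: float = 1e4,
                      center_cells: bool = True) -> CNVProfile:
    """Infer per-cell relative copy-number profiles.

    Requires ``chrom`` and ``start`` columns in ``adata.var``; genes without
    annotation are excluded with a warning.  ``window`` is an odd gene count
    and must not exceed the smallest chromosome's gene count.  By
    construction the reference cells' per-gene mean is 0 before the per-cell
    median re-centering (``center_cells=False`` exposes that stage).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if clip <= 0:
        raise ValueError("clip must be > 0")
    var = adata.var
    if "chrom" not in var or "start" not in var:
        raise ValueError("gene annotation requires 'chrom' and 'start' columns")
    annotated = var["chrom"].notna() & var["start"].notna()
    if not annotated.all():
        log.warning("excluding %d unannotated gene(s)", int((~annotated).sum()))
    order = var.loc[annotated].sort_values(["chrom", "start"]).index
    sub = adata[:, order]

    ref_mask = adata.obs_names.isin(pd.Index(reference_ids))
    if not ref_mask.any():
        raise ValueError("reference cell set is empty")

    X = sub.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    lib = X.sum(axis=1, keepdims=True)
    if (lib == 0).any():
        raise ValueError("cell(s) with zero total counts; run QC first")
    logx = np.log2(1.0 + X / lib * target_depth)
    logx -= logx[ref_mask].mean(axis=0, keepdims=True)

    chroms = sub.var["chrom"].to_numpy()
    smooth = np.empty_like(logx)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        if cols.size < window:
            raise ValueError(
                f"window {window} exceeds gene count on {chrom} ({cols.size})")
        smooth[:, cols] = _truncated_moving_average(logx[:, cols], window)
    if center_cells:
        smooth -= np.median(smooth, axis=1, keepdims=True)
    np.clip(smooth, -clip, clip, out=smooth)
    return CNVProfile(values=smooth, cell_ids=adata.obs_names,
                      genes=pd.Index(order), chroms=chroms, window=window,
                      clip=clip,
                      reference_ids=pd.Index(adata.obs_names[ref_mask]))


def total_cnv_score(profile: CNVProfile) -> pd.Series:
    """Per-cell total CNV score: sum over genes of |processed value|."""
    return pd.Series(np.abs(profile.values).sum(axis=1),
                     index=profile.cell_ids, name="cnv_score")


def call_tumor_cells(scores: pd.Series, clusters: pd.Series,
                     samples: pd.Series | None = None,
                     score_quantile: float = 0.25,
                     mixing_threshold: float = 0.75) -> tuple[pd.Series, pd.DataFrame]:
    """Tumor/normal call per cell from cluster-level evidence.

    A cluster is normal when its median score falls at or below the
    ``score_quantile`` quantile of all scores AND no single sample
    contributes more than ``mixing_threshold`` of its cells; every other
    cluster is tumor.  With a single sample (or none given) the mixing
    criterion is skipped with a warning and the score criterion alone
    applies.
    """
    if not 0.0 <= score_quantile <= 1.0:
        raise ValueError("score_quantile must be in [0, 1]")
    clusters = clusters.reindex(scores.index)
    cutoff = float(scores.quantile(score_quantile))
    use_mixing = samples is not None and samples.reindex(scores.index).nunique() > 1
    if not use_mixing:
        log.warning("single-sample input: mixing criterion skipped")

    rows = []
    normal_clusters = set()
    for cl, idx in scores.groupby(clusters).groups.items():
        med = float(scores.loc[idx].median())
        low = med <= cutoff  # non-strict so a degenerate all-equal cluster counts low
        if use_mixing:
            shares = samples.reindex(idx).value_counts(normalize=True)
            mixed = float(shares.max()) <= mixing_threshold
        else:
            mixed = True
        is_normal = low and mixed
        if is_normal:
            normal_clusters.add(cl)
        rows.append({"cluster": cl, "n_cells": len(idx), "median_score": med,
                     "low_score": low, "sample_mixed": mixed,
                     "call": "normal" if is_normal else "tumor"})
    is_tumor = ~clusters.isin(normal_clusters)
    is_tumor.name = "is_tumor"
    return is_tumor, pd.DataFrame(rows).set_index("cluster")
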