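"""Single-cell expression stages: QC, signature scoring, epitope accounting.

QC follows the strict printed thresholds (cells kept with genes > floor,
UMIs > floor, mitochondrial ratio < ceiling; genes detected in too few cells
dropped afterwards), with a relaxed CTC mode and an optional low-capture
filter on the fraction of all genes detected.

Subtype signature scores are per-cell Mann-Whitney U statistics on
within-cell gene ranks (UCell-style): genes are ranked by descending
expression with average ranks on ties, undetected genes share the capped
rank ``max_rank + 1``, and the score is ``1 - U' / (n * max_rank)`` in
[0, 1].  Being rank-based, scores are invariant under any strictly monotone
transform of a cell's expression values.  Epitope positivity is the
at-least-one-UMI rule throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import sparse
from scipy.stats import rankdata

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signature sets


@dataclass(frozen=True)
class SignatureSet:
    """Named gene lists: the four SCLC subtype signatures, the targetable
    epitopes (DLL3/SEZ6/B7H3=CD276), the Notch pathway set and the
    epithelial (EpCAM + keratin) set."""

    subtypes: dict[str, list[str]]
    epitopes: list[str]
    notch: list[str]
    epithelial: list[str]

    def __post_init__(self) -> None:
        for name, genes in {**self.subtypes, "epitopes": self.epitopes,
                            "notch": self.notch,
                            "epithelial": self.epithelial}.items():
            if not genes:
                raise ValueError(f"signature list {name!r} is empty")

    def check_against(self, gene_ids: Sequence[str]) -> None:
        """Warn about signature genes absent from a matrix."""
        present = set(gene_ids)
        for name, genes in self.subtypes.items():
            absent = [g for g in genes if g not in present]
            if absent:
                log.warning("signature %s: %d gene(s) absent from matrix: %s",
                            name, len(absent), absent)


def load_signatures() -> SignatureSet:
    """Load the packaged signature gene lists."""
    text = resources.files("ctcdll3.data").joinpath("signatures.yaml").read_text()
    raw = yaml.safe_load(text)
    return SignatureSet(subtypes=raw["subtypes"], epitopes=raw["epitopes"],
                        notch=raw["notch"], epithelial=raw["epithelial"])


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC thresholds.

    Cells are kept when detected genes > ``min_genes``, total UMIs >
    ``min_umi`` and mitochondrial fraction < ``max_mito`` (all strict), and,
    when ``min_gene_detection_frac`` is set, when the fraction of all genes
    detected is at least that value.  Genes are then kept when detected in
    at least ``min_cells_per_gene`` of the remaining cells (the printed rule
    excludes genes detected in <= 3 cells, hence the default 4).
    """

    min_genes: int = 500
    min_umi: int = 1000
    max_mito: float = 0.1
    min_cells_per_gene: int = 4
    min_gene_detection_frac: float | None = None

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_umi, self.min_cells_per_gene) < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ValueError("max_mito must be in [0, 1]")
        if self.min_gene_detection_frac is not None and not \
                0.0 <= self.min_gene_detection_frac <= 1.0:
            raise ValueError("min_gene_detection_frac must be in [0, 1]")

    @classmethod
    def ctc_mode(cls, **kw) -> "QCThresholds":
        """Relaxed cell-level floors used for CTC-enriched blood products."""
        return replace(cls(min_genes=300, min_umi=500), **kw)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def qc_filter(adata: AnnData, thresholds: QCThresholds | None = None,
              mito_prefix: str = "MT-") -> tuple[AnnData, pd.DataFrame, pd.DataFrame]:
    """Filter cells then genes; returns the filtered AnnData plus per-cell
    and per-gene pass-flag tables for audit.  Thresholds removing every cell
    produce an empty output with a warning, not an exception."""
    thresholds = thresholds or QCThresholds()
    X = adata.X
    counts = X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)
    n_genes_by_cell = counts.getnnz(axis=1)
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.char.startswith(adata.var_names.to_numpy(str), mito_prefix)
    mito_sum = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() \
        else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_sum / np.maximum(total, 1), 0.0)

    keep_cell = ((n_genes_by_cell > thresholds.min_genes)
                 & (total > thresholds.min_umi)
                 & (mito_frac < thresholds.max_mito))
    if thresholds.min_gene_detection_frac is not None:
        keep_cell &= (n_genes_by_cell / adata.n_vars
                      >= thresholds.min_gene_detection_frac)
    cell_flags = pd.DataFrame({
        "n_genes": n_genes_by_cell, "total_umi": total.astype(int),
        "mito_frac": mito_frac, "pass": keep_cell}, index=adata.obs_names)

    filtered = adata[keep_cell].copy()
    cells_per_gene = (filtered.X.tocsc().getnnz(axis=0)
                      if sparse.issparse(filtered.X)
                      else (np.asarray(filtered.X) > 0).sum(axis=0))
    keep_gene = cells_per_gene >= thresholds.min_cells_per_gene
    gene_flags = pd.DataFrame({"cells_detected": cells_per_gene,
                               "pass": keep_gene}, index=adata.var_names)
    out = filtered[:, keep_gene].copy()
    if out.n_obs == 0:
        log.warning("QC removed every cell")
    return out, cell_flags, gene_flags


# ---------------------------------------------------------------------------
# rank-based signature scoring


def ucell_score_cell(expr: np.ndarray, signature_idx: np.ndarray,
                     max_rank: int = 1500) -> float:
    """Signature score of one cell from its expression vector.

    Genes are ranked by descending expression with average ranks on ties;
    undetected (zero) genes share rank ``max_rank + 1`` and every rank is
    capped there.  ``U' = sum(signature ranks) - n(n+1)/2`` and the score is
    ``1 - U' / (n * max_rank)``, clipped to [0, 1].  A cell detecting none
    of the signature genes scores exactly 0 by convention.
    """
    n = signature_idx.size
    if n == 0:
        raise ValueError("signature is empty after intersection with gene ids")
    if n >= max_rank:
        raise ValueError("max_rank must exceed the signature size")
    expr = np.asarray(expr, float)
    if not (expr[signature_idx] > 0).any():
        return 0.0
    ranks = rankdata(-expr, method="average")
    ranks[expr == 0] = max_rank + 1
    ranks = np.minimum(ranks, max_rank + 1)
    u = ranks[signature_idx].sum() - n * (n + 1) / 2.0
    return float(np.clip(1.0 - u / (n * max_rank), 0.0, 1.0))


def ucell_scores(adata: AnnData, signatures: Mapping[str, Sequence[str]],
                 max_rank: int = 1500, chunk: int = 512) -> pd.DataFrame:
    """Per-cell scores for several signatures (cells x signatures)."""
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}
    sig_idx: dict[str, np.ndarray] = {}
    for name, genes in signatures.items():
        idx = np.array([gene_pos[g] for g in genes if g in gene_pos], int)
        if idx.size == 0:
            raise ValueError(f"signature {name!r} has no gene in the matrix")
        if idx.size >= max_rank:
            raise ValueError("max_rank must exceed every signature size")
        sig_idx[name] = idx

    out = np.zeros((adata.n_obs, len(sig_idx)))
    for start in range(0, adata.n_obs, chunk):
        block = _dense(adata.X[start:start + chunk]).astype(float)
        ranks = rankdata(-block, method="average", axis=1)
        ranks[block == 0] = max_rank + 1
        np.minimum(ranks, max_rank + 1, out=ranks)
        for k, (name, idx) in enumerate(sig_idx.items()):
            n = idx.size
            u = ranks[:, idx].sum(axis=1) - n * (n + 1) / 2.0
            score = np.clip(1.0 - u / (n * max_rank), 0.0, 1.0)
            score[~(block[:, idx] > 0).any(axis=1)] = 0.0
            out[start:start + chunk, k] = score
    return pd.DataFrame(out, index=adata.obs_names, columns=list(sig_idx))


def assign_subtypes(scores: pd.DataFrame,
                    priority: Sequence[str] = ("SCLC-A", "SCLC-N", "SCLC-P",
                                               "SCLC-I")) -> pd.DataFrame:
    """Assign each cell to its most enriched signature.

    Ties are broken by the fixed priority order (prevalence order of the
    subtypes); tied cells are flagged and their occurrence logged.
    """
    cols = [c for c in priority if c in scores.columns]
    if len(cols) != len(scores.columns):
        raise ValueError("priority must cover all score columns")
    vals = scores[cols].to_numpy()
    best = vals.argmax(axis=1)  # argmax takes the first (highest-priority) max
    tie = (vals == vals[np.arange(len(vals)), best][:, None]).sum(axis=1) > 1
    if tie.any():
        log.info("subtype assignment: %d tie(s) broken by priority order",
                 int(tie.sum()))
    return pd.DataFrame({"subtype": np.asarray(cols)[best], "tie": tie},
                        index=scores.index)


# ---------------------------------------------------------------------------
# epitope positivity and coexpression


def call_epitope(adata: AnnData, gene: str, min_umi: int = 1) -> pd.Series:
    """Per-cell epitope positivity: count >= ``min_umi`` (default: at least
    one UMI).  A gene absent from the matrix yields all-False with a
    warning."""
    if gene not in adata.var_names:
        log.warning("gene %r not in matrix; reporting all cells negative", gene)
        return pd.Series(False, index=adata.obs_names, name=gene)
    col = adata[:, gene].X
    vals = np.asarray(col.todense()).ravel() if sparse.issparse(col) \
        else np.asarray(col).ravel()
    return pd.Series(vals >= min_umi, index=adata.obs_names, name=gene)


@dataclass(frozen=True)
class DropoutAssessment:
    """Bounds on the DLL3-positive fraction allowing for technical dropout.

    A DLL3-negative cell detecting at least ``k_min`` Notch-pathway genes
    (which are coregulated with DLL3) is a candidate technical false
    negative.  The corrected fraction is bracketed by
    ``observed <= corrected <= observed + candidate``.
    """

    observed_fraction: float
    candidate_fraction: float
    corrected_lower: float
    corrected_upper: float
    candidate_flags: pd.Series


def dropout_assessment(adata: AnnData, dll3_positive: pd.Series,
                       notch_genes: Sequence[str] | None = None,
                       k_min: int = 2) -> DropoutAssessment:
    """Estimate how many DLL3-negative cells may be technical dropouts."""
    if notch_genes is None:
        notch_genes = load_signatures().notch
    present = [g for g in notch_genes if g in adata.var_names]
    if not present:
        log.warning("no Notch-set gene in matrix; dropout estimate undefined")
        return DropoutAssessment(np.nan, np.nan, np.nan, np.nan,
                                 pd.Series(False, index=adata.obs_names))
    sub = adata[:, present].X
    n_detected = (sub.getnnz(axis=1) if sparse.issparse(sub)
                  else (np.asarray(sub) > 0).sum(axis=1))
    pos = dll3_positive.reindex(adata.obs_names).to_numpy(bool)
    candidate = (~pos) & (n_detected >= k_min)
    obs = float(pos.mean())
    cand = float(candidate.mean())
    return DropoutAssessment(
        observed_fraction=obs, candidate_fraction=cand,
        corrected_lower=obs, corrected_upper=obs + cand,
        candidate_flags=pd.Series(candidate, index=adata.obs_names))


@dataclass(frozen=True)
class VennCounts:
    """Counts over every region of the k-set Venn partition of cells.

    ``regions`` maps a frozenset of gene names (the exact positivity
    combination) to its cell count; regions partition the cell set together
    with ``none``.  Percentages are reported against the any-positive
    denominator.
    """

    genes: tuple[str, ...]
    regions: dict[frozenset, int]
    none: int
    total: int

    @property
    def any_positive(self) -> int:
        return self.total - self.none

    def count_positive(self, genes: Sequence[str]) -> int:
        """Cells positive for at least one of ``genes``."""
        want = set(genes)
        return sum(n for combo, n in self.regions.items() if combo & want)

    def percent_of_any(self, genes: Sequence[str]) -> float:
        """Percent of any-positive cells positive for >= 1 of ``genes``."""
        if self.any_positive == 0:
            return np.nan
        return 100.0 * self.count_positive(genes) / self.any_positive

    def percent_of_total(self, genes: Sequence[str]) -> float:
        if self.total == 0:
            return np.nan
        return 100.0 * self.count_positive(genes) / self.total


def coexpression_venn(adata: AnnData, genes: Sequence[str],
                      min_umi: int = 1) -> VennCounts:
    """Count cells in every region of the Venn partition over ``genes``
    (at most 4 sets), by the at-least-``min_umi`` positivity rule."""
    genes = tuple(genes)
    if not 1 <= len(genes) <= 4:
        raise ValueError("coexpression_venn supports 1 to 4 gene sets")
    flags = np.column_stack([call_epitope(adata, g, min_umi).to_numpy()
                             for g in genes])
    regions: dict[frozenset, int] = {}
    for r in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            sel = np.ones(adata.n_obs, bool)
            for g in genes:
                sel &= flags[:, genes.index(g)] == (g in combo)
            regions[frozenset(combo)] = int(sel.sum())
    none = int((~flags.any(axis=1)).sum())
    return VennCounts(genes=genes, regions=regions, none=none,
                      total=adata.n_obs)


# ---------------------------------------------------------------------------
# aggregation and joint epithelial/DLL3 classification


def pseudobulk(adata: AnnData, groupby: str | pd.Series,
               per_million: bool = False) -> pd.DataFrame:
    """Per-group summed raw counts (groups x genes); with ``per_million``
    each group profile is scaled to one million counts.  Group sums conserve
    the global per-gene totals."""
    groups = adata.obs[groupby] if isinstance(groupby, str) \
        else groupby.reindex(adata.obs_names)
    if groups.isna().any():
        raise ValueError("grouping must cover all cells")
    rows = {}
    for key in pd.unique(groups):
        sel = (groups == key).to_numpy()
        sub = adata.X[sel]
        total = np.asarray(sub.sum(axis=0)).ravel()
        rows[key] = total
    out = pd.DataFrame(rows, index=adata.var_names).T
    if per_million:
        out = out.div(out.sum(axis=1), axis=0) * 1e6
    return out


def epithelial_origin(adata: AnnData, dll3_gene: str = "DLL3",
                      epithelial_genes: Sequence[str] | None = None,
                      min_umi: int = 1) -> tuple[pd.Series, dict[str, float]]:
    """Joint DLL3/epithelial transcript classification per cell.

    Categories: ``dll3+epith+``, ``dll3+only``, ``epith+only``, ``neither``
    by the at-least-one-UMI rule; fractions are over all cells supplied
    (intended: CNV-confirmed tumor cells).
    """
    if epithelial_genes is None:
        epithelial_genes = load_signatures().epithelial
    present = [g for g in epithelial_genes if g in adata.var_names]
    if not present:
        raise ValueError("no epithelial gene present in the matrix")
    dll3 = call_epitope(adata, dll3_gene, min_umi).to_numpy()
    epi = np.zeros(adata.n_obs, bool)
    for g in present:
        epi |= call_epitope(adata, g, min_umi).to_numpy()
    cat = np.select(
        [dll3 & epi, dll3 & ~epi, ~dll3 & epi],
        ["dll3+epith+", "dll3+only", "epith+only"], default="neither")
    series = pd.Series(cat, index=adata.obs_names, name="origin")
    fracs = {k: float((cat == k).mean())
             for k in ("dll3+epith+", "dll3+only", "epith+only", "neither")}
    return series, fracs
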