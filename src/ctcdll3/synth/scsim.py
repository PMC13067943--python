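"""Synthetic gene x cell UMI count matrices with known ground truth.

Emulates the statistical structure the single-cell stages rely on: SCLC
subtype signature elevation, a designated DLL3-positive tumor-cell fraction
(positivity = at least one transcript before detection loss), Notch-pathway
expression coregulated with DLL3, chromosome-block copy-number shifts in
tumor cells, log-normal library sizes, and detection loss modeled as
per-molecule thinning with a shared per-cell efficiency latent (so a
single-copy transcript fails detection with probability ~ ``dropout``) plus
optional whole-gene zeroing for designated genes (``gene_dropout``), used to
inject technical DLL3 false negatives.  Counts are returned as an AnnData
(cells x genes, sparse) whose ``var`` carries a genomically ordered
annotation and whose ``obs`` carries the per-cell truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from ..scxpr import load_signatures

SUBTYPES = ("SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I")

#: human mitochondrial protein-coding gene symbols (MT- prefix convention)
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


@dataclass(frozen=True)
class CNVBlock:
    """A copy-number segment: genes on ``chrom`` with start in [start, end)
    have their expression rate multiplied by ``fold`` in the affected tumor
    populations (all tumor populations when ``populations`` is None)."""

    chrom: str
    start: int
    end: int
    fold: float
    populations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("CNV fold-change must be > 0")
        if self.end <= self.start:
            raise ValueError("CNV block must have end > start")


@dataclass(frozen=True)
class SCCountParams:
    """Parameters of a synthetic single-cell count experiment.

    ``n_cells`` maps population name to cell count; populations listed in
    ``tumor_populations`` (default: every population except ``reference``)
    are tumor subclones.  ``samples`` optionally assigns each population to a
    sample id; a population mapped to None has its cells spread round-robin
    across all named samples (used to build sample-mixed normal clusters).
    """

    n_cells: Mapping[str, int] = field(
        default_factory=lambda: {"tumor": 1000, "reference": 500})
    tumor_populations: tuple[str, ...] | None = None
    samples: Mapping[str, str | None] | None = None
    n_genes: int = 2000
    n_chromosomes: int = 10
    subtype_mixture: Sequence[float] = (0.70, 0.18, 0.10, 0.02)
    signature_effect: float = 8.0
    dll3_positive_fraction: float = 0.35
    dll3_mean: float = 4.0
    dropout: float = 0.3
    dropout_dispersion: float = 0.4
    gene_dropout: Mapping[str, float] = field(default_factory=dict)
    notch_coregulation: float = 0.8
    cnv_blocks: tuple[CNVBlock, ...] = ()
    library_log_mean: float = float(np.log(5000.0))
    library_log_sd: float = 0.35
    mito_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_cells.values()):
            raise ValueError("n_cells must be nonnegative")
        mix = np.asarray(self.subtype_mixture, float)
        if mix.shape != (4,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_mixture must be 4 proportions summing to 1")
        if not 0.0 <= self.dll3_positive_fraction <= 1.0:
            raise ValueError("dll3_positive_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        for gene, p in self.gene_dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gene_dropout[{gene!r}] must be in [0, 1]")
        if not 0.0 <= self.notch_coregulation <= 1.0:
            raise ValueError("notch_coregulation must be in [0, 1]")
        if self.signature_effect <= 0:
            raise ValueError("signature_effect must be > 0")
        if self.dll3_mean < 1:
            raise ValueError("dll3_mean must be >= 1")

    @property
    def tumor_pops(self) -> tuple[str, ...]:
        if self.tumor_populations is not None:
            return self.tumor_populations
        return tuple(p for p in self.n_cells if p != "reference")


def build_gene_universe(n_genes: int, n_chromosomes: int) -> pd.DataFrame:
    """Deterministic gene annotation: the signature/epitope/Notch/epithelial
    and mitochondrial symbols padded with filler genes, assigned round-robin
    to chromosomes with 0-based half-open 1-kb spacing."""
    sigs = load_signatures()
    named: list[str] = []
    for group in (*[sigs.subtypes[s] for s in SUBTYPES], sigs.epitopes,
                  sigs.notch, sigs.epithelial, list(MITO_GENES)):
        for g in group:
            if g not in named:
                named.append(g)
    if n_genes < len(named):
        raise ValueError(f"n_genes must be >= {len(named)} to carry the named gene sets")
    genes = named + [f"FILL{i:05d}" for i in range(n_genes - len(named))]
    idx = np.arange(n_genes)
    return pd.DataFrame({
        "gene": genes,
        "chrom": [f"chr{(i % n_chromosomes) + 1}" for i in idx],
        "start": (idx // n_chromosomes) * 1000,
    }).set_index("gene")


def _block_gene_mask(annot: pd.DataFrame, block: CNVBlock) -> np.ndarray:
    mask = ((annot["chrom"] == block.chrom)
            & (annot["start"] >= block.start)
            & (annot["start"] < block.end)).to_numpy()
    if not mask.any():
        raise ValueError(
            f"CNV block {block.chrom}:{block.start}-{block.end} matches no "
            "annotated gene")
    return mask


def simulate_counts(params: SCCountParams) -> tuple[AnnData, pd.DataFrame]:
    """Simulate a sparse UMI count matrix with ground truth.

    Returns ``(adata, truth)`` where ``adata`` is cells x genes with the
    genomic annotation in ``.var`` and the truth columns also stored in
    ``.obs``.  Identical params give identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    annot = build_gene_universe(params.n_genes, params.n_chromosomes)
    genes = annot.index.to_numpy()
    gi = {g: j for j, g in enumerate(genes)}
    sigs = load_signatures()

    # base relative expression rates; mitochondrial genes pinned so that
    # their expected share of a library equals mito_fraction
    base = rng.gamma(0.45, 1.0, params.n_genes) + 1e-3
    # subtype marker genes (lineage TFs and their programs) are expressed at
    # a dependable moderate level before the subtype fold is applied
    floor = float(np.median(base)) * 2.0
    for st in SUBTYPES:
        for g in sigs.subtypes[st]:
            if g in gi:
                base[gi[g]] = max(base[gi[g]], floor)
    # Notch pathway genes sit low at baseline (Notch-off neuroendocrine
    # state) and are lifted in DLL3-positive cells by the coregulation fold
    for g in sigs.notch:
        base[gi[g]] = float(np.median(base)) * 0.3
    base[gi["DLL3"]] = 0.0  # handled by the designated-positive model
    mito_idx = np.array([gi[g] for g in MITO_GENES])
    non_mito = base.sum() - base[mito_idx].sum()
    base[mito_idx] = params.mito_fraction * non_mito / (
        (1 - params.mito_fraction) * mito_idx.size)
    base /= base.sum()

    pops = [p for p, n in params.n_cells.items() for _ in range(n)]
    n_cells = len(pops)
    pop_arr = np.asarray(pops)
    is_tumor = np.isin(pop_arr, params.tumor_pops)

    # sample assignment: fixed per population, round-robin for None
    sample_map = params.samples or {p: "S1" for p in params.n_cells}
    named_samples = sorted({s for s in sample_map.values() if s is not None}) or ["S1"]
    samples = np.empty(n_cells, dtype=object)
    for p in params.n_cells:
        idx = np.flatnonzero(pop_arr == p)
        s = sample_map.get(p, "S1")
        if s is None:
            samples[idx] = [named_samples[i % len(named_samples)]
                            for i in range(idx.size)]
        else:
            samples[idx] = s

    subtype = np.full(n_cells, "", dtype=object)
    subtype[is_tumor] = rng.choice(
        SUBTYPES, int(is_tumor.sum()), p=np.asarray(params.subtype_mixture, float))
    dll3_pos = np.zeros(n_cells, bool)
    dll3_pos[is_tumor] = rng.random(int(is_tumor.sum())) < params.dll3_positive_fraction

    # per-cell rate matrix
    rates = np.tile(base, (n_cells, 1))
    for st in SUBTYPES:
        cols = [gi[g] for g in sigs.subtypes[st] if g in gi]
        rows = np.flatnonzero(subtype == st)
        if rows.size:
            rates[np.ix_(rows, cols)] *= params.signature_effect
    notch_cols = [gi[g] for g in sigs.notch]
    notch_fold = 1.0 + 9.0 * params.notch_coregulation
    rows = np.flatnonzero(dll3_pos)
    if rows.size:
        rates[np.ix_(rows, notch_cols)] *= notch_fold
    for block in params.cnv_blocks:
        mask = _block_gene_mask(annot, block)
        affected = (block.populations if block.populations is not None
                    else params.tumor_pops)
        rows = np.flatnonzero(np.isin(pop_arr, affected))
        rates[np.ix_(rows, np.flatnonzero(mask))] *= block.fold

    lib = rng.lognormal(params.library_log_mean, params.library_log_sd, n_cells)
    rates *= (lib / rates.sum(axis=1))[:, None]
    counts = rng.poisson(rates).astype(np.int32)

    # designated DLL3-positive cells carry at least one transcript pre-dropout
    counts[:, gi["DLL3"]] = 0
    counts[dll3_pos, gi["DLL3"]] = 1 + rng.poisson(
        params.dll3_mean - 1.0, int(dll3_pos.sum()))

    sez6_pre = counts[:, gi["SEZ6"]] >= 1
    b7h3_pre = counts[:, gi["CD276"]] >= 1

    # detection loss: per-molecule thinning with a shared per-cell efficiency
    # latent (a transcript evades detection with probability ~ dropout), plus
    # optional whole-gene zeroing injections for specific genes
    if params.dropout > 0:
        eff = np.exp(rng.normal(0.0, params.dropout_dispersion, n_cells))
        keep_p = np.clip((1.0 - params.dropout) ** eff, 0.0, 1.0)
        counts = rng.binomial(counts, keep_p[:, None]).astype(np.int32)
    for gene, p_drop in params.gene_dropout.items():
        if gene not in gi:
            raise ValueError(f"gene_dropout gene {gene!r} not in annotation")
        kept = rng.random(n_cells) >= p_drop
        counts[:, gi[gene]] = np.where(kept, counts[:, gi[gene]], 0)

    truth = pd.DataFrame({
        "cell_id": [f"C{i:06d}" for i in range(n_cells)],
        "population": pop_arr,
        "sample": samples.astype(str),
        "is_tumor": is_tumor,
        "subtype": subtype.astype(str),
        "dll3_positive": dll3_pos,
        "sez6_positive": sez6_pre,
        "b7h3_positive": b7h3_pre,
    }).set_index("cell_id")

    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=truth.copy(),
        var=annot.copy(),
    )
    adata.uns["seed"] = params.seed
    return adata, truth
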