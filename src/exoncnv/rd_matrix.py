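"""Observed read-depth matrix: counting, filtering, QC.

Builds the genes × samples read-depth (RD) matrix from 5'-base read
placements, applies the median-read-depth data filters, computes the
per-sample median read depth (MRD) used as the coverage normalizer, and
provides a PCA batch-effect check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_and_config import ConsistencyError, ParseError, TargetSet

logger = logging.getLogger("exoncnv")


@dataclass
class RDMatrix:
    """Integer read-depth counts, genes × samples, with a filter provenance log."""

    counts: np.ndarray           # shape (n_genes, n_samples), integer, >= 0
    genes: list[str]
    samples: list[str]
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ConsistencyError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ConsistencyError("duplicate sample ids")
        if (self.counts < 0).any():
            raise ValueError("read-depth counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def write_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RDMatrix":
        """Read a gene × sample count TSV (first column gene names)."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.index.has_duplicates:
            raise ConsistencyError(f"{path}: duplicate gene ids")
        if frame.columns.has_duplicates:
            raise ConsistencyError(f"{path}: duplicate sample ids")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_float = frame.to_numpy(dtype=float)
            if not np.all(np.isfinite(as_float)) or not np.all(
                as_float == np.round(as_float)
            ):
                raise ParseError(f"{path}: counts must be integers")
            values = as_float.astype(np.int64)
        if (values < 0).any():
            raise ParseError(f"{path}: counts must be non-negative")
        return cls(values, list(frame.index), list(frame.columns))


def read_rd_matrix(path: str | Path) -> RDMatrix:
    return RDMatrix.from_tsv(path)


def count_reads(
    placements: pd.DataFrame,
    targets: TargetSet,
    mapq_min: int = 20,
    use_duplicates: bool = False,
) -> RDMatrix:
    """Count, per gene and sample, reads whose 5' base falls in an exon.

    A read contributes to at most one gene: when exons of two genes overlap
    the read is assigned to the gene whose covering exon starts first, ties
    broken by gene name.  Duplicate reads and reads below mapq_min are
    discarded.  Samples with no in-target reads keep all-zero columns.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene in targets:
        tree = trees.setdefault(gene.chromosome, IntervalTree())
        for s, e in gene.exons:
            tree[s:e] = gene.name

    samples = sorted(placements["sample_id"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    gene_names = [g.name for g in targets]
    gene_idx = {g: i for i, g in enumerate(gene_names)}

    keep = placements["mapq"] >= mapq_min
    if not use_duplicates:
        keep &= ~placements["is_duplicate"]
    kept = placements[keep]
    logger.info(
        "count_reads: %d of %d placements pass mapq/duplicate filters",
        len(kept), len(placements),
    )

    counts = np.zeros((len(gene_names), len(samples)), dtype=np.int64)
    unknown_chrom = 0
    for chrom, group in kept.groupby("chromosome", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            unknown_chrom += len(group)
            continue
        pos = group["pos5"].to_numpy()
        cols = group["sample_id"].map(sample_idx).to_numpy()
        for p, col in zip(pos, cols):
            hits = tree[p]
            if not hits:
                continue
            gene = min(hits, key=lambda iv: (iv.begin, iv.data)).data
            counts[gene_idx[gene], col] += 1
    if unknown_chrom:
        logger.warning(
            "count_reads: %d placements on chromosomes absent from targets",
            unknown_chrom,
        )
    return RDMatrix(counts, gene_names, samples)


def compute_mrd(rd: RDMatrix) -> pd.Series:
    """Per-sample median of gene read depths (the MRD coverage normalizer)."""
    if rd.shape[0] < 1:
        raise ValueError("need at least one gene to compute MRD")
    return pd.Series(np.median(rd.counts, axis=0), index=rd.samples, name="mrd")


def filter_matrix(
    rd: RDMatrix,
    target_median_rd_min: int = 30,
    sample_median_rd_min: int = 30,
) -> RDMatrix:
    """Drop low-coverage genes, then low-coverage samples.

    A gene is kept when its median RD across samples is >= the target
    threshold; then a sample is kept when its median RD across the retained
    genes is >= the sample threshold.  Defaults (30, 30) suit short-read
    data; (5, 1) is the relaxed setting for long-read (454-style) data.
    """
    gene_medians = np.median(rd.counts, axis=1)
    keep_genes = gene_medians >= target_median_rd_min
    if not keep_genes.any():
        raise ValueError(
            "all genes removed by the target median-RD filter; "
            "consider relaxed thresholds (e.g. 5, 1 for long-read data)"
        )
    sub = rd.counts[keep_genes]
    sample_medians = np.median(sub, axis=0)
    keep_samples = sample_medians >= sample_median_rd_min
    if not keep_samples.any():
        raise ValueError(
            "all samples removed by the sample median-RD filter; "
            "consider relaxed thresholds (e.g. 5, 1 for long-read data)"
        )
    removed_genes = [g for g, k in zip(rd.genes, keep_genes) if not k]
    removed_samples = [s for s, k in zip(rd.samples, keep_samples) if not k]
    logger.info(
        "filter_matrix: removed %d/%d genes (<%d), %d/%d samples (<%d)",
        len(removed_genes), len(rd.genes), target_median_rd_min,
        len(removed_samples), len(rd.samples), sample_median_rd_min,
    )
    log = list(rd.filter_log) + [
        {
            "step": "filter_matrix",
            "target_median_rd_min": target_median_rd_min,
            "sample_median_rd_min": sample_median_rd_min,
            "removed_genes": removed_genes,
            "removed_samples": removed_samples,
        }
    ]
    return RDMatrix(
        sub[:, keep_samples],
        [g for g, k in zip(rd.genes, keep_genes) if k],
        [s for s, k in zip(rd.samples, keep_samples) if k],
        log,
    )


def qc_pca(rd: RDMatrix, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto leading principal components for batch QC.

    Sample columns are scaled by their MRD and genes centered before the
    decomposition; distinct capture/sequencing batches separate on the
    leading components when gene affinities differ between them.
    """
    from sklearn.decomposition import PCA

    if rd.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    max_comp = min(rd.shape)
    if n_components > max_comp:
        logger.warning(
            "qc_pca: n_components %d clipped to %d", n_components, max_comp
        )
        n_components = max_comp
    mrd = compute_mrd(rd).to_numpy()
    scaled = rd.counts / np.where(mrd > 0, mrd, 1.0)[None, :]
    centered = scaled - scaled.mean(axis=1, keepdims=True)
    scores = PCA(n_components=n_components).fit_transform(centered.T)
    return pd.DataFrame(
        scores,
        index=rd.samples,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
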