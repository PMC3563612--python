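"""Input/output formats, run configuration and logging.

This module holds everything that is *not* science: the capture-design
(BED) reader, the read-placement and read-depth-matrix TSV formats, the
copy-number prior table, call writers (TSV + VCF 4.2) and the run
configuration with the pipeline's tunable thresholds.

Coordinate conventions: BED input is 0-based half-open; all reported
output (call tables, VCF) is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("exoncnv")

# Nominal per-gene prior probability of each copy number (CN=0..9) for an
# autosomal locus, taken from population CNV surveys.  Renormalized on load.
DEFAULT_PRIOR_TABLE: dict[int, float] = {
    0: 6.34e-4,
    1: 2.11e-3,
    2: 9.96e-1,
    3: 5.38e-4,
    4: 6.68e-4,
    5: 3.57e-5,
    6: 7.52e-6,
    7: 1.39e-6,
    8: 3.61e-7,
    9: 4.37e-8,
}


class ParseError(ValueError):
    """Raised when an input file is malformed; names the offending line."""


class ConsistencyError(ValueError):
    """Raised when an input file contradicts itself (duplicate ids etc.)."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds and switches.

    h_call / h_neighbor are posterior-probability cutoffs for standalone and
    neighbor-supported deletion calls.  Median-read-depth filters default to
    the short-read setting (30, 30); long-read (454-style) data needs the
    relaxed (5, 1).  ODF clamping bounds and the homozygous-deletion residual
    fraction parameterize the over-dispersed likelihood model.
    """

    h_call: float = 0.65
    h_neighbor: float = 0.1
    neighbor_max_distance: int = 3_000_000
    mapq_min: int = 20
    target_median_rd_min: int = 30
    sample_median_rd_min: int = 30
    r2_min: float = 0.7
    odf_min: float = 1.0
    odf_max: float = 20.0
    hom_residual_fraction: float = 0.01
    cn_max: int = 9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h_neighbor <= self.h_call < 1.0):
            raise ValueError(
                f"require 0 < h_neighbor <= h_call < 1, got "
                f"h_neighbor={self.h_neighbor}, h_call={self.h_call}"
            )
        if self.odf_min > self.odf_max:
            raise ValueError("odf_min must not exceed odf_max")
        if not (0.0 < self.hom_residual_fraction < 0.5):
            raise ValueError("hom_residual_fraction must be in (0, 0.5)")
        if self.cn_max < 2:
            raise ValueError("cn_max must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# Prior table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorTable:
    """Prior probability of each copy number, renormalized to sum to 1."""

    probs: np.ndarray  # indexed by CN, length cn_max+1

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "PriorTable":
        cn_max = max(mapping)
        probs = np.zeros(cn_max + 1)
        for cn, p in mapping.items():
            if not (0 <= cn <= cn_max):
                raise ValueError(f"copy number {cn} out of range")
            if p <= 0:
                raise ValueError(f"prior for CN={cn} must be > 0, got {p}")
            probs[cn] = p
        total = probs.sum()
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"priors sum to {total:.6f}, expected 1 within 1e-3")
        return cls(probs / total)

    @classmethod
    def default(cls) -> "PriorTable":
        return cls.from_mapping(DEFAULT_PRIOR_TABLE)

    @classmethod
    def from_file(cls, path: str | Path) -> "PriorTable":
        """Load a 2-column (CN, probability) whitespace/tab table."""
        mapping: dict[int, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns")
                try:
                    cn, p = int(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if cn in mapping:
                    raise ConsistencyError(f"{path}:{lineno}: duplicate CN {cn}")
                mapping[cn] = p
        return cls.from_mapping(mapping)

    @property
    def cn_max(self) -> int:
        return len(self.probs) - 1

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


# ---------------------------------------------------------------------------
# Capture design (targets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    name: str
    chromosome: str
    start: int  # min over exon starts, 0-based
    end: int    # max over exon ends, half-open
    exons: tuple[tuple[int, int], ...]


@dataclass
class TargetSet:
    """The capture design: genes with their exon intervals.

    Genes are ordered by (chromosome, start); this ordering defines gene
    adjacency for the neighboring-gene deletion rescue.
    """

    genes: list[Gene]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConsistencyError(f"duplicate gene names: {dupes}")
        for g in self.genes:
            if not g.exons:
                raise ValueError(f"gene {g.name} has no exons")
            for s, e in g.exons:
                if not (g.start <= s < e <= g.end):
                    raise ValueError(f"gene {g.name}: bad exon ({s}, {e})")
        self.genes.sort(key=lambda g: (g.chromosome, g.start, g.name))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_name(self) -> dict[str, Gene]:
        return {g.name: g for g in self.genes}

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                for s, e in g.exons:
                    fh.write(f"{g.chromosome}\t{s}\t{e}\t{g.name}\n")


def read_targets(path: str | Path) -> TargetSet:
    """Read a BED-style (chrom, start, end, gene) file into a TargetSet.

    Exons are grouped by gene name; each gene's span is the min/max over its
    exons.  Coordinates are 0-based half-open per BED convention.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    chroms: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, name = parts[0], parts[3]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if name in chroms and chroms[name] != chrom:
                raise ConsistencyError(
                    f"{path}:{lineno}: gene {name} on both "
                    f"{chroms[name]} and {chrom}"
                )
            chroms[name] = chrom
            exons.setdefault(name, []).append((start, end))
            n_lines += 1
    if n_lines == 0:
        logger.warning("target file %s is empty", path)
    genes = [
        Gene(
            name=name,
            chromosome=chroms[name],
            start=min(s for s, _ in ivs),
            end=max(e for _, e in ivs),
            exons=tuple(sorted(ivs)),
        )
        for name, ivs in exons.items()
    ]
    ts = TargetSet(genes)
    logger.info("read %d genes (%d exons) from %s", len(ts), n_lines, path)
    return ts


# ---------------------------------------------------------------------------
# Read placements
# ---------------------------------------------------------------------------

PLACEMENT_COLUMNS = ["sample_id", "chromosome", "pos5", "mapq", "is_duplicate"]


def read_placements(path: str | Path) -> pd.DataFrame:
    """Read a read-placement TSV: sample_id, chromosome, pos5, mapq, is_duplicate.

    pos5 is the 0-based reference position of the read's 5' base.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str})
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df[PLACEMENT_COLUMNS].copy()
    df["pos5"] = df["pos5"].astype(np.int64)
    df["mapq"] = df["mapq"].astype(np.int64)
    df["is_duplicate"] = df["is_duplicate"].astype(bool)
    if (df["pos5"] < 0).any() or (df["mapq"] < 0).any():
        raise ParseError(f"{path}: pos5 and mapq must be non-negative")
    return df


def placements_from_bam(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Optional adapter: extract placements from a BAM/SAM file via pysam.

    The 5' base is the alignment start for forward reads and the last aligned
    base for reverse reads.  The core pipeline never touches alignments
    directly; this adapter only produces the placement table.
    """
    import pysam  # deferred: alignment support is optional

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if sample_id is None:
            rgs = af.header.to_dict().get("RG", [])
            sample_id = rgs[0]["SM"] if rgs else Path(path).stem
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            pos5 = read.reference_end - 1 if read.is_reverse else read.reference_start
            rows.append(
                (sample_id, read.reference_name, pos5,
                 read.mapping_quality, read.is_duplicate)
            )
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def read_rd_matrix(path: str | Path):
    """Read a gene × sample read-depth TSV (see RDMatrix.from_tsv)."""
    from .rd_matrix import RDMatrix  # deferred: RDMatrix lives downstream

    return RDMatrix.from_tsv(path)


# ---------------------------------------------------------------------------
# Calls: TSV + VCF writers
# ---------------------------------------------------------------------------

CALL_TSV_COLUMNS = [
    "sample", "gene", "chromosome", "start", "end", "called_CN",
    "posterior", "RD_observed", "RD_expected", "neighbor_supported",
]


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    """Convert a list of GSSCall objects into the reporting table (1-based)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample,
                "gene": c.gene,
                "chromosome": c.chromosome,
                "start": c.start + 1,  # reporting is 1-based inclusive
                "end": c.end,
                "called_CN": c.called_cn,
                "posterior": c.call_posterior,
                "RD_observed": c.rd_obs,
                "RD_expected": c.rd_exp,
                "neighbor_supported": c.neighbor_supported,
            }
        )
    return pd.DataFrame(rows, columns=CALL_TSV_COLUMNS)


def write_calls(calls: Sequence, path_tsv: str | Path, path_vcf: str | Path) -> None:
    """Write finalized calls as a TSV table and a VCF 4.2 with symbolic ALTs."""
    frame = calls_to_frame(calls)
    frame.to_csv(path_tsv, sep="\t", index=False, float_format="%.6g")
    _write_vcf(calls, path_vcf)
    logger.info("wrote %d calls to %s / %s", len(frame), path_tsv, path_vcf)


def _write_vcf(calls: Sequence, path: str | Path) -> None:
    samples = sorted({c.sample for c in calls})
    chroms = []
    for c in calls:
        if c.chromosome not in chroms:
            chroms.append(c.chromosome)
    # one record per (gene, DEL/DUP); genotype columns carry CN and posterior
    grouped: dict[tuple, dict] = {}
    for c in calls:
        kind = "DEL" if c.called_cn < 2 else "DUP"
        key = (c.chromosome, c.start, c.end, c.gene, kind)
        grouped.setdefault(key, {})[c.sample] = c
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exoncnv\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        fh.write('##FORMAT=<ID=CNP,Number=1,Type=Float,'
                 'Description="Posterior probability of called CN">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + samples
        fh.write("\t".join(header) + "\n")
        for (chrom, start, end, gene, kind), per_sample in sorted(
            grouped.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][4])
        ):
            cols = [chrom, str(start + 1), gene, "N", f"<{kind}>", ".", "PASS",
                    f"END={end};SVTYPE={kind};GENE={gene}", "GT:CN:CNP"]
            for s in samples:
                c = per_sample.get(s)
                if c is None:
                    cols.append("./.:.:.")
                else:
                    post = "." if c.call_posterior is None else f"{c.call_posterior:.4f}"
                    cols.append(f"./.:{c.called_cn}:{post}")
            fh.write("\t".join(cols) + "\n")


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
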