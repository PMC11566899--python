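"""Strand collapse, quality filtering, beta values, and sample summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from methyloscope.errors import ConfigError, DataError, ValidationError
from methyloscope.io_formats import GeneModel, MethylationCountRecord

__all__ = [
    "CpGSiteMatrix",
    "FilterReport",
    "collapse_strands",
    "build_matrix",
    "apply_quality_filters",
    "mask_snps_and_chroms",
    "beta_values",
    "pairwise_spearman",
    "conversion_rate",
    "gene_metaprofile",
]


@dataclass
class CpGSiteMatrix:
    """Per-site, per-sample methylation counts for strand-collapsed CpG sites.

    ``present`` marks cells with data; a missing cell means the site was
    absent from that sample's table (never encoded as zero counts).
    """

    chroms: list[str]
    positions: np.ndarray  # (n_sites,) int
    sample_ids: list[str]
    meth: np.ndarray  # (n_sites, n_samples) int
    total: np.ndarray  # (n_sites, n_samples) int
    present: np.ndarray  # (n_sites, n_samples) bool

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        n_sites, n_samples = len(self.chroms), len(self.sample_ids)
        for name in ("meth", "total", "present"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise ValidationError(f"{name} matrix shape {arr.shape} incongruent")
        if np.any(self.meth[self.present] > self.total[self.present]):
            raise ValidationError("meth > total at a present cell")

    @property
    def n_sites(self) -> int:
        return len(self.chroms)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sites(self) -> list[tuple[str, int]]:
        return list(zip(self.chroms, self.positions.tolist()))

    def subset_sites(self, keep: np.ndarray) -> "CpGSiteMatrix":
        keep = np.asarray(keep)
        return CpGSiteMatrix(
            chroms=[c for c, k in zip(self.chroms, keep) if k],
            positions=self.positions[keep],
            sample_ids=list(self.sample_ids),
            meth=self.meth[keep],
            total=self.total[keep],
            present=self.present[keep],
        )


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_missing_removed: int
    n_low_depth_removed: int
    n_high_depth_removed: int
    n_retained: int


def collapse_strands(
    records: Sequence[MethylationCountRecord],
) -> list[MethylationCountRecord]:
    """Sum top/bottom strand counts of each CpG onto the forward-C position.

    A CpG site pairs the forward-strand C at position p with the reverse
    C at p + 1; a site seen on only one strand keeps that strand's counts.
    """
    by_pos: dict[tuple[str, int], list[int]] = {}
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        if rec.strand not in ("+", "-"):
            raise ValidationError(
                f"collapse requires stranded records, got {rec.strand!r} "
                f"at {rec.chrom}:{rec.pos}"
            )
        key = (rec.chrom, rec.pos, rec.strand)
        if key in seen:
            raise ValidationError(
                f"duplicate {rec.strand} record at {rec.chrom}:{rec.pos}"
            )
        seen.add(key)
        cpg_pos = rec.pos if rec.strand == "+" else rec.pos - 1
        if cpg_pos < 0:
            raise ValidationError(f"reverse-strand C at position 0 on {rec.chrom}")
        acc = by_pos.setdefault((rec.chrom, cpg_pos), [0, 0])
        acc[0] += rec.meth
        acc[1] += rec.total
    return [
        MethylationCountRecord(chrom=chrom, pos=pos, meth=m, total=t, strand=".")
        for (chrom, pos), (m, t) in sorted(by_pos.items())
    ]


def build_matrix(
    tables: Mapping[str, Sequence[MethylationCountRecord]],
    sample_ids: Sequence[str] | None = None,
) -> CpGSiteMatrix:
    """Assemble per-sample collapsed tables into one site x sample matrix.

    Sites are the union across samples, sorted by (chrom, pos); cells for
    (site, sample) pairs absent from a table are marked missing.
    """
    if sample_ids is None:
        sample_ids = list(tables)
    sample_ids = list(sample_ids)
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError("duplicate sample_id")
    if not sample_ids:
        raise ConfigError("need >= 1 sample")
    all_sites = sorted(
        {(r.chrom, r.pos) for sid in sample_ids for r in tables[sid]}
    )
    index = {site: i for i, site in enumerate(all_sites)}
    n_sites, n_samples = len(all_sites), len(sample_ids)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    present = np.zeros((n_sites, n_samples), dtype=bool)
    for j, sid in enumerate(sample_ids):
        for r in tables[sid]:
            i = index[(r.chrom, r.pos)]
            if present[i, j]:
                raise ValidationError(
                    f"duplicate record for sample {sid} at {r.chrom}:{r.pos}"
                )
            meth[i, j] = r.meth
            total[i, j] = r.total
            present[i, j] = True
    return CpGSiteMatrix(
        chroms=[c for c, _ in all_sites],
        positions=np.array([p for _, p in all_sites], dtype=np.int64),
        sample_ids=sample_ids,
        meth=meth,
        total=total,
        present=present,
    )


def apply_quality_filters(
    matrix: CpGSiteMatrix,
    min_depth: int = 10,
    max_depth: int = 500,
    require_all: bool = True,
) -> tuple[CpGSiteMatrix, FilterReport]:
    """Retain sites with data and min_depth <= total <= max_depth in every sample.

    Both bounds are inclusive: depths below 10 or above 500 are removed,
    depth exactly 10 or 500 is retained.
    """
    if min_depth > max_depth:
        raise ConfigError(f"min_depth {min_depth} > max_depth {max_depth}")
    present_all = matrix.present.all(axis=1)
    low = (matrix.present & (matrix.total < min_depth)).any(axis=1)
    high = (matrix.present & (matrix.total > max_depth)).any(axis=1)
    keep = present_all & ~low & ~high
    if not require_all:
        keep = ~(low | high)
    report = FilterReport(
        n_input=matrix.n_sites,
        n_missing_removed=int((~present_all).sum()) if require_all else 0,
        n_low_depth_removed=int(low.sum()),
        n_high_depth_removed=int(high.sum()),
        n_retained=int(keep.sum()),
    )
    return matrix.subset_sites(keep), report


def mask_snps_and_chroms(
    matrix: CpGSiteMatrix,
    snp_positions: Sequence[tuple[str, int]] = (),
    drop_chroms: set[str] = frozenset({"chrX"}),
) -> CpGSiteMatrix:
    """Remove sites whose C (pos) or G (pos + 1) carries a SNP, and whole chroms."""
    snps = set(snp_positions)
    keep = np.ones(matrix.n_sites, dtype=bool)
    for i, (chrom, pos) in enumerate(zip(matrix.chroms, matrix.positions.tolist())):
        if chrom in drop_chroms:
            keep[i] = False
        elif (chrom, pos) in snps or (chrom, pos + 1) in snps:
            keep[i] = False
    return matrix.subset_sites(keep)


def beta_values(matrix: CpGSiteMatrix) -> np.ndarray:
    """Beta = meth/total per present cell; missing cells are NaN."""
    if np.any(matrix.present & (matrix.total == 0)):
        raise DataError("zero total at a present cell (should be missing)")
    beta = np.full(matrix.meth.shape, np.nan)
    np.divide(matrix.meth, matrix.total, out=beta, where=matrix.present)
    return beta


def pairwise_spearman(beta: np.ndarray) -> np.ndarray:
    """Samples x samples Spearman correlation (average ranks for ties).

    Requires a complete matrix (post-filter).  A sample with zero variance
    yields NaN correlations with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[1] < 2:
        raise ConfigError("need >= 2 samples")
    if np.isnan(beta).any():
        raise DataError("beta matrix contains missing cells; filter first")
    ranks = np.apply_along_axis(sps.rankdata, 0, beta)
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("sample(s) with zero variance: correlations undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr[np.ix_(sd == 0, np.arange(beta.shape[1]))] = np.nan
    corr[np.ix_(np.arange(beta.shape[1]), sd == 0)] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def conversion_rate(non_cg_converted: int, non_cg_total: int) -> float:
    """Bisulfite conversion rate: converted / total non-CpG-context cytosines."""
    if non_cg_total <= 0:
        raise ConfigError("non_cg_total must be positive")
    if non_cg_converted > non_cg_total or non_cg_converted < 0:
        raise ValidationError("converted count outside [0, total]")
    return non_cg_converted / non_cg_total


def gene_metaprofile(
    site_chroms: Sequence[str],
    site_positions: np.ndarray,
    site_mean_beta: np.ndarray,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank_bp: int = 2000,
    flank_bins: int = 40,
) -> np.ndarray:
    """Scaled meta-profile of mean beta across gene bodies and flanks.

    Each gene body is linearly rescaled to ``body_bins``; the ``flank_bp``
    upstream/downstream flanks are split into ``flank_bins`` each.  Minus-
    strand genes are mirrored so bin 0 is always 5'.  Bin value = mean beta
    of the CpGs falling in the bin pooled across genes; empty bins are NaN.
    Genes shorter than ``body_bins`` bp are skipped with a warning.
    """
    site_positions = np.asarray(site_positions)
    site_mean_beta = np.asarray(site_mean_beta, dtype=float)
    chroms_arr = np.asarray(site_chroms, dtype=object)
    n_bins = body_bins + 2 * flank_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in genes:
        iv = gene.interval
        if len(iv) < body_bins:
            warnings.warn(f"gene {gene.gene_id} shorter than body_bins; skipped")
            continue
        lo, hi = iv.start - flank_bp, iv.end + flank_bp
        mask = (chroms_arr == iv.chrom) & (site_positions >= lo) & (site_positions < hi)
        pos = site_positions[mask]
        vals = site_mean_beta[mask]
        ok = ~np.isnan(vals)
        pos, vals = pos[ok], vals[ok]
        if pos.size == 0:
            continue
        bins = np.empty(pos.size, dtype=np.int64)
        up = pos < iv.start
        down = pos >= iv.end
        body = ~up & ~down
        bins[up] = (pos[up] - lo) * flank_bins // flank_bp
        bins[body] = flank_bins + (pos[body] - iv.start) * body_bins // len(iv)
        bins[down] = flank_bins + body_bins + (pos[down] - iv.end) * flank_bins // flank_bp
        if iv.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(sums, bins, vals)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile
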