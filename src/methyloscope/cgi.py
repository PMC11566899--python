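"""CpG-island detection, methylation classification, and feature annotation.

Detection is a deterministic seed–merge–trim scan over composition criteria
(GC ratio, CpG observed/expected ratio, minimum length).  Two printed
criteria sets are provided: the traditional composition thresholds with
strict inequalities (GC > 0.5, O/E > 0.6, length > 200 bp) and the stricter
inclusive variant (GC >= 0.55, O/E >= 0.65, length >= 500 bp).

The trim step selects, inside each merged seed cluster, the longest
sub-interval that still satisfies every threshold (leftmost on ties), so the
output is exactly reproducible by exhaustive interval enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from methyloscope.errors import ConfigError, ValidationError
from methyloscope.intervals import complement_intervals, merge_intervals, overlaps_any
from methyloscope.io_formats import GeneModel, GenomicInterval

UNMETHYLATED = "unmethylated"
LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class CgiCriteria:
    """Composition thresholds for island detection.

    ``inclusive`` selects >= comparisons for all three thresholds (and a
    minimum window of exactly ``min_length``); the default strict mode uses
    > comparisons and a minimum window of ``min_length + 1``.
    """

    min_gc: float
    min_oe: float
    min_length: int
    name: str = "custom"
    inclusive: bool = False

    def __post_init__(self):
        if not (0 < self.min_gc < 1):
            raise ConfigError("min_gc must be in (0, 1)")
        if self.min_oe <= 0:
            raise ConfigError("min_oe must be positive")
        if self.min_length < 1:
            raise ConfigError("min_length must be >= 1")

    @property
    def min_window(self) -> int:
        return self.min_length if self.inclusive else self.min_length + 1

    def passes(self, gc_ratio: float, cpg_oe: float, length: int) -> bool:
        if self.inclusive:
            return (
                gc_ratio >= self.min_gc
                and cpg_oe >= self.min_oe
                and length >= self.min_length
            )
        return (
            gc_ratio > self.min_gc and cpg_oe > self.min_oe and length > self.min_length
        )


GGF_CRITERIA = CgiCriteria(
    min_gc=0.5, min_oe=0.6, min_length=200, name="gardiner-garden-frommer"
)
TAKAI_JONES_CRITERIA = CgiCriteria(
    min_gc=0.55, min_oe=0.65, min_length=500, name="takai-jones", inclusive=True
)


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_ratio: float
    cpg_oe: float
    n_cpg: int
    mean_beta: float | None = None
    meth_class: str | None = None


def seq_stats(sequence: str) -> tuple[float, float, int]:
    """(gc_ratio, cpg_oe, n_cpg) of a sequence.

    gc_ratio = (#C + #G) / L; cpg_oe = (#CG x L) / (#C x #G), defined as 0
    when either base count is zero; n_cpg = number of CG dinucleotides.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    c = sequence.count("C")
    g = sequence.count("G")
    n_cpg = sequence.count("CG")
    length = len(sequence)
    gc_ratio = (c + g) / length
    cpg_oe = (n_cpg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return gc_ratio, cpg_oe, n_cpg


def _base_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_n, is_cpg


def _window_pass(
    c_cum, g_cum, n_cum, cpg_cum, starts: np.ndarray, length: int, criteria: CgiCriteria
) -> np.ndarray:
    """Vectorized criteria check for all windows [s, s+length)."""
    ends = starts + length
    c = c_cum[ends] - c_cum[starts]
    g = g_cum[ends] - g_cum[starts]
    n = n_cum[ends] - n_cum[starts]
    # CpG count inside the window: CG pairs starting at s .. s+length-2
    cpg = cpg_cum[ends - 1] - cpg_cum[starts]
    gc_ratio = (c + g) / length
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c > 0) & (g > 0), cpg * length / np.maximum(c * g, 1), 0.0)
    if criteria.inclusive:
        ok = (gc_ratio >= criteria.min_gc) & (oe >= criteria.min_oe)
    else:
        ok = (gc_ratio > criteria.min_gc) & (oe > criteria.min_oe)
    return ok & (n == 0)


def detect_cgis(
    genome: Mapping[str, str], criteria: CgiCriteria = GGF_CRITERIA
) -> list[CpGIsland]:
    """Scan every chromosome for islands satisfying ``criteria``.

    Seeds are all minimum-length windows passing the thresholds; overlapping
    or abutting seeds are merged into clusters; each cluster is reduced to
    its longest passing sub-interval (leftmost on ties).  Windows containing
    N are disqualified.  Output islands are disjoint and sorted.
    """
    islands: list[CpGIsland] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        w0 = criteria.min_window
        if len(seq) < w0:
            continue
        is_c, is_g, is_n, is_cpg = _base_arrays(seq)
        c_cum = np.concatenate(([0], np.cumsum(is_c)))
        g_cum = np.concatenate(([0], np.cumsum(is_g)))
        n_cum = np.concatenate(([0], np.cumsum(is_n)))
        cpg_cum = np.concatenate(([0], np.cumsum(is_cpg)))
        cums = (c_cum, g_cum, n_cum, cpg_cum)

        starts = np.arange(len(seq) - w0 + 1)
        seed_ok = _window_pass(*cums, starts, w0, criteria)
        seed_starts = starts[seed_ok]
        if len(seed_starts) == 0:
            continue
        # cluster seeds whose windows overlap or abut: gap in starts <= w0
        breaks = np.flatnonzero(np.diff(seed_starts) > w0)
        cluster_bounds = zip(
            np.concatenate(([0], breaks + 1)),
            np.concatenate((breaks, [len(seed_starts) - 1])),
        )
        for lo, hi in cluster_bounds:
            region_start = int(seed_starts[lo])
            region_end = int(seed_starts[hi]) + w0
            best = _longest_passing_subinterval(
                cums, region_start, region_end, criteria
            )
            if best is None:  # cannot happen: seeds themselves pass
                continue
            s, e = best
            sub = seq[s:e]
            gc_ratio, cpg_oe, n_cpg = seq_stats(sub)
            islands.append(
                CpGIsland(
                    interval=GenomicInterval(chrom, s, e),
                    gc_ratio=gc_ratio,
                    cpg_oe=cpg_oe,
                    n_cpg=n_cpg,
                )
            )
    return islands


def _longest_passing_subinterval(
    cums, region_start: int, region_end: int, criteria: CgiCriteria
) -> tuple[int, int] | None:
    """Longest (leftmost) sub-interval of [region_start, region_end) passing."""
    c_cum, g_cum, n_cum, cpg_cum = cums
    region_len = region_end - region_start
    for length in range(region_len, criteria.min_window - 1, -1):
        starts = np.arange(region_start, region_end - length + 1)
        ok = _window_pass(c_cum, g_cum, n_cum, cpg_cum, starts, length, criteria)
        hit = np.flatnonzero(ok)
        if len(hit):
            s = int(starts[hit[0]])
            return s, s + length
    return None


def classify_beta(mean_beta: float) -> str:
    """Methylation class from mean beta: [0,0.1) / [0.1,0.5] / (0.5,1]."""
    if not (0.0 <= mean_beta <= 1.0):
        raise ValidationError(f"mean beta {mean_beta} outside [0, 1]")
    if mean_beta < 0.1:
        return UNMETHYLATED
    if mean_beta <= 0.5:
        return LOW
    return HIGH


def classify_cgi_methylation(
    cgi: CpGIsland, site_mean_betas: Sequence[float]
) -> CpGIsland:
    """Score one island from the per-site mean betas of CpGs inside it.

    Raises ``ValidationError`` when no filtered CpG falls inside (the caller
    should flag such islands unscorable).
    """
    if len(site_mean_betas) == 0:
        raise ValidationError(
            f"no filtered CpGs inside {cgi.interval.chrom}:"
            f"{cgi.interval.start}-{cgi.interval.end}; island unscorable"
        )
    mean_beta = float(np.mean(site_mean_betas))
    return replace(cgi, mean_beta=mean_beta, meth_class=classify_beta(mean_beta))


def score_cgis(
    cgis: Sequence[CpGIsland],
    site_chroms: Sequence[str],
    site_positions: np.ndarray,
    site_mean_betas: np.ndarray,
) -> tuple[list[CpGIsland], list[CpGIsland]]:
    """Classify every island; returns (scored, unscorable)."""
    site_positions = np.asarray(site_positions)
    site_mean_betas = np.asarray(site_mean_betas, dtype=float)
    chroms_arr = np.asarray(site_chroms, dtype=object)
    scored: list[CpGIsland] = []
    unscorable: list[CpGIsland] = []
    for cgi in cgis:
        mask = (
            (chroms_arr == cgi.interval.chrom)
            & (site_positions >= cgi.interval.start)
            & (site_positions < cgi.interval.end)
        )
        betas = site_mean_betas[mask]
        if betas.size == 0:
            unscorable.append(cgi)
        else:
            scored.append(classify_cgi_methylation(cgi, betas))
    return scored, unscorable


@dataclass
class FeatureCatalog:
    """Named interval collections; 'others' is the complement of their union."""

    promoters: list[GenomicInterval]
    gene_bodies: list[GenomicInterval]
    cgis: list[GenomicInterval]
    shores: list[GenomicInterval]
    shelves: list[GenomicInterval]
    ctcf_sites: list[GenomicInterval]
    repeats: list[GenomicInterval]
    others: list[GenomicInterval]

    def items(self) -> list[tuple[str, list[GenomicInterval]]]:
        return [
            ("promoter", self.promoters),
            ("gene_body", self.gene_bodies),
            ("cgi", self.cgis),
            ("cgi_shore", self.shores),
            ("cgi_shelf", self.shelves),
            ("ctcf", self.ctcf_sites),
            ("repeat", self.repeats),
            ("others", self.others),
        ]


def _clip(chrom: str, start: int, end: int, size: int) -> GenomicInterval | None:
    start = max(0, start)
    end = min(size, end)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end)


def build_feature_catalog(
    genes: Sequence[GeneModel],
    cgis: Sequence[GenomicInterval],
    ctcf: Sequence[GenomicInterval],
    repeats: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    promoter_bp: int = 1500,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> FeatureCatalog:
    """Derive promoters/shores/shelves and the residual 'others' partition.

    Promoter of a + gene [s, e) is [s - promoter_bp, s); of a - gene,
    [e, e + promoter_bp).  Shores are the 0-``shore_bp`` flanks outside each
    island (island bases excluded), shelves the next ``shelf_bp``.  All
    intervals are clipped to chromosome bounds; features may overlap each
    other, and 'others' is the complement of their union.
    """
    promoters: list[GenomicInterval] = []
    gene_bodies: list[GenomicInterval] = []
    for gene in genes:
        iv = gene.interval
        size = chrom_sizes[iv.chrom]
        gene_bodies.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        if iv.strand == "+":
            prom = _clip(iv.chrom, iv.start - promoter_bp, iv.start, size)
        else:
            prom = _clip(iv.chrom, iv.end, iv.end + promoter_bp, size)
        if prom is not None:
            promoters.append(prom)

    cgi_union = merge_intervals(cgis) if cgis else []
    shores: list[GenomicInterval] = []
    shelves: list[GenomicInterval] = []
    for cgi in cgis:
        size = chrom_sizes[cgi.chrom]
        for s, e in (
            (cgi.start - shore_bp, cgi.start),
            (cgi.end, cgi.end + shore_bp),
        ):
            iv = _clip(cgi.chrom, s, e, size)
            if iv is not None:
                shores.append(iv)
        for s, e in (
            (cgi.start - shore_bp - shelf_bp, cgi.start - shore_bp),
            (cgi.end + shore_bp, cgi.end + shore_bp + shelf_bp),
        ):
            iv = _clip(cgi.chrom, s, e, size)
            if iv is not None:
                shelves.append(iv)
    shores = _subtract(shores, cgi_union, chrom_sizes)
    shelves = _subtract(shelves, cgi_union, chrom_sizes)

    listed = (
        promoters
        + gene_bodies
        + list(cgis)
        + shores
        + shelves
        + list(ctcf)
        + list(repeats)
    )
    others = complement_intervals(listed, chrom_sizes) if listed else [
        GenomicInterval(c, 0, s) for c, s in sorted(chrom_sizes.items())
    ]
    return FeatureCatalog(
        promoters=promoters,
        gene_bodies=gene_bodies,
        cgis=[GenomicInterval(iv.chrom, iv.start, iv.end) for iv in cgis],
        shores=shores,
        shelves=shelves,
        ctcf_sites=list(ctcf),
        repeats=list(repeats),
        others=others,
    )


def _subtract(
    intervals: Iterable[GenomicInterval],
    remove: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
) -> list[GenomicInterval]:
    """Set difference intervals minus the union of ``remove``."""
    if not remove:
        return merge_intervals(intervals)
    keep_region = complement_intervals(remove, chrom_sizes)
    out: list[GenomicInterval] = []
    for iv in merge_intervals(intervals):
        for kr in keep_region:
            if kr.chrom != iv.chrom:
                continue
            s = max(iv.start, kr.start)
            e = min(iv.end, kr.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out, key=lambda x: (x.chrom, x.start))


def gene_end_cgi_presence(
    genes: Sequence[GeneModel],
    cgis: Sequence[GenomicInterval],
    window_bp: int = 2000,
) -> dict[str, bool]:
    """Per gene: does any island overlap the strand-resolved 3' end window.

    The window is [gene_end - window_bp, gene_end + window_bp) where gene_end
    is ``end`` for + genes and ``start`` for - genes.
    """
    windows = []
    for gene in genes:
        iv = gene.interval
        end3 = iv.end if iv.strand == "+" else iv.start
        windows.append(
            GenomicInterval(iv.chrom, max(0, end3 - window_bp), end3 + window_bp)
        )
    hits = overlaps_any(windows, list(cgis)) if cgis else np.zeros(len(genes), bool)
    return {gene.gene_id: bool(hit) for gene, hit in zip(genes, hits)}
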