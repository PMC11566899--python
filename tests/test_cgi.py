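import numpy as np
import pytest

from methyloscope.cgi import (
    GGF_CRITERIA,
    HIGH,
    LOW,
    TAKAI_JONES_CRITERIA,
    UNMETHYLATED,
    CgiCriteria,
    CpGIsland,
    build_feature_catalog,
    classify_beta,
    classify_cgi_methylation,
    detect_cgis,
    gene_end_cgi_presence,
    score_cgis,
    seq_stats,
)
from methyloscope.errors import ValidationError
from methyloscope.intervals import merge_intervals
from methyloscope.io_formats import GeneModel, GenomicInterval


# ---------------------------------------------------------------- oracle
def _oracle_passes(sub: str, criteria: CgiCriteria) -> bool:
    """Independent criteria check by direct string counting."""
    if "N" in sub:
        return False
    c, g = sub.count("C"), sub.count("G")
    ncpg = sub.count("CG")
    L = len(sub)
    gc = (c + g) / L
    oe = (ncpg * L) / (c * g) if c and g else 0.0
    if criteria.inclusive:
        return gc >= criteria.min_gc and oe >= criteria.min_oe and L >= criteria.min_length
    return gc > criteria.min_gc and oe > criteria.min_oe and L > criteria.min_length


def brute_force_islands(seq: str, criteria: CgiCriteria) -> list[tuple[int, int]]:
    """Exhaustive seed enumeration + cluster + maximal-subinterval search."""
    w0 = criteria.min_window
    seeds = [s for s in range(len(seq) - w0 + 1)
             if _oracle_passes(seq[s : s + w0], criteria)]
    if not seeds:
        return []
    clusters: list[list[int]] = [[seeds[0]]]
    for s in seeds[1:]:
        if s - clusters[-1][-1] <= w0:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    out = []
    for cl in clusters:
        lo, hi = cl[0], cl[-1] + w0
        found = None
        for length in range(hi - lo, w0 - 1, -1):
            for start in range(lo, hi - length + 1):
                if _oracle_passes(seq[start : start + length], criteria):
                    found = (start, start + length)
                    break
            if found:
                break
        out.append(found)
    return out


class TestSeqStats:
    def test_cg_repeats(self):
        gc, oe, n = seq_stats("CGCGCG")
        assert (gc, n) == (1.0, 3)
        assert oe == pytest.approx(2.0)

    def test_at_only(self):
        gc, oe, n = seq_stats("ATATAT")
        assert (gc, oe, n) == (0.0, 0.0, 0)

    def test_gc_repeats(self):
        gc, oe, n = seq_stats("GCGCGC")
        assert n == 2
        assert oe == pytest.approx(2 * 6 / 9)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            seq_stats("")


class TestDetect:
    def test_single_cg_block(self):
        # a 300 bp CG block flanked by AT: thresholds tolerate AT dilution up
        # to 50% GC, so the maximal island is the block plus symmetric flank
        # inside the seed cluster [900, 1400) — matching the oracle exactly
        seq = "AT" * 500 + "CG" * 150 + "AT" * 500
        islands = detect_cgis({"chr1": seq}, GGF_CRITERIA)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.interval.start <= 1000 and isl.interval.end >= 1300
        assert [(isl.interval.start, isl.interval.end)] == brute_force_islands(
            seq, GGF_CRITERIA
        )

    def test_too_short_for_takai_jones(self):
        # 220 bp CG block: even maximally diluted (220/0.55 = 400 bp) it can
        # never reach the 500 bp floor, so only the lenient criteria fire
        seq = "AT" * 500 + "CG" * 110 + "AT" * 500
        assert detect_cgis({"chr1": seq}, GGF_CRITERIA)
        assert detect_cgis({"chr1": seq}, TAKAI_JONES_CRITERIA) == []

    def test_islands_satisfy_criteria_when_rescored(self, small_genome):
        genome, _ = small_genome
        for criteria in (GGF_CRITERIA, TAKAI_JONES_CRITERIA):
            for isl in detect_cgis(genome, criteria):
                seq = genome[isl.interval.chrom][isl.interval.start : isl.interval.end]
                gc, oe, _ = seq_stats(seq)
                assert criteria.passes(gc, oe, len(seq))

    def test_n_disqualifies(self):
        core = "CG" * 150
        seq = "AT" * 500 + core[:140] + "N" + core[141:] + "AT" * 500
        islands = detect_cgis({"chr1": seq}, GGF_CRITERIA)
        for isl in islands:
            sub = seq[isl.interval.start : isl.interval.end]
            assert "N" not in sub

    def test_reverse_complement_mirror(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 1500, p=[0.2, 0.3, 0.3, 0.2]))
            rc = seq.translate(comp)[::-1]
            fwd = detect_cgis({"c": seq}, GGF_CRITERIA)
            rev = detect_cgis({"c": rc}, GGF_CRITERIA)
            L = len(seq)
            mirrored = sorted(
                (L - i.interval.end, L - i.interval.start) for i in fwd
            )
            got = sorted((i.interval.start, i.interval.end) for i in rev)
            assert got == mirrored

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            seq = "".join(rng.choice(list("ACGT"), 1200,
                                     p=[0.22, 0.28, 0.28, 0.22]))
            expected = brute_force_islands(seq, GGF_CRITERIA)
            got = [(i.interval.start, i.interval.end)
                   for i in detect_cgis({"c": seq}, GGF_CRITERIA)]
            assert got == expected


class TestClassification:
    @pytest.mark.parametrize("beta,expected", [
        (0.05, UNMETHYLATED), (0.0, UNMETHYLATED), (0.0999, UNMETHYLATED),
        (0.10, LOW), (0.3, LOW), (0.50, LOW),
        (0.51, HIGH), (1.0, HIGH),
    ])
    def test_thresholds(self, beta, expected):
        assert classify_beta(beta) == expected

    def test_classify_island(self):
        isl = CpGIsland(GenomicInterval("chr1", 0, 300), 0.6, 0.8, 20)
        scored = classify_cgi_methylation(isl, [0.02, 0.04, 0.09])
        assert scored.meth_class == UNMETHYLATED
        assert scored.mean_beta == pytest.approx(0.05)

    def test_no_cpgs_unscorable(self):
        isl = CpGIsland(GenomicInterval("chr1", 0, 300), 0.6, 0.8, 20)
        with pytest.raises(ValidationError, match="unscorable"):
            classify_cgi_methylation(isl, [])

    def test_score_cgis_splits_unscorable(self):
        islands = [
            CpGIsland(GenomicInterval("chr1", 0, 100), 0.6, 0.8, 5),
            CpGIsland(GenomicInterval("chr1", 500, 600), 0.6, 0.8, 5),
        ]
        scored, unscorable = score_cgis(
            islands, ["chr1", "chr1"], np.array([50, 60]), np.array([0.7, 0.9])
        )
        assert len(scored) == 1 and scored[0].meth_class == HIGH
        assert len(unscorable) == 1


class TestFeatureCatalog:
    def test_promoter_plus_strand(self):
        genes = [GeneModel(GenomicInterval("chr1", 5000, 8000, "+"), "g1")]
        cat = build_feature_catalog(genes, [], [], [], {"chr1": 20000})
        assert [(p.start, p.end) for p in cat.promoters] == [(3500, 5000)]

    def test_promoter_minus_strand(self):
        genes = [GeneModel(GenomicInterval("chr1", 5000, 8000, "-"), "g1")]
        cat = build_feature_catalog(genes, [], [], [], {"chr1": 20000})
        assert [(p.start, p.end) for p in cat.promoters] == [(8000, 9500)]

    def test_shores_and_shelves(self):
        cgi = GenomicInterval("chr1", 10000, 11000)
        genes = [GeneModel(GenomicInterval("chr1", 100, 200, "+"), "g")]
        cat = build_feature_catalog(genes, [cgi], [], [], {"chr1": 30000})
        assert sorted((s.start, s.end) for s in cat.shores) == [
            (8000, 10000), (11000, 13000),
        ]
        assert sorted((s.start, s.end) for s in cat.shelves) == [
            (6000, 8000), (13000, 15000),
        ]

    def test_others_is_complement(self):
        genes = [GeneModel(GenomicInterval("chr1", 0, 30000, "+"), "g")]
        cat = build_feature_catalog(genes, [], [], [], {"chr1": 30000})
        assert cat.others == []

    def test_others_covers_residual(self):
        genes = [GeneModel(GenomicInterval("chr1", 2000, 3000, "+"), "g")]
        cat = build_feature_catalog(genes, [], [], [], {"chr1": 5000})
        union = merge_intervals(
            [x for _, ivs in cat.items() for x in ivs]
        )
        assert [(u.start, u.end) for u in union] == [(0, 5000)]


class TestGeneEnd:
    def test_minus_strand_resolves_start(self):
        gene = GeneModel(GenomicInterval("chr1", 5000, 8000, "-"), "g")
        cgi = GenomicInterval("chr1", 4500, 4800)
        assert gene_end_cgi_presence([gene], [cgi], 2000) == {"g": True}

    def test_no_cgis_all_false(self):
        gene = GeneModel(GenomicInterval("chr1", 5000, 8000, "+"), "g")
        assert gene_end_cgi_presence([gene], []) == {"g": False}

    def test_half_open_boundary(self):
        gene = GeneModel(GenomicInterval("chr1", 5000, 8000, "+"), "g")
        # window is [6000, 10000); an island starting exactly at 10000 misses
        cgi = GenomicInterval("chr1", 10000, 10500)
        assert gene_end_cgi_presence([gene], [cgi], 2000) == {"g": False}
        cgi2 = GenomicInterval("chr1", 9999, 10500)
        assert gene_end_cgi_presence([gene], [cgi2], 2000) == {"g": True}
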