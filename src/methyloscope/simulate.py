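"""Synthetic genomes, methylomes, and annotations with known ground truth.

The generator plants CpG-rich islands on a CpG-depleted background, then
simulates per-sample beta-binomial methylation counts with optional planted
breed effects, high-variance loci, and age-correlated loci.  All randomness
flows from a single seed through named substreams (genome / counts /
annotations), so each stage can be regenerated independently and every
output is deterministic given the config.

Planted effects can be declared explicitly as intervals, or requested as
counts (``n_auto_*``), in which case whole planted islands are assigned the
role so that the affected CpGs are dense enough to merge into regions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from methyloscope.cgi import seq_stats
from methyloscope.errors import ConfigError
from methyloscope.io_formats import (
    GeneModel,
    GenomicInterval,
    MethylationCountRecord,
    RepeatAnnotation,
    SampleMetadata,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedDmr:
    chrom: str
    start: int
    end: int
    breed_offsets: Mapping[str, float]


@dataclass(frozen=True)
class PlantedVariableLocus:
    chrom: str
    start: int
    end: int
    beta_sd: float


@dataclass(frozen=True)
class PlantedAgeLocus:
    chrom: str
    start: int
    end: int
    slope_per_year: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 100_000
    background_gc: float = 0.42
    background_cpg_rate: float = 0.005
    n_cgis: int = 6
    cgi_length_range: tuple[int, int] = (600, 1200)
    cgi_gc: float = 0.65
    cgi_oe: float = 0.75
    cgi_spacing: int = 4000
    n_samples_per_breed: Mapping[str, int] = field(
        default_factory=lambda: {"breedA": 3, "breedB": 3, "breedC": 3}
    )
    mean_depth: float = 50.0
    depth_overdispersion: float = 0.2
    beta_precision: float = 60.0  # beta-binomial concentration; inf = binomial
    background_beta: float = 0.8
    cgi_beta: float = 0.05
    cgi_meth_fraction: float = 0.0  # fraction of islands kept methylated
    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    planted_variable_loci: list[PlantedVariableLocus] = field(default_factory=list)
    planted_age_loci: list[PlantedAgeLocus] = field(default_factory=list)
    n_auto_dmrs: int = 0
    auto_dmr_offset: float = 0.4
    n_auto_variable_loci: int = 0
    auto_variable_sd: float = 0.25
    auto_variable_base_beta: float = 0.5
    n_auto_age_loci: int = 0
    auto_age_slope: float = 0.02
    auto_age_base_beta: float = 0.1
    snp_rate: float = 0.0
    fraction_snps_on_cpg: float = 0.5
    n_genes: int = 5
    gene_length_range: tuple[int, int] = (2000, 8000)
    repeat_subfamilies: list[str] = field(default_factory=lambda: ["SINEC", "MIR"])
    n_repeats_per_subfamily: int = 20
    repeat_length_range: tuple[int, int] = (100, 300)
    enriched_subfamily: str | None = None
    enriched_fraction: float = 0.8  # members placed inside methylated islands
    n_ctcf: int = 10
    age_range: tuple[float, float] = (3.0, 14.0)
    injury_fraction: float = 0.0

    def __post_init__(self):
        for name in (
            "background_gc", "background_cpg_rate", "cgi_gc", "snp_rate",
            "fraction_snps_on_cpg", "cgi_meth_fraction", "background_beta",
            "cgi_beta", "injury_fraction", "enriched_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigError("genome dimensions must be positive")
        if self.cgi_length_range[0] > self.cgi_length_range[1]:
            raise ConfigError("bad cgi_length_range")
        n_roles = self.n_auto_dmrs + self.n_auto_variable_loci + self.n_auto_age_loci
        if n_roles > self.n_cgis * self.n_chroms:
            raise ConfigError(
                f"{n_roles} auto-planted effects need at most "
                f"{self.n_cgis * self.n_chroms} islands"
            )
        if not self.n_samples_per_breed:
            raise ConfigError("need at least one breed")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key, typ in (
            ("planted_dmrs", PlantedDmr),
            ("planted_variable_loci", PlantedVariableLocus),
            ("planted_age_loci", PlantedAgeLocus),
        ):
            if key in data:
                data[key] = [
                    typ(**d) if isinstance(d, dict) else d for d in data[key]
                ]
        for key in ("cgi_length_range", "gene_length_range",
                    "repeat_length_range", "age_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    true_cgis: list[GenomicInterval] = field(default_factory=list)
    cgi_base_beta: list[float] = field(default_factory=list)
    true_dmrs: list[PlantedDmr] = field(default_factory=list)
    true_variable_regions: list[PlantedVariableLocus] = field(default_factory=list)
    true_age_regions: list[PlantedAgeLocus] = field(default_factory=list)
    snp_positions: list[tuple[str, int]] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatAnnotation] = field(default_factory=list)
    ctcf_sites: list[GenomicInterval] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval) -> dict:
            return {"chrom": i.chrom, "start": i.start, "end": i.end,
                    "strand": i.strand}

        payload = {
            "true_cgis": [iv(i) for i in self.true_cgis],
            "cgi_base_beta": self.cgi_base_beta,
            "true_dmrs": [dataclasses.asdict(d) for d in self.true_dmrs],
            "true_variable_regions": [
                dataclasses.asdict(d) for d in self.true_variable_regions
            ],
            "true_age_regions": [dataclasses.asdict(d) for d in self.true_age_regions],
            "snp_positions": [list(s) for s in self.snp_positions],
            "gene_models": [
                {"gene_id": g.gene_id, **iv(g.interval)} for g in self.gene_models
            ],
            "repeats": [
                {"subfamily": r.subfamily, "class_family": r.class_family,
                 **iv(r.interval)}
                for r in self.repeats
            ],
            "ctcf_sites": [iv(i) for i in self.ctcf_sites],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _substream(config: SimulationConfig, channel: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, channel)))


def _random_sequence(
    rng: np.random.Generator, length: int, gc: float, cpg_rate: float | None
) -> np.ndarray:
    """IID draw at the given GC, with CpG dinucleotides thinned to cpg_rate."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    if cpg_rate is not None:
        iid_rate = (gc / 2) ** 2
        keep_prob = min(1.0, cpg_rate / iid_rate) if iid_rate > 0 else 1.0
        is_cpg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        hits = np.flatnonzero(is_cpg)
        drop = hits[rng.random(hits.size) >= keep_prob]
        # break the pair by swapping the G for A/T (cannot create a new CpG)
        arr[drop + 1] = np.where(rng.random(drop.size) < 0.5, ord("A"), ord("T"))
    return arr


def _island_sequence(
    rng: np.random.Generator, length: int, gc: float, oe: float
) -> np.ndarray:
    """Rejection-sample an island whose realized GC and O/E meet the targets."""
    for _ in range(500):
        cand = _random_sequence(rng, length, min(0.95, gc + 0.04), None)
        seq = cand.tobytes().decode("ascii")
        got_gc, got_oe, _ = seq_stats(seq)
        if got_gc >= gc and got_oe >= oe:
            return cand
    raise ConfigError(
        f"could not realize an island with GC >= {gc} and O/E >= {oe}"
    )


def _place_islands(
    rng: np.random.Generator, chrom_len: int, lengths: list[int], spacing: int
) -> list[int]:
    """Non-overlapping starts, pairwise gaps and edge margins >= spacing."""
    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    for length in lengths:
        lo, hi = spacing, chrom_len - length - spacing
        if hi <= lo:
            raise ConfigError("chromosome too short for island placement")
        for _ in range(1000):
            s = int(rng.integers(lo, hi))
            if all(
                s + length + spacing <= ps or ps + pl + spacing <= s
                for ps, pl in placed
            ):
                placed.append((s, length))
                starts.append(s)
                break
        else:
            raise ConfigError(
                f"cannot place {len(lengths)} islands with spacing {spacing}"
            )
    return starts


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], GroundTruth]:
    """Build the genome and record planted islands and their assigned effects."""
    rng = _substream(config, 0)
    genome: dict[str, str] = {}
    truth = GroundTruth(
        true_dmrs=list(config.planted_dmrs),
        true_variable_regions=list(config.planted_variable_loci),
        true_age_regions=list(config.planted_age_loci),
    )
    breeds = sorted(config.n_samples_per_breed)
    all_islands: list[GenomicInterval] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _random_sequence(
            rng, config.chrom_length, config.background_gc, config.background_cpg_rate
        )
        if config.n_cgis > 0:
            lengths = [
                int(rng.integers(config.cgi_length_range[0],
                                 config.cgi_length_range[1] + 1))
                for _ in range(config.n_cgis)
            ]
            starts = _place_islands(
                rng, config.chrom_length, lengths, config.cgi_spacing
            )
            for s, length in sorted(zip(starts, lengths)):
                arr[s : s + length] = _island_sequence(
                    rng, length, config.cgi_gc, config.cgi_oe
                )
                all_islands.append(GenomicInterval(chrom, s, s + length))
        genome[chrom] = arr.tobytes().decode("ascii")

    # assign island roles: dmr / variable / age / plain, then base betas
    order = rng.permutation(len(all_islands))
    cursor = 0
    roles = ["plain"] * len(all_islands)
    for role, count in (
        ("dmr", config.n_auto_dmrs),
        ("variable", config.n_auto_variable_loci),
        ("age", config.n_auto_age_loci),
    ):
        for _ in range(count):
            roles[order[cursor]] = role
            cursor += 1
    plain = [i for i in range(len(all_islands)) if roles[i] == "plain"]
    n_meth = int(round(config.cgi_meth_fraction * len(plain)))
    methylated = set(rng.permutation(plain)[:n_meth].tolist()) if plain else set()

    for i, island in enumerate(all_islands):
        role = roles[i]
        if role == "dmr":
            base = config.cgi_beta
            offsets = {b: 0.0 for b in breeds}
            offsets[breeds[int(rng.integers(len(breeds)))]] = config.auto_dmr_offset
            truth.true_dmrs.append(
                PlantedDmr(island.chrom, island.start, island.end, offsets)
            )
        elif role == "variable":
            base = config.auto_variable_base_beta
            truth.true_variable_regions.append(
                PlantedVariableLocus(
                    island.chrom, island.start, island.end, config.auto_variable_sd
                )
            )
        elif role == "age":
            base = config.auto_age_base_beta
            truth.true_age_regions.append(
                PlantedAgeLocus(
                    island.chrom, island.start, island.end, config.auto_age_slope
                )
            )
        else:
            base = config.background_beta if i in methylated else config.cgi_beta
        truth.true_cgis.append(island)
        truth.cgi_base_beta.append(base)
    return genome, truth


def cpg_positions(genome: Mapping[str, str]) -> list[tuple[str, int]]:
    """Forward-strand positions of every CG dinucleotide."""
    out: list[tuple[str, int]] = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        out.extend((chrom, int(p)) for p in hits)
    return out


def make_sample_metadata(config: SimulationConfig) -> list[SampleMetadata]:
    rng = _substream(config, 3)
    samples: list[SampleMetadata] = []
    k = 0
    for breed in sorted(config.n_samples_per_breed):
        for i in range(config.n_samples_per_breed[breed]):
            age = float(
                np.round(rng.uniform(config.age_range[0], config.age_range[1]), 1)
            )
            samples.append(
                SampleMetadata(
                    sample_id=f"{breed}_{i + 1}",
                    breed=breed,
                    sex="M" if k % 2 == 0 else "F",
                    neutered=bool(rng.integers(2)),
                    age_years=age,
                    condition="injured"
                    if rng.random() < config.injury_fraction
                    else "healthy",
                )
            )
            k += 1
    return samples


def true_beta_matrix(
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    samples: Sequence[SampleMetadata],
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Noise-free per-site, per-sample methylation means (clipped to [0, 1])."""
    sites = cpg_positions(genome)
    chroms = np.asarray([c for c, _ in sites], dtype=object)
    pos = np.array([p for _, p in sites])
    n_sites, n_samples = len(sites), len(samples)
    base = np.full(n_sites, config.background_beta)
    for island, b in zip(truth.true_cgis, truth.cgi_base_beta):
        mask = (chroms == island.chrom) & (pos >= island.start) & (pos < island.end)
        base[mask] = b
    beta = np.tile(base[:, None], (1, n_samples))
    for dmr in truth.true_dmrs:
        mask = (chroms == dmr.chrom) & (pos >= dmr.start) & (pos < dmr.end)
        for j, s in enumerate(samples):
            beta[mask, j] += dmr.breed_offsets.get(s.breed, 0.0)
    for locus in truth.true_age_regions:
        mask = (chroms == locus.chrom) & (pos >= locus.start) & (pos < locus.end)
        for j, s in enumerate(samples):
            beta[mask, j] += locus.slope_per_year * s.age_years
    if rng is not None:
        for locus in truth.true_variable_regions:
            mask = (chroms == locus.chrom) & (pos >= locus.start) & (pos < locus.end)
            shift = rng.normal(0.0, locus.beta_sd, size=n_samples)
            beta[mask] += shift[None, :]
    return sites, np.clip(beta, 0.0, 1.0)


def simulate_count_matrix(
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray, list[SampleMetadata]]:
    """(sites, meth, total, samples) without materializing per-record objects.

    Depth is negative-binomial around ``mean_depth`` (Poisson when
    ``depth_overdispersion`` is 0); methylated counts are beta-binomial with
    concentration ``beta_precision`` (pure binomial when infinite).
    """
    samples = make_sample_metadata(config)
    rng = _substream(config, 1)
    sites, beta = true_beta_matrix(genome, truth, config, samples, rng=rng)
    n_sites, n_samples = beta.shape
    if config.depth_overdispersion > 0:
        size = 1.0 / config.depth_overdispersion
        depth = rng.negative_binomial(
            size, size / (size + config.mean_depth), size=(n_sites, n_samples)
        )
    else:
        depth = rng.poisson(config.mean_depth, size=(n_sites, n_samples))
    if math.isinf(config.beta_precision):
        p = beta
    else:
        prec = config.beta_precision
        a = np.clip(beta, 1e-9, None) * prec
        b = np.clip(1.0 - beta, 1e-9, None) * prec
        p = rng.beta(a, b)
        p[beta <= 0.0] = 0.0
        p[beta >= 1.0] = 1.0
    meth = rng.binomial(depth, p)
    return sites, meth, depth, samples


def simulate_methylomes(
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, list[MethylationCountRecord]], list[SampleMetadata]]:
    """Per-sample collapsed count tables plus sample metadata.

    Zero-depth sites are omitted from a sample's table (missing, not 0/0).
    """
    sites, meth, depth, samples = simulate_count_matrix(genome, truth, config)
    n_sites = len(sites)
    tables: dict[str, list[MethylationCountRecord]] = {}
    for j, s in enumerate(samples):
        recs = [
            MethylationCountRecord(
                chrom=sites[i][0], pos=sites[i][1],
                meth=int(meth[i, j]), total=int(depth[i, j]),
            )
            for i in range(n_sites)
            if depth[i, j] > 0
        ]
        tables[s.sample_id] = recs
    return tables, samples


def random_sequences(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    gc: float,
    cpg_oe: float,
) -> list[str]:
    """IID-composition sequences whose expected GC and CpG O/E hit the targets.

    The CpG rate is thinned to ``cpg_oe x (gc/2)^2`` so the realized
    observed/expected ratio fluctuates around ``cpg_oe``.
    """
    rate = cpg_oe * (gc / 2) ** 2
    return [
        _random_sequence(
            rng, int(rng.integers(length_range[0], length_range[1] + 1)), gc, rate
        ).tobytes().decode("ascii")
        for _ in range(n)
    ]


def simulate_annotations(
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> GroundTruth:
    """Place genes, repeats, CTCF sites, and SNPs; updates and returns truth."""
    rng = _substream(config, 2)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    chrom_names = sorted(chrom_sizes)

    # genes: non-overlapping; where possible anchor the 3' end near an island
    genes: list[GeneModel] = []
    occupied: list[tuple[str, int, int]] = []
    islands = list(truth.true_cgis)
    for gi in range(config.n_genes):
        length = int(
            rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        if gi < len(islands):  # anchor some genes' 3' ends at planted islands
            isl = islands[gi]
            if strand == "+":
                start, end = isl.start - length + len(isl) // 2, isl.start + len(isl) // 2
            else:
                start, end = isl.end - len(isl) // 2, isl.end + length - len(isl) // 2
            if 0 <= start < end <= chrom_sizes[isl.chrom]:
                chrom = isl.chrom
                placed = True
        if not placed:
            for _ in range(200):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                if chrom_sizes[chrom] <= length + 2:
                    continue
                start = int(rng.integers(0, chrom_sizes[chrom] - length))
                end = start + length
                if all(
                    c != chrom or end <= s or e <= start for c, s, e in occupied
                ):
                    placed = True
                    break
        if not placed:
            continue
        occupied.append((chrom, start, end))
        genes.append(
            GeneModel(
                interval=GenomicInterval(chrom, start, end, strand),
                gene_id=f"gene{gi + 1:04d}",
            )
        )
    truth.gene_models = genes

    # repeats: random placement; the designated subfamily prefers methylated islands
    meth_islands = [
        iv for iv, b in zip(truth.true_cgis, truth.cgi_base_beta) if b > 0.5
    ]
    repeats: list[RepeatAnnotation] = []
    for sub in config.repeat_subfamilies:
        for ri in range(config.n_repeats_per_subfamily):
            length = int(
                rng.integers(
                    config.repeat_length_range[0], config.repeat_length_range[1] + 1
                )
            )
            if (
                sub == config.enriched_subfamily
                and meth_islands
                and rng.random() < config.enriched_fraction
            ):
                isl = meth_islands[int(rng.integers(len(meth_islands)))]
                start = int(rng.integers(isl.start, max(isl.start + 1, isl.end - length)))
                chrom = isl.chrom
            else:
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
            repeats.append(
                RepeatAnnotation(
                    interval=GenomicInterval(chrom, start, start + length),
                    subfamily=sub,
                    class_family=sub.split("-")[0],
                )
            )
    truth.repeats = repeats

    ctcf: list[GenomicInterval] = []
    for _ in range(config.n_ctcf):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - 20)))
        ctcf.append(GenomicInterval(chrom, start, start + 20))
    truth.ctcf_sites = ctcf

    # SNPs: snp_rate per bp; a set fraction lands on CpG dinucleotide bases
    snps: set[tuple[str, int]] = set()
    total_len = sum(chrom_sizes.values())
    n_snps = int(round(config.snp_rate * total_len))
    if n_snps > 0:
        cpgs = cpg_positions(genome)
        n_on_cpg = int(round(config.fraction_snps_on_cpg * n_snps))
        n_on_cpg = min(n_on_cpg, len(cpgs))
        if n_on_cpg > 0:
            picks = rng.choice(len(cpgs), size=n_on_cpg, replace=False)
            for k in picks:
                chrom, p = cpgs[int(k)]
                snps.add((chrom, p + int(rng.integers(2))))  # C or G of the pair
        while len(snps) < n_snps:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            snps.add((chrom, int(rng.integers(chrom_sizes[chrom]))))
    truth.snp_positions = sorted(snps)
    return truth
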