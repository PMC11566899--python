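"""Enrichment statistics: genomic features, repeat subfamilies, gene sets.

Feature enrichment of high-SD CpGs uses an exact binomial test against the
background proportion of eligible sites in the feature (two-sided via the
doubled smaller tail, direction reported).  Repeat-subfamily enrichment
within island methylation classes uses a one-tailed (upper) binomial test
with BH adjustment, omitting subfamilies overlapping fewer than 100 islands.
Gene-set over-representation is the hypergeometric upper tail with BH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from methyloscope.cgi import CpGIsland, FeatureCatalog
from methyloscope.errors import ConfigError, ValidationError
from methyloscope.intervals import (
    interval_overlap,
    overlaps_any,
    points_in_intervals,
)
from methyloscope.io_formats import GenomicInterval, RepeatAnnotation
from methyloscope.regions import bh_fdr

__all__ = [
    "EnrichmentResult",
    "feature_enrichment",
    "repeat_class_enrichment",
    "gene_set_enrichment",
    "interval_overlap",
    "binom_two_sided",
]


@dataclass(frozen=True)
class EnrichmentResult:
    feature_or_set: str
    observed: int
    expected: float
    obs_exp_ratio: float
    p_value: float
    q_value: float | None
    direction: str  # 'over' or 'under'


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p as the doubled smaller tail, capped at 1."""
    upper = sps.binom.sf(k - 1, n, p0)  # P(X >= k)
    lower = sps.binom.cdf(k, n, p0)  # P(X <= k)
    return float(min(1.0, 2 * min(upper, lower)))


def feature_enrichment(
    high_sd_sites: Sequence[tuple[str, int]],
    all_eligible_sites: Sequence[tuple[str, int]],
    catalog: FeatureCatalog,
    two_sided: bool = True,
    rng: np.random.Generator | None = None,
    n_resamples: int = 0,
) -> list[EnrichmentResult]:
    """Per feature: is the high-SD set over/under-represented vs eligible sites.

    Background p0 = (#eligible in feature) / (#eligible); observed = #high-SD
    in feature; expected = p0 x #high-SD.  With ``n_resamples > 0`` the
    p-value is instead estimated by drawing random site sets of the same size
    from the eligible pool (add-one estimator).
    """
    high = set(high_sd_sites)
    if not high <= set(all_eligible_sites):
        raise ValidationError("high-SD sites must be a subset of eligible sites")
    elig_chroms = [c for c, _ in all_eligible_sites]
    elig_pos = np.array([p for _, p in all_eligible_sites])
    high_mask = np.array([s in high for s in all_eligible_sites])
    n_high = int(high_mask.sum())
    n_elig = len(all_eligible_sites)
    results: list[EnrichmentResult] = []
    for name, intervals in catalog.items():
        if not intervals:
            continue
        inside = points_in_intervals(elig_chroms, elig_pos, intervals)
        n_in = int(inside.sum())
        if n_in == 0:
            continue  # zero eligible sites in feature: skipped
        p0 = n_in / n_elig
        observed = int((inside & high_mask).sum())
        expected = p0 * n_high
        if n_resamples > 0:
            if rng is None:
                rng = np.random.default_rng()
            draws = np.array(
                [
                    inside[rng.choice(n_elig, size=n_high, replace=False)].sum()
                    for _ in range(n_resamples)
                ]
            )
            if observed >= expected:
                tail = (draws >= observed).sum()
            else:
                tail = (draws <= observed).sum()
            p = float(min(1.0, 2 * (tail + 1) / (n_resamples + 1)))
        elif two_sided:
            p = binom_two_sided(observed, n_high, p0)
        else:
            p = float(sps.binom.sf(observed - 1, n_high, p0))
        ratio = observed / expected if expected > 0 else np.nan
        results.append(
            EnrichmentResult(
                feature_or_set=name,
                observed=observed,
                expected=expected,
                obs_exp_ratio=ratio,
                p_value=p,
                q_value=None,
                direction="over" if observed >= expected else "under",
            )
        )
    q = bh_fdr([r.p_value for r in results])
    return [
        EnrichmentResult(
            r.feature_or_set, r.observed, r.expected, r.obs_exp_ratio,
            r.p_value, float(qv), r.direction,
        )
        for r, qv in zip(results, q)
    ]


def repeat_class_enrichment(
    cgis: Sequence[CpGIsland],
    repeats: Sequence[RepeatAnnotation],
    min_regions: int = 100,
) -> list[EnrichmentResult]:
    """One-tailed binomial enrichment of repeat subfamilies per island class.

    A CGI 'overlaps' a subfamily when >= 1 bp of any member overlaps it.
    Background p0 per subfamily = (#CGIs overlapping it) / (#CGIs); per class
    observed = #CGIs of that class overlapping, n = class size.  Subfamilies
    overlapping fewer than ``min_regions`` CGIs are omitted before testing;
    BH adjustment runs across all retained (subfamily, class) pairs.
    """
    if any(cgi.meth_class is None for cgi in cgis):
        raise ValidationError("every island must carry a methylation class")
    n_cgis = len(cgis)
    if n_cgis == 0:
        return []
    cgi_intervals = [c.interval for c in cgis]
    classes = np.asarray([c.meth_class for c in cgis], dtype=object)
    subfamilies = sorted({r.subfamily for r in repeats})
    overlap_by_sub: dict[str, np.ndarray] = {}
    for sub in subfamilies:
        sub_ivs = [r.interval for r in repeats if r.subfamily == sub]
        hit = overlaps_any(cgi_intervals, sub_ivs)
        if int(hit.sum()) >= min_regions:
            overlap_by_sub[sub] = hit
    results: list[EnrichmentResult] = []
    for sub, hit in overlap_by_sub.items():
        p0 = hit.sum() / n_cgis
        for cls in sorted(set(classes.tolist())):
            cls_mask = classes == cls
            n_cls = int(cls_mask.sum())
            observed = int((hit & cls_mask).sum())
            expected = p0 * n_cls
            p = float(sps.binom.sf(observed - 1, n_cls, p0))
            results.append(
                EnrichmentResult(
                    feature_or_set=f"{sub}|{cls}",
                    observed=observed,
                    expected=expected,
                    obs_exp_ratio=observed / expected if expected > 0 else np.nan,
                    p_value=p,
                    q_value=None,
                    direction="over" if observed >= expected else "under",
                )
            )
    q = bh_fdr([r.p_value for r in results])
    return [
        EnrichmentResult(
            r.feature_or_set, r.observed, r.expected, r.obs_exp_ratio,
            r.p_value, float(qv), r.direction,
        )
        for r, qv in zip(results, q)
    ]


def gene_set_enrichment(
    hit_genes: Sequence[str],
    background_genes: Sequence[str],
    sets: Mapping[str, Sequence[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of hit genes in each gene set.

    p = P(X >= observed), X ~ Hypergeom(N=#background, K=#set&background,
    n=#hits); BH adjustment across sets.
    """
    background = set(background_genes)
    if not background:
        raise ConfigError("empty background gene list")
    hits = set(hit_genes)
    if not hits <= background:
        raise ValidationError("hit genes must be a subset of the background")
    N = len(background)
    n = len(hits)
    results: list[EnrichmentResult] = []
    for set_id in sorted(sets):
        members = set(sets[set_id]) & background
        K = len(members)
        if K == 0:
            continue
        observed = len(hits & members)
        expected = n * K / N
        p = float(sps.hypergeom.sf(observed - 1, N, K, n))
        results.append(
            EnrichmentResult(
                feature_or_set=set_id,
                observed=observed,
                expected=expected,
                obs_exp_ratio=observed / expected if expected > 0 else np.nan,
                p_value=p,
                q_value=None,
                direction="over" if observed >= expected else "under",
            )
        )
    q = bh_fdr([r.p_value for r in results])
    return [
        EnrichmentResult(
            r.feature_or_set, r.observed, r.expected, r.obs_exp_ratio,
            r.p_value, float(qv), r.direction,
        )
        for r, qv in zip(results, q)
    ]
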