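"""Per-CpG association statistics and run-merging into regions.

Implements one-way fixed-effects ANOVA (breed, and its two-group special
case for sex), Benjamini-Hochberg FDR, logistic regression with covariates
(injury), age rank correlation, per-site SD with a top-fraction cut, and
greedy chaining of significant sites into regions (gap <= 100 bp, >= 5
members by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from methyloscope.errors import ConfigError, DataError, ValidationError
from methyloscope.io_formats import GenomicInterval, SampleMetadata


@dataclass(frozen=True)
class SiteStat:
    chrom: str
    pos: int
    statistic: float
    p_value: float | None
    q_value: float | None = None
    flag: str | None = None  # 'degenerate', 'separation', 'no_variance', ...


@dataclass(frozen=True)
class Dmr:
    interval: GenomicInterval
    n_dmcs: int
    group_means: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VariableRegion:
    interval: GenomicInterval
    n_high_sd_cpgs: int
    association: Mapping[str, float] = field(default_factory=dict)


def anova_per_cpg(
    beta: np.ndarray,
    group_labels: Sequence[str],
    chroms: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
) -> list[SiteStat]:
    """One-way fixed-effects ANOVA at every site (row of ``beta``).

    F = (SSB/(k-1)) / (SSW/(n-k)); p from the F distribution.  Sites with
    SSW = 0 and SSB > 0 get p = 0 and a 'degenerate' flag; SSB = SSW = 0
    gives F = 0, p = 1.
    """
    beta = np.asarray(beta, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ConfigError("ANOVA needs >= 2 groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ConfigError(f"groups with < 2 samples: {small}")
    n = beta.shape[1]
    k = len(groups)
    grand = beta.mean(axis=1)
    ssb = np.zeros(beta.shape[0])
    ssw = np.zeros(beta.shape[0])
    for g in groups:
        sub = beta[:, labels == g]
        gm = sub.mean(axis=1)
        ssb += sub.shape[1] * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    # squash float roundoff from constant rows (betas are O(1), so genuine
    # variation produces sums of squares far above this floor)
    ssb[ssb < 1e-20] = 0.0
    ssw[ssw < 1e-20] = 0.0
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = np.ones(beta.shape[0])
    ok = ssw > 0
    p[ok] = sps.f.sf(f[ok], df_b, df_w)
    degenerate = (~ok) & (ssb > 0)
    p[degenerate] = 0.0
    f[~ok] = np.where(ssb[~ok] > 0, np.inf, 0.0)
    chroms = chroms if chroms is not None else [""] * beta.shape[0]
    positions = positions if positions is not None else list(range(beta.shape[0]))
    return [
        SiteStat(
            chrom=c,
            pos=int(pp),
            statistic=float(ff),
            p_value=float(pv),
            flag="degenerate" if dg else None,
        )
        for c, pp, ff, pv, dg in zip(chroms, positions, f, p, degenerate)
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def attach_q_values(stats_list: Sequence[SiteStat]) -> list[SiteStat]:
    """BH-adjust over the sites with defined p-values (missing p kept missing)."""
    idx = [i for i, s in enumerate(stats_list) if s.p_value is not None]
    q = bh_fdr([stats_list[i].p_value for i in idx])
    out = list(stats_list)
    for j, i in enumerate(idx):
        s = out[i]
        out[i] = SiteStat(s.chrom, s.pos, s.statistic, s.p_value, float(q[j]), s.flag)
    return out


def call_dmcs(
    stats_list: Sequence[SiteStat], fdr_threshold: float = 0.05
) -> list[tuple[str, int]]:
    """Sites with q < threshold (strict), in genomic order."""
    hits = [
        (s.chrom, s.pos)
        for s in stats_list
        if s.q_value is not None and s.q_value < fdr_threshold
    ]
    return sorted(hits)


def merge_runs(
    positions: Sequence[tuple[str, int]] | Sequence[int],
    gap_bp: int = 100,
    min_count: int = 5,
    chrom: str = "chr",
) -> list[tuple[GenomicInterval, int]]:
    """Greedy left-to-right chaining of positions into regions.

    Consecutive positions at most ``gap_bp`` apart (inclusive) join one run;
    runs with ``count >= min_count`` are returned as [first, last + 1)
    intervals with their member counts.  Accepts bare integer positions
    (single chromosome) or (chrom, pos) tuples; input is sorted internally.
    """
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    pairs: list[tuple[str, int]] = []
    for item in positions:
        if isinstance(item, tuple):
            pairs.append((item[0], int(item[1])))
        else:
            pairs.append((chrom, int(item)))
    pairs = sorted(set(pairs))
    regions: list[tuple[GenomicInterval, int]] = []
    run: list[tuple[str, int]] = []
    for item in pairs:
        if run and (item[0] != run[-1][0] or item[1] - run[-1][1] > gap_bp):
            if len(run) >= min_count:
                regions.append(
                    (GenomicInterval(run[0][0], run[0][1], run[-1][1] + 1), len(run))
                )
            run = []
        run.append(item)
    if len(run) >= min_count:
        regions.append(
            (GenomicInterval(run[0][0], run[0][1], run[-1][1] + 1), len(run))
        )
    return regions


def sd_per_cpg(beta: np.ndarray) -> np.ndarray:
    """Across-sample standard deviation per site (n-1 denominator)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[1] < 2:
        raise ConfigError("SD needs >= 2 samples")
    return beta.std(axis=1, ddof=1)


def top_fraction_threshold(sds: np.ndarray, fraction: float = 0.01) -> float:
    """Smallest SD v such that exactly ceil(fraction * n) sites have SD >= v.

    Order-statistic definition, no interpolation; a site is 'high-SD' iff
    its SD >= the returned threshold.
    """
    if not (0 < fraction <= 1):
        raise ConfigError("fraction must be in (0, 1]")
    sds = np.asarray(sds, dtype=float)
    if sds.size == 0:
        raise ConfigError("no SD values")
    k = int(np.ceil(fraction * sds.size))
    return float(np.sort(sds)[::-1][k - 1])


def region_mean_beta(
    region: GenomicInterval,
    chroms: Sequence[str],
    positions: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Per-sample mean beta over the member CpGs of one region."""
    chroms_arr = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions)
    mask = (
        (chroms_arr == region.chrom)
        & (positions >= region.start)
        & (positions < region.end)
    )
    if not mask.any():
        raise DataError(f"region {region.chrom}:{region.start}-{region.end} has no CpGs")
    return np.asarray(beta, dtype=float)[mask].mean(axis=0)


def associate_regions(
    regions: Sequence[tuple[GenomicInterval, int]],
    chroms: Sequence[str],
    positions: np.ndarray,
    beta: np.ndarray,
    metadata: Sequence[SampleMetadata],
    alpha: float = 0.01,
) -> list[VariableRegion]:
    """Sex/breed ANOVA and age rank correlation per region.

    Region value = per-sample mean beta over member CpGs.  Each family of
    p-values is BH-adjusted across regions separately; ``association`` maps
    '<covariate>_q' to the adjusted p, '<covariate>_significant' to 0/1 at
    adjusted p < alpha, and 'age_rho' to the correlation.  Covariates that
    are constant across samples are skipped with a warning.
    """
    sexes = np.asarray([m.sex for m in metadata])
    breeds = np.asarray([m.breed for m in metadata])
    ages = np.asarray([m.age_years for m in metadata], dtype=float)
    values = np.vstack(
        [region_mean_beta(region, chroms, positions, beta) for region, _ in regions]
    ) if regions else np.empty((0, len(metadata)))

    results: dict[str, dict[str, np.ndarray]] = {}
    for name, labels in (("sex", sexes), ("breed", breeds)):
        if len(set(labels.tolist())) < 2:
            warnings.warn(f"covariate {name!r} constant across samples; test skipped")
            continue
        stats_list = anova_per_cpg(values, labels) if len(values) else []
        pvals = np.array([s.p_value for s in stats_list])
        results[name] = {"p": pvals, "q": bh_fdr(pvals)}
    if np.unique(ages).size < 2:
        warnings.warn("covariate 'age' constant across samples; test skipped")
    elif len(values):
        rho = np.empty(len(values))
        pvals = np.empty(len(values))
        for i, row in enumerate(values):
            if np.allclose(row, row[0]):
                rho[i], pvals[i] = 0.0, 1.0
            else:
                r, p = sps.spearmanr(row, ages)
                rho[i], pvals[i] = r, p
        results["age"] = {"p": pvals, "q": bh_fdr(pvals), "rho": rho}

    out: list[VariableRegion] = []
    for i, (region, count) in enumerate(regions):
        assoc: dict[str, float] = {}
        for name, res in results.items():
            assoc[f"{name}_p"] = float(res["p"][i])
            assoc[f"{name}_q"] = float(res["q"][i])
            assoc[f"{name}_significant"] = float(res["q"][i] < alpha)
            if "rho" in res:
                assoc["age_rho"] = float(res["rho"][i])
        out.append(
            VariableRegion(interval=region, n_high_sd_cpgs=count, association=assoc)
        )
    return out


def logistic_dmc(
    beta: np.ndarray,
    outcome: Sequence[int] | np.ndarray,
    covariates: np.ndarray | None = None,
    chroms: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> list[SiteStat]:
    """Per-site logistic regression outcome ~ intercept + beta (+ covariates).

    Fit by Newton-Raphson maximum likelihood, vectorized across sites; the
    reported p-value is the Wald test on the methylation coefficient.
    Sites with no methylation variance are skipped ('no_variance'); fits
    showing (quasi-)separation or non-convergence are flagged and get a
    missing p-value.
    """
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if classes.size != 2 or not set(classes.tolist()) <= {0.0, 1.0}:
        raise ConfigError("outcome must be binary 0/1 with both classes present")
    n_sites, n_samples = beta.shape
    if covariates is None:
        covariates = np.empty((n_samples, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n_samples:
        covariates = covariates.T
    n_cov = covariates.shape[1]
    p_dim = 2 + n_cov  # intercept, methylation, covariates

    # design per site: column 1 varies by site, the rest are shared
    X_shared = np.concatenate(
        [np.ones((n_samples, 1)), np.zeros((n_samples, 1)), covariates], axis=1
    )
    coefs = np.zeros((n_sites, p_dim))
    converged = np.zeros(n_sites, dtype=bool)
    no_var = np.array([np.allclose(row, row[0]) for row in beta])
    active = ~no_var
    X = np.broadcast_to(X_shared, (n_sites, n_samples, p_dim)).copy()
    X[:, :, 1] = beta

    b = coefs.copy()
    for _ in range(max_iter):
        idx = np.flatnonzero(active & ~converged)
        if idx.size == 0:
            break
        Xa = X[idx]
        eta = np.einsum("snp,sp->sn", Xa, b[idx])
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        grad = np.einsum("snp,sn->sp", Xa, y[None, :] - mu)
        hess = np.einsum("snp,sn,snq->spq", Xa, w, Xa)
        # ridge jitter guards singular Hessians from quasi-separation
        hess += 1e-12 * np.eye(p_dim)[None]
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(hess, grad)]
            )
        step = np.clip(step, -1e3, 1e3)
        b[idx] += step
        done = np.max(np.abs(step), axis=1) < tol
        converged[idx[done]] = True

    separated = active & (np.max(np.abs(b), axis=1) > 1e2)
    failed = active & ~converged & ~separated

    stats_out: list[SiteStat] = []
    chroms = chroms if chroms is not None else [""] * n_sites
    positions = positions if positions is not None else list(range(n_sites))
    for i in range(n_sites):
        if no_var[i]:
            stats_out.append(
                SiteStat(chroms[i], int(positions[i]), np.nan, None, flag="no_variance")
            )
            continue
        if separated[i]:
            stats_out.append(
                SiteStat(chroms[i], int(positions[i]), np.nan, None, flag="separation")
            )
            continue
        if failed[i]:
            stats_out.append(
                SiteStat(chroms[i], int(positions[i]), np.nan, None, flag="no_convergence")
            )
            continue
        eta = X[i] @ b[i]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        hess = (X[i] * w[:, None]).T @ X[i]
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            stats_out.append(
                SiteStat(chroms[i], int(positions[i]), np.nan, None, flag="singular")
            )
            continue
        se = np.sqrt(max(cov[1, 1], 0.0))
        if se == 0 or not np.isfinite(se):
            stats_out.append(
                SiteStat(chroms[i], int(positions[i]), np.nan, None, flag="singular")
            )
            continue
        z = b[i, 1] / se
        p = 2 * sps.norm.sf(abs(z))
        stats_out.append(SiteStat(chroms[i], int(positions[i]), float(z), float(p)))
    return stats_out
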