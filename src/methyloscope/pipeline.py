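"""Stage functions behind the CLI: each reads/writes documented formats only.

Every stage writes a ``manifest_<stage>.json`` with the config hash, seed,
package version, and SHA-256 checksums of its inputs, so any stage can be
re-run reproducibly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np

from methyloscope import __version__
from methyloscope import cgi as cgi_mod
from methyloscope import enrichment as enrich_mod
from methyloscope import methylome as meth_mod
from methyloscope import regions as reg_mod
from methyloscope import simulate as sim_mod
from methyloscope.embedding import (
    MlmConfig,
    class_separation,
    embed_cgis,
    project_tsne,
    tokenize_and_filter,
    train_bpe,
    train_mlm,
)
from methyloscope.errors import ConfigError
from methyloscope.io_formats import (
    GeneModel,
    GenomicInterval,
    RepeatAnnotation,
    read_bed,
    read_fasta,
    read_methylation_table,
    read_sample_metadata,
    write_bed,
    write_fasta,
    write_methylation_table,
    write_sample_metadata,
)

logger = logging.getLogger("methyloscope")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def stage_simulate(config: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = sim_mod.SimulationConfig.from_dict(config.get("simulate", {}))
    logger.info("simulate: seed=%d genome=%dx%dbp", sim_cfg.seed,
                sim_cfg.n_chroms, sim_cfg.chrom_length)
    genome, truth = sim_mod.simulate_genome(sim_cfg)
    tables, samples = sim_mod.simulate_methylomes(genome, truth, sim_cfg)
    truth = sim_mod.simulate_annotations(genome, truth, sim_cfg)
    write_fasta(genome, outdir / "genome.fa")
    for sid, recs in tables.items():
        write_methylation_table(recs, outdir / f"meth_{sid}.tsv")
    write_sample_metadata(samples, outdir / "metadata.tsv")
    write_bed([g.interval for g in truth.gene_models], outdir / "genes.bed")
    write_bed(
        [GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                         name=r.subfamily) for r in truth.repeats],
        outdir / "repeats.bed",
    )
    write_bed(truth.ctcf_sites, outdir / "ctcf.bed")
    with open(outdir / "snps.tsv", "w") as fh:
        for chrom, pos in truth.snp_positions:
            fh.write(f"{chrom}\t{pos + 1}\n")
    truth.to_json(outdir / "ground_truth.json")
    _write_manifest(outdir, "simulate", config, [])


def _read_snps(path: Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos1 = line.split("\t")[:2]
            out.append((chrom, int(pos1) - 1))
    return out


def _load_matrix(outdir: Path):
    samples = read_sample_metadata(outdir / "metadata.tsv")
    tables = {
        s.sample_id: read_methylation_table(outdir / f"meth_{s.sample_id}.tsv")
        for s in samples
    }
    return meth_mod.build_matrix(tables, [s.sample_id for s in samples]), samples


def stage_qc(config: dict, outdir: Path) -> None:
    qc_cfg = config.get("qc", {})
    matrix, samples = _load_matrix(outdir)
    filtered, report = meth_mod.apply_quality_filters(
        matrix,
        min_depth=qc_cfg.get("min_depth", 10),
        max_depth=qc_cfg.get("max_depth", 500),
    )
    snps_path = outdir / "snps.tsv"
    snps = _read_snps(snps_path) if snps_path.exists() else []
    filtered = meth_mod.mask_snps_and_chroms(
        filtered, snps, set(qc_cfg.get("drop_chroms", ["chrX"]))
    )
    beta = meth_mod.beta_values(filtered)
    with open(outdir / "filtered_matrix.tsv", "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(filtered.sample_ids) + "\n")
        for i in range(filtered.n_sites):
            vals = "\t".join(f"{b:.6g}" for b in beta[i])
            fh.write(f"{filtered.chroms[i]}\t{filtered.positions[i] + 1}\t{vals}\n")
    corr = meth_mod.pairwise_spearman(beta) if filtered.n_sites else None
    if corr is not None:
        with open(outdir / "correlation.tsv", "w") as fh:
            fh.write("\t" + "\t".join(filtered.sample_ids) + "\n")
            for sid, row in zip(filtered.sample_ids, corr):
                fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(report.__dict__, fh, indent=1)
    genes_path = outdir / "genes.bed"
    if genes_path.exists() and filtered.n_sites:
        from methyloscope.io_formats import GeneModel, read_bed

        genes = [
            GeneModel(interval=iv, gene_id=iv.name or f"gene{i}")
            for i, iv in enumerate(read_bed(genes_path))
        ]
        profile = meth_mod.gene_metaprofile(
            filtered.chroms, filtered.positions, beta.mean(axis=1), genes,
            body_bins=qc_cfg.get("body_bins", 100),
            flank_bp=qc_cfg.get("flank_bp", 2000),
            flank_bins=qc_cfg.get("flank_bins", 40),
        )
        with open(outdir / "gene_profile.tsv", "w") as fh:
            fh.write("bin\tmean_beta\n")
            for i, v in enumerate(profile):
                fh.write(f"{i}\t{'' if np.isnan(v) else f'{v:.6g}'}\n")
    logger.info("qc: retained %d/%d sites", report.n_retained, report.n_input)
    _write_manifest(outdir, "qc", config,
                    [outdir / "metadata.tsv", snps_path])


def _read_filtered(outdir: Path):
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[list[float]] = []
    with open(outdir / "filtered_matrix.tsv") as fh:
        sample_ids = fh.readline().rstrip("\n").split("\t")[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chroms.append(parts[0])
            positions.append(int(parts[1]) - 1)
            rows.append([float(v) for v in parts[2:]])
    beta = np.array(rows) if rows else np.empty((0, len(sample_ids)))
    return chroms, np.array(positions, dtype=np.int64), sample_ids, beta


def stage_cgi(config: dict, outdir: Path) -> None:
    cgi_cfg = config.get("cgi", {})
    genome = read_fasta(outdir / "genome.fa")
    crit_name = cgi_cfg.get("criteria", "ggf")
    criteria = {
        "ggf": cgi_mod.GGF_CRITERIA,
        "takai_jones": cgi_mod.TAKAI_JONES_CRITERIA,
    }.get(crit_name)
    if criteria is None:
        raise ConfigError(f"unknown criteria {crit_name!r}")
    cgis = cgi_mod.detect_cgis(genome, criteria)
    chroms, positions, sample_ids, beta = _read_filtered(outdir)
    site_means = beta.mean(axis=1) if beta.size else np.empty(0)
    scored, unscorable = cgi_mod.score_cgis(cgis, chroms, positions, site_means)
    logger.info("cgi: %d islands (%d unscorable)", len(cgis), len(unscorable))
    out = [
        GenomicInterval(
            c.interval.chrom, c.interval.start, c.interval.end,
            name=c.meth_class, score=round(1000 * c.mean_beta),
        )
        for c in scored
    ] + [
        GenomicInterval(c.interval.chrom, c.interval.start, c.interval.end,
                        name="unscorable", score=-1)
        for c in unscorable
    ]
    write_bed(sorted(out, key=lambda iv: (iv.chrom, iv.start)), outdir / "cgis.bed")
    _write_manifest(outdir, "cgi", config,
                    [outdir / "genome.fa", outdir / "filtered_matrix.tsv"])


def stage_dmr(config: dict, outdir: Path) -> None:
    dmr_cfg = config.get("dmr", {})
    chroms, positions, sample_ids, beta = _read_filtered(outdir)
    samples = read_sample_metadata(outdir / "metadata.tsv")
    by_id = {s.sample_id: s for s in samples}
    breeds = [by_id[sid].breed for sid in sample_ids]
    stats = reg_mod.anova_per_cpg(beta, breeds, chroms, positions)
    stats = reg_mod.attach_q_values(stats)
    dmcs = reg_mod.call_dmcs(stats, dmr_cfg.get("fdr", 0.05))
    regions = reg_mod.merge_runs(
        dmcs, gap_bp=dmr_cfg.get("gap_bp", 100), min_count=dmr_cfg.get("min_count", 5)
    )
    write_bed(
        [GenomicInterval(iv.chrom, iv.start, iv.end, name=f"n_dmcs={n}")
         for iv, n in regions],
        outdir / "dmrs.bed",
    )
    logger.info("dmr: %d DMCs -> %d DMRs", len(dmcs), len(regions))
    _write_manifest(outdir, "dmr", config,
                    [outdir / "filtered_matrix.tsv", outdir / "metadata.tsv"])


def stage_varreg(config: dict, outdir: Path) -> None:
    var_cfg = config.get("varreg", {})
    chroms, positions, sample_ids, beta = _read_filtered(outdir)
    samples = read_sample_metadata(outdir / "metadata.tsv")
    by_id = {s.sample_id: s for s in samples}
    meta = [by_id[sid] for sid in sample_ids]
    sds = reg_mod.sd_per_cpg(beta)
    threshold = reg_mod.top_fraction_threshold(sds, var_cfg.get("fraction", 0.01))
    high = sds >= threshold
    sites = [(c, int(p)) for c, p, h in zip(chroms, positions, high) if h]
    regions = reg_mod.merge_runs(
        sites, gap_bp=var_cfg.get("gap_bp", 100), min_count=var_cfg.get("min_count", 5)
    )
    assoc = reg_mod.associate_regions(
        regions, chroms, positions, beta, meta, alpha=var_cfg.get("alpha", 0.01)
    )
    write_bed(
        [GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                         name=f"n_cpgs={r.n_high_sd_cpgs}")
         for r in assoc],
        outdir / "variable_regions.bed",
    )
    with open(outdir / "variable_region_assoc.tsv", "w") as fh:
        keys = sorted({k for r in assoc for k in r.association})
        fh.write("chrom\tstart\tend\tn_cpgs\t" + "\t".join(keys) + "\n")
        for r in assoc:
            vals = "\t".join(f"{r.association.get(k, float('nan')):.6g}" for k in keys)
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.n_high_sd_cpgs}\t{vals}\n"
            )
    with open(outdir / "sd_threshold.json", "w") as fh:
        json.dump({"threshold": threshold, "n_high_sd": int(high.sum())}, fh)
    logger.info("varreg: threshold %.4f, %d regions", threshold, len(regions))
    _write_manifest(outdir, "varreg", config,
                    [outdir / "filtered_matrix.tsv", outdir / "metadata.tsv"])


def stage_enrich(config: dict, outdir: Path) -> None:
    enr_cfg = config.get("enrich", {})
    chroms, positions, sample_ids, beta = _read_filtered(outdir)
    genome = read_fasta(outdir / "genome.fa")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    genes = [
        GeneModel(interval=iv, gene_id=iv.name or f"gene{i}")
        for i, iv in enumerate(read_bed(outdir / "genes.bed"))
    ]
    cgi_bed = read_bed(outdir / "cgis.bed")
    repeats_bed = read_bed(outdir / "repeats.bed")
    ctcf = read_bed(outdir / "ctcf.bed")
    catalog = cgi_mod.build_feature_catalog(
        genes, cgi_bed, ctcf, repeats_bed, chrom_sizes,
        promoter_bp=enr_cfg.get("promoter_bp", 1500),
    )
    sds = reg_mod.sd_per_cpg(beta)
    threshold = reg_mod.top_fraction_threshold(sds, enr_cfg.get("fraction", 0.01))
    all_sites = list(zip(chroms, positions.tolist()))
    high_sites = [s for s, sd in zip(all_sites, sds) if sd >= threshold]
    feats = enrich_mod.feature_enrichment(high_sites, all_sites, catalog)
    with open(outdir / "feature_enrichment.tsv", "w") as fh:
        fh.write("feature\tobserved\texpected\tratio\tp\tq\tdirection\n")
        for r in feats:
            fh.write(
                f"{r.feature_or_set}\t{r.observed}\t{r.expected:.4f}"
                f"\t{r.obs_exp_ratio:.4f}\t{r.p_value:.4g}\t{r.q_value:.4g}"
                f"\t{r.direction}\n"
            )
    # repeat-subfamily enrichment per island class
    scored_cgis = [
        cgi_mod.CpGIsland(
            interval=iv, gc_ratio=0.0, cpg_oe=0.0, n_cpg=0,
            mean_beta=(iv.score or 0) / 1000, meth_class=iv.name,
        )
        for iv in cgi_bed
        if iv.name in (cgi_mod.UNMETHYLATED, cgi_mod.LOW, cgi_mod.HIGH)
    ]
    repeats = [
        RepeatAnnotation(interval=iv, subfamily=iv.name or "unknown")
        for iv in repeats_bed
    ]
    reps = enrich_mod.repeat_class_enrichment(
        scored_cgis, repeats, min_regions=enr_cfg.get("min_regions", 100)
    )
    with open(outdir / "repeat_enrichment.tsv", "w") as fh:
        fh.write("subfamily_class\tobserved\texpected\tratio\tp\tq\tdirection\n")
        for r in reps:
            fh.write(
                f"{r.feature_or_set}\t{r.observed}\t{r.expected:.4f}"
                f"\t{r.obs_exp_ratio:.4f}\t{r.p_value:.4g}\t{r.q_value:.4g}"
                f"\t{r.direction}\n"
            )
    logger.info("enrich: %d feature rows, %d repeat rows", len(feats), len(reps))
    _write_manifest(outdir, "enrich", config, [outdir / "cgis.bed"])


def stage_embed(config: dict, outdir: Path) -> None:
    emb_cfg = config.get("embed", {})
    genome = read_fasta(outdir / "genome.fa")
    cgi_bed = read_bed(outdir / "cgis.bed")
    seqs = {
        f"{iv.chrom}:{iv.start}-{iv.end}": genome[iv.chrom][iv.start : iv.end]
        for iv in cgi_bed
    }
    classes = {
        f"{iv.chrom}:{iv.start}-{iv.end}": iv.name for iv in cgi_bed
    }
    if not seqs:
        raise ConfigError("no islands to embed; run the cgi stage first")
    tokenizer = train_bpe(
        list(seqs.values()), vocab_size=emb_cfg.get("vocab_size", 512)
    )
    tokenizer.to_json(outdir / "tokenizer.json")
    corpus, dropped = tokenize_and_filter(
        seqs, tokenizer, max_tokens=emb_cfg.get("max_tokens", 512)
    )
    mlm_cfg = MlmConfig(
        embed_dim=emb_cfg.get("embed_dim", 64),
        n_layers=emb_cfg.get("n_layers", 2),
        n_heads=emb_cfg.get("n_heads", 4),
        mask_rate=emb_cfg.get("mask_rate", 0.15),
        max_tokens=emb_cfg.get("max_tokens", 512),
        epochs=emb_cfg.get("epochs", 5),
        batch_size=emb_cfg.get("batch_size", 16),
        learning_rate=emb_cfg.get("learning_rate", 1e-3),
        seed=config.get("seed", 0),
    )
    encoder = train_mlm(corpus, tokenizer, mlm_cfg)
    embeddings = embed_cgis(corpus, encoder)
    with open(outdir / "embeddings.tsv", "w") as fh:
        for cid, vec in zip(embeddings.cgi_ids, embeddings.vectors):
            fh.write(cid + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")
    n = embeddings.vectors.shape[0]
    perplexity = min(emb_cfg.get("perplexity", 30.0), max(2.0, (n - 1) / 3.5))
    if n > 3 * perplexity:
        coords = project_tsne(embeddings, perplexity=perplexity,
                              seed=config.get("seed", 0))
        with open(outdir / "tsne.tsv", "w") as fh:
            fh.write("cgi_id\ttsne1\ttsne2\tmeth_class\n")
            for cid, (x, y) in zip(embeddings.cgi_ids, coords):
                fh.write(f"{cid}\t{x:.4f}\t{y:.4f}\t{classes.get(cid, 'NA')}\n")
    labels = [classes.get(cid, "NA") for cid in embeddings.cgi_ids]
    sep = class_separation(embeddings, labels, seed=config.get("seed", 0))
    with open(outdir / "separation.json", "w") as fh:
        json.dump({**sep, "n_dropped_long": len(dropped),
                   "final_loss": encoder.loss_history[-1]
                   if encoder.loss_history else None}, fh, indent=1)
    logger.info("embed: %d sequences embedded, %d dropped", n, len(dropped))
    _write_manifest(outdir, "embed", config,
                    [outdir / "genome.fa", outdir / "cgis.bed"])


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "cgi": stage_cgi,
    "dmr": stage_dmr,
    "varreg": stage_varreg,
    "enrich": stage_enrich,
    "embed": stage_embed,
}


def run_all(config: dict, outdir: Path) -> None:
    for name in ("simulate", "qc", "cgi", "dmr", "varreg", "enrich", "embed"):
        logger.info("=== stage %s ===", name)
        STAGES[name](config, outdir)
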