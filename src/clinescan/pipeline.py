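"""End-to-end orchestration over a multi-transect dataset.

Stage order follows the analysis narrative: per-transect relatedness
pruning and scans, candidate and top-candidate gene sets, cross-transect
overlap permutation tests, parallel allele-frequency-shift analysis,
GO enrichment in three modes, and the pooled mixed-model GWAS for body
weight with the GWAS x scan overlap test.  One master seed derives
per-stage seeds by fixed offsets; every random stage records its seed
in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, enrichment, gwas, popstructure, scan, shared
from .datatypes import GenotypeTable
from .simulate import SimConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger(__name__)

# fixed offsets deriving stage seeds from the master seed
_SEED_OFFSETS = {"overlap": 11, "parallel": 23, "enrichment": 37, "gwas": 53}


@dataclass
class PipelineConfig:
    scan: scan.ScanConfig = field(default_factory=scan.ScanConfig)
    scan_K: dict[str, int] = field(default_factory=dict)   # per-transect K
    variables: list[str] = field(default_factory=lambda: ["LAT", "MAT", "PDM"])
    relatedness_threshold: float = 0.25
    n_top: int = 100
    overlap_replicates: int = 10_000
    parallel_iterations: int = 1000
    enrichment_simulations: int = 1000
    min_call_fraction_ends: float = 0.6
    gwas_min_maf: float = 0.05
    gwas_max_missing: float = 0.10
    gwas_fdr: float = 0.05
    run_enrichment: bool = True
    run_gwas: bool = True
    seed: int = 0


def run_full_pipeline(dataset: SyntheticDataset, config: PipelineConfig,
                      outdir: str | Path | None = None) -> dict:
    """Run every stage; returns a JSON-serializable report."""
    cfg = config
    report: dict = {"seed": cfg.seed, "stage_seeds": {
        k: cfg.seed + v for k, v in _SEED_OFFSETS.items()}}
    transects = list(dataset.genotypes)
    genes = dataset.genes

    # stage 1: relatedness pruning per transect
    stage = "relatedness"
    try:
        pruned: dict[str, GenotypeTable] = {}
        samples: dict[str, pd.DataFrame] = {}
        for t in transects:
            pruner = popstructure.RelatednessPruner(
                threshold=cfg.relatedness_threshold
            ).fit(dataset.genotypes[t])
            pruned[t] = pruner.transform(dataset.genotypes[t])
            samples[t] = dataset.samples[t].set_index("sample_id").loc[
                pruned[t].sample_ids].reset_index()
        report["relatedness"] = {
            t: {"n_kept": pruned[t].n_samples,
                "n_removed": dataset.genotypes[t].n_samples
                - pruned[t].n_samples} for t in transects}

        # stage 2: scans per transect x variable, candidate sets
        stage = "scan"
        any_sites = next(iter(dataset.genotypes.values())).sites
        assign_body = annotate.map_snps_to_genes(any_sites, genes, "gene_body")
        assign_exon = annotate.map_snps_to_genes(any_sites, genes, "exon_only")
        candidate: dict[str, dict[str, annotate.CandidateSet]] = {}
        scans: dict[str, dict[str, scan.ScanResult]] = {}
        universes: dict[str, set[str]] = {}
        report["scans"] = {}
        for t in transects:
            candidate[t], scans[t] = {}, {}
            k_t = cfg.scan_K.get(t, cfg.scan.K)
            sc = scan.ScanConfig(K=k_t, variables=cfg.variables,
                                 q_threshold=cfg.scan.q_threshold,
                                 z_threshold=cfg.scan.z_threshold,
                                 min_maf=cfg.scan.min_maf,
                                 min_call_fraction=cfg.scan.min_call_fraction)
            for var in cfg.variables:
                env = samples[t][var].to_numpy(float)
                res = scan.scan_genotypes(pruned[t], env, sc, var, t)
                snps = scan.call_outliers(res, sc)
                cs = annotate.build_candidate_set(res, snps, assign_body,
                                                  cfg.n_top)
                scans[t][var] = res
                candidate[t][var] = cs
                report["scans"].setdefault(t, {})[var] = {
                    "lambda": res.lambda_, "n_tested": res.n_sites_tested,
                    "n_outlier_snps": len(snps),
                    "n_candidate_genes": len(cs.genes)}
            tested = set(scans[t][cfg.variables[0]].table["site"])
            universes[t] = annotate.genes_of_snps(tested, assign_body)

        # stage 3: cross-transect overlap permutation tests
        stage = "overlap"
        report["overlap"] = {}
        for var in cfg.variables:
            entry = {}
            for a, b in combinations(transects, 2):
                r = shared.overlap_permutation_test(
                    candidate[a][var].genes, candidate[b][var].genes,
                    universes[a], universes[b],
                    n_replicates=cfg.overlap_replicates,
                    seed=report["stage_seeds"]["overlap"])
                entry[f"{a}-{b}"] = {"observed": r.observed, "z": r.z,
                                     "p": r.p, "null_mean": r.null_mean}
            if len(transects) >= 3:
                a, b, c = transects[:3]
                r = shared.overlap_permutation_test(
                    candidate[a][var].genes, candidate[b][var].genes,
                    universes[a], universes[b],
                    set_c=candidate[c][var].genes, universe_c=universes[c],
                    n_replicates=cfg.overlap_replicates,
                    seed=report["stage_seeds"]["overlap"])
                entry["three_way"] = {"observed": r.observed, "z": r.z,
                                      "p": r.p, "null_mean": r.null_mean}
            report["overlap"][var] = entry

        # stage 4: parallel allele-frequency shifts
        stage = "parallel"
        report["parallel"] = {}
        ends = {t: shared.extreme_latitude_tables(dataset.genotypes[t],
                                                  dataset.samples[t])
                for t in transects}
        directions = {
            t: shared.shift_directions(
                ends[t][0], ends[t][1],
                list(next(iter(dataset.genotypes.values())).site_ids),
                cfg.min_call_fraction_ends)
            for t in transects}
        genome_calls = shared.gene_parallel_calls(directions, assign_body)
        frac = (float(genome_calls["concordant"].mean())
                if len(genome_calls) else 0.0)
        report["parallel"]["genome_wide"] = {
            "n_genes": len(genome_calls),
            "n_concordant": int(genome_calls["concordant"].sum())
            if len(genome_calls) else 0,
            "fraction": frac}
        expected = shared.expected_parallel_fraction(len(transects))
        for var in cfg.variables:
            shared_genes = set.intersection(
                *(candidate[t][var].genes for t in transects))
            sub = genome_calls[genome_calls["gene_id"].isin(shared_genes)]
            n_total, n_par = len(sub), int(sub["concordant"].sum())
            entry = {"n_shared_genes": len(shared_genes),
                     "n_evaluable": n_total, "n_parallel": n_par}
            if n_total:
                chi2, p, small = shared.parallel_chisq(n_par, n_total, expected)
                entry["chisq"] = {"chi2": chi2, "p": p,
                                  "small_sample_warning": small}
                perm = shared.parallel_permutation(
                    genome_calls["concordant"].to_numpy(), n_total,
                    observed=n_par, n_iter=cfg.parallel_iterations,
                    seed=report["stage_seeds"]["parallel"])
                entry["permutation"] = {"z": perm.z, "p": perm.p,
                                        "cutoff_95": perm.cutoff_95,
                                        "null_mean": perm.null_mean}
            report["parallel"][var] = entry

        # stage 5: GO enrichment (three modes) on the first transect's
        # first-variable candidates
        if cfg.run_enrichment:
            stage = "enrichment"
            t0, v0 = transects[0], cfg.variables[0]
            cand_snps = candidate[t0][v0].snps
            bg_snps = set(scans[t0][v0].table["site"])
            report["enrichment"] = {}
            for mode in ("snp", "gene"):
                r = enrichment.permutation_enrichment(
                    cand_snps, bg_snps, assign_exon, dataset.go_map,
                    mode=mode, n_sim=cfg.enrichment_simulations,
                    seed=report["stage_seeds"]["enrichment"])
                report["enrichment"][mode] = _summarize_enrichment(r)
            r = enrichment.ld_pruned_enrichment(
                cand_snps, bg_snps, pruned[t0], assign_exon, dataset.go_map,
                n_sim=cfg.enrichment_simulations,
                seed=report["stage_seeds"]["enrichment"])
            report["enrichment"]["ld_snp"] = _summarize_enrichment(r)

        # stage 6: pooled GWAS for body weight + scan overlap
        if cfg.run_gwas:
            stage = "gwas"
            report["gwas"] = _run_gwas_stage(dataset, candidate, universes,
                                             assign_body, cfg, report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        _write_markdown_report(report, outdir / "report.md")
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _summarize_enrichment(r: enrichment.EnrichmentResult) -> dict:
    sig = r.table[(r.table["fdr"].notna()) & (r.table["fdr"] <= 0.05)]
    return {"n_terms": len(r.table), "n_significant": len(sig),
            "n_simulations": r.n_simulations, "seed": r.seed}


def _run_gwas_stage(dataset, candidate, universes, assign_body, cfg, report):
    # pool adult, non-pregnant samples across transects
    pooled_samples = pd.concat(dataset.samples.values(), ignore_index=True)
    ok = (pooled_samples["age_class"] == "adult")
    if "reproductive_status" in pooled_samples:
        ok &= ~pooled_samples["reproductive_status"].isin(
            ["pregnant", "lactating"])
    pooled_samples = pooled_samples[ok & pooled_samples["body_weight"].notna()]
    tables = list(dataset.genotypes.values())
    sites = tables[0].sites
    calls = np.vstack([t.calls for t in tables])
    all_ids = [s for t in tables for s in t.sample_ids]
    pooled = GenotypeTable(all_ids, sites.copy(), calls)
    pooled = pooled.take_samples(list(pooled_samples["sample_id"]))
    sex = (pooled_samples.set_index("sample_id").loc[
        pooled.sample_ids, "sex"] == "M").to_numpy(float)
    y = pooled_samples.set_index("sample_id").loc[
        pooled.sample_ids, "body_weight"].to_numpy(float)
    model = gwas.MixedModelGWAS(min_maf=cfg.gwas_min_maf,
                                max_missing=cfg.gwas_max_missing,
                                fdr=cfg.gwas_fdr)
    model.fit(pooled, y, covariates=sex)
    hits = model.significant_snps()
    gwas_genes = annotate.genes_of_snps(hits, assign_body)
    scan_genes = set().union(*(candidate[t][v].genes
                               for t in candidate for v in candidate[t]))
    universe = set().union(*universes.values())
    entry = {"n_samples": pooled.n_samples,
             "n_snps_tested": len(model.result_.table),
             "n_hits": len(hits), "n_hit_genes": len(gwas_genes),
             "heritability": model.heritability_}
    if gwas_genes and scan_genes and universe:
        r = gwas.gwas_scan_overlap(gwas_genes & universe,
                                   scan_genes & universe, universe,
                                   n_replicates=cfg.overlap_replicates,
                                   seed=report["stage_seeds"]["gwas"])
        entry["scan_overlap"] = {"observed": r.observed, "z": r.z, "p": r.p}
    return entry


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", "",
             f"Master seed: {report['seed']}", ""]
    for section in ("relatedness", "scans", "overlap", "parallel",
                    "enrichment", "gwas"):
        if section not in report:
            continue
        lines.append(f"## {section}")
        lines.append("```json")
        lines.append(json.dumps(report[section], indent=2, sort_keys=True,
                                default=_jsonable))
        lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))


def run_synthetic(sim_config: SimConfig | None = None,
                  pipeline_config: PipelineConfig | None = None,
                  outdir=None) -> dict:
    """Simulate a dataset and run the full pipeline over it."""
    sim = sim_config or SimConfig()
    pipe = pipeline_config or PipelineConfig(seed=sim.seed)
    dataset = simulate_dataset(sim)
    return run_full_pipeline(dataset, pipe, outdir)
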