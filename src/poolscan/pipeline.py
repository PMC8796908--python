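"""End-to-end orchestration: simulate/ingest -> filter -> diversity ->
genes -> top candidates -> Null-W -> cross-species comparison.

One YAML/dict config drives a full run. Every output table carries the
parameter set in its comment line, and a ``manifest.json`` records
versions, seeds, and per-stage input/output counts. Reruns with the same
config and seed reproduce every table byte-identically (the manifest's
timestamp is the only run-specific field).
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .comparison import (
    extreme_overlap,
    match_gene_scores,
    population_he_matrix,
    spearman_gene_correlation,
)
from .convergence import NullWConfig, null_w_test
from .diversity import (
    collapse_pairs_mean,
    genomewide_summary,
    global_fst,
    snp_fst_frame,
    windowed_he,
)
from .gene_level import assign_window_he, filter_orthologs, gene_mean_fst, gene_table
from .io_formats import (
    read_gff_genes,
    read_ortholog_table,
    read_pooled_vcf,
    read_population_meta,
    variants_to_frame,
    vcf_contig_lengths,
    write_table,
)
from .scans import candidate_table, fst_outlier_flags, top_candidates
from .synthetic_data import preset, simulate_species_pair
from .variant_filtering import FilterConfig, filter_variants

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "window_size": 50_000,
    "fst_estimator": "anova",
    "outlier_quantile": 0.999,
    "p_success": 0.001,
    "filter": {},
    "nullw": {},
    "ortholog_filter": {"min_mapq": 80.0, "min_identity": 90.0},
}


class SpeciesResult:
    """Holds per-species intermediates so later stages can reuse them."""

    def __init__(self, name: str):
        self.name = name
        self.meta = None
        self.frame = None
        self.windows = None
        self.fst_frame = None
        self.snp_fst = None  # collapsed, one value per SNP
        self.gene_records = None
        self.candidates = None
        self.filter_report = None
        self.outlier_threshold = None


def _analyse_species(
    name: str, vcf: str, gff: str, meta_path: str, cfg: dict, out: Path
) -> SpeciesResult:
    res = SpeciesResult(name)
    res.meta = read_population_meta(meta_path)
    fcfg = FilterConfig(**cfg.get("filter", {}))
    variants, report = filter_variants(read_pooled_vcf(vcf, res.meta), fcfg)
    res.filter_report = report
    res.frame = variants_to_frame(variants, res.meta)
    params = {"species": name, "seed": cfg["seed"], "window_size": cfg["window_size"]}
    write_table(res.frame, out / f"filtered_{name}.tsv", params)

    chrom_lengths = vcf_contig_lengths(vcf)
    res.windows = windowed_he(
        res.frame, res.meta, chrom_lengths or None, cfg["window_size"]
    )
    write_table(res.windows, out / f"windows_{name}.tsv", params)

    res.fst_frame = snp_fst_frame(res.frame, res.meta, estimator=cfg["fst_estimator"])
    write_table(
        res.fst_frame.drop(columns=["fst_num", "fst_den"]),
        out / f"fst_{name}.tsv",
        {**params, "estimator": cfg["fst_estimator"]},
    )
    res.snp_fst = collapse_pairs_mean(res.fst_frame)

    genes = read_gff_genes(gff)
    res.gene_records = assign_window_he(
        gene_mean_fst(genes, res.fst_frame), res.windows, res.meta
    )
    write_table(gene_table(res.gene_records, res.meta), out / f"genes_{name}.tsv", params)

    _, threshold = fst_outlier_flags(
        res.snp_fst["fst"].to_numpy(), cfg["outlier_quantile"]
    )
    res.outlier_threshold = threshold
    res.candidates = top_candidates(
        res.gene_records, threshold, cfg["outlier_quantile"], cfg["p_success"]
    )
    write_table(
        candidate_table(res.candidates),
        out / f"candidates_{name}.tsv",
        {**params, "fst_threshold": f"{threshold:.6g}"},
    )
    return res


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every stage; return the manifest (also written as JSON)."""
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "poolscan_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }

    if "simulate" in cfg:
        sim = cfg["simulate"]
        overrides_a = sim.get("overrides_a", sim.get("overrides", {}))
        overrides_b = sim.get("overrides_b", sim.get("overrides", {}))
        pair = simulate_species_pair(
            preset(sim.get("preset_a", "threespine"), seed, **overrides_a),
            preset(sim.get("preset_b", "tubesnout"), seed + 1, **overrides_b),
            convergent_fraction=sim.get("convergent_fraction", 0.0),
            seed=seed,
            out_dir=out,
        )
        name_a = pair.dataset_a.cfg.species
        name_b = pair.dataset_b.cfg.species
        inputs = {
            "species_a": {
                "name": name_a,
                "vcf": pair.dataset_a.vcf_path,
                "gff": pair.dataset_a.gff_path,
                "meta": str(out / f"{name_a}.meta.tsv"),
            },
            "species_b": {
                "name": name_b,
                "vcf": pair.dataset_b.vcf_path,
                "gff": pair.dataset_b.gff_path,
                "meta": str(out / f"{name_b}.meta.tsv"),
            },
            "orthologs": pair.ortholog_path,
        }
        manifest["stages"]["simulate"] = {
            "n_snps_a": len(pair.dataset_a.frame),
            "n_snps_b": len(pair.dataset_b.frame),
            "n_ortholog_pairs": len(pair.orthologs),
        }
    else:
        inputs = cfg["inputs"]

    results: dict[str, SpeciesResult] = {}
    for key in ("species_a", "species_b"):
        spec = inputs[key]
        res = _analyse_species(
            spec["name"], spec["vcf"], spec["gff"], spec["meta"], cfg, out
        )
        results[key] = res
        he_means = {
            m.pool_id: genomewide_summary(res.windows[f"he_{m.pool_id}"])[0]
            for m in res.meta
        }
        manifest["stages"][f"analyse_{spec['name']}"] = {
            "filter": {
                "total": res.filter_report.total,
                "passed": res.filter_report.passed,
                "removed": res.filter_report.removed,
            },
            "n_windows": len(res.windows),
            "n_genes": len(res.gene_records),
            "mean_window_he": he_means,
            "global_fst": global_fst(
                res.fst_frame["fst_num"].to_numpy(), res.fst_frame["fst_den"].to_numpy()
            ),
            "mean_snp_fst": genomewide_summary(res.snp_fst["fst"])[0],
            "snp_outlier_threshold": res.outlier_threshold,
            "n_top_candidates": int(sum(c.is_candidate for c in res.candidates)),
        }

    res_a, res_b = results["species_a"], results["species_b"]
    pairs_raw = read_ortholog_table(inputs["orthologs"])
    ofilt = cfg["ortholog_filter"]
    genes_a = [r.annotation for r in res_a.gene_records]
    genes_b = [r.annotation for r in res_b.gene_records]
    pairs = filter_orthologs(
        pairs_raw, genes_a, genes_b, ofilt["min_mapq"], ofilt["min_identity"]
    )
    manifest["stages"]["ortholog_filter"] = {
        "input_pairs": len(pairs_raw),
        "kept_pairs": len(pairs),
    }

    nw_cfg = NullWConfig(rng_seed=seed, **cfg.get("nullw", {}))
    flipped = [
        type(p)(p.gene_b, p.gene_a, p.mapping_quality, p.percent_identity, p.relation)
        for p in pairs
    ]
    directions = {
        f"{res_a.name}_to_{res_b.name}": (res_a.candidates, pairs, res_b),
        f"{res_b.name}_to_{res_a.name}": (res_b.candidates, flipped, res_a),
    }
    for label, (cands, orth, target) in directions.items():
        nw = null_w_test(
            cands, orth, target.gene_records, target.snp_fst["fst"].to_numpy(), nw_cfg
        )
        write_table(nw.table(), out / f"nullw_{label}.tsv", {"seed": seed})
        manifest["stages"][f"nullw_{label}"] = {
            "n_test_genes": len(nw.results),
            "n_null_genes": int(nw.null_z.size),
            "n_significant": int(sum(r.significant for r in nw.results)),
        }

    comp_rows = []
    for metric in ("fst", "he"):
        table = match_gene_scores(res_a.gene_records, res_b.gene_records, pairs, metric)
        if len(table) >= 3:
            corr = spearman_gene_correlation(table)
            upper, lower = extreme_overlap(table)
            comp_rows.append(
                {
                    "species_a": res_a.name,
                    "species_b": res_b.name,
                    "metric": metric,
                    "rho": corr.rho,
                    "p_value": corr.p_value,
                    "n_genes": corr.n_genes,
                    "shared_upper": upper,
                    "shared_lower": lower,
                }
            )
    comp = pd.DataFrame(comp_rows)
    write_table(comp, out / "comparison.tsv", {"seed": seed})
    manifest["stages"]["comparison"] = comp.to_dict("records")

    rho, tier = population_he_matrix(
        {res_a.name: res_a.windows, res_b.name: res_b.windows},
        {res_a.name: res_a.gene_records, res_b.name: res_b.gene_records},
        {res_a.name: res_a.meta, res_b.name: res_b.meta},
        {(res_a.name, res_b.name): pairs},
    )
    write_table(rho.reset_index(names="pool"), out / "population_he_rho.tsv", {"seed": seed})

    manifest["generated_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
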