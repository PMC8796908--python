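"""Synthetic multi-species Pool-seq datasets with known ground truth.

The differentiation model is Balding–Nichols: each SNP has an ancestral
frequency p0 ~ Uniform(0.05, 0.95) and every population draws its true
frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F), so allele frequencies have
mean p0 and variance F p0 (1-p0). SNPs inside planted "selected" genes
use an elevated F, mimicking a locally adapted locus. Pool-seq noise is
two-stage, matching the real sampling process: 2N allele copies are drawn
binomially from the population frequency, then reads are drawn binomially
(depth ~ Poisson) from the pool allele fraction. SNPs are unlinked; the
downstream analyses are marginal per SNP/gene, so linkage is out of
scope.

Named presets mirror the three study species qualitatively: moderate
differentiation with two pools (threespine-like F = 0.14, tubesnout-like
F = 0.12) and a bottlenecked four-pool scenario (ninespine-like F = 0.49
with sparse, low-frequency variation hence low H̄E). Pool sizes follow
the study populations and sequencing depth is 2N reads per pool.

``simulate_species_pair`` additionally builds a shared gene catalogue
with a configurable mix of 1:1 and 1:many ortholog links and an identity
distribution that leaves some pairs below the 90% filter, plus optional
convergently selected genes planted in both species.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import write_table
from .types import GeneAnnotation, OrthologPair, PopulationMeta


@dataclass
class SimulationConfig:
    species: str = "speciesA"
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_genes: int = 200
    gene_length: int = 2_000
    n_snps: int = 5_000
    pools: list[tuple[int, int]] = field(default_factory=lambda: [(50, 100), (50, 100)])
    baseline_fst: float = 0.14
    selected_genes: list[tuple[str, float]] = field(default_factory=list)
    p0_range: tuple[float, float] = (0.05, 0.95)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_fst < 1.0:
            raise ValueError("baseline_fst must be in (0, 1)")
        for _, f in self.selected_genes:
            if f <= self.baseline_fst:
                raise ValueError("elevated_fst must exceed baseline_fst")
        if len(self.pools) < 2:
            raise ValueError("each species needs at least 2 pools")

    def gene_id(self, i: int) -> str:
        return f"{self.species}_g{i:04d}"

    def meta(self) -> list[PopulationMeta]:
        """Pool metadata; the first half of the pools is northern."""
        out = []
        for i, (n_ind, _) in enumerate(self.pools):
            lat = "north" if i < len(self.pools) / 2 else "south"
            out.append(
                PopulationMeta(
                    pool_id=f"{self.species}_p{i}",
                    species=self.species,
                    n_individuals=n_ind,
                    latitude_class=lat,
                )
            )
        return out


@dataclass
class SpeciesDataset:
    cfg: SimulationConfig
    meta: list[PopulationMeta]
    frame: pd.DataFrame  # SNP table (io_formats schema)
    genes: list[GeneAnnotation]
    truth_snps: pd.DataFrame
    truth_genes: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    vcf_path: str | None = None
    gff_path: str | None = None


@dataclass
class PairDataset:
    dataset_a: SpeciesDataset
    dataset_b: SpeciesDataset
    orthologs: list[OrthologPair]
    truth_orthologs: pd.DataFrame
    ortholog_path: str | None = None


def _place_genes(cfg: SimulationConfig) -> list[GeneAnnotation]:
    """Evenly spaced, non-overlapping genes across the chromosomes."""
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    spacing = cfg.chromosome_length / per_chrom
    if spacing < cfg.gene_length:
        raise ValueError("gene placement exceeds chromosome length")
    genes = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = int(slot * spacing + (spacing - cfg.gene_length) / 2)
        genes.append(
            GeneAnnotation(
                gene_id=cfg.gene_id(i),
                chrom=chrom,
                start=start,
                end=start + cfg.gene_length,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


def simulate_species(cfg: SimulationConfig, out_dir: str | os.PathLike | None = None) -> SpeciesDataset:
    """Simulate one species' pooled variant calls, annotation and truth.

    Returns the dataset in memory; when ``out_dir`` is given, also writes
    ``<species>.vcf``, ``<species>.gff3``, ``<species>.meta.tsv`` and the
    truth tables, and records the paths on the dataset.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _place_genes(cfg)
    chrom_lengths = {
        f"chr{c + 1}": cfg.chromosome_length for c in range(cfg.n_chromosomes)
    }
    meta = cfg.meta()
    elevated = dict(cfg.selected_genes)

    # SNP positions: unique per chromosome, sorted
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(
            rng.choice(cfg.chromosome_length, size=per_chrom[c], replace=False)
        )
        positions.append(pos)
        chroms += [f"chr{c + 1}"] * per_chrom[c]
    positions = np.concatenate(positions)
    chroms = np.asarray(chroms, object)

    # per-SNP F: baseline, or elevated inside a selected gene
    fst_per_snp = np.full(cfg.n_snps, cfg.baseline_fst)
    gene_of_snp = np.full(cfg.n_snps, "", object)
    for g in genes:
        inside = (chroms == g.chrom) & (positions >= g.start) & (positions < g.end)
        gene_of_snp[inside] = g.gene_id
        if g.gene_id in elevated:
            fst_per_snp[inside] = elevated[g.gene_id]

    p0 = rng.uniform(*cfg.p0_range, cfg.n_snps)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, cfg.n_snps)) % 4
    qual = np.round(rng.uniform(30.0, 90.0, cfg.n_snps), 1)

    truth = {"chrom": chroms, "pos0": positions, "p0": p0, "fst_used": fst_per_snp,
             "gene_id": gene_of_snp}
    frame = {
        "chrom": chroms,
        "pos0": positions,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        "qual": qual,
        "n_alt": np.ones(cfg.n_snps, int),
    }
    with np.errstate(divide="ignore"):
        shape = (1.0 - fst_per_snp) / fst_per_snp
    for m, (n_ind, depth_target) in zip(meta, cfg.pools):
        p_pop = rng.beta(p0 * shape, (1.0 - p0) * shape)
        two_n = 2 * n_ind
        k = rng.binomial(two_n, p_pop)
        depth = rng.poisson(depth_target, cfg.n_snps)
        alt_reads = rng.binomial(depth, k / two_n)
        frame[f"ref_{m.pool_id}"] = depth - alt_reads
        frame[f"alt_{m.pool_id}"] = alt_reads
        truth[f"p_{m.pool_id}"] = p_pop
    frame = pd.DataFrame(frame)
    truth_snps = pd.DataFrame(truth)
    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "selected": [g.gene_id in elevated for g in genes],
            "fst_used": [elevated.get(g.gene_id, cfg.baseline_fst) for g in genes],
        }
    )

    ds = SpeciesDataset(
        cfg=cfg,
        meta=meta,
        frame=frame,
        genes=genes,
        truth_snps=truth_snps,
        truth_genes=truth_genes,
        chrom_lengths=chrom_lengths,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ds.vcf_path = str(out / f"{cfg.species}.vcf")
        ds.gff_path = str(out / f"{cfg.species}.gff3")
        write_vcf(frame, meta, chrom_lengths, ds.vcf_path)
        write_gff3(genes, ds.gff_path)
        write_table(truth_snps, out / f"{cfg.species}.truth_snps.tsv",
                    {"seed": cfg.rng_seed})
        write_table(truth_genes, out / f"{cfg.species}.truth_genes.tsv",
                    {"seed": cfg.rng_seed})
        from .io_formats import write_population_meta

        write_population_meta(meta, out / f"{cfg.species}.meta.tsv")
    return ds


def write_vcf(
    frame: pd.DataFrame,
    meta: Sequence[PopulationMeta],
    chrom_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Emit the SNP table as VCF 4.2 with per-sample DP and AD (ref,alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=poolscan {__version__}\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">\n'
        )
        samples = "\t".join(m.pool_id for m in meta)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for row in frame.itertuples(index=False):
            cells = [
                row.chrom,
                str(int(row.pos0) + 1),
                ".",
                row.ref,
                row.alt,
                f"{row.qual:g}",
                "PASS",
                ".",
                "DP:AD",
            ]
            for m in meta:
                r = int(getattr(row, f"ref_{m.pool_id}"))
                a = int(getattr(row, f"alt_{m.pool_id}"))
                cells.append(f"{r + a}:{r},{a}")
            fh.write("\t".join(cells) + "\n")


def write_gff3(genes: Sequence[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpoolscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def simulate_species_pair(
    cfg_a: SimulationConfig,
    cfg_b: SimulationConfig,
    convergent_fraction: float = 0.0,
    seed: int = 0,
    one2many_fraction: float = 0.1,
    identity_mean: float = 94.0,
    identity_sd: float = 3.0,
    convergent_fst: float | None = None,
    out_dir: str | os.PathLike | None = None,
) -> PairDataset:
    """Simulate two species sharing a gene catalogue and an ortholog map.

    Ortholog links are built index-to-index over the shared catalogue;
    ``one2many_fraction`` of genes get an extra cross-link (so they and
    their partners fail the 1:1 filter), alignment identity is Normal
    (``identity_mean``, ``identity_sd``) clipped to [70, 100], and mapping
    quality is a 90/10 mixture of Uniform(80, 100) and Uniform(40, 80),
    so some pairs fail each arm of the quality filter.
    Convergent genes are chosen among clean 1:1 pairs and planted with
    elevated F (default 4x baseline, capped at 0.9) in BOTH species.
    """
    if cfg_a.n_genes != cfg_b.n_genes:
        raise ValueError("paired configs must share n_genes")
    rng = np.random.default_rng(seed)
    n = cfg_a.n_genes

    # 90% well-aligned pairs, 10% poor alignments failing the mapq filter
    good = rng.random(n) < 0.9
    mapq = np.where(good, rng.uniform(80.0, 100.0, n), rng.uniform(40.0, 80.0, n))
    identity = np.clip(rng.normal(identity_mean, identity_sd, n), 70.0, 100.0)
    n_multi = int(round(one2many_fraction * n))
    multi_idx = np.sort(rng.choice(n, size=n_multi, replace=False)) if n_multi else np.empty(0, int)
    multi_set = set(int(i) for i in multi_idx)

    pairs: list[OrthologPair] = []
    for i in range(n):
        rel = "one2many" if i in multi_set else "one2one"
        pairs.append(
            OrthologPair(
                gene_a=cfg_a.gene_id(i),
                gene_b=cfg_b.gene_id(i),
                mapping_quality=float(mapq[i]),
                percent_identity=float(identity[i]),
                relation=rel,
            )
        )
    # extra links make 1:many structure: each flagged gene_a also maps to the
    # next flagged gene's b-side (cyclically), so both b-genes gain multiplicity
    for j, i in enumerate(multi_idx):
        partner = int(multi_idx[(j + 1) % len(multi_idx)])
        if partner == i:
            continue
        pairs.append(
            OrthologPair(
                gene_a=cfg_a.gene_id(int(i)),
                gene_b=cfg_b.gene_id(partner),
                mapping_quality=float(mapq[i]),
                percent_identity=float(identity[i]),
                relation="one2many",
            )
        )

    clean_11 = [
        i
        for i in range(n)
        if i not in multi_set and mapq[i] >= 80.0 and identity[i] >= 90.0
    ]
    frac_one2one = len(clean_11) / n
    if convergent_fraction > frac_one2one:
        raise ValueError(
            f"convergent_fraction {convergent_fraction} exceeds clean 1:1 fraction {frac_one2one:.3f}"
        )
    n_conv = int(round(convergent_fraction * n))
    conv_idx = (
        np.sort(rng.choice(np.asarray(clean_11), size=n_conv, replace=False))
        if n_conv
        else np.empty(0, int)
    )
    conv_set = set(int(i) for i in conv_idx)

    def planted(cfg: SimulationConfig) -> list[tuple[str, float]]:
        f = convergent_fst if convergent_fst is not None else min(0.9, 4 * cfg.baseline_fst)
        return list(cfg.selected_genes) + [(cfg.gene_id(i), f) for i in sorted(conv_set)]

    sub = rng.integers(0, 2**31 - 1, 2)
    ds_a = simulate_species(
        replace(cfg_a, selected_genes=planted(cfg_a), rng_seed=int(sub[0])), out_dir
    )
    ds_b = simulate_species(
        replace(cfg_b, selected_genes=planted(cfg_b), rng_seed=int(sub[1])), out_dir
    )

    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for p in pairs:
        count_a[p.gene_a] = count_a.get(p.gene_a, 0) + 1
        count_b[p.gene_b] = count_b.get(p.gene_b, 0) + 1
    truth = pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "relation": [p.relation for p in pairs],
            "mapping_quality": [p.mapping_quality for p in pairs],
            "percent_identity": [p.percent_identity for p in pairs],
            "expected_kept": [
                p.relation == "one2one"
                and p.mapping_quality >= 80.0
                and p.percent_identity >= 90.0
                and count_a[p.gene_a] == 1
                and count_b[p.gene_b] == 1
                for p in pairs
            ],
            "convergent": [
                p.gene_a in {cfg_a.gene_id(i) for i in conv_set} for p in pairs
            ],
        }
    )

    pd_out = PairDataset(ds_a, ds_b, pairs, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd_out.ortholog_path = str(out / "orthologs.tsv")
        write_table(
            pd.DataFrame(
                {
                    "gene_a": [p.gene_a for p in pairs],
                    "gene_b": [p.gene_b for p in pairs],
                    "mapping_quality": [p.mapping_quality for p in pairs],
                    "percent_identity": [p.percent_identity for p in pairs],
                    "relation": [p.relation for p in pairs],
                }
            ),
            pd_out.ortholog_path,
            {"seed": seed},
        )
        write_table(truth, out / "truth_orthologs.tsv", {"seed": seed})
    return pd_out


# ---------------------------------------------------------------------------
# presets mirroring the three study species (pool sizes as sampled; depth 2N)

PRESETS: dict[str, SimulationConfig] = {
    "threespine": SimulationConfig(
        species="threespine",
        pools=[(52, 104), (51, 102)],
        baseline_fst=0.14,
        n_snps=5_000,
    ),
    "tubesnout": SimulationConfig(
        species="tubesnout",
        pools=[(44, 88), (50, 100)],
        baseline_fst=0.12,
        n_snps=5_000,
    ),
    "ninespine": SimulationConfig(
        species="ninespine",
        pools=[(46, 92), (42, 84), (30, 60), (41, 82)],
        baseline_fst=0.49,
        n_snps=1_000,
        p0_range=(0.05, 0.5),
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A named species scenario with a fresh seed (raises on unknown name)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], rng_seed=seed, **overrides)
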