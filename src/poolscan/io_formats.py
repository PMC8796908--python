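"""Readers and writers for the formats the pipeline touches.

VCF (via cyvcf2) and GFF3 (via gffutils) are read into the internal data
model; ortholog maps and all result tables are tab-separated files with a
single ``#``-prefixed provenance comment line.

Pooled read depths are taken from per-sample depth fields; genotype calls
are ignored. Two depth conventions are supported and auto-detected:

* standard ``AD`` (ref,alt counts in one field), as emitted by GATK-style
  callers and by :mod:`poolscan.synthetic_data`;
* VarScan-style separate ``RD`` (ref depth) and ``AD`` (alt depth).
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .types import GeneAnnotation, OrthologPair, PooledVariant, PopulationMeta

ORTHOLOG_COLUMNS = ["gene_a", "gene_b", "mapping_quality", "percent_identity", "relation"]
META_COLUMNS = ["pool_id", "species", "n_individuals", "latitude_class"]


class VcfFormatError(ValueError):
    """A VCF record whose depth fields cannot be interpreted."""


def read_pooled_vcf(path: str | os.PathLike, meta: Sequence[PopulationMeta]) -> Iterator[PooledVariant]:
    """Yield one :class:`PooledVariant` per VCF record, in file order.

    Sample columns are matched to ``meta`` by pool id, not position.
    Multiallelic records are yielded with ``n_alt_alleles_at_site`` > 1
    (using the first ALT allele's counts); filtering is downstream.

    Raises
    ------
    KeyError
        If a declared pool has no sample column in the VCF.
    VcfFormatError
        If a record's depth fields are malformed or absent.
    """
    vcf = VCF(os.fspath(path))
    sample_index: dict[str, int] = {s: i for i, s in enumerate(vcf.samples)}
    order = []
    for m in meta:
        if m.pool_id not in sample_index:
            raise KeyError(
                f"pool {m.pool_id!r} declared in metadata has no sample column in {path}"
            )
        order.append(sample_index[m.pool_id])
    order = np.asarray(order)

    has_rd = "RD" in {h["ID"] for h in vcf.header_iter() if h.type == "FORMAT"}
    for rec_no, v in enumerate(vcf, start=1):
        ad = v.format("AD")
        if ad is None:
            raise VcfFormatError(f"record {rec_no} ({v.CHROM}:{v.POS}): no AD field")
        rd = v.format("RD") if has_rd else None
        if rd is not None:
            # VarScan convention: RD = ref reads, AD = alt reads.
            ref_reads = rd[:, 0]
            alt_reads = ad[:, 0]
        else:
            if ad.shape[1] < 2:
                raise VcfFormatError(
                    f"record {rec_no} ({v.CHROM}:{v.POS}): AD field has no alt depth"
                )
            ref_reads = ad[:, 0]
            alt_reads = ad[:, 1]
        ref_reads = np.where(ref_reads < 0, 0, ref_reads)
        alt_reads = np.where(alt_reads < 0, 0, alt_reads)
        counts = [(int(ref_reads[i]), int(alt_reads[i])) for i in order]
        yield PooledVariant(
            chrom=v.CHROM,
            pos=v.POS,
            ref_allele=v.REF,
            alt_allele=v.ALT[0] if v.ALT else "N",
            counts=counts,
            site_quality=float(v.QUAL) if v.QUAL is not None else 0.0,
            n_alt_alleles_at_site=len(v.ALT),
        )


def vcf_contig_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Contig lengths declared in the VCF header (empty if undeclared)."""
    vcf = VCF(os.fspath(path))
    try:
        return dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:
        return {}


def read_gff_genes(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read gene-level features from a GFF3 file.

    Only records of type ``gene`` are returned; coordinates are converted
    from GFF3 1-based closed to 0-based half-open. Duplicated gene ids are
    an error.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        from_string=False,
    )
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=None):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicated gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return genes


def read_ortholog_table(path: str | os.PathLike) -> list[OrthologPair]:
    """Read a cross-species ortholog map (TSV with a fixed header).

    No filtering happens at read time; quality/multiplicity filters live in
    :func:`poolscan.gene_level.filter_orthologs`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table {path} missing columns: {missing}")
    pairs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mapq = float(row.mapping_quality)
            ident = float(row.percent_identity)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {row_no}: non-numeric quality field") from exc
        pairs.append(
            OrthologPair(
                gene_a=str(row.gene_a),
                gene_b=str(row.gene_b),
                mapping_quality=mapq,
                percent_identity=ident,
                relation=str(row.relation),
            )
        )
    return pairs


def read_population_meta(path: str | os.PathLike) -> list[PopulationMeta]:
    """Read pool metadata (pool_id, species, n_individuals, latitude_class)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} missing columns: {missing}")
    return [
        PopulationMeta(
            pool_id=r.pool_id,
            species=r.species,
            n_individuals=int(r.n_individuals),
            latitude_class=r.latitude_class,
        )
        for r in df.itertuples(index=False)
    ]


def write_population_meta(meta: Sequence[PopulationMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "pool_id": [m.pool_id for m in meta],
            "species": [m.species for m in meta],
            "n_individuals": [m.n_individuals for m in meta],
            "latitude_class": [m.latitude_class for m in meta],
        }
    )
    write_table(df, path, params={"kind": "population_meta"})


# ---------------------------------------------------------------------------
# tabular SNP representation


def variants_to_frame(variants: Iterable[PooledVariant], meta: Sequence[PopulationMeta]) -> pd.DataFrame:
    """Collect variants into the pipeline's tabular SNP representation.

    One row per site with columns ``chrom, pos0, ref, alt, qual, n_alt``
    plus ``ref_<pool>`` / ``alt_<pool>`` read counts per pool.
    """
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos0": v.pos0,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "qual": v.site_quality,
            "n_alt": v.n_alt_alleles_at_site,
        }
        for m, (r, a) in zip(meta, v.counts):
            row[f"ref_{m.pool_id}"] = r
            row[f"alt_{m.pool_id}"] = a
        rows.append(row)
    cols = ["chrom", "pos0", "ref", "alt", "qual", "n_alt"]
    for m in meta:
        cols += [f"ref_{m.pool_id}", f"alt_{m.pool_id}"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_variants(frame: pd.DataFrame, meta: Sequence[PopulationMeta]) -> list[PooledVariant]:
    out = []
    for row in frame.itertuples(index=False):
        counts = [
            (int(getattr(row, f"ref_{m.pool_id}")), int(getattr(row, f"alt_{m.pool_id}")))
            for m in meta
        ]
        out.append(
            PooledVariant(
                chrom=row.chrom,
                pos=int(row.pos0) + 1,
                ref_allele=row.ref,
                alt_allele=row.alt,
                counts=counts,
                site_quality=float(row.qual),
                n_alt_alleles_at_site=int(row.n_alt),
            )
        )
    return out


# ---------------------------------------------------------------------------
# generic result tables


def write_table(df: pd.DataFrame, path: str | os.PathLike, params: dict | None = None) -> None:
    """Write a results table as TSV with one provenance comment line."""
    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# poolscan {__version__} {items}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
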