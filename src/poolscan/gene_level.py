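"""Gene-level aggregation: per-gene mean FST, window H̄E assignment, and
ortholog-map filtering down to clean 1:1 pairs.

Windowed H̄E cannot be computed per gene directly (windows are much longer
than genes), so each gene inherits the H̄E of the window holding most of
its span. Neighbouring genes therefore share window scores — accepted
pseudoreplication, which slightly overstates the significance of any true
cross-species correlation.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GeneAnnotation, GeneRecord, OrthologPair, PopulationMeta


def gene_mean_fst(
    genes: Sequence[GeneAnnotation],
    fst_frame: pd.DataFrame,
    collapse_pairs: bool = True,
) -> list[GeneRecord]:
    """Collect per-SNP FST values inside each gene and average them.

    ``fst_frame`` is the long table from :func:`poolscan.diversity.snp_fst_frame`.
    With ``collapse_pairs`` (default) multi-pair species first average the
    pairwise FST of each SNP across its north–south pairs, so every SNP
    contributes one value. Genes with no SNPs carry NaN means.
    """
    if collapse_pairs and {"pool_a", "pool_b"} <= set(fst_frame.columns):
        from .diversity import collapse_pairs_mean

        snp = collapse_pairs_mean(fst_frame)
    else:
        snp = fst_frame[["chrom", "pos0", "fst"]]
    snp = snp.dropna(subset=["fst"])

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in snp.groupby("chrom"):
        order = np.argsort(grp["pos0"].to_numpy())
        by_chrom[chrom] = (
            grp["pos0"].to_numpy(int)[order],
            grp["fst"].to_numpy(float)[order],
        )

    records = []
    for g in genes:
        vals: list[float] = []
        if g.chrom in by_chrom:
            pos, fst = by_chrom[g.chrom]
            lo = np.searchsorted(pos, g.start, side="left")
            hi = np.searchsorted(pos, g.end, side="left")
            vals = fst[lo:hi].tolist()
        records.append(GeneRecord(annotation=g, snp_fst_values=vals))
    return records


def assign_window_he(
    records: Sequence[GeneRecord],
    windows: pd.DataFrame,
    meta: Sequence[PopulationMeta],
) -> list[GeneRecord]:
    """Give each gene the per-population H̄E of its majority window.

    A gene spanning several windows is assigned the window with the
    largest base-pair overlap; an exact tie goes to the lower-coordinate
    window. Genes on chromosomes without windows keep empty assignments.
    """
    he_cols = [f"he_{m.pool_id}" for m in meta]
    by_chrom = {c: grp.sort_values("start").reset_index(drop=True) for c, grp in windows.groupby("chrom")}
    for rec in records:
        g = rec.annotation
        if g.chrom not in by_chrom:
            continue
        win = by_chrom[g.chrom]
        starts = win["start"].to_numpy(int)
        ends = win["end"].to_numpy(int)
        overlap = np.minimum(ends, g.end) - np.maximum(starts, g.start)
        overlap = np.clip(overlap, 0, None)
        if overlap.max() <= 0:
            continue
        best = int(np.argmax(overlap))  # argmax takes the first (leftmost) maximum
        rec.assigned_window = (g.chrom, int(starts[best]), int(ends[best]))
        rec.assigned_he = {
            m.pool_id: float(win.iloc[best][col]) for m, col in zip(meta, he_cols)
        }
    return list(records)


def _overlapping_gene_ids(genes: Sequence[GeneAnnotation]) -> set[str]:
    """Ids of genes sharing at least one base pair with another gene."""
    bad: set[str] = set()
    for _, group in pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    ).groupby("chrom"):
        grp = group.sort_values(["start", "end"]).reset_index(drop=True)
        prev_ids: list[tuple[int, str]] = []  # (end, gene_id) still open
        for row in grp.itertuples(index=False):
            prev_ids = [(e, gid) for e, gid in prev_ids if e > row.start]
            if prev_ids:
                bad.add(row.gene_id)
                bad.update(gid for _, gid in prev_ids)
            prev_ids.append((row.end, row.gene_id))
    return bad


def filter_orthologs(
    pairs: Sequence[OrthologPair],
    genes_a: Sequence[GeneAnnotation],
    genes_b: Sequence[GeneAnnotation],
    min_mapq: float = 80.0,
    min_identity: float = 90.0,
) -> list[OrthologPair]:
    """Reduce an ortholog map to clean one-to-one pairs.

    In order: (1) drop pairs with mapping quality < ``min_mapq`` or percent
    identity < ``min_identity``; (2) drop every pair whose gene occurs in
    more than one surviving pair (1:many and many:many links); (3) drop
    pairs whose gene overlaps another annotated gene within its species.
    Pairs naming genes absent from the annotations are dropped with a
    warning.
    """
    ids_a = {g.gene_id for g in genes_a}
    ids_b = {g.gene_id for g in genes_b}
    resolved = [p for p in pairs if p.gene_a in ids_a and p.gene_b in ids_b]
    n_unresolved = len(pairs) - len(resolved)
    if n_unresolved:
        warnings.warn(f"{n_unresolved} ortholog pairs with unresolvable gene ids dropped")

    surviving = [
        p for p in resolved
        if p.mapping_quality >= min_mapq and p.percent_identity >= min_identity
    ]

    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for p in surviving:
        count_a[p.gene_a] = count_a.get(p.gene_a, 0) + 1
        count_b[p.gene_b] = count_b.get(p.gene_b, 0) + 1
    surviving = [p for p in surviving if count_a[p.gene_a] == 1 and count_b[p.gene_b] == 1]

    bad_a = _overlapping_gene_ids(genes_a)
    bad_b = _overlapping_gene_ids(genes_b)
    return [p for p in surviving if p.gene_a not in bad_a and p.gene_b not in bad_b]


def gene_table(records: Sequence[GeneRecord], meta: Sequence[PopulationMeta]) -> pd.DataFrame:
    """Flatten gene records into the pipeline's per-gene results table."""
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "chrom": r.annotation.chrom,
            "start": r.annotation.start,
            "end": r.annotation.end,
            "n_snps": r.n_snps,
            "mean_fst": r.mean_fst,
        }
        for m in meta:
            row[f"he_{m.pool_id}"] = r.assigned_he.get(m.pool_id, np.nan)
        rows.append(row)
    cols = ["gene_id", "chrom", "start", "end", "n_snps", "mean_fst"] + [
        f"he_{m.pool_id}" for m in meta
    ]
    return pd.DataFrame(rows, columns=cols)
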