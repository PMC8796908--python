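"""Cross-species similarity analyses on ortholog-matched gene scores.

Species are compared through their filtered 1:1 ortholog pairs: each pair
contributes one point of matched per-gene scores (mean FST, or window H̄E
averaged over that species' populations). Similarity is summarised by
Spearman rank correlations, a population-by-population H̄E correlation
matrix, and counts of genes that are extreme (top/bottom tail) in both
species at once.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diversity import quantile_threshold
from .types import GeneRecord, OrthologPair, PopulationMeta


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_genes: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def gene_score(record: GeneRecord, metric: str) -> float:
    """One score per gene: mean FST, or H̄E averaged across populations."""
    if metric == "fst":
        return record.mean_fst
    if metric == "he":
        vals = [v for v in record.assigned_he.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")
    raise ValueError(f"unknown metric {metric!r}")


def match_gene_scores(
    records_a: Sequence[GeneRecord],
    records_b: Sequence[GeneRecord],
    orthologs: Sequence[OrthologPair],
    metric: str = "fst",
) -> pd.DataFrame:
    """Ortholog-matched per-gene scores for a species pair.

    Rows with a missing score on either side are dropped.
    """
    by_a = {r.gene_id: r for r in records_a}
    by_b = {r.gene_id: r for r in records_b}
    rows = []
    for p in orthologs:
        ra, rb = by_a.get(p.gene_a), by_b.get(p.gene_b)
        if ra is None or rb is None:
            continue
        sa, sb = gene_score(ra, metric), gene_score(rb, metric)
        if np.isfinite(sa) and np.isfinite(sb):
            rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b, "score_a": sa, "score_b": sb})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score_a", "score_b"])


def spearman_gene_correlation(pair_table: pd.DataFrame) -> CorrelationResult:
    """Spearman rho (midranks for ties, t-approximation p) on matched scores."""
    n = len(pair_table)
    if n < 3:
        raise ValueError("need at least 3 matched gene pairs")
    a = pair_table["score_a"].to_numpy(float)
    b = pair_table["score_b"].to_numpy(float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CorrelationResult(float("nan"), float("nan"), n)
    rho, p = spearmanr(a, b)
    return CorrelationResult(float(rho), float(p), n)


def significance_tier(p: float) -> str:
    """Figure-legend style stars: * p<.05, ** p<.01, *** p<.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def population_he_matrix(
    windows_by_species: dict[str, pd.DataFrame],
    records_by_species: dict[str, Sequence[GeneRecord]],
    meta_by_species: dict[str, Sequence[PopulationMeta]],
    orthologs_by_pair: dict[tuple[str, str], Sequence[OrthologPair]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrix of H̄E across every population pair.

    Within a species, populations are correlated over their shared genomic
    windows. Across species, windows are not homologous, so each species'
    window scores are projected onto genes (the gene's assigned window
    H̄E) and matched through the filtered ortholog map. Returns (rho
    matrix, significance-tier matrix) with unit diagonal; cells without
    shared support are NaN.
    """
    pools: list[tuple[str, str]] = []  # (species, pool_id)
    for sp, meta in meta_by_species.items():
        pools += [(sp, m.pool_id) for m in meta]
    labels = [p for _, p in pools]
    rho = pd.DataFrame(np.eye(len(pools)), index=labels, columns=labels)
    tier = pd.DataFrame("", index=labels, columns=labels)

    def oriented_orthologs(sa: str, sb: str):
        if (sa, sb) in orthologs_by_pair:
            return orthologs_by_pair[(sa, sb)], False
        if (sb, sa) in orthologs_by_pair:
            return orthologs_by_pair[(sb, sa)], True
        return None, False

    for i, (sp_i, pool_i) in enumerate(pools):
        for j in range(i + 1, len(pools)):
            sp_j, pool_j = pools[j]
            if sp_i == sp_j:
                win = windows_by_species[sp_i]
                x = win[f"he_{pool_i}"].to_numpy(float)
                y = win[f"he_{pool_j}"].to_numpy(float)
            else:
                orth, flipped = oriented_orthologs(sp_i, sp_j)
                if orth is None:
                    rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                    continue
                by_i = {r.gene_id: r for r in records_by_species[sp_i]}
                by_j = {r.gene_id: r for r in records_by_species[sp_j]}
                x, y = [], []
                for p in orth:
                    id_i, id_j = (p.gene_b, p.gene_a) if flipped else (p.gene_a, p.gene_b)
                    ri, rj = by_i.get(id_i), by_j.get(id_j)
                    if ri is None or rj is None:
                        continue
                    xi = ri.assigned_he.get(pool_i, np.nan)
                    yj = rj.assigned_he.get(pool_j, np.nan)
                    if np.isfinite(xi) and np.isfinite(yj):
                        x.append(xi)
                        y.append(yj)
                x, y = np.asarray(x), np.asarray(y)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p_val = spearmanr(x[ok], y[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            tier.iloc[i, j] = tier.iloc[j, i] = significance_tier(p_val)
    return rho, tier


def extreme_overlap(
    pair_table: pd.DataFrame, upper_q: float = 0.95, lower_q: float = 0.05
) -> tuple[int, int]:
    """Count genes extreme in BOTH species of a matched pair table.

    Quantile thresholds are computed per species over the matched set;
    shared-upper genes are strictly above the upper threshold on both
    sides, shared-lower strictly below the lower threshold on both.
    """
    if len(pair_table) == 0:
        return 0, 0
    a = pair_table["score_a"].to_numpy(float)
    b = pair_table["score_b"].to_numpy(float)
    ua, ub = quantile_threshold(a, upper_q), quantile_threshold(b, upper_q)
    la, lb = quantile_threshold(a, lower_q), quantile_threshold(b, lower_q)
    shared_upper = int(np.sum((a > ua) & (b > ub)))
    shared_lower = int(np.sum((a < la) & (b < lb)))
    return shared_upper, shared_lower
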