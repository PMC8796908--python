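r"""Per-SNP and windowed diversity statistics from pooled read counts.

Expected heterozygosity
    Per SNP and pool, the biallelic plug-in :math:`H_E = 2\hat p(1-\hat p)`
    with :math:`\hat p` the alt-read frequency. Windowed H̄E divides the
    summed per-SNP :math:`H_E` by the full window length, so invariant
    sites contribute zeros — a per-base-pair diversity on [0, 0.5].

FST
    The default per-SNP estimator is a method-of-moments ANOVA estimator
    that corrects for the two-stage sampling of Pool-seq (2N allele copies
    per pool, then reads with replacement from those copies). With pool
    haploid sizes :math:`n_i`, read depths :math:`c_i` and read
    frequencies :math:`\hat p_i`, let

    .. math:: a_i = \frac{n_i + c_i - 1}{n_i c_i}, \qquad
              \hat\pi_i = \frac{\hat p_i(1-\hat p_i)}{1 - a_i},

    where :math:`\hat\pi_i` unbiasedly estimates :math:`p_i(1-p_i)`. Then

    .. math:: \widehat{\mathrm{Num}} = (\hat p_1-\hat p_2)^2
                  - a_1\hat\pi_1 - a_2\hat\pi_2, \qquad
              \widehat{\mathrm{Den}} = (\hat p_1-\hat p_2)^2
                  + \hat p_1(1-\hat p_1) + \hat p_2(1-\hat p_2),

    both unbiased for the numerator/denominator of pairwise FST in the
    Hudson parameterisation. Per-SNP FST is Num/Den; the genome-wide
    (multilocus) estimate is the ratio of sums over SNPs, which is the
    stable quantity for parameter recovery — per-SNP ratios are noisy and
    their arithmetic mean is biased toward zero.

    A read-depth-only Hudson estimator (no pool correction) is provided as
    a cross-check mode, along with the naive plug-in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import PooledVariant, PopulationMeta

WINDOW_SIZE_DEFAULT = 50_000


# ---------------------------------------------------------------------------
# per-SNP heterozygosity


def snp_he(p):
    """Expected heterozygosity 2p(1-p) of a biallelic site (NaN passes through)."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def pool_frequency_arrays(
    frame: pd.DataFrame, meta: Sequence[PopulationMeta]
) -> tuple[np.ndarray, np.ndarray]:
    """Alt-read frequencies and depths per (SNP, pool) from a SNP table.

    Frequencies are NaN where a pool has zero depth at the site.
    """
    refs = np.stack([frame[f"ref_{m.pool_id}"].to_numpy(float) for m in meta], axis=1)
    alts = np.stack([frame[f"alt_{m.pool_id}"].to_numpy(float) for m in meta], axis=1)
    depths = refs + alts
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(depths > 0, alts / np.where(depths > 0, depths, 1), np.nan)
    return freqs, depths


# ---------------------------------------------------------------------------
# windowed H̄E


def read_callable_bed(path, chrom_lengths: dict[str, int], window_size: int) -> dict[str, np.ndarray]:
    """Callable base pairs per window from a BED mask (0-based half-open)."""
    callable_bp = {
        c: np.zeros(math.ceil(L / window_size)) for c, L in chrom_lengths.items()
    }
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for row in bed.itertuples(index=False):
        if row.chrom not in callable_bp:
            continue
        lo, hi = int(row.start), min(int(row.end), chrom_lengths[row.chrom])
        w = lo // window_size
        while lo < hi:
            w_end = min((w + 1) * window_size, hi)
            callable_bp[row.chrom][w] += w_end - max(lo, w * window_size)
            lo = w_end
            w += 1
    return callable_bp


def windowed_he(
    frame: pd.DataFrame,
    meta: Sequence[PopulationMeta],
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = WINDOW_SIZE_DEFAULT,
    callable_bp: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tile each chromosome with fixed windows and average per-SNP H_E.

    Window H̄E per pool is the sum of per-SNP heterozygosities divided by
    the window length (invariant sites count as zeros); a trailing partial
    window uses its actual length. An optional callable-site mask replaces
    the denominator with callable base pairs per window.

    Returns a table with ``chrom, start, end, n_snps`` and one
    ``he_<pool_id>`` column per pool.
    """
    if chrom_lengths is None:
        chrom_lengths = (
            frame.groupby("chrom")["pos0"].max().add(1).to_dict() if len(frame) else {}
        )
    freqs, _ = pool_frequency_arrays(frame, meta)
    he = snp_he(freqs)
    he = np.where(np.isnan(he), 0.0, he)

    rows = []
    pos0 = frame["pos0"].to_numpy(int) if len(frame) else np.empty(0, int)
    chroms = frame["chrom"].to_numpy() if len(frame) else np.empty(0, object)
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        n_win = max(1, math.ceil(length / window_size))
        sel = chroms == chrom
        cpos = pos0[sel]
        if cpos.size and cpos.max() >= length:
            raise ValueError(
                f"SNP at {chrom}:{cpos.max()} outside declared chromosome length {length}"
            )
        widx = cpos // window_size
        n_snps = np.bincount(widx, minlength=n_win)
        sums = np.zeros((n_win, len(meta)))
        for j in range(len(meta)):
            sums[:, j] = np.bincount(widx, weights=he[sel, j], minlength=n_win)
        for w in range(n_win):
            start = w * window_size
            end = min(start + window_size, length)
            denom = end - start
            if callable_bp is not None:
                denom = callable_bp[chrom][w]
            row = {"chrom": chrom, "start": start, "end": end, "n_snps": int(n_snps[w])}
            for j, m in enumerate(meta):
                row[f"he_{m.pool_id}"] = sums[w, j] / denom if denom > 0 else np.nan
            rows.append(row)
    cols = ["chrom", "start", "end", "n_snps"] + [f"he_{m.pool_id}" for m in meta]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# FST estimators (vectorised over SNPs)


def anova_fst_components(ref1, alt1, ref2, alt2, n1: int, n2: int):
    """Pool-corrected per-SNP FST numerator and denominator (see module docs)."""
    ref1, alt1, ref2, alt2 = (np.asarray(x, float) for x in (ref1, alt1, ref2, alt2))
    c1, c2 = ref1 + alt1, ref2 + alt2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(c1 > 0, alt1 / np.where(c1 > 0, c1, 1), np.nan)
        p2 = np.where(c2 > 0, alt2 / np.where(c2 > 0, c2, 1), np.nan)
        a1 = (n1 + c1 - 1.0) / (n1 * c1)
        a2 = (n2 + c2 - 1.0) / (n2 * c2)
        pi1 = p1 * (1 - p1) / (1 - a1)
        pi2 = p2 * (1 - p2) / (1 - a2)
        num = (p1 - p2) ** 2 - a1 * pi1 - a2 * pi2
        den = (p1 - p2) ** 2 + p1 * (1 - p1) + p2 * (1 - p2)
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def hudson_fst_components(ref1, alt1, ref2, alt2):
    """Hudson estimator with read-depth (but no pool-size) correction."""
    ref1, alt1, ref2, alt2 = (np.asarray(x, float) for x in (ref1, alt1, ref2, alt2))
    c1, c2 = ref1 + alt1, ref2 + alt2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(c1 > 0, alt1 / np.where(c1 > 0, c1, 1), np.nan)
        p2 = np.where(c2 > 0, alt2 / np.where(c2 > 0, c2, 1), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.where(c1 > 1, c1 - 1, np.nan)
            - p2 * (1 - p2) / np.where(c2 > 1, c2 - 1, np.nan)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    return np.where(bad, np.nan, num), np.where(bad, np.nan, den)


def plugin_fst_components(ref1, alt1, ref2, alt2):
    """Naive plug-in on read frequencies: no correction for any sampling stage."""
    ref1, alt1, ref2, alt2 = (np.asarray(x, float) for x in (ref1, alt1, ref2, alt2))
    c1, c2 = ref1 + alt1, ref2 + alt2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(c1 > 0, alt1 / np.where(c1 > 0, c1, 1), np.nan)
        p2 = np.where(c2 > 0, alt2 / np.where(c2 > 0, c2, 1), np.nan)
        num = (p1 - p2) ** 2
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    return np.where(bad, np.nan, num), np.where(bad, np.nan, den)


_ESTIMATORS = {
    "anova": None,  # dispatched specially (needs pool sizes)
    "hudson": hudson_fst_components,
    "plugin": plugin_fst_components,
}


def per_snp_fst(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Per-SNP ratio, NaN where the denominator is 0 (both pools fixed same)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, num / np.where(den != 0, den, 1), np.nan)


def global_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Multilocus ratio-of-sums FST over all SNPs with defined components."""
    ok = np.isfinite(num) & np.isfinite(den)
    d = den[ok].sum()
    return float(num[ok].sum() / d) if d > 0 else float("nan")


def collapse_pairs_mean(fst_frame: pd.DataFrame) -> pd.DataFrame:
    """One FST value per SNP: mean over a species' north–south pool pairs."""
    return (
        fst_frame.groupby(["chrom", "pos0"], sort=True)["fst"].mean().reset_index()
    )


@dataclass
class SnpFst:
    chrom: str
    pos0: int
    pool_a: str
    pool_b: str
    fst: float


def north_south_pairs(meta: Sequence[PopulationMeta]) -> list[tuple[str, str]]:
    """All (north, south) pool pairings within one species' metadata."""
    north = [m.pool_id for m in meta if m.latitude_class == "north"]
    south = [m.pool_id for m in meta if m.latitude_class == "south"]
    return [(a, b) for a in north for b in south]


def snp_fst_frame(
    frame: pd.DataFrame,
    meta: Sequence[PopulationMeta],
    pairs: Sequence[tuple[str, str]] | None = None,
    estimator: str = "anova",
) -> pd.DataFrame:
    """Per-SNP FST for designated pool pairs (default: all north–south pairs).

    Returns a table ``chrom, pos0, pool_a, pool_b, fst, fst_num, fst_den``;
    the component columns support the multilocus ratio-of-sums summary.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if pairs is None:
        pairs = north_south_pairs(meta)
        if not pairs:
            raise ValueError("no north-south pool pairs in metadata")
    by_id = {m.pool_id: m for m in meta}
    out = []
    for a, b in pairs:
        ma, mb = by_id[a], by_id[b]
        r1 = frame[f"ref_{a}"].to_numpy(float)
        a1 = frame[f"alt_{a}"].to_numpy(float)
        r2 = frame[f"ref_{b}"].to_numpy(float)
        a2 = frame[f"alt_{b}"].to_numpy(float)
        if estimator == "anova":
            num, den = anova_fst_components(r1, a1, r2, a2, ma.ploidy_per_pool, mb.ploidy_per_pool)
        else:
            num, den = _ESTIMATORS[estimator](r1, a1, r2, a2)
        out.append(
            pd.DataFrame(
                {
                    "chrom": frame["chrom"].to_numpy(),
                    "pos0": frame["pos0"].to_numpy(int),
                    "pool_a": a,
                    "pool_b": b,
                    "fst": per_snp_fst(num, den),
                    "fst_num": num,
                    "fst_den": den,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def snp_fst(
    variant: PooledVariant,
    meta: Sequence[PopulationMeta],
    pair: tuple[str, str],
    estimator: str = "anova",
) -> SnpFst:
    """Single-site convenience wrapper around the vectorised estimators."""
    idx = {m.pool_id: i for i, m in enumerate(meta)}
    ia, ib = idx[pair[0]], idx[pair[1]]
    (r1, a1), (r2, a2) = variant.counts[ia], variant.counts[ib]
    if estimator == "anova":
        num, den = anova_fst_components(
            [r1], [a1], [r2], [a2], meta[ia].ploidy_per_pool, meta[ib].ploidy_per_pool
        )
    else:
        num, den = _ESTIMATORS[estimator]([r1], [a1], [r2], [a2])
    return SnpFst(variant.chrom, variant.pos0, pair[0], pair[1], float(per_snp_fst(num, den)[0]))


# ---------------------------------------------------------------------------
# summaries


def genomewide_summary(values: Iterable[float]) -> tuple[float, float, int]:
    """Arithmetic mean, standard error (sd/sqrt(n)) and n over non-missing values."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return mean, se, n


def quantile_threshold(values: Iterable[float], q: float) -> float:
    """Nearest-rank empirical quantile: the ⌈nq⌉-th smallest value.

    Matches R's ``quantile(type = 1)``. The rank product is rounded to 9
    decimals before taking the ceiling so binary float dust (e.g.
    1000 × 0.999 = 999.0000000000001) cannot shift the rank.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("quantile of empty input")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    rank = int(math.ceil(round(arr.size * q, 9)))
    rank = min(max(rank, 1), arr.size)
    return float(np.sort(arr)[rank - 1])
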