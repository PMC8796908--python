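"""Top-candidate scan for local adaptation within one species.

SNP-level FST outliers are the sites strictly above the species-wide
0.999 empirical quantile. Each gene's outlier count is then compared with
what a binomial draw (n = SNPs in the gene, success probability 0.001)
would produce by chance: a gene is a top candidate when its outlier count
strictly exceeds the 0.999 quantile of that binomial. The success
probability stays at the nominal 0.001 — not the realised outlier
fraction — so sparse genomes are not penalised.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom

from .diversity import quantile_threshold
from .types import GeneRecord

OUTLIER_QUANTILE_DEFAULT = 0.999
P_SUCCESS_DEFAULT = 0.001


@dataclass
class TopCandidateResult:
    gene_id: str
    n_snps: int
    n_outliers: int
    binom_threshold: int | None
    is_candidate: bool
    outlier_quantile_used: float
    p_success: float


def fst_outlier_flags(
    fst: Sequence[float] | np.ndarray, q: float = OUTLIER_QUANTILE_DEFAULT
) -> tuple[np.ndarray, float]:
    """Flag SNPs whose FST strictly exceeds the species-wide q-quantile.

    Returns a boolean array aligned with ``fst`` (missing values are never
    outliers) and the nearest-rank threshold used.
    """
    arr = np.asarray(fst, float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot flag outliers on empty FST input")
    if finite.size < 1000:
        warnings.warn(
            f"only {finite.size} SNPs available; the {q} quantile is unstable"
        )
    threshold = quantile_threshold(finite, q)
    with np.errstate(invalid="ignore"):
        flags = np.where(np.isfinite(arr), arr > threshold, False)
    return flags.astype(bool), threshold


def binom_candidate_threshold(
    n_snps: int, p_success: float = P_SUCCESS_DEFAULT, q: float = OUTLIER_QUANTILE_DEFAULT
) -> int:
    """Smallest integer k with Binomial(n_snps, p_success) CDF(k) >= q."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return int(binom.ppf(q, n_snps, p_success))


def top_candidates(
    genes: Sequence[GeneRecord],
    snp_outlier_fst_threshold: float,
    q: float = OUTLIER_QUANTILE_DEFAULT,
    p_success: float = P_SUCCESS_DEFAULT,
) -> list[TopCandidateResult]:
    """Apply the binomial top-candidate rule to every gene.

    ``snp_outlier_fst_threshold`` is the species-wide SNP threshold from
    :func:`fst_outlier_flags`; a gene's outliers are its SNPs strictly
    above it. Candidacy requires strictly more outliers than the binomial
    quantile; genes without SNPs are never candidates.
    """
    results = []
    for g in genes:
        vals = np.asarray(g.snp_fst_values, float)
        vals = vals[np.isfinite(vals)]
        n = int(vals.size)
        n_out = int((vals > snp_outlier_fst_threshold).sum())
        if n == 0:
            results.append(
                TopCandidateResult(g.gene_id, 0, 0, None, False, q, p_success)
            )
            continue
        k = binom_candidate_threshold(n, p_success, q)
        results.append(
            TopCandidateResult(g.gene_id, n, n_out, k, n_out > k, q, p_success)
        )
    return results


def candidate_table(results: Sequence[TopCandidateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "n_snps": [r.n_snps for r in results],
            "n_outliers": [r.n_outliers for r in results],
            "binom_threshold": [
                r.binom_threshold if r.binom_threshold is not None else np.nan
                for r in results
            ],
            "is_candidate": [r.is_candidate for r in results],
            "outlier_quantile": [r.outlier_quantile_used for r in results],
            "p_success": [r.p_success for r in results],
        }
    )
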