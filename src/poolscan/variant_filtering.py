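"""Post-calling SNP filters for pooled variant tables.

A site passes when it is biallelic, its summed depth across pools reaches
``min_coverage``, its call quality reaches ``min_quality``, the pooled
minor-allele frequency reaches ``min_maf``, and the minor allele is
covered by at least ``min_minor_reads`` reads. The minor-allele frequency
is computed from read counts summed over every pool of the species
(``alt_total / depth_total``, folded to ``min(f, 1 - f)``) — the
multi-sample behaviour of a caller run on a combined pileup of all pools.

Coverage is total across pools by default, which makes the coverage floor
an "each individual represented at least once" guarantee for balanced
pools; ``per_pool_coverage`` switches to the stricter per-pool reading.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .types import PooledVariant

#: attribution order for the filter report (first failing rule wins)
RULES = ("multiallelic", "coverage", "quality", "maf", "min_reads")


@dataclass
class FilterConfig:
    min_coverage: int = 50
    min_quality: float = 20.0
    min_maf: float = 0.01
    min_minor_reads: int = 2
    drop_multiallelic: bool = True
    per_pool_coverage: bool = False

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_quality < 0 or self.min_minor_reads < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Removal counts per rule; ``passed + sum(removed) == total``."""

    total: int = 0
    passed: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})

    def conserved(self) -> bool:
        return self.passed + sum(self.removed.values()) == self.total


def failing_rule(v: PooledVariant, cfg: FilterConfig) -> str | None:
    """Name of the first rule the variant fails, or None if it passes."""
    if cfg.drop_multiallelic and v.n_alt_alleles_at_site != 1:
        return "multiallelic"
    if cfg.per_pool_coverage:
        if any(r + a < cfg.min_coverage for r, a in v.counts):
            return "coverage"
    elif v.total_depth < cfg.min_coverage:
        return "coverage"
    if v.site_quality < cfg.min_quality:
        return "quality"
    depth = v.total_depth
    alt = v.total_alt
    maf = min(alt, depth - alt) / depth if depth > 0 else 0.0
    if maf < cfg.min_maf:
        return "maf"
    if min(alt, depth - alt) < cfg.min_minor_reads:
        return "min_reads"
    return None


def filter_variants(
    variants: Iterable[PooledVariant], cfg: FilterConfig | None = None
) -> tuple[list[PooledVariant], FilterReport]:
    """Apply the SNP filters; return passing variants and a removal report."""
    cfg = cfg or FilterConfig()
    report = FilterReport()
    kept: list[PooledVariant] = []
    for v in variants:
        report.total += 1
        rule = failing_rule(v, cfg)
        if rule is None:
            report.passed += 1
            kept.append(v)
        else:
            report.removed[rule] += 1
    return kept, report


def iter_filter_variants(
    variants: Iterable[PooledVariant], cfg: FilterConfig, report: FilterReport
) -> Iterator[PooledVariant]:
    """Streaming variant of :func:`filter_variants`, updating ``report`` in place."""
    for v in variants:
        report.total += 1
        rule = failing_rule(v, cfg)
        if rule is None:
            report.passed += 1
            yield v
        else:
            report.removed[rule] += 1
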