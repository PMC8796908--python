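"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open internally; 1-based formats
(VCF, GFF3) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class PooledVariant:
    """One biallelic site with per-pool ref/alt read counts.

    ``pos`` is the 1-based VCF position; ``pos0`` gives the internal
    0-based coordinate. ``counts`` holds one ``(ref_reads, alt_reads)``
    pair per population pool, in the order declared by the metadata.
    ``n_alt_alleles_at_site`` is > 1 for multiallelic records; those are
    carried through reading and dropped by the variant filter.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: list[tuple[int, int]]
    site_quality: float = 0.0
    n_alt_alleles_at_site: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        if self.site_quality < 0:
            raise ValueError("site_quality must be >= 0")
        for ref, alt in self.counts:
            if ref < 0 or alt < 0:
                raise ValueError("read counts must be >= 0")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def total_depth(self) -> int:
        return sum(r + a for r, a in self.counts)

    @property
    def total_ref(self) -> int:
        return sum(r for r, _ in self.counts)

    @property
    def total_alt(self) -> int:
        return sum(a for _, a in self.counts)


@dataclass
class PopulationMeta:
    """One sequencing pool: a population sample of ``n_individuals`` diploids.

    ``ploidy_per_pool`` is the haploid sample size 2N used by the
    pool-aware FST estimator and the simulator.
    """

    pool_id: str
    species: str
    n_individuals: int
    latitude_class: str
    ploidy_per_pool: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.latitude_class not in ("north", "south"):
            raise ValueError(f"latitude_class must be north/south, got {self.latitude_class!r}")
        if self.ploidy_per_pool == 0:
            self.ploidy_per_pool = 2 * self.n_individuals
        elif self.ploidy_per_pool != 2 * self.n_individuals:
            raise ValueError("ploidy_per_pool must equal 2 * n_individuals")


@dataclass
class GeneAnnotation:
    """Gene interval in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class OrthologPair:
    """Cross-species gene link with alignment quality metadata."""

    gene_a: str
    gene_b: str
    mapping_quality: float
    percent_identity: float
    relation: str = "one2one"

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.relation not in ("one2one", "one2many", "many2many"):
            raise ValueError(f"bad relation {self.relation!r}")


@dataclass
class GeneRecord:
    """Per-gene aggregate: SNP FST values, their mean, and the window H_E
    assigned from the window holding most of the gene."""

    annotation: GeneAnnotation
    snp_fst_values: list[float] = field(default_factory=list)
    assigned_he: dict[str, float] = field(default_factory=dict)
    assigned_window: Optional[tuple[str, int, int]] = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_fst_values)

    @property
    def mean_fst(self) -> float:
        if not self.snp_fst_values:
            return float("nan")
        return float(sum(self.snp_fst_values)) / len(self.snp_fst_values)

    @property
    def gene_id(self) -> str:
        return self.annotation.gene_id


def pools_of_species(meta: list[PopulationMeta], species: str) -> list[PopulationMeta]:
    return [m for m in meta if m.species == species]
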