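"""Shared domain types.

Coordinate convention: every in-memory interval is 0-based half-open.
VCF positions are stored 1-based (as on disk) in :class:`VariantRecord`;
conversion to 0-based happens at the point of interval comparison.
Genotypes are unordered and unphased: a call is a sorted pair of allele
indices, or ``None`` for a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = ("+", "-")

Genotype = Optional[tuple[int, int]]


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open interval on a named sequence."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonRecord:
    """One source-assembly exon from the catalog.

    ``sequence`` is the exon DNA in chromosome-forward orientation; the
    orientation of the parent gene is carried separately in ``strand``.
    """

    exon_id: str
    gene_id: str
    gene_name: str
    chromosome: str
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"exon {self.exon_id}: empty sequence")


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotypes and a string-list INFO map."""

    chromosome: str
    position: int  # 1-based, as in the VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: dict[str, Genotype]
    info: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele:
            raise ValueError("empty REF allele")
        n_alt = len(self.alt_alleles)
        for sample, gt in self.genotypes.items():
            if gt is None:
                continue
            if any(a < 0 or a > n_alt for a in gt):
                raise ValueError(
                    f"{self.chromosome}:{self.position} sample {sample}: "
                    f"allele index out of range in {gt}"
                )

    @property
    def pos0(self) -> int:
        """0-based position of the reference base."""
        return self.position - 1

    def site_key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chromosome, self.position, self.ref_allele, self.alt_alleles)


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of an exon sequence onto the target assembly."""

    query_id: str
    target_chromosome: str
    target_interval: GenomeInterval
    strand: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    score: float

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"hit {self.query_id}: bad strand {self.strand!r}")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"hit {self.query_id}: bad identity")
        if self.alignment_length < self.mismatches:
            raise ValueError(f"hit {self.query_id}: mismatches exceed length")
        if self.target_interval.chromosome != self.target_chromosome:
            raise ValueError(f"hit {self.query_id}: chromosome mismatch")


@dataclass(frozen=True)
class LiftedFeature:
    """A BED-style interval on the target assembly carrying annotations.

    ``kind`` is ``"exon"`` (exon_id set, percent_identity set) or
    ``"gene"`` (gene span; exon_id empty, no identity value).
    """

    kind: str
    interval: GenomeInterval
    exon_id: str
    gene_id: str
    gene_name: str
    strand: str
    percent_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "gene"):
            raise ValueError(f"bad feature kind {self.kind!r}")
        if (self.kind == "exon") != bool(self.exon_id):
            raise ValueError("kind=exon iff exon_id is non-empty")
        if self.kind == "gene" and self.percent_identity is not None:
            raise ValueError("gene spans carry no identity value")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class LineSpec:
    """One mutant line: its samples, inheritance model, optional linkage."""

    line_id: str
    sample_ids: tuple[str, ...]
    inheritance: str  # "dominant" | "recessive"
    linkage_regions: Optional[tuple[GenomeInterval, ...]] = None

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError(f"line {self.line_id}: no samples")
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError(
                f"line {self.line_id}: unknown inheritance {self.inheritance!r}"
            )
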