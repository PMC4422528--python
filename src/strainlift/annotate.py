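"""Attach lifted exon and gene features to VCF records as INFO tags.

Five tags are written: EID (exon IDs containing the position), GID
(gene IDs of those exons), GIR (gene IDs of all gene spans overlapping
the position), GNM (gene names of the EID exons) and GNR (gene names of
the GIR genes).  Overlap is tested at the variant's POS base only; empty
tags are omitted; all lists are deduplicated and sorted.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from strainlift.models import LiftedFeature, VariantRecord

log = logging.getLogger(__name__)


class FeatureIndex:
    """Per-chromosome stabbing index over lifted features, split by kind."""

    def __init__(self, features: Iterable[LiftedFeature]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for f in features:
            key = (f.interval.chromosome, f.kind)
            tree = self._trees.get(key)
            if tree is None:
                tree = self._trees[key] = IntervalTree()
            tree.addi(f.interval.start, f.interval.end, f)

    def query(self, chromosome: str, pos0: int, kind: str) -> list[LiftedFeature]:
        """Features of ``kind`` whose half-open interval contains ``pos0``."""
        tree = self._trees.get((chromosome, kind))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos0)]

    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _ in self._trees}


def build_feature_index(features: Iterable[LiftedFeature]) -> FeatureIndex:
    return FeatureIndex(features)


def annotate_variants(
    records: Sequence[VariantRecord],
    index: FeatureIndex,
) -> list[VariantRecord]:
    """Annotate each record with the five lift-over INFO tags.

    Annotation is idempotent (the five tags are recomputed, any other
    INFO content is preserved) and conserves the record count.  Variants
    on chromosomes absent from the index get no annotation; one warning
    is logged per unknown chromosome.
    """
    known = index.chromosomes()
    warned: set[str] = set()
    out: list[VariantRecord] = []
    for rec in records:
        if rec.chromosome not in known and rec.chromosome not in warned:
            log.warning(
                "chromosome %s not covered by any lifted feature", rec.chromosome
            )
            warned.add(rec.chromosome)
        exons = index.query(rec.chromosome, rec.pos0, "exon")
        genes = index.query(rec.chromosome, rec.pos0, "gene")
        info = {k: list(v) for k, v in rec.info.items() if k not in
                ("EID", "GID", "GIR", "GNM", "GNR")}
        tags = {
            "EID": {f.exon_id for f in exons},
            "GID": {f.gene_id for f in exons},
            "GIR": {f.gene_id for f in genes},
            "GNM": {f.gene_name for f in exons if f.gene_name},
            "GNR": {f.gene_name for f in genes if f.gene_name},
        }
        for tag, values in tags.items():
            if values:
                info[tag] = sorted(values)
        out.append(
            VariantRecord(
                rec.chromosome,
                rec.position,
                rec.ref_allele,
                rec.alt_alleles,
                dict(rec.genotypes),
                info,
            )
        )
    return out
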