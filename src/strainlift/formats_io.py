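"""Readers and writers for every external format the pipeline touches.

Conversion between coordinate conventions happens only here: VCF
positions and 12-column tabular alignment hits are 1-based inclusive on
disk, BED and every in-memory interval are 0-based half-open.

Serialization is byte-stable: INFO list values are deduplicated and
sorted, genotypes are written unphased with ascending allele order, and
no timestamps are emitted, so re-running a command reproduces its output
byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from strainlift.models import (
    AlignmentHit,
    ExonRecord,
    FormatError,
    GenomeInterval,
    Genotype,
    LiftedFeature,
    VariantRecord,
)

log = logging.getLogger(__name__)

EXON_TABLE_COLUMNS = (
    "exon_id",
    "gene_id",
    "gene_name",
    "chromosome",
    "strand",
    "sequence",
)

#: The five lift-over INFO tags attached to annotated VCFs.
INFO_TAGS = ("EID", "GID", "GIR", "GNM", "GNR")

INFO_DESCRIPTIONS = {
    "EID": "Exon IDs of lifted exons overlapping the position",
    "GID": "Gene IDs for the exons in EID",
    "GIR": "Gene IDs for all lifted gene spans overlapping the position",
    "GNM": "Associated gene names for the exons in EID",
    "GNR": "Associated gene names for the genes in GIR",
}

ENU_INFO = (
    "ENU",
    "1 if the REF>ALT change is a predominant ENU-type substitution "
    "(T>C, A>G, T>A or A>T)",
)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a {name: sequence} map.

    The sequence name is the first whitespace-delimited token of each
    header.  Malformed or empty files raise :class:`FormatError` naming
    the offending line; duplicate sequence names are rejected.
    """
    path = Path(path)
    lineno = 0
    with open(path) as fh:
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>'"
                    )
                break
        else:
            raise FormatError(f"{path}: line {max(lineno, 1)}: empty FASTA file")

    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Bio.SeqIO wraps at 60 columns; kept for signature stability


# ---------------------------------------------------------------------------
# Exon catalog


def read_exon_table(path) -> list[ExonRecord]:
    """Read a tab-separated exon catalog into ExonRecords.

    Requires a header naming at least the six canonical columns
    (exon_id, gene_id, gene_name, chromosome, strand, sequence).  Rows
    with an empty sequence are skipped with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[ExonRecord] = []
    n_skipped = 0
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        seq = str(getattr(row, "sequence")).strip().upper()
        if not seq:
            n_skipped += 1
            continue
        exon_id = getattr(row, "exon_id")
        if exon_id in seen:
            raise FormatError(f"{path}: duplicate exon_id {exon_id!r}")
        seen.add(exon_id)
        records.append(
            ExonRecord(
                exon_id=exon_id,
                gene_id=getattr(row, "gene_id"),
                gene_name=getattr(row, "gene_name"),
                chromosome=getattr(row, "chromosome"),
                strand=getattr(row, "strand"),
                sequence=seq,
            )
        )
    if n_skipped:
        log.warning("%s: skipped %d row(s) with empty sequence", path, n_skipped)
    return records


def write_exon_table(exons: Iterable[ExonRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXON_TABLE_COLUMNS) + "\n")
        for e in exons:
            fh.write(
                f"{e.exon_id}\t{e.gene_id}\t{e.gene_name}\t"
                f"{e.chromosome}\t{e.strand}\t{e.sequence}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def _parse_genotype(token: str, path, lineno: int) -> Genotype:
    gt_field = token.split(":", 1)[0]
    if gt_field in (".", "./.", ".|."):
        return None
    parts = gt_field.replace("|", "/").split("/")
    if len(parts) != 2:
        raise FormatError(f"{path}: line {lineno}: unsupported genotype {token!r}")
    if "." in parts:
        return None
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise FormatError(
            f"{path}: line {lineno}: non-numeric genotype {token!r}"
        ) from exc
    return (a, b) if a <= b else (b, a)


def _parse_info(field: str) -> dict[str, list[str]]:
    if field in (".", ""):
        return {}
    info: dict[str, list[str]] = {}
    for item in field.split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = sorted(set(value.split(",")))
        else:
            info[item] = []
    return info


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF 4.x text file.

    Genotypes are normalized to unordered allele-index pairs (the phase
    separator is ignored); missing calls are kept as ``None``.  All INFO
    key=value pairs are parsed into the record's info map as sorted,
    deduplicated string lists.
    """
    path = Path(path)
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                samples = fields[9:] if len(fields) > 9 else []
                continue
            if samples is None:
                raise FormatError(
                    f"{path}: line {lineno}: data before #CHROM header"
                )
            fields = line.split("\t")
            expected = (9 if samples else 8) + len(samples)
            if len(fields) != expected:
                raise FormatError(
                    f"{path}: line {lineno}: expected {expected} columns, "
                    f"found {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt = fields[0:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric POS {pos_s!r}"
                ) from exc
            alts = tuple() if alt in (".", "") else tuple(alt.split(","))
            info = _parse_info(fields[7])
            genotypes = {
                sample: _parse_genotype(token, path, lineno)
                for sample, token in zip(samples, fields[9:])
            }
            try:
                records.append(
                    VariantRecord(chrom, pos, ref, alts, genotypes, info)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if samples is None:
        raise FormatError(f"{path}: missing #CHROM header line")
    return samples, records


def _format_info(info: dict[str, list[str]]) -> str:
    if not info:
        return "."
    parts = []
    for key in sorted(info):
        values = sorted(set(info[key]))
        parts.append(f"{key}={','.join(values)}" if values else key)
    return ";".join(parts)


def _format_genotype(gt: Genotype) -> str:
    if gt is None:
        return "./."
    a, b = sorted(gt)
    return f"{a}/{b}"


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path,
    extra_info: Iterable[tuple[str, str]] = (),
) -> None:
    """Write records as a multi-sample VCF 4.2 text file.

    The header always carries ##INFO definitions for the five lift-over
    tags (EID, GID, GIR, GNM, GNR); ``extra_info`` adds further
    (ID, description) string-typed definitions.  INFO values are written
    comma-separated in sorted order, genotypes unphased with "/" and
    ascending allele order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strainlift\n")
        for tag in INFO_TAGS:
            fh.write(
                f'##INFO=<ID={tag},Number=.,Type=String,'
                f'Description="{INFO_DESCRIPTIONS[tag]}">\n'
            )
        for tag, desc in extra_info:
            fh.write(
                f'##INFO=<ID={tag},Number=.,Type=String,Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT", *samples]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            missing = [s for s in samples if s not in rec.genotypes]
            if missing:
                raise ValueError(
                    f"{rec.chromosome}:{rec.position}: no genotype for "
                    f"sample(s) {', '.join(missing)}"
                )
            row = [
                rec.chromosome,
                str(rec.position),
                ".",
                rec.ref_allele,
                ",".join(rec.alt_alleles) if rec.alt_alleles else ".",
                ".",
                ".",
                _format_info(rec.info),
            ]
            if samples:
                row.append("GT")
                row.extend(_format_genotype(rec.genotypes[s]) for s in samples)
            fh.write("\t".join(row) + "\n")


def merge_identical_sites(
    cohorts: Sequence[tuple[Sequence[str], Sequence[VariantRecord]]],
) -> tuple[list[str], list[VariantRecord]]:
    """Merge per-line VCFs that were called on identical sites.

    Every input must present exactly the same (chrom, pos, ref, alts)
    sites in the same order and disjoint sample sets; genotype maps are
    unioned per site.  This is the only supported path for per-line
    inputs — the canonical input is one multi-sample VCF.
    """
    if not cohorts:
        raise ValueError("nothing to merge")
    all_samples: list[str] = []
    for samples, _ in cohorts:
        overlap = set(all_samples) & set(samples)
        if overlap:
            raise ValueError(f"duplicate sample(s) across inputs: {sorted(overlap)}")
        all_samples.extend(samples)
    first = cohorts[0][1]
    keys = [rec.site_key() for rec in first]
    for samples, records in cohorts[1:]:
        if [rec.site_key() for rec in records] != keys:
            raise ValueError("inputs do not present identical sites")
    merged = []
    for i, rec in enumerate(first):
        genotypes: dict[str, Genotype] = {}
        info: dict[str, list[str]] = {}
        for _, records in cohorts:
            genotypes.update(records[i].genotypes)
            for key, values in records[i].info.items():
                info[key] = sorted(set(info.get(key, [])) | set(values))
        merged.append(
            VariantRecord(
                rec.chromosome, rec.position, rec.ref_allele, rec.alt_alleles,
                genotypes, info,
            )
        )
    return all_samples, merged


# ---------------------------------------------------------------------------
# 12-column tabular alignment hits


def read_tabular_hits(path) -> list[AlignmentHit]:
    """Read alignment hits in the standard 12-column tabular dialect.

    Columns: query, subject, %identity, length, mismatches, gap opens,
    qstart, qend, sstart, send, evalue, bitscore.  Subject coordinates
    are 1-based inclusive; sstart > send denotes a minus-strand hit and
    is normalized to an ascending interval with the strand recorded.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, "
                    f"found {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatches = int(fields[4])
                gap_opens = int(fields[5])
                sstart = int(fields[8])
                send = int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric field: {exc}"
                ) from exc
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    target_chromosome=fields[1],
                    target_interval=GenomeInterval(fields[1], lo - 1, hi),
                    strand=strand,
                    percent_identity=pident,
                    alignment_length=length,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    score=bitscore,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# BED6


def _feature_name(f: LiftedFeature) -> str:
    return f"{f.kind}|{f.exon_id}|{f.gene_id}|{f.gene_name}"


def write_bed(features: Sequence[LiftedFeature], path) -> None:
    """Write features as BED6; the name field encodes
    ``kind|exon_id|gene_id|gene_name`` and the score column carries the
    percent identity for exon features ("." for gene spans)."""
    with open(path, "w") as fh:
        for f in features:
            score = f"{f.percent_identity:.2f}" if f.kind == "exon" else "."
            fh.write(
                f"{f.interval.chromosome}\t{f.interval.start}\t{f.interval.end}\t"
                f"{_feature_name(f)}\t{score}\t{f.strand}\n"
            )


def read_bed(path) -> list[LiftedFeature]:
    path = Path(path)
    features: list[LiftedFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 BED columns"
                )
            chrom, start_s, end_s, name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            parts = name.split("|")
            if len(parts) != 4 or parts[0] not in ("exon", "gene"):
                raise FormatError(
                    f"{path}: line {lineno}: malformed feature name {name!r}"
                )
            kind, exon_id, gene_id, gene_name = parts
            pident = float(score) if kind == "exon" else None
            features.append(
                LiftedFeature(
                    kind=kind,
                    interval=GenomeInterval(chrom, start, end),
                    exon_id=exon_id,
                    gene_id=gene_id,
                    gene_name=gene_name,
                    strand=strand,
                    percent_identity=pident,
                )
            )
    return features
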