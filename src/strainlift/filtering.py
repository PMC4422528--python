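"""Multi-line inheritance-model variant filtration cascade.

For each mutant line the cascade keeps the sites whose genotypes match
the line's inheritance model in every sequenced animal of the line while
every animal of every other line is homozygous reference, restricts to
exonic (or genic) positions, drops genes hit more than once, optionally
restricts to an experimentally determined linkage region, and flags the
predominant ENU substitution types (T>C, A>G, T>A, A>T).  The stage
counts mirror a per-line summary table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
import yaml

from strainlift.models import (
    FormatError,
    GenomeInterval,
    Genotype,
    LineSpec,
    VariantRecord,
)

log = logging.getLogger(__name__)

#: The predominant ENU-induced base changes (ordered ref>alt pairs).
ENU_PAIRS = frozenset({("T", "C"), ("A", "G"), ("T", "A"), ("A", "T")})

HOM_REF: Genotype = (0, 0)

SUMMARY_COLUMNS = [
    "line_id",
    "inheritance",
    "selected_genotype",
    "n_samples",
    "n_private",
    "n_exonic",
    "n_one_per_gene",
    "n_in_linkage",
    "n_enu_type",
]


def expected_genotype(inheritance: str) -> tuple[int, int]:
    """The genotype a causative variant must show in affected animals:
    homozygous alternative (1/1) for recessive lines, heterozygous (0/1)
    for dominant lines."""
    if inheritance == "recessive":
        return (1, 1)
    if inheritance == "dominant":
        return (0, 1)
    raise ValueError(f"unknown inheritance model {inheritance!r}")


def genotype_string(gt: tuple[int, int]) -> str:
    return f"{gt[0]}/{gt[1]}"


# ---------------------------------------------------------------------------
# Line configuration

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(text: str) -> GenomeInterval:
    """Parse a ``chrom:start-end`` region (1-based inclusive) into a
    0-based half-open interval."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise FormatError(f"malformed region {text!r} (expected chrom:start-end)")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise FormatError(f"malformed region {text!r}: bad coordinates")
    return GenomeInterval(chrom, start - 1, end)


def region_string(iv: GenomeInterval) -> str:
    return f"{iv.chromosome}:{iv.start + 1}-{iv.end}"


def parse_lines_config(path) -> list[LineSpec]:
    """Read a YAML line-definition config.

    Schema::

        lines:
          - line_id: line1
            samples: [line1_s1, line1_s2]
            inheritance: recessive
            regions: ["chr1:100-30000"]   # optional, 1-based inclusive

    Sample sets must be disjoint across lines.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "lines" not in data:
        raise FormatError(f"{path}: expected a top-level 'lines' list")
    lines: list[LineSpec] = []
    seen_samples: set[str] = set()
    for entry in data["lines"]:
        try:
            line_id = entry["line_id"]
            samples = tuple(entry["samples"])
            inheritance = entry["inheritance"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: malformed line entry {entry!r}") from exc
        overlap = seen_samples & set(samples)
        if overlap:
            raise FormatError(
                f"{path}: sample(s) {sorted(overlap)} appear in more than one line"
            )
        seen_samples.update(samples)
        regions = entry.get("regions")
        parsed = (
            tuple(parse_region(r) for r in regions) if regions else None
        )
        lines.append(LineSpec(line_id, samples, inheritance, parsed))
    if not lines:
        raise FormatError(f"{path}: no lines defined")
    return lines


def write_lines_config(lines: Sequence[LineSpec], path) -> None:
    data = {
        "lines": [
            {
                "line_id": spec.line_id,
                "samples": list(spec.sample_ids),
                "inheritance": spec.inheritance,
                **(
                    {"regions": [region_string(r) for r in spec.linkage_regions]}
                    if spec.linkage_regions
                    else {}
                ),
            }
            for spec in lines
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Filter stages


def _check_samples(records: Sequence[VariantRecord], lines: Sequence[LineSpec]) -> None:
    if not records:
        return
    present = set(records[0].genotypes)
    wanted = {s for spec in lines for s in spec.sample_ids}
    missing = sorted(wanted - present)
    if missing:
        raise ValueError(
            f"line config references sample(s) absent from the VCF: "
            f"{', '.join(missing)}"
        )


def private_line_filter(
    records: Sequence[VariantRecord],
    lines: Sequence[LineSpec],
    target_line_id: str,
    missing: str = "strict",
) -> list[VariantRecord]:
    """Keep sites private to the target line under its inheritance model.

    A site is kept iff every target-line sample carries the line's
    expected genotype and every sample of every other line is homozygous
    reference.  Under the strict missing-data policy any missing call
    among the tested samples excludes the site; the lenient policy treats
    missing calls in *other* lines as compatible with homozygous
    reference (a missing call in the target line always excludes).
    """
    if missing not in ("strict", "lenient"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    _check_samples(records, lines)
    by_id = {spec.line_id: spec for spec in lines}
    if target_line_id not in by_id:
        raise ValueError(f"unknown line {target_line_id!r}")
    target = by_id[target_line_id]
    expected = expected_genotype(target.inheritance)
    others = [spec for spec in lines if spec.line_id != target_line_id]

    kept: list[VariantRecord] = []
    for rec in records:
        if any(rec.genotypes.get(s) != expected for s in target.sample_ids):
            continue
        ok = True
        for spec in others:
            for s in spec.sample_ids:
                gt = rec.genotypes.get(s)
                if gt is None:
                    if missing == "strict":
                        ok = False
                        break
                elif gt != HOM_REF:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append(rec)
    return kept


def exonic_filter(
    records: Sequence[VariantRecord], level: str = "exon"
) -> list[VariantRecord]:
    """Keep annotated positions: inside exons (non-empty EID) at
    level="exon", inside gene spans (non-empty GIR) at level="gene"."""
    if level == "exon":
        tag = "EID"
    elif level == "gene":
        tag = "GIR"
    else:
        raise ValueError(f"unknown level {level!r}")
    return [rec for rec in records if rec.info.get(tag)]


def one_per_gene_filter(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Exclude private variants in genes holding more than one variant.

    A record is excluded iff any gene in its GIR tag holds two or more
    records of the input set (a mutagen hitting the same gene twice is
    highly unlikely, so multi-hit genes are treated as artefacts).
    Exclusion is evaluated against the input set, not recomputed
    iteratively.
    """
    gene_counts: dict[str, int] = {}
    for rec in records:
        for gene in rec.info.get("GIR", []):
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
    return [
        rec
        for rec in records
        if all(gene_counts[g] < 2 for g in rec.info.get("GIR", []))
    ]


def enu_type_flag(ref_allele: str, alt_allele: str) -> bool:
    """True iff ref>alt is one of the predominant ENU substitution types
    (T>C, A>G, T>A, A>T); indels and multi-base alleles are never
    flagged."""
    return (ref_allele.upper(), alt_allele.upper()) in ENU_PAIRS


def _carried_alt_indices(rec: VariantRecord, spec: LineSpec) -> set[int]:
    carried: set[int] = set()
    for s in spec.sample_ids:
        gt = rec.genotypes.get(s)
        if gt is not None:
            carried.update(a for a in gt if a > 0)
    return carried


def record_is_enu_type(rec: VariantRecord, spec: LineSpec) -> bool:
    """ENU typing evaluated per alt allele actually carried by the line."""
    return any(
        enu_type_flag(rec.ref_allele, rec.alt_alleles[a - 1])
        for a in _carried_alt_indices(rec, spec)
        if a - 1 < len(rec.alt_alleles)
    )


def linkage_restrict(
    records: Sequence[VariantRecord],
    regions: Optional[Sequence[GenomeInterval]],
) -> list[VariantRecord]:
    """Keep records whose POS base lies in any linkage region; with no
    regions configured the operation is the identity."""
    if not regions:
        return list(records)
    return [
        rec
        for rec in records
        if any(
            r.chromosome == rec.chromosome and r.contains(rec.pos0)
            for r in regions
        )
    ]


# ---------------------------------------------------------------------------
# The cascade


@dataclass(frozen=True)
class CascadeOptions:
    level: str = "exon"  # exonic restriction via EID ("exon") or GIR ("gene")
    missing: str = "strict"  # missing-genotype policy
    enu_only: bool = False  # make the ENU flag a hard filter


def run_cascade(
    records: Sequence[VariantRecord],
    lines: Sequence[LineSpec],
    options: CascadeOptions = CascadeOptions(),
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Apply the full filtration cascade per line.

    Stages: private genotype pattern -> exonic restriction ->
    one-per-gene -> linkage region (identity when no region is
    configured; the summary marks the stage not-applicable with NA) ->
    ENU flag (annotate-and-count by default, a hard filter with
    ``enu_only``).  Returns per-line candidate lists (flagged records
    carry INFO tag ENU=1) and the per-line stage-count summary; counts
    are non-increasing along the cascade.
    """
    candidates: dict[str, list[VariantRecord]] = {}
    rows = []
    for spec in lines:
        private = private_line_filter(
            records, lines, spec.line_id, missing=options.missing
        )
        exonic = exonic_filter(private, level=options.level)
        one_per_gene = one_per_gene_filter(exonic)
        in_linkage = linkage_restrict(one_per_gene, spec.linkage_regions)

        final: list[VariantRecord] = []
        n_enu = 0
        for rec in in_linkage:
            flagged = record_is_enu_type(rec, spec)
            if flagged:
                n_enu += 1
            if options.enu_only and not flagged:
                continue
            info = {k: list(v) for k, v in rec.info.items()}
            if flagged:
                info["ENU"] = ["1"]
            final.append(
                VariantRecord(
                    rec.chromosome,
                    rec.position,
                    rec.ref_allele,
                    rec.alt_alleles,
                    dict(rec.genotypes),
                    info,
                )
            )
        candidates[spec.line_id] = final
        rows.append(
            {
                "line_id": spec.line_id,
                "inheritance": spec.inheritance,
                "selected_genotype": genotype_string(
                    expected_genotype(spec.inheritance)
                ),
                "n_samples": len(spec.sample_ids),
                "n_private": len(private),
                "n_exonic": len(exonic),
                "n_one_per_gene": len(one_per_gene),
                "n_in_linkage": (
                    len(in_linkage) if spec.linkage_regions else pd.NA
                ),
                "n_enu_type": n_enu,
            }
        )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return candidates, summary


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write the stage-count summary as TSV; not-applicable linkage
    counts (lines with no region available) appear as NA."""
    summary.to_csv(path, sep="\t", index=False, na_rep="NA")
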