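"""Self-contained synthetic fixtures for the whole pipeline.

Emulates the experimental structure of a mutagenesis screen run against
a strain-matched alternative assembly: a source genome with an exon
catalog, a target genome diverged from it by i.i.d. substitutions
(optionally small indels), and a multi-line cohort VCF containing
strain-shared background variants, line-private noise variants, and
exactly one planted causative exonic ENU-type variant per line with the
genotype pattern of its inheritance model.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from strainlift import formats_io
from strainlift.filtering import expected_genotype, write_lines_config
from strainlift.models import (
    ExonRecord,
    GenomeInterval,
    Genotype,
    LineSpec,
    VariantRecord,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Per-line plan mirroring the screen the defaults emulate: eight lines,
#: (inheritance, animals sequenced, linkage region available).  Two
#: recessive lines sequenced at 4 animals; linkage regions for 3 lines.
STUDY_LINE_PLAN: tuple[tuple[str, int, bool], ...] = (
    ("recessive", 4, False),
    ("dominant", 4, False),
    ("dominant", 4, False),
    ("recessive", 4, True),
    ("dominant", 2, False),
    ("dominant", 2, False),
    ("dominant", 2, True),
    ("dominant", 2, True),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated genome pair and cohort."""

    n_chromosomes: int = 4
    chromosome_length: int = 120_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 250)
    intron_length: tuple[int, int] = (80, 400)
    intergenic_gap: tuple[int, int] = (200, 800)
    divergence_rate: float = 0.01  # per-base substitution source -> target
    indel_rate: float = 0.0  # per-base small-indel rate (default: none)
    indel_length: tuple[int, int] = (1, 5)
    n_lines: int = 8
    samples_per_line: tuple[int, int] = (2, 4)
    n_shared_strain_variants: int = 5000
    n_private_noise_per_line: int = 200
    noise_exonic_fraction: float = 0.4
    noise_genotype: str = "expected"  # worst case for the privacy filter
    linkage_region_length: int = 30_000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_chromosomes", "chromosome_length", "n_genes", "n_lines",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.divergence_rate < 0.1):
            raise ValueError("divergence_rate must be in [0, 0.1)")
        if not (0.0 <= self.noise_exonic_fraction <= 1.0):
            raise ValueError("noise_exonic_fraction must be in [0, 1]")
        if self.noise_genotype not in ("expected", "random"):
            raise ValueError(f"unknown noise_genotype {self.noise_genotype!r}")

    def line_plan(self, rng: np.random.Generator) -> list[tuple[str, int, bool]]:
        """(inheritance, n_samples, has_linkage) per line.  Uses the
        fixed eight-line plan when it applies, otherwise draws from the
        configured ranges."""
        if (
            self.n_lines == len(STUDY_LINE_PLAN)
            and self.samples_per_line == (2, 4)
        ):
            return list(STUDY_LINE_PLAN)
        lo, hi = self.samples_per_line
        return [
            (
                str(rng.choice(["dominant", "recessive"])),
                int(rng.integers(lo, hi + 1)),
                bool(rng.random() < 0.375),
            )
            for _ in range(self.n_lines)
        ]


class CoordinateMap:
    """Maps source-assembly positions onto the target assembly.

    With no indels the map is the identity.  With indels it is piecewise
    linear; positions deleted on the target map to ``None``.
    """

    def __init__(self, breakpoints: Optional[dict[str, list[tuple[int, int, int]]]] = None):
        # per chrom: sorted (src_start, offset, deleted_until) segments;
        # a source position p in [src_start, next_src_start) maps to
        # p + offset, unless p < deleted_until (deleted).
        self._segments = breakpoints or {}

    @property
    def is_identity(self) -> bool:
        return not self._segments

    def to_target(self, chromosome: str, pos0: int) -> Optional[int]:
        segs = self._segments.get(chromosome)
        if not segs:
            return pos0
        i = bisect.bisect_right(segs, (pos0, float("inf"), float("inf"))) - 1
        if i < 0:
            return pos0
        src_start, offset, deleted_until = segs[i]
        if pos0 < deleted_until:
            return None
        return pos0 + offset

    def segments(self) -> dict[str, list[tuple[int, int, int]]]:
        return {c: list(v) for c, v in self._segments.items()}


@dataclass
class GenomePair:
    source: dict[str, str]
    target: dict[str, str]
    exons: list[ExonRecord]
    exon_intervals: dict[str, GenomeInterval]  # source coordinates
    gene_intervals: dict[str, GenomeInterval]  # source coordinates
    coordinate_map: CoordinateMap
    config: SimConfig


@dataclass(frozen=True)
class PlantedVariant:
    line_id: str
    chromosome: str
    position: int  # 1-based, target assembly
    ref_allele: str
    alt_allele: str
    gene_id: str
    enu_type: bool


@dataclass
class TruthTable:
    plants: dict[str, PlantedVariant]
    shared_positions: set[tuple[str, int]]
    noise_positions: dict[str, set[tuple[str, int]]]


@dataclass
class Cohort:
    samples: list[str]
    records: list[VariantRecord]
    lines: list[LineSpec]
    truth: TruthTable


# ---------------------------------------------------------------------------
# Genome pair


def _random_genome(rng: np.random.Generator, config: SimConfig) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": rng.integers(0, 4, size=config.chromosome_length, dtype=np.uint8)
        for i in range(config.n_chromosomes)
    }


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _diverge(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        mask = rng.random(codes.size) < rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        out[mask] = (out[mask] + shifts) % 4
    return out


def _apply_indels(
    codes: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Introduce small indels; returns the new sequence and the
    coordinate-map segments (src_start, offset, deleted_until)."""
    n = codes.size
    positions = np.flatnonzero(rng.random(n) < config.indel_rate)
    pieces: list[np.ndarray] = []
    segments: list[tuple[int, int, int]] = [(0, 0, 0)]
    cursor = 0
    offset = 0
    lo, hi = config.indel_length
    for pos in positions:
        pos = int(pos)
        if pos < cursor:
            continue
        length = int(rng.integers(lo, hi + 1))
        pieces.append(codes[cursor:pos])
        if rng.random() < 0.5:  # deletion of [pos, pos+length)
            deleted_until = min(pos + length, n)
            offset -= deleted_until - pos
            segments.append((pos, offset, deleted_until))
            cursor = deleted_until
        else:  # insertion before pos
            pieces.append(rng.integers(0, 4, size=length, dtype=np.uint8))
            offset += length
            segments.append((pos, offset, 0))
            cursor = pos
    pieces.append(codes[cursor:])
    return np.concatenate(pieces), segments


def simulate_genome_pair(config: SimConfig) -> GenomePair:
    """Generate the source genome, its exon catalog, and the diverged
    target genome; deterministic given ``config.seed``.

    Genes are placed non-overlapping with stranded exons; catalog exon
    sequences are stored in chromosome-forward orientation.  The target
    is the source with i.i.d. substitutions at the divergence rate (and
    optional small indels, recorded in the coordinate map).
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 1])
    source_codes = _random_genome(rng, config)

    exons: list[ExonRecord] = []
    exon_intervals: dict[str, GenomeInterval] = {}
    gene_intervals: dict[str, GenomeInterval] = {}
    chrom_names = list(source_codes)
    cursors = {c: 0 for c in chrom_names}
    for g in range(config.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        gap = int(rng.integers(*_incl(config.intergenic_gap)))
        n_ex = int(rng.integers(*_incl(config.exons_per_gene)))
        ex_lens = [int(rng.integers(*_incl(config.exon_length))) for _ in range(n_ex)]
        in_lens = [
            int(rng.integers(*_incl(config.intron_length))) for _ in range(n_ex - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_len = sum(ex_lens) + sum(in_lens)
        start = cursors[chrom] + gap
        if start + gene_len > config.chromosome_length:
            raise ValueError(
                f"gene placement impossible at requested density on {chrom}"
            )
        gene_id = f"G{g:04d}"
        gene_name = f"Gene{g:04d}"
        pos = start
        for e, ex_len in enumerate(ex_lens):
            exon_id = f"E{g:04d}.{e + 1}"
            seq = _to_str(source_codes[chrom][pos : pos + ex_len])
            exons.append(
                ExonRecord(exon_id, gene_id, gene_name, chrom, strand, seq)
            )
            exon_intervals[exon_id] = GenomeInterval(chrom, pos, pos + ex_len)
            pos += ex_len
            if e < n_ex - 1:
                pos += in_lens[e]
        gene_intervals[gene_id] = GenomeInterval(chrom, start, start + gene_len)
        cursors[chrom] = start + gene_len

    target: dict[str, str] = {}
    segments: dict[str, list[tuple[int, int, int]]] = {}
    for chrom in chrom_names:
        diverged = _diverge(source_codes[chrom], config.divergence_rate, rng)
        if config.indel_rate > 0:
            diverged, segs = _apply_indels(diverged, config, rng)
            segments[chrom] = segs
        target[chrom] = _to_str(diverged)
    coord_map = CoordinateMap(segments if segments else None)
    return GenomePair(
        source={c: _to_str(v) for c, v in source_codes.items()},
        target=target,
        exons=exons,
        exon_intervals=exon_intervals,
        gene_intervals=gene_intervals,
        coordinate_map=coord_map,
        config=config,
    )


def _incl(bounds: tuple[int, int]) -> tuple[int, int]:
    lo, hi = bounds
    return lo, hi + 1


# ---------------------------------------------------------------------------
# Cohort


_ENU_ALTS = {"T": ("C", "A"), "A": ("G", "T")}


def _random_nonref(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return str(rng.choice(choices))


def simulate_cohort(config: SimConfig, pair: GenomePair) -> Cohort:
    """Simulate the multi-line genotype matrix on the target assembly.

    Shared strain variants are non-reference in every sample of every
    line; noise variants carry the owning line's expected genotype there
    and homozygous reference elsewhere (worst case for the privacy
    filter); exactly one causative exonic ENU-type variant is planted per
    line, in a gene no noise variant touches, with the line's expected
    genotype in all its samples and homozygous reference elsewhere.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 2])
    plan = config.line_plan(rng)
    lines_meta = []
    samples: list[str] = []
    for i, (inheritance, n_samples, has_linkage) in enumerate(plan):
        line_id = f"line{i + 1}"
        sample_ids = tuple(f"{line_id}_s{j + 1}" for j in range(n_samples))
        samples.extend(sample_ids)
        lines_meta.append((line_id, sample_ids, inheritance, has_linkage))

    cmap = pair.coordinate_map
    # Target-assembly exonic positions by gene.
    exonic_by_gene: dict[str, list[tuple[str, int]]] = {}
    for exon in pair.exons:
        iv = pair.exon_intervals[exon.exon_id]
        gene_positions = exonic_by_gene.setdefault(exon.gene_id, [])
        for src in range(iv.start, iv.end):
            tgt = cmap.to_target(iv.chromosome, src)
            if tgt is not None:
                gene_positions.append((iv.chromosome, tgt))

    used: set[tuple[str, int]] = set()
    plants: dict[str, PlantedVariant] = {}

    # Plant one causative ENU-type exonic variant per line, each in its
    # own gene.
    gene_order = [f"G{g:04d}" for g in rng.permutation(config.n_genes)]
    gene_iter = iter(gene_order)
    planted_genes: set[str] = set()
    for line_id, sample_ids, inheritance, _ in lines_meta:
        plant = None
        while plant is None:
            try:
                gene_id = next(gene_iter)
            except StopIteration:
                raise ValueError(
                    "not enough exonic positions for the requested plants"
                ) from None
            positions = exonic_by_gene.get(gene_id, [])
            eligible = [
                (c, p)
                for c, p in positions
                if (c, p) not in used and pair.target[c][p] in "AT"
            ]
            if not eligible:
                continue
            chrom, pos0 = eligible[int(rng.integers(len(eligible)))]
            ref = pair.target[chrom][pos0]
            alt = str(rng.choice(_ENU_ALTS[ref]))
            plant = PlantedVariant(
                line_id, chrom, pos0 + 1, ref, alt, gene_id, True
            )
            used.add((chrom, pos0))
            planted_genes.add(gene_id)
        plants[line_id] = plant

    # Noise variants: exonic ones go to genes no line's plant occupies;
    # the rest land anywhere outside every planted gene's source span.
    planted_spans = [pair.gene_intervals[g] for g in planted_genes]
    free_exonic = [
        (c, p)
        for gene_id, positions in sorted(exonic_by_gene.items())
        if gene_id not in planted_genes
        for c, p in positions
    ]
    chrom_names = list(pair.target)

    def _sample_free_position() -> tuple[str, int]:
        while True:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos0 = int(rng.integers(len(pair.target[chrom])))
            if (chrom, pos0) in used:
                continue
            if any(
                s.chromosome == chrom and s.contains(pos0) for s in planted_spans
            ):
                continue
            return chrom, pos0

    noise_positions: dict[str, set[tuple[str, int]]] = {}
    noise_sites: list[tuple[str, str, int]] = []  # (line_id, chrom, pos0)
    n_exonic_noise = round(config.noise_exonic_fraction * config.n_private_noise_per_line)
    for line_id, *_ in lines_meta:
        chosen: set[tuple[str, int]] = set()
        if n_exonic_noise:
            pool = [xy for xy in free_exonic if xy not in used]
            if len(pool) < n_exonic_noise:
                raise ValueError("not enough exonic positions for requested noise")
            idx = rng.choice(len(pool), size=n_exonic_noise, replace=False)
            for i in idx:
                chosen.add(pool[int(i)])
        while len(chosen) < config.n_private_noise_per_line:
            chosen.add(_sample_free_position())
        used.update(chosen)
        noise_positions[line_id] = {(c, p + 1) for c, p in chosen}
        noise_sites.extend((line_id, c, p) for c, p in sorted(chosen))

    shared_sites: list[tuple[str, int]] = []
    for _ in range(config.n_shared_strain_variants):
        site = _sample_free_position()
        used.add(site)
        shared_sites.append(site)

    # Assemble records.
    hom_ref: Genotype = (0, 0)
    records: list[VariantRecord] = []

    def _line_of(sample: str) -> str:
        return sample.rsplit("_", 1)[0]

    expected_by_line = {
        line_id: expected_genotype(inh) for line_id, _, inh, _ in lines_meta
    }

    for line_id, _, inheritance, _ in lines_meta:
        plant = plants[line_id]
        genotypes = {
            s: (expected_by_line[line_id] if _line_of(s) == line_id else hom_ref)
            for s in samples
        }
        records.append(
            VariantRecord(
                plant.chromosome,
                plant.position,
                plant.ref_allele,
                (plant.alt_allele,),
                genotypes,
            )
        )

    for line_id, chrom, pos0 in noise_sites:
        ref = pair.target[chrom][pos0]
        alt = _random_nonref(ref, rng)
        if config.noise_genotype == "expected":
            own_gt = expected_by_line[line_id]
            genotypes = {
                s: (own_gt if _line_of(s) == line_id else hom_ref) for s in samples
            }
        else:
            genotypes = {}
            for s in samples:
                if _line_of(s) == line_id:
                    genotypes[s] = ((0, 1), (1, 1))[int(rng.integers(2))]
                else:
                    genotypes[s] = hom_ref
        records.append(
            VariantRecord(chrom, pos0 + 1, ref, (alt,), genotypes)
        )

    for chrom, pos0 in shared_sites:
        ref = pair.target[chrom][pos0]
        alt = _random_nonref(ref, rng)
        genotypes = {
            s: ((0, 1), (1, 1))[int(rng.integers(2))] for s in samples
        }
        records.append(VariantRecord(chrom, pos0 + 1, ref, (alt,), genotypes))

    order = {c: i for i, c in enumerate(chrom_names)}
    records.sort(key=lambda r: (order[r.chromosome], r.position))

    # Line specs; linkage regions are windows around each plant.
    line_specs: list[LineSpec] = []
    for line_id, sample_ids, inheritance, has_linkage in lines_meta:
        regions = None
        if has_linkage:
            plant = plants[line_id]
            half = config.linkage_region_length // 2
            chrom_len = len(pair.target[plant.chromosome])
            start = max(0, plant.position - 1 - half)
            end = min(chrom_len, start + config.linkage_region_length)
            regions = (GenomeInterval(plant.chromosome, start, end),)
        line_specs.append(LineSpec(line_id, sample_ids, inheritance, regions))

    truth = TruthTable(
        plants=plants,
        shared_positions={(c, p + 1) for c, p in shared_sites},
        noise_positions=noise_positions,
    )
    return Cohort(samples=samples, records=records, lines=line_specs, truth=truth)


# ---------------------------------------------------------------------------
# Recovery evaluation


@dataclass
class RecoveryReport:
    per_line: pd.DataFrame
    sensitivity: float
    mean_false_positives: float
    shared_leakage: int


def evaluate_recovery(
    candidates: dict[str, Sequence[VariantRecord]],
    truth: TruthTable,
) -> RecoveryReport:
    """Compare per-line candidate lists against the simulation truth."""
    rows = []
    leak = 0
    for line_id, plant in sorted(truth.plants.items()):
        cands = candidates.get(line_id, [])
        sites = {(r.chromosome, r.position) for r in cands}
        found = (plant.chromosome, plant.position) in sites
        fp = len(sites) - int(found)
        n_shared = len(sites & truth.shared_positions)
        leak += n_shared
        rows.append(
            {
                "line_id": line_id,
                "planted_found": found,
                "false_positives": fp,
                "shared_in_candidates": n_shared,
                "n_candidates": len(sites),
            }
        )
    df = pd.DataFrame(rows)
    return RecoveryReport(
        per_line=df,
        sensitivity=float(df["planted_found"].mean()) if len(df) else float("nan"),
        mean_false_positives=(
            float(df["false_positives"].mean()) if len(df) else float("nan")
        ),
        shared_leakage=leak,
    )


# ---------------------------------------------------------------------------
# File output


def write_genome_pair(pair: GenomePair, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formats_io.write_fasta(pair.source, out / "source.fa")
    formats_io.write_fasta(pair.target, out / "target.fa")
    formats_io.write_exon_table(pair.exons, out / "exons.tsv")
    with open(out / "coordmap.tsv", "w") as fh:
        fh.write("kind\tid\tchromosome\tstart\tend\tstrand_or_offset\n")
        for exon in pair.exons:
            iv = pair.exon_intervals[exon.exon_id]
            fh.write(
                f"exon\t{exon.exon_id}\t{iv.chromosome}\t{iv.start}\t{iv.end}\t"
                f"{exon.strand}\n"
            )
        for gene_id, iv in sorted(pair.gene_intervals.items()):
            fh.write(
                f"gene\t{gene_id}\t{iv.chromosome}\t{iv.start}\t{iv.end}\t.\n"
            )
        for chrom, segs in sorted(pair.coordinate_map.segments().items()):
            for src_start, offset, deleted_until in segs:
                fh.write(
                    f"offset\t{chrom}\t{src_start}\t{deleted_until}\t.\t{offset}\n"
                )


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formats_io.write_vcf(cohort.records, cohort.samples, out / "cohort.vcf")
    write_lines_config(cohort.lines, out / "lines.yaml")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("kind\tline_id\tchromosome\tposition\tref\talt\tgene_id\n")
        for line_id, p in sorted(cohort.truth.plants.items()):
            fh.write(
                f"plant\t{line_id}\t{p.chromosome}\t{p.position}\t"
                f"{p.ref_allele}\t{p.alt_allele}\t{p.gene_id}\n"
            )
        for line_id, sites in sorted(cohort.truth.noise_positions.items()):
            for chrom, pos in sorted(sites):
                fh.write(f"noise\t{line_id}\t{chrom}\t{pos}\t.\t.\t.\n")
        for chrom, pos in sorted(cohort.truth.shared_positions):
            fh.write(f"shared\t.\t{chrom}\t{pos}\t.\t.\t.\n")
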