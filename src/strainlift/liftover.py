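"""Best single-hit lift-over of exon annotations onto a target assembly.

Each catalog exon sequence is aligned against the target genome and the
single highest-scoring local alignment is kept — one hit per sequence —
from which exon features and strand-aware gene spans are derived.

The built-in aligner is a k-mer seed-and-extend local aligner (seed
index with k=16 by default, candidate diagonals chained, banded affine
extension scored match +1 / mismatch -2 / gap open -4 / gap extend -1).
Externally computed hits in the 12-column tabular dialect can be used
instead via :func:`strainlift.formats_io.read_tabular_hits`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from strainlift.models import (
    AlignmentHit,
    ExonRecord,
    GenomeInterval,
    LiftedFeature,
)

log = logging.getLogger(__name__)

DEFAULT_K = 16
DEFAULT_MIN_COVERAGE = 0.7
DEFAULT_BAND = 16

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Seed index


class KmerIndex:
    """Exact k-mer position index over a genome.

    Stores forward-strand k-mer positions; reverse-strand seeding is done
    by looking up k-mers of the reverse-complemented query, so the index
    of a genome and of its reverse complement expose the same seed set
    with flipped strands.
    """

    def __init__(self, genome: Mapping[str, str], k: int = DEFAULT_K):
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        if not genome:
            raise ValueError("empty genome")
        if all(len(seq) < k for seq in genome.values()):
            raise ValueError(f"k={k} exceeds the length of every sequence")
        self.k = k
        positions: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.items():
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                positions.setdefault(kmer, []).append((name, i))
        self._positions = positions

    def lookup(self, kmer: str) -> Sequence[tuple[str, int]]:
        return self._positions.get(kmer, ())


def build_kmer_index(genome: Mapping[str, str], k: int = DEFAULT_K) -> KmerIndex:
    return KmerIndex(genome, k=k)


# ---------------------------------------------------------------------------
# Banded affine local alignment


@dataclass
class _Alignment:
    score: int
    q_start: int
    q_end: int  # 0-based half-open on the query
    t_start: int
    t_end: int  # 0-based half-open on the target window
    matches: int
    mismatches: int
    gap_opens: int
    columns: int


def banded_local_alignment(
    q: str,
    t: str,
    diag: int,
    band: int = DEFAULT_BAND,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> Optional[_Alignment]:
    """Affine-gap Smith-Waterman restricted to a band around ``diag``.

    ``diag`` is the expected offset t_pos - q_pos; cells with
    ``|t_pos - q_pos - diag| > band`` are not computed.  The first gapped
    column costs ``gap_open``, each further one ``gap_extend``.  Returns
    ``None`` if no positive-scoring cell exists.
    """
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return None
    W = 2 * band + 1
    NEG = -(1 << 30)
    M = [[NEG] * W for _ in range(n + 1)]
    X = [[NEG] * W for _ in range(n + 1)]  # gap in query (consumes target)
    Y = [[NEG] * W for _ in range(n + 1)]  # gap in target (consumes query)
    PM = [[0] * W for _ in range(n + 1)]  # 0 fresh start, 1 M, 2 X, 3 Y
    PX = [[0] * W for _ in range(n + 1)]  # 1 open from M, 2 extend
    PY = [[0] * W for _ in range(n + 1)]
    best = 0
    best_cell = None
    for i in range(1, n + 1):
        qc = q[i - 1]
        base = i + diag - band  # target position j at offset 0
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for o in range(W):
            j = base + o
            if j < 1 or j > m:
                continue
            s = match if qc == t[j - 1] else mismatch
            prev_best, ptr = 0, 0
            if Mp[o] > prev_best:
                prev_best, ptr = Mp[o], 1
            if Xp[o] > prev_best:
                prev_best, ptr = Xp[o], 2
            if Yp[o] > prev_best:
                prev_best, ptr = Yp[o], 3
            Mi[o] = prev_best + s
            PM[i][o] = ptr
            if o >= 1:
                opn = Mi[o - 1] + gap_open
                ext = Xi[o - 1] + gap_extend
                if opn >= ext:
                    Xi[o] = opn
                    PX[i][o] = 1
                else:
                    Xi[o] = ext
                    PX[i][o] = 2
            if o + 1 < W:
                opn = Mp[o + 1] + gap_open
                ext = Yp[o + 1] + gap_extend
                if opn >= ext:
                    Yi[o] = opn
                    PY[i][o] = 1
                else:
                    Yi[o] = ext
                    PY[i][o] = 2
            if Mi[o] > best:
                best = Mi[o]
                best_cell = (i, o)
    if best_cell is None or best <= 0:
        return None

    i, o = best_cell
    q_end = i
    t_end = i + diag - band + o
    matches = mismatches = gap_opens = 0
    columns = 0
    state = 1
    while True:
        if state == 1:
            j = i + diag - band + o
            columns += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            else:
                mismatches += 1
            ptr = PM[i][o]
            i -= 1
            if ptr == 0:
                break
            state = ptr
        elif state == 2:
            columns += 1
            if PX[i][o] == 1:
                gap_opens += 1
                state = 1
            o -= 1
        else:
            columns += 1
            if PY[i][o] == 1:
                gap_opens += 1
                state = 1
            i -= 1
            o += 1
    q_start = i
    t_start = i + diag - band + o
    return _Alignment(
        score=best,
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        columns=columns,
    )


# ---------------------------------------------------------------------------
# Seed chaining and best-hit search


def _candidate_diagonals(
    seq: str, index: KmerIndex, band: int
) -> list[tuple[str, int, int]]:
    """Cluster seed hits into candidate (chromosome, diagonal, weight)."""
    k = index.k
    counts: Counter[tuple[str, int]] = Counter()
    for i in range(len(seq) - k + 1):
        for chrom, pos in index.lookup(seq[i : i + k]):
            counts[(chrom, pos - i)] += 1
    if not counts:
        return []
    clusters: list[tuple[str, int, int]] = []
    cur_chrom = None
    cur: list[tuple[int, int]] = []
    for (chrom, diag) in sorted(counts):
        if cur and (chrom != cur_chrom or diag - cur[-1][0] > band):
            clusters.append(_close_cluster(cur_chrom, cur))
            cur = []
        cur_chrom = chrom
        cur.append((diag, counts[(chrom, diag)]))
    clusters.append(_close_cluster(cur_chrom, cur))
    # heaviest clusters first; deterministic tie-break on (chrom, diag)
    clusters.sort(key=lambda c: (-c[2], c[0], c[1]))
    return clusters


def _close_cluster(chrom: str, members: list[tuple[int, int]]) -> tuple[str, int, int]:
    weight = sum(c for _, c in members)
    rep = min((d for d, c in members if c == max(c for _, c in members)))
    return (chrom, rep, weight)


def find_best_hit(
    exon: ExonRecord,
    index: KmerIndex,
    genome: Mapping[str, str],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    band: int = DEFAULT_BAND,
    max_candidates: int = 5,
) -> Optional[AlignmentHit]:
    """Align one exon against the target genome; keep the best single hit.

    Both strands are searched; a hit is discarded when its alignment
    covers less than ``min_coverage`` of the exon length.  Returns
    ``None`` (logged at debug level) when no acceptable hit exists.
    """
    query = exon.sequence.upper()
    hits: list[AlignmentHit] = []
    for strand, seq in (("+", query), ("-", reverse_complement(query))):
        for chrom, diag, _weight in _candidate_diagonals(seq, index, band)[
            :max_candidates
        ]:
            target = genome[chrom]
            ws = max(0, diag - band - 2)
            we = min(len(target), diag + len(seq) + band + 2)
            if we <= ws:
                continue
            aln = banded_local_alignment(seq, target[ws:we], diag - ws, band)
            if aln is None:
                continue
            if (aln.q_end - aln.q_start) < min_coverage * len(seq):
                continue
            pident = round(100.0 * aln.matches / aln.columns, 2)
            hits.append(
                AlignmentHit(
                    query_id=exon.exon_id,
                    target_chromosome=chrom,
                    target_interval=GenomeInterval(
                        chrom, ws + aln.t_start, ws + aln.t_end
                    ),
                    strand=strand,
                    percent_identity=pident,
                    alignment_length=aln.columns,
                    mismatches=aln.mismatches,
                    gap_opens=aln.gap_opens,
                    score=float(aln.score),
                )
            )
    if not hits:
        log.debug("exon %s: no acceptable hit", exon.exon_id)
        return None
    return select_best(hits)


def select_best(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Pick the single best hit for one query.

    Maximizes (score, percent_identity, alignment_length); remaining ties
    go to the lowest (chromosome name, start).  Deterministic under any
    permutation of the input.
    """
    if not hits:
        raise ValueError("select_best: empty hit list")
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"select_best: hits for multiple queries {sorted(query_ids)}")
    return min(
        hits,
        key=lambda h: (
            -h.score,
            -h.percent_identity,
            -h.alignment_length,
            h.target_chromosome,
            h.target_interval.start,
            h.strand,
        ),
    )


# ---------------------------------------------------------------------------
# Feature derivation


def _compose_strands(a: str, b: str) -> str:
    return "+" if a == b else "-"


def lift_exons(
    exons: Sequence[ExonRecord],
    best_hits: Mapping[str, AlignmentHit],
) -> list[LiftedFeature]:
    """Turn per-exon best hits into exon features on the target assembly.

    The feature strand composes the source gene strand with the hit
    strand (two minuses give +).  Exons without a hit are dropped and
    counted in the logged run report.
    """
    catalog = {e.exon_id: e for e in exons}
    unknown = sorted(set(best_hits) - set(catalog))
    if unknown:
        raise ValueError(f"hits reference unknown exon id(s): {', '.join(unknown)}")
    features: list[LiftedFeature] = []
    for exon in exons:
        hit = best_hits.get(exon.exon_id)
        if hit is None:
            continue
        features.append(
            LiftedFeature(
                kind="exon",
                interval=hit.target_interval,
                exon_id=exon.exon_id,
                gene_id=exon.gene_id,
                gene_name=exon.gene_name,
                strand=_compose_strands(exon.strand, hit.strand),
                percent_identity=hit.percent_identity,
            )
        )
    n_unmapped = len(exons) - len(features)
    log.info(
        "lift-over: %d/%d exons mapped (%d unmapped)",
        len(features), len(exons), n_unmapped,
    )
    return features


def derive_gene_spans(exon_features: Sequence[LiftedFeature]) -> list[LiftedFeature]:
    """Derive one gene span per gene from its lifted exons.

    The span runs from the outermost exon start to the outermost exon end
    on the gene's majority chromosome; exons lifted to other chromosomes
    are excluded from the span and logged.  The gene strand is the
    majority exon strand (ties go to +).
    """
    by_gene: dict[str, list[LiftedFeature]] = defaultdict(list)
    for f in exon_features:
        if f.kind != "exon":
            raise ValueError("derive_gene_spans expects exon features only")
        by_gene[f.gene_id].append(f)
    spans: list[LiftedFeature] = []
    for gene_id in sorted(by_gene):
        feats = by_gene[gene_id]
        chrom_counts = Counter(f.interval.chromosome for f in feats)
        top = max(chrom_counts.values())
        chrom = min(c for c, v in chrom_counts.items() if v == top)
        kept = [f for f in feats if f.interval.chromosome == chrom]
        if len(kept) < len(feats):
            log.warning(
                "gene %s: %d exon(s) lifted off the majority chromosome %s; "
                "excluded from the gene span",
                gene_id, len(feats) - len(kept), chrom,
            )
        start = min(f.interval.start for f in kept)
        end = max(f.interval.end for f in kept)
        n_plus = sum(1 for f in kept if f.strand == "+")
        strand = "+" if 2 * n_plus >= len(kept) else "-"
        spans.append(
            LiftedFeature(
                kind="gene",
                interval=GenomeInterval(chrom, start, end),
                exon_id="",
                gene_id=gene_id,
                gene_name=kept[0].gene_name,
                strand=strand,
                percent_identity=None,
            )
        )
    return spans


def identity_summary(
    hits: Iterable[AlignmentHit],
    exon_chromosomes: Mapping[str, str],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-source-chromosome identity statistics and the overall mean.

    Returns a table with one row per source chromosome (n, min, mean of
    percent identity) and the mean over all hits, or ``None`` when there
    are no hits (flagged with a warning).
    """
    rows = [
        (exon_chromosomes[h.query_id], h.percent_identity) for h in hits
    ]
    if not rows:
        log.warning("identity_summary: no hits; overall mean undefined")
        return (
            pd.DataFrame(columns=["chromosome", "n", "min", "mean"]),
            None,
        )
    df = pd.DataFrame(rows, columns=["chromosome", "identity"])
    table = (
        df.groupby("chromosome")["identity"]
        .agg(n="count", min="min", mean="mean")
        .reset_index()
        .sort_values("chromosome", kind="mergesort")
        .reset_index(drop=True)
    )
    return table, float(df["identity"].mean())


def lift_catalog(
    exons: Sequence[ExonRecord],
    genome: Mapping[str, str],
    k: int = DEFAULT_K,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    band: int = DEFAULT_BAND,
) -> tuple[list[LiftedFeature], list[LiftedFeature], dict[str, AlignmentHit]]:
    """Run the whole lift-over: index, per-exon best hits, features, spans."""
    index = build_kmer_index(genome, k=k)
    best_hits: dict[str, AlignmentHit] = {}
    for exon in exons:
        hit = find_best_hit(
            exon, index, genome, min_coverage=min_coverage, band=band
        )
        if hit is not None:
            best_hits[exon.exon_id] = hit
    exon_features = lift_exons(exons, best_hits)
    gene_features = derive_gene_spans(exon_features)
    return exon_features, gene_features, best_hits
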