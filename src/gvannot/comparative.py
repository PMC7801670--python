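"""Cross-genome proteome comparison and gene-order collinearity.

Percent identity is computed from a global protein alignment (BLOSUM62,
affine gaps, end gaps penalized) as identical aligned residue pairs over
the full alignment length including gap columns, reported as a rounded
percentage — the ClustalW-style convention used in baculovirus annotation
tables. Homolog tables keep, per query ORF, the best hit by score plus any
secondary hits scoring within a configurable fraction of the best. Gene
parity analysis turns best hits into (rank in A, rank in B) points and
extracts maximal collinear / reverse-collinear runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class HomologPair:
    """A protein match between ordinals of two proteomes."""

    orf_a: int
    orf_b: int
    percent_identity: int
    aln_len: int
    score: float
    secondary: bool = False


@dataclass(frozen=True)
class ParityPoint:
    i: int  # ordinal rank in genome A
    j: int  # ordinal rank of the homolog in genome B


@dataclass(frozen=True)
class ParityCluster:
    points: tuple[ParityPoint, ...]
    direction: str  # "collinear" | "reverse"

    def __len__(self) -> int:
        return len(self.points)


@lru_cache(maxsize=4)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def _align(a: str, b: str, matrix: str, gap_open: float, gap_extend: float):
    aligner = _aligner(matrix, gap_open, gap_extend)
    # canonical order makes the result symmetric under argument swap even
    # when co-optimal alignments exist
    swapped = b < a
    first, second = (b, a) if swapped else (a, b)
    aln = aligner.align(first, second)[0]
    return aln


def percent_identity(
    prot_a: str,
    prot_b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    denominator: str = "alignment",
) -> tuple[int, int, float]:
    """(identity %, alignment length, score) for two proteins.

    ``denominator="alignment"`` divides identical pairs by the full
    alignment length (gap columns included); ``"shorter"`` divides by the
    shorter sequence's length.
    """
    if not prot_a or not prot_b:
        raise ValueError("empty protein sequence")
    if denominator not in {"alignment", "shorter"}:
        raise ValueError("denominator must be 'alignment' or 'shorter'")
    aln = _align(prot_a, prot_b, matrix, gap_open, gap_extend)
    identities = aln.counts().identities
    denom = aln.length if denominator == "alignment" else min(len(prot_a), len(prot_b))
    return round(100 * identities / denom), aln.length, aln.score


def _as_ordered(proteome) -> list[tuple[int, str]]:
    out = []
    for k, item in enumerate(proteome, start=1):
        if isinstance(item, str):
            out.append((k, item))
        elif hasattr(item, "protein"):
            out.append((item.index if item.index else k, item.protein))
        else:
            ordinal, prot = item
            out.append((int(ordinal), prot))
    return out


def build_homolog_table(
    proteome_a,
    proteome_b,
    min_identity: int = 20,
    keep_secondary: float = 0.9,
    **aln_kwargs,
) -> list[HomologPair]:
    """Best-hit (plus near-best secondary) homolog table of A against B.

    Proteomes are ordered collections of proteins: plain strings,
    ``(ordinal, protein)`` pairs, or ORF records. For each A protein the
    best-scoring B protein is reported when its identity is at least
    ``min_identity`` percent; further hits with score >=
    ``keep_secondary`` x best (and passing ``min_identity``) are flagged
    secondary. Ties break to the lower B ordinal.
    """
    A, B = _as_ordered(proteome_a), _as_ordered(proteome_b)
    if not A or not B:
        raise ValueError("empty proteome")
    table: list[HomologPair] = []
    for ord_a, prot_a in A:
        scored = []
        for ord_b, prot_b in B:
            ident, aln_len, score = percent_identity(prot_a, prot_b, **aln_kwargs)
            scored.append(HomologPair(ord_a, ord_b, ident, aln_len, score))
        scored.sort(key=lambda h: (-h.score, h.orf_b))
        best = scored[0]
        if best.percent_identity < min_identity:
            continue
        table.append(best)
        for h in scored[1:]:
            if h.score >= keep_secondary * best.score and \
                    h.percent_identity >= min_identity:
                table.append(HomologPair(h.orf_a, h.orf_b, h.percent_identity,
                                         h.aln_len, h.score, secondary=True))
    return table


def shared_count_and_mean_identity(
    table: Sequence[HomologPair],
) -> tuple[int, int | None]:
    """(# A-ORFs with a hit, rounded mean best-hit identity) of a table."""
    best: dict[int, HomologPair] = {}
    for h in table:
        if h.secondary:
            continue
        if h.orf_a not in best or h.score > best[h.orf_a].score:
            best[h.orf_a] = h
    if not best:
        return 0, None
    mean = sum(h.percent_identity for h in best.values()) / len(best)
    return len(best), round(mean)


def find_duplicates(
    proteome,
    min_identity: int = 95,
    **aln_kwargs,
) -> list[HomologPair]:
    """Intra-proteome duplicate gene pairs at >= ``min_identity`` percent."""
    P = _as_ordered(proteome)
    if len(P) < 2:
        raise ValueError("need at least two proteins")
    pairs = []
    for x in range(len(P)):
        for y in range(x + 1, len(P)):
            ident, aln_len, score = percent_identity(P[x][1], P[y][1], **aln_kwargs)
            if ident >= min_identity:
                pairs.append(HomologPair(P[x][0], P[y][0], ident, aln_len, score))
    return pairs


def parity_points(
    table: Sequence[HomologPair],
    n_a: int,
    n_b: int,
) -> list[ParityPoint]:
    """One (rank-in-A, rank-in-B) point per A-ORF best hit, A order."""
    best: dict[int, HomologPair] = {}
    for h in table:
        if h.secondary:
            continue
        if h.orf_a not in best or h.score > best[h.orf_a].score:
            best[h.orf_a] = h
    points = []
    for ord_a in sorted(best):
        h = best[ord_a]
        if not (1 <= h.orf_a <= n_a and 1 <= h.orf_b <= n_b):
            raise ValueError(f"ordinal out of range: {h}")
        points.append(ParityPoint(i=h.orf_a, j=h.orf_b))
    return points


def collinear_clusters(
    points: Sequence[ParityPoint],
    min_len: int = 3,
) -> list[ParityCluster]:
    """Maximal runs of consecutive gene-order points, length >= min_len.

    Within a run, successive i increase by exactly 1 while j steps by a
    constant +1 (collinear) or -1 (reverse). With ``min_len=1`` the
    returned clusters partition the input point list in order.
    """
    clusters: list[ParityCluster] = []
    run: list[ParityPoint] = []
    direction = 0

    def close() -> None:
        nonlocal run, direction
        if len(run) >= min_len:
            clusters.append(ParityCluster(
                points=tuple(run),
                direction="reverse" if direction < 0 else "collinear"))
        run, direction = [], 0

    for p in points:
        if not run:
            run.append(p)
            continue
        di, dj = p.i - run[-1].i, p.j - run[-1].j
        if di == 1 and dj in (1, -1) and (direction == 0 or dj == direction):
            run.append(p)
            direction = dj
        else:
            close()
            run.append(p)
    close()
    return clusters


def parity_tsv(
    points: Sequence[ParityPoint],
    clusters: Sequence[ParityCluster],
    path: str | Path,
) -> None:
    """Plot-ready TSV: i, j, cluster id (0 = unclustered), direction."""
    membership: dict[tuple[int, int], tuple[int, str]] = {}
    for cid, cl in enumerate(clusters, start=1):
        for p in cl.points:
            membership[(p.i, p.j)] = (cid, cl.direction)
    lines = ["i\tj\tcluster\tdirection"]
    for p in points:
        cid, direction = membership.get((p.i, p.j), (0, "."))
        lines.append(f"{p.i}\t{p.j}\t{cid}\t{direction}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
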