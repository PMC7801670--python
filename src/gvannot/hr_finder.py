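"""Homologous-region (hr) detection anchored on the conserved 10-bp core.

Baculovirus hrs are AT-rich regions of imperfect ~120-bp direct repeats,
each repeat carrying a highly conserved 10-bp core, TTAAT(G/A)TCGA, at
roughly the same offset. Because the core is the only fully specified
signature of the repeat unit, detection here scans both strands for the
core (within a Hamming-distance budget) and single-linkage clusters the
hits: clusters with two or more cores are major hrs, isolated cores are
short hrs and are labelled with a letter suffix on the preceding major hr
(the hr5a convention). An optional filter can require the clustered region
to be AT-rich.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from gvannot.genome_io import CircularGenome, gc_content, reverse_complement

CORE_CONSENSI = ("TTAATGTCGA", "TTAATATCGA")
CORE_LEN = 10


@dataclass(frozen=True)
class CoreHit:
    """One core-motif occurrence at forward-strand coordinates."""

    position: int  # 1-based start of the 10-mer on the forward strand
    strand: str    # "forward" | "reverse"
    mismatches: int


@dataclass(frozen=True)
class HrRegion:
    label: str
    start: int
    end: int
    cores: tuple[CoreHit, ...]
    klass: str  # "major" | "short"
    orientation_summary: str  # "all_forward" | "all_reverse" | "mixed"

    @property
    def repeat_count(self) -> int:
        return len(self.cores)


def _min_hamming(word: str) -> int:
    return min(sum(a != b for a, b in zip(word, consensus))
               for consensus in CORE_CONSENSI)


def find_cores(genome: CircularGenome, max_mismatch: int = 1) -> list[CoreHit]:
    """All core-motif hits on both strands, circular wrap included.

    A hit is any 10-mer within Hamming distance ``max_mismatch`` of either
    consensus; reverse-strand hits are reported at the forward-strand
    coordinate of the 10-mer's first base.
    """
    if max_mismatch >= 5:
        raise ValueError("max_mismatch >= 5 degenerates the 10-bp motif")
    if genome.length < CORE_LEN:
        raise ValueError("genome shorter than the core motif")
    L = genome.length
    fwd = genome.seq + (genome.seq[:CORE_LEN - 1] if genome.circular else "")
    hits: list[CoreHit] = []
    for i in range(len(fwd) - CORE_LEN + 1):
        word = fwd[i:i + CORE_LEN]
        if "N" in word:
            continue
        d = _min_hamming(word)
        if d <= max_mismatch:
            hits.append(CoreHit(position=i + 1, strand="forward", mismatches=d))
        d = _min_hamming(reverse_complement(word))
        if d <= max_mismatch:
            hits.append(CoreHit(position=i + 1, strand="reverse", mismatches=d))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _orientation(cores: Sequence[CoreHit]) -> str:
    strands = {c.strand for c in cores}
    if strands == {"forward"}:
        return "all_forward"
    if strands == {"reverse"}:
        return "all_reverse"
    return "mixed"


def cluster_hrs(
    cores: Sequence[CoreHit],
    max_gap: int = 400,
    flank: int = 60,
    genome_length: int | None = None,
    circular: bool = True,
    min_at_fraction: float | None = None,
    genome: CircularGenome | None = None,
) -> list[HrRegion]:
    """Single-linkage clustering of core hits into hr regions.

    Cores whose positions are within ``max_gap`` are merged (repeats ~120
    bp apart therefore co-cluster); on circular genomes the first and last
    clusters merge across the origin when close enough. Region bounds are
    ``[min core - flank, max core + 9 + flank]``. Major hrs (>= 2 cores)
    are labelled hr1..hrN in genome order; a short hr (single core) takes
    the preceding major hr's number with a letter suffix (hr5a style).
    ``min_at_fraction`` optionally drops regions whose spanned sequence is
    not AT-rich (requires ``genome``).
    """
    if not cores:
        return []
    cores = sorted(cores, key=lambda c: (c.position, c.strand))
    if genome is not None and genome_length is None:
        genome_length = genome.length
        circular = genome.circular

    clusters: list[list[CoreHit]] = [[cores[0]]]
    for hit in cores[1:]:
        if hit.position - clusters[-1][-1].position <= max_gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    if circular and len(clusters) > 1 and genome_length is not None:
        wrap_gap = (clusters[0][0].position + genome_length
                    - clusters[-1][-1].position)
        if wrap_gap <= max_gap:
            clusters[0] = clusters.pop() + clusters[0]

    regions: list[tuple[int, int, list[CoreHit]]] = []
    for cl in clusters:
        start = min(c.position for c in cl) - flank
        end = max(c.position for c in cl) + CORE_LEN - 1 + flank
        if genome_length is not None:
            if circular:
                start = (start - 1) % genome_length + 1
                end = (end - 1) % genome_length + 1
            else:
                start = max(1, start)
                end = min(genome_length, end)
        else:
            start = max(1, start)
        regions.append((start, end, cl))
    regions.sort(key=lambda r: min(c.position for c in r[2]))

    if min_at_fraction is not None:
        if genome is None:
            raise ValueError("AT-fraction filter requires the genome")
        kept = []
        for start, end, cl in regions:
            hi = end if end >= start else end + genome.length
            at = 1.0 - gc_content(genome.fetch(start, hi))
            if at >= min_at_fraction:
                kept.append((start, end, cl))
        regions = kept

    out: list[HrRegion] = []
    major_n = 0
    short_since_major = 0
    for start, end, cl in regions:
        if len(cl) >= 2:
            major_n += 1
            short_since_major = 0
            label = f"hr{major_n}"
        else:
            short_since_major += 1
            suffix = chr(ord("a") + short_since_major - 1)
            label = f"hr{major_n}{suffix}" if major_n else f"hr0{suffix}"
        out.append(HrRegion(
            label=label, start=start, end=end, cores=tuple(cl),
            klass="major" if len(cl) >= 2 else "short",
            orientation_summary=_orientation(cl),
        ))
    return out


def orientation_report(hrs: Iterable[HrRegion]) -> dict[str, str]:
    """Per-hr orientation call (the arrow summary of repeat directions)."""
    return {hr.label: hr.orientation_summary for hr in hrs}
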