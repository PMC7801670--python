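"""ORF enumeration, overlap curation, numbering and translation.

The ORF model is the common ORF-finder one: for every stop codon, in each
of the six reading frames, the open reading frame is the stretch from the
*first* (most upstream) ATG after the previous stop down to that stop, and
it is reported when it encodes at least ``min_codons`` amino acids (the
terminal stop excluded from the count). Nested shorter ATG variants of the
same stop are not reported separately. On a circular genome frames continue
across the origin; origin-wrapping ORFs are found by scanning the doubled
sequence and deduplicating by stop position modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from gvannot.genome_io import CircularGenome, normalize_origin, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class OrfConsistencyError(ValueError):
    """Raised when an ORF's coordinates contradict its genome."""


@dataclass
class OrfRecord:
    """One putative gene on a circular genome.

    ``start`` is the lower and ``end`` the higher 1-based genomic
    coordinate for non-wrapping ORFs; a wrapping ORF has ``start > end``
    and covers ``start..L`` plus ``1..end``. ``aa_length`` excludes the
    terminal stop, so the nucleotide span is ``3 * (aa_length + 1)`` and
    for non-wrapping records ``aa_length == (end - start + 1)/3 - 1``.
    """

    start: int
    end: int
    strand: str  # "sense" | "antisense"
    aa_length: int
    index: int = 0
    name: str = ""
    wraps_origin: bool = False
    protein: str = ""
    promoter_class: str = "unset"
    evidence_score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"sense", "antisense"}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def nt_length(self) -> int:
        """Nucleotide span including start and stop codons."""
        return 3 * (self.aa_length + 1)

    def intervals(self, genome_length: int | None = None) -> list[tuple[int, int]]:
        """Covered genomic interval(s), 1-based inclusive."""
        if not self.wraps_origin:
            return [(self.start, self.end)]
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping ORF")
        return [(self.start, genome_length), (1, self.end)]

    def atg_position(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "sense" else self.end


def _scan_strand(
    seq: str,
    circular: bool,
    min_codons: int,
    require_atg: bool,
) -> list[tuple[int, int, int]]:
    """ORFs on one strand given 5'->3'.

    Yields ``(start0, stop0, n_aa)`` with 0-based strand-local positions of
    the start codon and the stop codon (stop reduced modulo the length on
    circular input; each genomic stop reported at most once).
    """
    L = len(seq)
    s = seq + seq if circular else seq
    out: list[tuple[int, int, int]] = []
    for frame in range(3):
        open_starts: list[int] = []
        for d in range(frame, len(s) - 2, 3):
            codon = s[d:d + 3]
            if "N" in codon:
                # untranslatable codon terminates ORF extension
                open_starts = []
                continue
            if codon in STOP_CODONS:
                # circular: a stop is emitted from its second-copy
                # occurrence (complete upstream context); a stop codon
                # spanning the origin occurs only once, at d in
                # {L-2, L-1}, and is emitted from there. Each genomic
                # stop therefore lands here in exactly one frame.
                if not circular or d >= L - 2:
                    stop0 = d % L if circular else d
                    max_back = L - 3 if circular else d
                    starts = [a for a in open_starts if d - a <= max_back]
                    if starts:
                        n_aa = (d - starts[0]) // 3
                        if n_aa >= min_codons:
                            out.append((starts[0] % L, stop0, n_aa))
                open_starts = []
                continue
            if require_atg:
                if codon == START_CODON:
                    open_starts.append(d)
            elif not open_starts:
                open_starts.append(d)
    return out


def enumerate_orfs(
    genome: CircularGenome,
    min_codons: int = 50,
    require_atg: bool = True,
) -> list[OrfRecord]:
    """Enumerate ATG-initiated ORFs of >= ``min_codons`` codons, six frames.

    Output is sorted by lower genomic coordinate, then upper coordinate,
    then strand (sense first). Proteins are translated eagerly.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if genome.length < 3:
        raise ValueError("genome too short")
    L = genome.length
    records: list[OrfRecord] = []
    for strand in ("sense", "antisense"):
        s = genome.seq if strand == "sense" else reverse_complement(genome.seq)
        for a, stop0, n_aa in _scan_strand(
            s, genome.circular, min_codons, require_atg
        ):
            first = a                      # first coding base, strand-local
            last = (stop0 + 2) % L if genome.circular else stop0 + 2
            if strand == "sense":
                g_first, g_last = first, last
            else:
                g_first, g_last = L - 1 - last, L - 1 - first
            records.append(OrfRecord(
                start=g_first + 1,
                end=g_last + 1,
                strand=strand,
                aa_length=n_aa,
                wraps_origin=g_first > g_last,
            ))
    for rec in records:
        rec.protein = translate(genome, rec)
    records.sort(key=lambda r: (r.start, r.end, r.strand != "sense"))
    return records


def translate(genome: CircularGenome, orf: OrfRecord) -> str:
    """Standard-code translation of an ORF, excluding the terminal stop."""
    L = genome.length
    end = orf.end + L if orf.wraps_origin else orf.end
    cds = genome.fetch(orf.start, end)
    if orf.strand == "antisense":
        cds = reverse_complement(cds)
    if len(cds) % 3 != 0:
        raise OrfConsistencyError(
            f"ORF span {orf.start}..{orf.end} is not a codon multiple")
    if "N" in cds:
        raise OrfConsistencyError("ORF contains an untranslatable N codon")
    aa = str(Seq(cds).translate(table=1))
    if not aa.endswith("*"):
        raise OrfConsistencyError("ORF does not end with a stop codon")
    body = aa[:-1]
    if "*" in body:
        raise OrfConsistencyError("internal stop codon in ORF")
    if len(body) != orf.aa_length:
        raise OrfConsistencyError(
            f"aa_length {orf.aa_length} != translated length {len(body)}")
    return body


def _overlap_nt(a: OrfRecord, b: OrfRecord, L: int) -> int:
    """Nucleotide overlap of two (possibly wrapping) ORF spans."""
    total = 0
    for s1, e1 in a.intervals(L):
        for s2, e2 in b.intervals(L):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def curate_overlaps(
    orfs: Sequence[OrfRecord],
    max_overlap_frac: float = 0.5,
    evidence: Mapping[int, float] | None = None,
    genome_length: int | None = None,
) -> list[OrfRecord]:
    """Greedy minimal-overlap curation.

    ORFs are ranked by homology evidence (descending; absent evidence ranks
    below any evidence), then amino-acid length, then lower start, then
    sense strand first. Walking down the ranking, an ORF is discarded if it
    is completely contained in an already-retained ORF or if its nucleotide
    overlap with any retained ORF exceeds ``max_overlap_frac`` of the
    shorter ORF's length. ``evidence`` maps indices into ``orfs`` to
    scores; a record's own ``evidence_score`` is used otherwise. The
    retained set is returned in genome order.
    """
    if not orfs:
        return []
    if genome_length is None:
        genome_length = max(max(o.start, o.end) for o in orfs)

    def score(i: int) -> float:
        if evidence is not None and i in evidence:
            return evidence[i]
        if orfs[i].evidence_score is not None:
            return orfs[i].evidence_score
        return float("-inf")

    order = sorted(
        range(len(orfs)),
        key=lambda i: (-score(i), -orfs[i].aa_length,
                       orfs[i].start, orfs[i].strand != "sense"),
    )
    retained: list[OrfRecord] = []
    for i in order:
        cand = orfs[i]
        keep = True
        for kept in retained:
            ov = _overlap_nt(cand, kept, genome_length)
            if ov == cand.nt_length:          # completely contained
                keep = False
                break
            if ov > max_overlap_frac * min(cand.nt_length, kept.nt_length):
                keep = False
                break
        if keep:
            retained.append(cand)
    retained.sort(key=lambda r: (r.start, r.end, r.strand != "sense"))
    return retained


def number_orfs(
    genome: CircularGenome,
    orfs: Sequence[OrfRecord],
    anchor: OrfRecord,
) -> tuple[CircularGenome, list[OrfRecord]]:
    """Renumber ORFs with ``anchor``'s start codon as nucleotide 1.

    The genome is origin-normalized so the anchor's ATG begins at position
    1 reading in the anchor's sense (the granulin convention); coordinates
    are remapped, strands flipped if the anchor was antisense, and ORFs
    renumbered 1..n by ascending start coordinate. Returns the rotated
    genome and new records; inputs are not mutated.
    """
    if not any(o is anchor or o == anchor for o in orfs):
        raise ValueError("anchor must be one of the supplied ORFs")
    L = genome.length
    if anchor.strand == "sense":
        new_genome, remap = normalize_origin(genome, anchor.start, "sense")
        flip = False
    else:
        new_genome, remap = normalize_origin(genome, anchor.end, "antisense")
        flip = True
    out: list[OrfRecord] = []
    for o in orfs:
        strand = o.strand
        if flip:
            strand = "antisense" if strand == "sense" else "sense"
        atg_new = remap(o.atg_position())
        span = o.nt_length
        if strand == "sense":
            s_new = atg_new
            e_new = (atg_new - 1 + span - 1) % L + 1
        else:
            e_new = atg_new
            s_new = (atg_new - 1 - (span - 1)) % L + 1
        out.append(replace(o, start=s_new, end=e_new, strand=strand,
                           wraps_origin=s_new > e_new))
    out.sort(key=lambda r: (r.start, r.end, r.strand != "sense"))
    renumbered = [replace(o, index=i) for i, o in enumerate(out, start=1)]
    return new_genome, renumbered


def orientation_tally(orfs: Iterable[OrfRecord]) -> tuple[int, int]:
    """(sense, antisense) counts, the headline orientation statistic."""
    sense = antisense = 0
    for o in orfs:
        if o.strand == "sense":
            sense += 1
        else:
            antisense += 1
    return sense, antisense
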