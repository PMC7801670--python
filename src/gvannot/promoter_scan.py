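"""Early/late baculovirus promoter motif classification.

An ORF's upstream region (180 bp 5' of the start codon on the coding
strand, wrapping the origin on circular genomes) is scanned for:

* early (E) signal: a TATA element with a CAGT or CATT mRNA start-site
  initiator 20-40 nucleotides downstream;
* late (L) signal: the (A/T/G)TAAG late transcription initiator.

An ORF is classed ``E`` (early hits only), ``L`` (late only), ``E/L``
(both) or ``none``. The 20-40 gap is measured by default as the number of
bases strictly between the last base of TATA and the first base of the
initiator; because the convention is not universal, ``gap_anchor``
alternatively measures start-to-start distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from gvannot.genome_io import CircularGenome, reverse_complement
from gvannot.orf_annotation import OrfRecord

TATA = "TATA"
INITIATORS = ("CAGT", "CATT")
LATE_MOTIFS = ("ATAAG", "TTAAG", "GTAAG")

DEFAULT_WINDOW = 180
GAP_MIN = 20
GAP_MAX = 40


@dataclass(frozen=True)
class EarlyHit:
    """A TATA/initiator pair; offsets are 1-based within the window, 5'->3'."""

    tata_start: int
    initiator_start: int
    initiator: str


@dataclass(frozen=True)
class LateHit:
    motif_start: int
    motif: str


@dataclass(frozen=True)
class PromoterAnnotation:
    orf_index: int
    early_hits: tuple[EarlyHit, ...]
    late_hits: tuple[LateHit, ...]
    klass: str  # "E" | "L" | "E/L" | "none"


def extract_upstream(
    genome: CircularGenome,
    orf: OrfRecord,
    window: int = DEFAULT_WINDOW,
) -> str:
    """The ``window`` bases immediately 5' of the start codon, coding strand.

    Wraps the origin on circular genomes; on linear genomes the window is
    truncated at the molecule's end.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = genome.length
    if genome.circular and window > L:
        raise ValueError("window longer than the genome")
    atg = orf.atg_position()
    if orf.strand == "sense":
        lo, hi = atg - window, atg - 1
        if genome.circular:
            return genome.fetch(lo + L, hi + L)
        lo = max(1, lo)
        return genome.seq[lo - 1:hi] if hi >= lo else ""
    lo, hi = atg + 1, atg + window
    if genome.circular:
        return reverse_complement(genome.fetch(lo, hi))
    hi = min(L, hi)
    return reverse_complement(genome.seq[lo - 1:hi]) if hi >= lo else ""


def _find_all(window: str, motif: str) -> list[int]:
    """All 0-based occurrence starts of ``motif``, overlapping included."""
    hits = []
    i = window.find(motif)
    while i != -1:
        hits.append(i)
        i = window.find(motif, i + 1)
    return hits


def scan_early(
    upstream: str,
    gap_min: int = GAP_MIN,
    gap_max: int = GAP_MAX,
    gap_anchor: str = "between",
) -> list[EarlyHit]:
    """All TATA + CAGT/CATT pairs at an admissible gap, fully in-window.

    ``gap_anchor="between"`` counts the bases strictly between the last A
    of TATA and the first base of the initiator; ``"start"`` measures
    start-to-start.
    """
    if gap_anchor not in {"between", "start"}:
        raise ValueError("gap_anchor must be 'between' or 'start'")
    tata_positions = _find_all(upstream, TATA)
    hits = []
    for init in INITIATORS:
        for ipos in _find_all(upstream, init):
            for tpos in tata_positions:
                if gap_anchor == "between":
                    gap = ipos - (tpos + len(TATA))
                else:
                    gap = ipos - tpos
                if gap_min <= gap <= gap_max:
                    hits.append(EarlyHit(tata_start=tpos + 1,
                                         initiator_start=ipos + 1,
                                         initiator=init))
    hits.sort(key=lambda h: (h.tata_start, h.initiator_start, h.initiator))
    return hits


def scan_late(upstream: str) -> list[LateHit]:
    """All (A/T/G)TAAG occurrences, overlapping included."""
    hits = [
        LateHit(motif_start=i + 1, motif=m)
        for m in LATE_MOTIFS
        for i in _find_all(upstream, m)
    ]
    hits.sort(key=lambda h: h.motif_start)
    return hits


def classify(early_hits: Sequence[EarlyHit], late_hits: Sequence[LateHit]) -> str:
    if early_hits and late_hits:
        return "E/L"
    if early_hits:
        return "E"
    if late_hits:
        return "L"
    return "none"


def annotate_promoters(
    genome: CircularGenome,
    orfs: Iterable[OrfRecord],
    window: int = DEFAULT_WINDOW,
    gap_anchor: str = "between",
    set_class: bool = True,
) -> list[PromoterAnnotation]:
    """Scan every ORF's upstream window and classify it.

    When ``set_class`` is true, each record's ``promoter_class`` field is
    updated in place with the call.
    """
    annotations = []
    for orf in orfs:
        upstream = extract_upstream(genome, orf, window)
        early = tuple(scan_early(upstream, gap_anchor=gap_anchor))
        late = tuple(scan_late(upstream))
        klass = classify(early, late)
        if set_class:
            orf.promoter_class = klass
        annotations.append(PromoterAnnotation(
            orf_index=orf.index, early_hits=early, late_hits=late, klass=klass))
    return annotations
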