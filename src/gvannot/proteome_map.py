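"""Peptide-to-ORF mapping of occlusion-body proteomics identifications.

Input is the peptide-sequence level (per gel-slice sample), the first point
where an occlusion-body proteomics experiment is reproducible without
instruments. A peptide matches a putative protein when it occurs as a
substring, by default under I/L equivalence (leucine and isoleucine are
isobaric and indistinguishable by standard MS/MS). Detections are
aggregated per protein; two or more distinct peptides make a detection
confident, the conventional identification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

MIN_PEPTIDE_LEN = 6


@dataclass(frozen=True)
class PeptideObservation:
    """One peptide identification in one gel-slice sample."""

    peptide: str
    sample_id: str


@dataclass(frozen=True)
class ProteinDetection:
    orf_index: int
    n_peptides: int          # distinct matched peptides (I/L-canonical)
    n_samples: int           # distinct samples with >= 1 match
    confident: bool          # n_peptides >= 2
    shared_peptides: tuple[str, ...] = ()  # peptides matching other proteins too


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 2,
    min_len: int = 6,
) -> list[str]:
    """In-silico tryptic peptides: cleave after K/R except before P.

    Returns all products with at most ``missed_cleavages`` internal
    cleavage sites and length >= ``min_len``, in positional order,
    de-duplicated.
    """
    if not protein:
        raise ValueError("empty protein")
    cut_after = [
        i for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(protein)]
    fragments = [protein[bounds[k]:bounds[k + 1]] for k in range(len(bounds) - 1)]
    peptides: list[str] = []
    seen: set[str] = set()
    for k in range(len(fragments)):
        for m in range(missed_cleavages + 1):
            if k + m >= len(fragments):
                break
            pep = "".join(fragments[k:k + m + 1])
            if len(pep) >= min_len and pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    return peptides


def _canon(seq: str, il_equivalent: bool) -> str:
    return seq.replace("I", "L") if il_equivalent else seq


def match_peptides(
    observations: Sequence[PeptideObservation],
    proteome,
    il_equivalent: bool = True,
    min_pep_len: int = MIN_PEPTIDE_LEN,
) -> list[ProteinDetection]:
    """Assign peptide observations to proteins and summarize per protein.

    ``proteome`` is an ordered collection of proteins (strings,
    ``(ordinal, protein)`` pairs, or ORF records). A peptide matching
    several proteins counts toward all of them and is flagged shared.
    Observations shorter than ``min_pep_len`` are rejected.
    """
    from gvannot.comparative import _as_ordered

    prots = _as_ordered(proteome)
    if not prots:
        raise ValueError("empty proteome")
    for obs in observations:
        if len(obs.peptide) < min_pep_len:
            raise ValueError(
                f"peptide {obs.peptide!r} shorter than min_pep_len={min_pep_len}")
    canon_prots = [(ordinal, _canon(p, il_equivalent)) for ordinal, p in prots]
    # peptide (canonical) -> matching ordinals
    by_pep: dict[str, set[int]] = {}
    pep_samples: dict[str, set[str]] = {}
    for obs in observations:
        pep = _canon(obs.peptide, il_equivalent)
        pep_samples.setdefault(pep, set()).add(obs.sample_id)
        if pep not in by_pep:
            by_pep[pep] = {ordinal for ordinal, p in canon_prots if pep in p}
    detections: list[ProteinDetection] = []
    ordinals = [ordinal for ordinal, _ in prots]
    for ordinal in ordinals:
        peps = sorted(p for p, hits in by_pep.items() if ordinal in hits)
        if not peps:
            continue
        samples = set().union(*(pep_samples[p] for p in peps))
        shared = tuple(p for p in peps if len(by_pep[p]) > 1)
        detections.append(ProteinDetection(
            orf_index=ordinal,
            n_peptides=len(peps),
            n_samples=len(samples),
            confident=len(peps) >= 2,
            shared_peptides=shared,
        ))
    return detections
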