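"""Synthetic circular genomes with fully known planted truth.

The generator emulates the statistical structure of an AT-rich (~40% G+C)
granulovirus genome: non-overlapping ATG-initiated ORFs of 50-1300 codons
on both strands, per-ORF promoter classes planted in the 180-bp upstream
window, homologous regions built from ~120-bp imperfect direct repeats
each carrying the 10-bp core TTAAT(G/A)TCGA at a fixed offset, duplicated
genes in opposite orientations, and peptide observations drawn from a
subset of the planted proteins across gel-slice samples.

Everything is deterministic for a fixed seed (a single NumPy generator
stream, no global state). With ``no_decoys=True`` the background and ORF
interiors are constructed free of spurious start codons (no ATG/CAT
trigrams outside planted starts, early-initiator motifs restricted to
CAGT, hr cores restricted to the ATG-free TTAATATCGA variant), so ORF
enumeration plus curation recovers exactly the planted set — separating
algorithm correctness from biological messiness, which the default mode
retains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gvannot.genome_io import CircularGenome, reverse_complement
from gvannot.hr_finder import CORE_CONSENSI, CORE_LEN, CoreHit, HrRegion, _min_hamming
from gvannot.orf_annotation import (
    STOP_CODONS,
    OrfRecord,
    enumerate_orfs,
    translate,
)
from gvannot.promoter_scan import (
    LATE_MOTIFS,
    classify,
    extract_upstream,
    scan_early,
    scan_late,
)
from gvannot.proteome_map import PeptideObservation, tryptic_digest

BASES = "ACGT"
_STOPS = sorted(STOP_CODONS)


class GenerationError(ValueError):
    """Raised when the requested features cannot be packed or planted."""


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic genome."""

    n_orfs: int = 20
    orf_len_range: tuple[int, int] = (50, 1300)      # codons incl. start Met
    promoter_counts: dict | None = None              # class -> count
    n_major_hrs: int = 8
    n_short_hrs: int = 1
    hr_repeat_range: tuple[int, int] = (2, 5)
    hr_unit_len: int = 120
    hr_core_offset: int = 35
    hr_core_mismatch: int = 1
    n_duplicates: int = 1
    gc: float = 0.40
    genome_length: int | None = None                 # None: sized to fit
    upstream_window: int = 180
    no_decoys: bool = False
    min_codons: int = 50
    n_detected_proteins: int | None = None           # None: min(24, available)
    n_single_peptide_proteins: int = 4
    n_samples: int = 29


@dataclass
class SyntheticTruth:
    genome: CircularGenome
    orfs: list[OrfRecord]
    promoter_classes: dict[int, str]                 # orf index -> class
    hrs: list[HrRegion]
    duplicate_pairs: list[tuple[int, int]]           # orf index pairs
    peptide_sources: dict[str, int]                  # peptide -> orf index
    observations: list[PeptideObservation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# low-level sequence construction
# ---------------------------------------------------------------------------

def _bg(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list(BASES), size=n, p=p))


def _has_corelike(s: str, budget: int) -> bool:
    for i in range(len(s) - CORE_LEN + 1):
        w = s[i:i + CORE_LEN]
        if _min_hamming(w) <= budget or _min_hamming(reverse_complement(w)) <= budget:
            return True
    return False


def _forbidden_trigram(s: str) -> bool:
    return "ATG" in s or "CAT" in s


def _coding(rng: np.random.Generator, n_aa: int, gc: float,
            no_decoys: bool, core_budget: int) -> str:
    """A CDS of ``n_aa`` codons (first = ATG) plus a stop, background-like
    base composition, free of internal stops and core-like 10-mers, and
    (with ``no_decoys``) of internal ATG/CAT trigrams."""
    out = ["A", "T", "G"]
    k = 1
    backtracks = 0
    while k < n_aa:
        for _ in range(100):
            codon = "".join(_bg(rng, 3, gc))
            if codon in STOP_CODONS:
                continue
            tail = "".join(out[-9:]) + codon
            if no_decoys and _forbidden_trigram("".join(out[-2:]) + codon):
                continue
            if _has_corelike(tail, core_budget):
                continue
            out.extend(codon)
            k += 1
            break
        else:
            # a suffix equal to a 9-char prefix of a core consensus makes
            # every next codon complete a core-like 10-mer; backtrack one
            # codon and resample it
            backtracks += 1
            if k == 1 or backtracks > 500:
                raise GenerationError("could not sample an admissible codon")
            del out[-3:]
            k -= 1
    for _backtrack in range(100):
        placed = False
        for _ in range(20):
            stop = _STOPS[rng.integers(0, 3)]
            tail = "".join(out[-9:]) + stop
            if no_decoys and _forbidden_trigram("".join(out[-2:]) + stop):
                continue
            if _has_corelike(tail, core_budget):
                continue
            out.extend(stop)
            placed = True
            break
        if placed:
            return "".join(out)
        # the last codon's tail can make every stop inadmissible (e.g. a
        # trailing CA forces CAT); resample it and retry
        if len(out) <= 3:
            raise GenerationError("could not place a stop codon")
        del out[-3:]
        for _ in range(200):
            codon = "".join(_bg(rng, 3, gc))
            if codon in STOP_CODONS:
                continue
            if no_decoys and _forbidden_trigram("".join(out[-2:]) + codon):
                continue
            if _has_corelike("".join(out[-9:]) + codon, core_budget):
                continue
            out.extend(codon)
            break
        else:
            raise GenerationError("could not resample the final codon")
    raise GenerationError("could not place a stop codon")


def _window_violations(w: str, klass: str, protected: set[int],
                       no_decoys: bool, core_budget: int) -> list[tuple[int, int]]:
    """Spans (0-based, half-open) inside a promoter window that would
    change its class away from ``klass`` or violate global constraints."""
    spans: list[tuple[int, int]] = []
    for i in range(len(w) - CORE_LEN + 1):
        word = w[i:i + CORE_LEN]
        if _min_hamming(word) <= core_budget or \
                _min_hamming(reverse_complement(word)) <= core_budget:
            spans.append((i, i + CORE_LEN))
    if no_decoys:
        for tri in ("ATG", "CAT"):
            j = w.find(tri)
            while j != -1:
                spans.append((j, j + 3))
                j = w.find(tri, j + 1)
        if w.endswith("C"):
            spans.append((len(w) - 1, len(w)))
    if klass in ("none", "E"):
        for h in scan_late(w):
            spans.append((h.motif_start - 1, h.motif_start - 1 + 5))
    if klass in ("none", "L"):
        for h in scan_early(w):
            spans.append((h.tata_start - 1, h.tata_start - 1 + 4))
    # drop spans that consist solely of protected positions
    out = []
    for a, b in spans:
        if any(i not in protected for i in range(a, b)):
            out.append((a, b))
    return out


def _make_window(rng: np.random.Generator, length: int, klass: str, gc: float,
                 no_decoys: bool, core_budget: int) -> str:
    """An upstream window (coding strand, 5'->3') of exactly class ``klass``."""
    initiators = ("CAGT",) if no_decoys else ("CAGT", "CATT")
    for _attempt in range(50):
        w = _bg(rng, length, gc)
        protected: set[int] = set()
        if klass in ("E", "E/L"):
            gap = int(rng.integers(20, 41))
            init = initiators[rng.integers(0, len(initiators))]
            tpos = int(rng.integers(0, length - (8 + gap) + 1))
            ipos = tpos + 4 + gap
            w[tpos:tpos + 4] = list("TATA")
            w[ipos:ipos + 4] = list(init)
            protected |= set(range(tpos, tpos + 4)) | set(range(ipos, ipos + 4))
        if klass in ("L", "E/L"):
            motif = LATE_MOTIFS[rng.integers(0, 3)]
            for _ in range(50):
                lpos = int(rng.integers(0, length - 5 + 1))
                span = set(range(lpos, lpos + 5))
                if not span & protected:
                    break
            else:
                continue
            w[lpos:lpos + 5] = list(motif)
            protected |= span
        ok = True
        for _round in range(300):
            spans = _window_violations("".join(w), klass, protected,
                                       no_decoys, core_budget)
            if not spans:
                break
            a, b = spans[0]
            free = [i for i in range(a, b) if i not in protected]
            i = free[rng.integers(0, len(free))]
            alternatives = [c for c in BASES if c != w[i]]
            w[i] = alternatives[rng.integers(0, 3)]
        else:
            ok = False
        if not ok:
            continue
        ws = "".join(w)
        if classify(scan_early(ws), scan_late(ws)) == klass:
            return ws
    raise GenerationError(f"could not build a class-{klass} upstream window")


def _mutate_positions(rng: np.random.Generator, word: list[str], k: int) -> None:
    if k <= 0:
        return
    pos = rng.choice(len(word), size=k, replace=False)
    for i in np.atleast_1d(pos):
        alternatives = [c for c in BASES if c != word[i]]
        word[int(i)] = alternatives[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# feature specs and layout
# ---------------------------------------------------------------------------

@dataclass
class _OrfSpec:
    n_aa: int
    strand: str
    klass: str
    cds: str
    dup_of: int | None = None    # index into the spec list
    start: int = 0               # 1-based, assigned at layout
    end: int = 0


@dataclass
class _HrSpec:
    n_repeats: int               # 1 for a short hr
    strands: list[str]           # per-repeat core orientation
    variant: str                 # consensus used
    start: int = 0
    cores: list[CoreHit] = field(default_factory=list)


def _default_promoter_counts(n: int) -> dict[str, int]:
    # roughly the class proportions of an annotated GV genome
    counts = {"L": round(0.41 * n), "E": round(0.22 * n), "E/L": round(0.18 * n)}
    counts["none"] = n - sum(counts.values())
    if counts["none"] < 0:
        raise GenerationError("promoter proportions infeasible")
    return counts


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Generate a synthetic circular genome and its planted truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    core_budget = cfg.hr_core_mismatch

    counts = dict(cfg.promoter_counts) if cfg.promoter_counts else \
        _default_promoter_counts(cfg.n_orfs)
    if sum(counts.values()) != cfg.n_orfs:
        raise GenerationError("promoter_counts must sum to n_orfs")
    klasses: list[str] = sum(([k] * v for k, v in sorted(counts.items())), [])
    klasses = [klasses[i] for i in rng.permutation(cfg.n_orfs)]

    if cfg.n_duplicates * 2 > cfg.n_orfs:
        raise GenerationError("too many duplicate pairs for n_orfs")

    # --- ORF specs (duplicates copy the CDS of an earlier spec, flipped) ---
    orf_specs: list[_OrfSpec] = []
    lo, hi = cfg.orf_len_range
    for k in range(cfg.n_orfs):
        if k >= cfg.n_orfs - cfg.n_duplicates:
            src = k - (cfg.n_orfs - cfg.n_duplicates)
            tmpl = orf_specs[src]
            strand = "antisense" if tmpl.strand == "sense" else "sense"
            orf_specs.append(_OrfSpec(tmpl.n_aa, strand, klasses[k],
                                      tmpl.cds, dup_of=src))
            continue
        n_aa = int(rng.integers(lo, hi + 1))
        strand = "sense" if rng.random() < 0.5 else "antisense"
        cds = _coding(rng, n_aa, cfg.gc, cfg.no_decoys, core_budget)
        orf_specs.append(_OrfSpec(n_aa, strand, klasses[k], cds))

    # --- hr specs ---
    hr_specs: list[_HrSpec] = []
    variants = (CORE_CONSENSI[1],) if cfg.no_decoys else CORE_CONSENSI
    rlo, rhi = cfg.hr_repeat_range
    for _ in range(cfg.n_major_hrs):
        n_rep = int(rng.integers(rlo, rhi + 1))
        if rng.random() < 0.5 or n_rep < 2:     # uniform-direction hr
            s = "forward" if rng.random() < 0.5 else "reverse"
            strands = [s] * n_rep
        else:                                   # mixed-direction hr
            while True:
                strands = ["forward" if rng.random() < 0.5 else "reverse"
                           for _ in range(n_rep)]
                if len(set(strands)) == 2:
                    break
        hr_specs.append(_HrSpec(n_rep, strands,
                                variants[rng.integers(0, len(variants))]))
    for _ in range(cfg.n_short_hrs):
        s = "forward" if rng.random() < 0.5 else "reverse"
        hr_specs.append(_HrSpec(1, [s], variants[rng.integers(0, len(variants))]))

    # --- layout ---
    w = cfg.upstream_window
    items: list[object] = list(orf_specs) + list(hr_specs)
    order = list(rng.permutation(len(items)))
    chunks: list[list[str]] = []
    protected: set[int] = set()        # 0-based genomic positions never mutated
    pos = 0                            # 0-based cursor

    def emit(chunk: list[str]) -> None:
        nonlocal pos
        chunks.append(chunk)
        pos += len(chunk)

    planted_cores: list[CoreHit] = []
    prev_hr = False
    for idx in order:
        item = items[idx]
        # keep inter-hr spacing above the default clustering linkage
        # distance (400 bp) so distinct hrs never co-cluster
        if isinstance(item, _HrSpec) or prev_hr:
            emit(_bg(rng, int(rng.integers(450, 700)), cfg.gc))
        else:
            emit(_bg(rng, int(rng.integers(60, 200)), cfg.gc))
        prev_hr = isinstance(item, _HrSpec)
        if isinstance(item, _OrfSpec):
            window = _make_window(rng, w, item.klass, cfg.gc,
                                  cfg.no_decoys, core_budget)
            nt = len(item.cds)
            if item.strand == "sense":
                item.start = pos + w + 1
                item.end = pos + w + nt
                emit(list(window))
                emit(list(item.cds))
                protected |= set(range(item.start - 1, item.end))
            else:
                item.start = pos + 1
                item.end = pos + nt
                emit(list(reverse_complement(item.cds)))
                protected |= set(range(item.start - 1, item.end))
                # genomic content of the window region is the reverse
                # complement of the coding-strand window string
                emit(list(reverse_complement(window)))
        else:
            item.start = pos + 1
            template = _bg(rng, cfg.hr_unit_len, cfg.gc)
            for r in range(item.n_repeats):
                unit = list(template)
                noise = rng.random(cfg.hr_unit_len) < 0.08
                for i in np.flatnonzero(noise):
                    alternatives = [c for c in BASES if c != unit[int(i)]]
                    unit[int(i)] = alternatives[rng.integers(0, 3)]
                base_word = (item.variant if item.strands[r] == "forward"
                             else reverse_complement(item.variant))
                n_mut = int(rng.integers(0, core_budget + 1))
                for _ in range(60):
                    word = list(base_word)
                    _mutate_positions(rng, word, n_mut)
                    # a mutated core must not itself contain a start codon
                    # on either strand when decoys are suppressed
                    if not (cfg.no_decoys and _forbidden_trigram("".join(word))):
                        break
                else:
                    raise GenerationError("could not mutate core admissibly")
                off = cfg.hr_core_offset
                unit[off:off + CORE_LEN] = word
                gpos = pos + off + 1
                fwd_word = "".join(word)
                if item.strands[r] == "forward":
                    mm = _min_hamming(fwd_word)
                else:
                    mm = _min_hamming(reverse_complement(fwd_word))
                core = CoreHit(position=gpos, strand=item.strands[r], mismatches=mm)
                item.cores.append(core)
                planted_cores.append(core)
                protected |= set(range(gpos - 1, gpos - 1 + CORE_LEN))
                emit(unit)
    emit(_bg(rng, int(rng.integers(150, 350)), cfg.gc))
    needed = pos
    if cfg.genome_length is not None:
        if needed > cfg.genome_length:
            raise GenerationError(
                f"features need {needed} bp > genome_length {cfg.genome_length}")
        emit(_bg(rng, cfg.genome_length - needed, cfg.gc))
    seq = [c for chunk in chunks for c in chunk]
    L = len(seq)

    # window regions are protected against scrubbing as well (their class
    # must survive); record their genomic spans per ORF for verification
    window_spans: list[tuple[_OrfSpec, int, int]] = []
    for spec in orf_specs:
        if spec.strand == "sense":
            a, b = spec.start - 1 - w, spec.start - 1
        else:
            a, b = spec.end, spec.end + w
        window_spans.append((spec, a, b))
        protected |= set(range(a, b))

    # --- truth ORF skeleton (needed for decoy comparison) ---
    truth_keys = {(s.start, s.end, s.strand) for s in orf_specs}

    # --- global scrub loop: remove accidental core-like hits outside the
    # planted cores and (no_decoys) spurious ORF starts; the two interact,
    # so iterate both to a joint fixed point ---
    planted_keys = {(c.position, c.strand) for c in planted_cores}
    from gvannot.hr_finder import find_cores
    for _round in range(80):
        genome = CircularGenome(id=f"synthetic-{seed}", seq="".join(seq))
        dirty = False
        extra = [h for h in find_cores(genome, core_budget)
                 if (h.position, h.strand) not in planted_keys]
        for h in extra:
            dirty = True
            span = [(h.position - 1 + i) % L for i in range(CORE_LEN)]
            free = [i for i in span if i not in protected]
            if not free:
                raise GenerationError("accidental core inside protected span")
            i = free[rng.integers(0, len(free))]
            alternatives = [c for c in BASES if c != seq[i]]
            seq[i] = alternatives[rng.integers(0, 3)]
        if not dirty and cfg.no_decoys:
            found = enumerate_orfs(genome, min_codons=cfg.min_codons)
            decoys = [o for o in found
                      if (o.start, o.end, o.strand) not in truth_keys]
            for d in decoys:
                dirty = True
                atg = d.atg_position()
                if d.strand == "sense":
                    span = [(atg - 1 + i) % L for i in range(3)]
                else:
                    span = [(atg - 1 - i) % L for i in range(3)]
                free = [i for i in span if i not in protected]
                if not free:
                    raise GenerationError("decoy start inside protected span")
                i = free[rng.integers(0, len(free))]
                seq[i] = "C" if seq[i] != "C" else "G"
        if not dirty:
            break
    else:
        raise GenerationError("scrub passes did not converge")

    # --- truth records ---
    orfs: list[OrfRecord] = []
    for spec in orf_specs:
        rec = OrfRecord(start=spec.start, end=spec.end, strand=spec.strand,
                        aa_length=spec.n_aa, promoter_class=spec.klass)
        rec.protein = translate(genome, rec)
        orfs.append(rec)
    order_idx = sorted(range(len(orfs)), key=lambda i: orfs[i].start)
    rank = {i: r + 1 for r, i in enumerate(order_idx)}
    for i, rec in enumerate(orfs):
        rec.index = rank[i]
    duplicate_pairs = sorted(
        (min(rank[i], rank[spec.dup_of]), max(rank[i], rank[spec.dup_of]))
        for i, spec in enumerate(orf_specs) if spec.dup_of is not None
    )
    orfs.sort(key=lambda r: r.index)
    promoter_classes = {rec.index: rec.promoter_class for rec in orfs}

    # --- verify planted promoter classes (window content is protected) ---
    for rec in orfs:
        up = extract_upstream(genome, rec, w)
        got = classify(scan_early(up), scan_late(up))
        if got != rec.promoter_class:
            raise GenerationError(
                f"window verification failed for ORF{rec.index}: "
                f"planted {rec.promoter_class}, scanned {got}")

    # --- hr truth (labelled in genome order, hr5a convention) ---
    hr_specs.sort(key=lambda h: h.start)
    hrs: list[HrRegion] = []
    major_n = 0
    short_since = 0
    for spec in hr_specs:
        cores = tuple(sorted(spec.cores, key=lambda c: c.position))
        start = cores[0].position
        end = cores[-1].position + CORE_LEN - 1
        if len(cores) >= 2:
            major_n += 1
            short_since = 0
            label = f"hr{major_n}"
        else:
            short_since += 1
            label = f"hr{major_n}{chr(ord('a') + short_since - 1)}" \
                if major_n else f"hr0{chr(ord('a') + short_since - 1)}"
        strands = {c.strand for c in cores}
        summary = ("all_forward" if strands == {"forward"} else
                   "all_reverse" if strands == {"reverse"} else "mixed")
        hrs.append(HrRegion(label=label, start=start, end=end, cores=cores,
                            klass="major" if len(cores) >= 2 else "short",
                            orientation_summary=summary))

    # --- peptide observations ---
    peptide_sources, observations = _make_peptides(rng, cfg, orfs, duplicate_pairs)

    return SyntheticTruth(
        genome=genome, orfs=orfs, promoter_classes=promoter_classes,
        hrs=hrs, duplicate_pairs=duplicate_pairs,
        peptide_sources=peptide_sources, observations=observations,
    )


def _make_peptides(rng, cfg, orfs, duplicate_pairs):
    dup_members = {i for pair in duplicate_pairs for i in pair}
    pool = [o for o in orfs if o.index not in dup_members]
    n_det = cfg.n_detected_proteins
    if n_det is None:
        n_det = min(24, len(pool))
    if n_det > len(pool):
        raise GenerationError(
            f"n_detected_proteins={n_det} exceeds {len(pool)} unique proteins")
    if n_det == 0:
        return {}, []
    chosen_idx = rng.choice(len(pool), size=n_det, replace=False)
    chosen = [pool[int(i)] for i in sorted(chosen_idx)]
    others = {o.index: o.protein.replace("I", "L") for o in orfs}
    single = set(np.atleast_1d(
        rng.choice(n_det, size=min(cfg.n_single_peptide_proteins, n_det),
                   replace=False)).tolist())
    peptide_sources: dict[str, int] = {}
    observations: list[PeptideObservation] = []
    for k, orf in enumerate(chosen):
        candidates = []
        for pep in tryptic_digest(orf.protein, missed_cleavages=1, min_len=6):
            cpep = pep.replace("I", "L")
            if cpep in peptide_sources:
                continue
            if any(cpep in prot for idx, prot in others.items()
                   if idx != orf.index):
                continue
            candidates.append(pep)
        if not candidates:
            raise GenerationError(
                f"no unique tryptic peptide for ORF{orf.index}")
        want = 1 if k in single else int(rng.integers(2, 5))
        take_n = min(want, len(candidates))
        take = [candidates[int(i)]
                for i in sorted(rng.choice(len(candidates), size=take_n,
                                           replace=False))]
        for pep in take:
            peptide_sources[pep.replace("I", "L")] = orf.index
            n_obs = int(rng.integers(1, 3))
            samples = rng.choice(cfg.n_samples, size=n_obs, replace=False)
            for s in np.atleast_1d(samples):
                observations.append(
                    PeptideObservation(peptide=pep, sample_id=f"S{int(s) + 1}"))
    observations.sort(key=lambda o: (o.sample_id, o.peptide))
    return peptide_sources, observations
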