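"""Genome input/output and circular-sequence primitives.

Coordinates everywhere in the package are 1-based with both ends inclusive,
the convention used in baculovirus annotation tables. A sense ("+") feature
is written ``start>end`` and an antisense ("-") feature ``start<end`` in the
tabular output, where ``start`` is always the lower genomic coordinate
except for origin-wrapping features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised for unparseable or illegal sequence input."""


class TopologyError(ValueError):
    """Raised when a circular-only operation is applied to a linear genome."""


@dataclass(frozen=True)
class CircularGenome:
    """A nucleotide sequence with (optionally) circular topology.

    Attributes
    ----------
    id:
        Text label, typically the FASTA/GenBank record id.
    seq:
        Uppercase nucleotide string over {A, C, G, T, N}.
    circular:
        Whether the molecule is a covalently closed circle.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise GenomeFormatError("empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise GenomeFormatError(
                f"illegal characters in sequence: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Bases ``start..end`` (1-based inclusive), wrapping the origin.

        On a circular genome any integer coordinates are accepted and taken
        modulo the length; ``end`` may be numerically smaller than ``start``
        only via wrapping, so callers pass e.g. ``fetch(L-2, L+5)``.
        """
        if end < start:
            raise ValueError("end < start; express wrapping as end > length")
        n = end - start + 1
        if self.circular:
            if n > self.length:
                raise ValueError("requested span longer than the genome")
            s0 = (start - 1) % self.length
            doubled = self.seq + self.seq
            return doubled[s0:s0 + n]
        if start < 1 or end > self.length:
            raise ValueError("coordinates out of range on a linear genome")
        return self.seq[start - 1:end]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise GenomeFormatError(f"illegal characters: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_genome(
    path: str | Path,
    format: str | None = None,
    circular: bool | None = None,
    record_id: str | None = None,
) -> CircularGenome:
    """Read the genome record from a FASTA or GenBank file.

    The first record is taken unless ``record_id`` names another one; a
    multi-record file without ``record_id`` is accepted with the first
    record only (single-genome tool). The circular flag is taken from
    GenBank topology metadata when present, else from ``circular``
    (defaulting to True).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "genbank" if suffix in {".gb", ".gbk", ".genbank"} else "fasta"
    if format not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported format: {format}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise GenomeFormatError(f"no sequence records in {path}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise GenomeFormatError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    else:
        rec = records[0]
    topology = rec.annotations.get("topology") if format == "genbank" else None
    if topology is not None:
        is_circular = topology == "circular"
    elif circular is not None:
        is_circular = circular
    else:
        is_circular = True
    seq = str(rec.seq).upper()
    if not seq:
        raise GenomeFormatError(f"record {rec.id!r} has an empty sequence")
    return CircularGenome(id=rec.id, seq=seq, circular=is_circular)


def gc_content(genome: CircularGenome | str) -> float:
    """G+C fraction over unambiguous bases; N excluded from both sides."""
    seq = genome.seq if isinstance(genome, CircularGenome) else genome
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / acgt


def normalize_origin(
    genome: CircularGenome,
    new_origin: int,
    strand: str = "sense",
) -> tuple[CircularGenome, Callable[[int], int]]:
    """Rotate a circular genome so ``new_origin`` becomes nucleotide 1.

    With ``strand="antisense"`` the rotated sequence is additionally
    reverse-complemented, so position 1 of the result is the complement of
    the requested base and numbering proceeds along the other strand (used
    to define the granulin-sense numbering orientation).

    Returns the new genome and a remapping function taking an old 1-based
    position to its new 1-based position.
    """
    if not genome.circular:
        raise TopologyError("origin normalization requires a circular genome")
    if not 1 <= new_origin <= genome.length:
        raise ValueError("new_origin out of range")
    if strand not in {"sense", "antisense"}:
        raise ValueError("strand must be 'sense' or 'antisense'")
    L = genome.length
    if strand == "sense":
        rotated = genome.seq[new_origin - 1:] + genome.seq[:new_origin - 1]

        def remap(pos: int) -> int:
            return (pos - new_origin) % L + 1
        return replace(genome, seq=rotated), remap

    # antisense: position 1 of the result is the complement of the
    # requested base, numbering continuing along the other strand
    flipped = reverse_complement(genome.seq[new_origin:] + genome.seq[:new_origin])

    def remap(pos: int) -> int:
        return (new_origin - pos) % L + 1

    return replace(genome, seq=flipped), remap


# ---------------------------------------------------------------------------
# Annotation output
# ---------------------------------------------------------------------------

_TSV_HEADER = ["orf", "name", "position", "aa_length", "promoter"]


def _check_coords(start: int, end: int, length: int | None) -> None:
    if start < 1 or end < 1:
        raise ValueError(f"coordinates must be positive: {start}..{end}")
    if length is not None and (start > length or end > length):
        raise ValueError(f"coordinates out of range: {start}..{end} > {length}")


def write_annotations(
    orfs: Sequence,
    hrs: Sequence,
    path: str | Path,
    format: str = "tsv",
    genome_id: str = "genome",
    genome_length: int | None = None,
) -> None:
    """Write ORF and hr annotations as GFF3 or TSV.

    GFF3 uses feature types ``CDS`` (ORFs) and ``repeat_region`` (hrs) with
    1-based inclusive coordinates. The TSV mirrors the annotation-table
    dialect: position written ``start>end`` for sense and ``start<end`` for
    antisense ORFs; hr rows carry the label in the name column.
    """
    path = Path(path)
    if format == "gff3":
        lines = ["##gff-version 3"]
        for orf in orfs:
            _check_coords(orf.start, orf.end, genome_length)
            strand = "+" if orf.strand == "sense" else "-"
            attrs = f"ID=orf{orf.index};Name={orf.name}"
            if getattr(orf, "promoter_class", "unset") not in ("unset", None):
                attrs += f";promoter_class={orf.promoter_class}"
            lines.append(
                "\t".join([genome_id, "gvannot", "CDS", str(orf.start),
                           str(orf.end), ".", strand, "0", attrs])
            )
        for hr in hrs:
            _check_coords(hr.start, hr.end, genome_length)
            lines.append(
                "\t".join([genome_id, "gvannot", "repeat_region", str(hr.start),
                           str(hr.end), ".", ".", ".", f"ID={hr.label}"])
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "tsv":
        lines = ["\t".join(_TSV_HEADER)]
        for orf in orfs:
            _check_coords(orf.start, orf.end, genome_length)
            mark = ">" if orf.strand == "sense" else "<"
            promoter = getattr(orf, "promoter_class", "unset")
            lines.append("\t".join([
                str(orf.index), orf.name, f"{orf.start}{mark}{orf.end}",
                str(orf.aa_length), promoter if promoter else "none",
            ]))
        for hr in hrs:
            _check_coords(hr.start, hr.end, genome_length)
            lines.append("\t".join(
                [hr.label, "hr", f"{hr.start}-{hr.end}", "", ""]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported annotation format: {format}")


def read_annotations(path: str | Path, format: str = "tsv"):
    """Read annotations written by :func:`write_annotations`.

    Returns ``(orf_rows, hr_rows)`` where each orf row is a dict with keys
    index/name/start/end/strand/aa_length/promoter_class and each hr row a
    dict with label/start/end. Used for round-trip checks and downstream
    tabular work; full :class:`OrfRecord` reconstruction (protein sequence)
    requires the genome.
    """
    path = Path(path)
    orfs: list[dict] = []
    hrs: list[dict] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if format == "tsv":
        for line in lines[1:]:
            if not line.strip():
                continue
            idx, name, position, aa, promoter = line.split("\t")
            if name == "hr":
                s, e = position.split("-")
                hrs.append({"label": idx, "start": int(s), "end": int(e)})
                continue
            m = re.fullmatch(r"(\d+)([<>])(\d+)", position)
            if not m:
                raise ValueError(f"bad position field: {position!r}")
            orfs.append({
                "index": int(idx), "name": name,
                "start": int(m.group(1)), "end": int(m.group(3)),
                "strand": "sense" if m.group(2) == ">" else "antisense",
                "aa_length": int(aa), "promoter_class": promoter,
            })
    elif format == "gff3":
        for line in lines:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            if cols[2] == "CDS":
                orfs.append({
                    "index": int(attrs["ID"].removeprefix("orf")),
                    "name": attrs.get("Name", ""),
                    "start": int(cols[3]), "end": int(cols[4]),
                    "strand": "sense" if cols[6] == "+" else "antisense",
                    "aa_length": (int(cols[4]) - int(cols[3]) + 1) // 3 - 1,
                    "promoter_class": attrs.get("promoter_class", "unset"),
                })
            elif cols[2] == "repeat_region":
                hrs.append({"label": attrs["ID"],
                            "start": int(cols[3]), "end": int(cols[4])})
    else:
        raise ValueError(f"unsupported annotation format: {format}")
    return orfs, hrs
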