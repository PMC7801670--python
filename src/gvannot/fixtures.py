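"""Bundled reference annotation table of the MyunGV-A genome (NC_013772).

The package ships a machine-readable transcription of the published
MyunGV-A annotation table: 183 ORF rows (coordinates in the granulin-origin
convention, orientation, amino-acid length, promoter class, and homologous
ORF / percent amino-acid identity against six reference genomes) plus the
nine homologous-region rows. Transcription quirks are recorded in the
``notes`` column rather than silently fixed; the file checksums below pin
the committed transcription.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

REFERENCE_GENOMES = ["acmnpv", "xcgv", "heargv", "tngv", "myungvb", "cpgv"]

ORF_TABLE_SHA256 = (
    "de921cbf00c5d09e14867f392257d337f34d8832f9e6325b2f45414950111e31")
HR_TABLE_SHA256 = (
    "87f092457a6127f281bfcf31213f1bc3a0fa221a0d1cb532b935417b568d6b4a")

_ORF_FILE = "myungv_a_orfs.tsv"
_HR_FILE = "myungv_a_hrs.tsv"


def _data_bytes(name: str) -> bytes:
    return (resources.files("gvannot.data") / name).read_bytes()


def load_orf_table() -> pd.DataFrame:
    """The 183-row ORF table; homolog cells are strings like ``8/55``,
    ``60/56,131/50`` (secondary hits) or ``-`` (no homolog)."""
    raw = _data_bytes(_ORF_FILE)
    df = pd.read_csv(pd.io.common.BytesIO(raw), sep="\t", dtype=str,
                     keep_default_na=False)
    for col in ("orf", "start", "end", "aa_length"):
        df[col] = df[col].astype(int)
    return df


def load_hr_table() -> pd.DataFrame:
    raw = _data_bytes(_HR_FILE)
    df = pd.read_csv(pd.io.common.BytesIO(raw), sep="\t",
                     keep_default_na=False)
    return df


def parse_homolog_cell(cell: str) -> list[tuple[str, int | None]]:
    """``"60/56,131/50"`` -> [("60", 56), ("131", 50)]; ``"-"`` -> []."""
    if cell in ("", "-"):
        return []
    out = []
    for entry in cell.split(","):
        orf, ident = entry.strip().split("/")
        out.append((orf, None if ident == "-" else int(ident)))
    return out


def orientation_tally(df: pd.DataFrame | None = None) -> tuple[int, int]:
    """(sense, antisense) counts over the ORF table."""
    if df is None:
        df = load_orf_table()
    sense = int((df["strand"] == "+").sum())
    return sense, len(df) - sense


def homolog_count(genome: str, df: pd.DataFrame | None = None) -> int:
    """Number of MyunGV-A ORFs with a homolog entry for ``genome``."""
    if df is None:
        df = load_orf_table()
    return int(sum(bool(parse_homolog_cell(c)) for c in df[genome.lower()]))


def mean_best_identity(genome: str, df: pd.DataFrame | None = None) -> int:
    """Rounded mean of the best-hit identities for ``genome`` (first entry
    per cell; cells without a printed identity are excluded)."""
    if df is None:
        df = load_orf_table()
    idents = []
    for cell in df[genome.lower()]:
        entries = parse_homolog_cell(cell)
        if entries and entries[0][1] is not None:
            idents.append(entries[0][1])
    return round(sum(idents) / len(idents))


def fixture_check() -> dict:
    """Validate the committed transcription.

    Checks the file checksums, the per-row coordinate arithmetic
    (aa_length == (end - start + 1)/3 - 1), the row counts (183 ORFs,
    9 hrs) and returns the orientation tally and per-genome homolog
    summaries. Raises AssertionError on any violation.
    """
    assert hashlib.sha256(_data_bytes(_ORF_FILE)).hexdigest() == ORF_TABLE_SHA256, \
        "ORF table checksum mismatch"
    assert hashlib.sha256(_data_bytes(_HR_FILE)).hexdigest() == HR_TABLE_SHA256, \
        "hr table checksum mismatch"
    df = load_orf_table()
    hrs = load_hr_table()
    assert len(df) == 183, f"expected 183 ORF rows, got {len(df)}"
    assert len(hrs) == 9, f"expected 9 hr rows, got {len(hrs)}"
    assert list(df["orf"]) == list(range(1, 184)), "ORF numbering not 1..183"
    bad = df[df["aa_length"] != (df["end"] - df["start"] + 1) // 3 - 1]
    assert bad.empty, f"aa-length arithmetic fails for ORFs {list(bad['orf'])}"
    assert (df["promoter"].isin(["E", "L", "E/L", "-"])).all()
    sense, antisense = orientation_tally(df)
    return {
        "orf_rows": len(df),
        "hr_rows": len(hrs),
        "orientation": {"sense": sense, "antisense": antisense},
        "homolog_counts": {g: homolog_count(g, df) for g in REFERENCE_GENOMES},
        "mean_identities": {g: mean_best_identity(g, df)
                            for g in REFERENCE_GENOMES},
    }
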