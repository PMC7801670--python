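import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gvannot.genome_io import (
    CircularGenome,
    GenomeFormatError,
    TopologyError,
    gc_content,
    normalize_origin,
    read_annotations,
    read_genome,
    reverse_complement,
    write_annotations,
)
from gvannot.orf_annotation import OrfRecord
from gvannot.hr_finder import HrRegion


class TestReadGenome:
    def test_minimal_fasta(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g1\nATGC\n")
        g = read_genome(p)
        assert (g.id, g.seq, g.length, g.circular) == ("g1", "ATGC", 4, True)

    def test_lowercase_is_uppercased(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g1\natgc\n")
        assert read_genome(p).seq == "ATGC"

    def test_genbank_topology_sets_circular_flag(self, tmp_path):
        rec = SeqRecord(Seq("ATGCATGCAT"), id="g1", name="g1",
                        description="",
                        annotations={"molecule_type": "DNA",
                                     "topology": "linear"})
        p = tmp_path / "g.gb"
        SeqIO.write([rec], str(p), "genbank")
        g = read_genome(p, format="genbank")
        assert not g.circular

    def test_record_selection_and_errors(self, tmp_path):
        p = tmp_path / "multi.fasta"
        p.write_text(">a\nAAAA\n>b\nCCCC\n")
        assert read_genome(p).seq == "AAAA"
        assert read_genome(p, record_id="b").seq == "CCCC"
        with pytest.raises(GenomeFormatError):
            read_genome(p, record_id="zzz")
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(GenomeFormatError):
            read_genome(empty)

    def test_illegal_characters_rejected(self):
        with pytest.raises(GenomeFormatError):
            CircularGenome("x", "ATGX")
        with pytest.raises(GenomeFormatError):
            CircularGenome("x", "")


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5),
        ("AAAA", 0.0),
        ("GGCC", 1.0),
        ("ATGCNNNN", 0.5),  # N excluded from both sides
    ])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    def test_equals_gc_of_reverse_complement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=50))
            if set(seq) == {"N"}:
                continue
            assert gc_content(seq) == pytest.approx(
                gc_content(reverse_complement(seq)))


class TestReverseComplement:
    def test_core_motif(self):
        assert reverse_complement("TTAATGTCGA") == "TCGACATTAA"

    def test_involution_and_n(self):
        rng = np.random.default_rng(3)
        assert reverse_complement("N") == "N"
        for _ in range(20):
            s = "".join(rng.choice(list("ACGTN"), size=30))
            assert reverse_complement(reverse_complement(s)) == s

    def test_illegal(self):
        with pytest.raises(GenomeFormatError):
            reverse_complement("AXG")


class TestNormalizeOrigin:
    def test_rotation(self):
        g = CircularGenome("g", "ATGC")
        rotated, remap = normalize_origin(g, 3)
        assert rotated.seq == "GCAT"
        assert remap(3) == 1 and remap(4) == 2 and remap(1) == 3

    def test_identity_rotation(self):
        g = CircularGenome("g", "ATGC")
        rotated, remap = normalize_origin(g, 1)
        assert rotated.seq == g.seq
        assert [remap(i) for i in (1, 2, 3, 4)] == [1, 2, 3, 4]

    def test_antisense_flip(self):
        g = CircularGenome("g", "AACGT")
        flipped, remap = normalize_origin(g, 5, "antisense")
        # position 5 (T) becomes position 1 read on the other strand (A)
        assert flipped.seq[0] == "A"
        assert remap(5) == 1
        assert flipped.length == g.length
        assert sorted(flipped.seq) == sorted(reverse_complement(g.seq))

    def test_preserves_length_and_multiset_compose_offsets(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        g = CircularGenome("g", seq)
        r1, m1 = normalize_origin(g, 17)
        r2, m2 = normalize_origin(r1, 9)
        direct, md = normalize_origin(g, (17 - 1 + 9 - 1) % 60 + 1)
        assert r2.seq == direct.seq
        assert sorted(r1.seq) == sorted(seq)
        for pos in (1, 5, 59):
            assert m2(m1(pos)) == md(pos)

    def test_linear_rejected(self):
        with pytest.raises(TopologyError):
            normalize_origin(CircularGenome("g", "ATGC", circular=False), 2)


class TestAnnotationsIO:
    @staticmethod
    def _records(rng, n):
        orfs = []
        for i in range(n):
            start = int(rng.integers(1, 5000))
            aa = int(rng.integers(50, 300))
            end = start + 3 * (aa + 1) - 1
            orfs.append(OrfRecord(start=start, end=end,
                                  strand="sense" if rng.random() < 0.5
                                  else "antisense",
                                  aa_length=aa, index=i + 1, name=f"orf{i+1}",
                                  promoter_class=["E", "L", "E/L", "none"][i % 4]))
        hrs = [HrRegion(label=f"hr{j+1}", start=int(rng.integers(1, 6000)),
                        end=int(rng.integers(6001, 9000)), cores=(),
                        klass="major", orientation_summary="all_forward")
               for j in range(2)]
        return orfs, hrs

    @pytest.mark.parametrize("fmt", ["tsv", "gff3"])
    def test_round_trip_preserves_fields(self, tmp_path, fmt):
        rng = np.random.default_rng(5)
        orfs, hrs = self._records(rng, 8)
        path = tmp_path / f"ann.{fmt}"
        write_annotations(orfs, hrs, path, fmt, genome_length=10000)
        orf_rows, hr_rows = read_annotations(path, fmt)
        assert len(orf_rows) == 8 and len(hr_rows) == 2
        for o, row in zip(orfs, orf_rows):
            assert (row["index"], row["start"], row["end"], row["strand"],
                    row["aa_length"]) == \
                (o.index, o.start, o.end, o.strand, o.aa_length)
        for h, row in zip(hrs, hr_rows):
            assert (row["label"], row["start"], row["end"]) == \
                (h.label, h.start, h.end)

    def test_sense_orf_gff3_line(self, tmp_path):
        orf = OrfRecord(start=1, end=747, strand="sense", aa_length=248,
                        index=1, name="granulin")
        path = tmp_path / "g.gff3"
        write_annotations([orf], [], path, "gff3", genome_id="g")
        line = path.read_text().splitlines()[1].split("\t")
        assert line[2] == "CDS" and line[3] == "1" and line[4] == "747" \
            and line[6] == "+"

    def test_zero_records_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_annotations([], [], path, "tsv")
        assert path.read_text().count("\n") == 1

    def test_out_of_range_rejected(self, tmp_path):
        orf = OrfRecord(start=100, end=402, strand="sense", aa_length=100)
        with pytest.raises(ValueError):
            write_annotations([orf], [], tmp_path / "x.tsv", "tsv",
                              genome_length=200)
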