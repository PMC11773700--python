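"""TE reference model: classification, headers, prep chain, chrom tables."""

import pytest

from pitescan import (
    EmptyReference,
    HeaderParseError,
    IntervalOutOfBounds,
    MalformedRow,
    UnknownChromosome,
    classify_family,
    extract_te_sequences,
    load_te_fasta,
    parse_chrom_lengths,
    parse_rmsk,
    parse_te_header,
    reverse_complement,
    rmsk_to_bed,
    table1_catalogue,
    write_bed,
    write_te_fasta,
)
from pitescan.reference import BedRecord, RmskRow, natural_sort_key


class TestClassification:
    def test_catalogue_shape(self):
        cat = table1_catalogue()
        sizes = {cls: len(stems) for cls, stems in cat.items()}
        assert sizes == {"DNA": 20, "LTR": 9, "LINE": 8, "SINE": 2,
                         "RC": 1, "Satellite": 2}
        assert cat["RC"] == ["Helitron"]
        assert cat["Satellite"] == ["BRSATI", "MOSAT"]
        assert sum(sizes.values()) == 42

    def test_every_catalogued_stem_maps_to_its_class(self):
        for cls, stems in table1_catalogue().items():
            for stem in stems:
                assert classify_family(stem) == cls, stem

    @pytest.mark.parametrize("family,expected", [
        ("Gypsy", "LTR"),
        ("hAT-Charlie", "DNA"),       # substring rule on compound names
        ("Tc1-Mariner", "DNA"),
        ("gypsy", "LTR"),             # case-insensitive
        ("Rex_Babar", "LINE"),        # '_' equivalent to '-'
        ("tRNA-V-RTE", "SINE"),       # longest stem beats the LINE stem RTE
        ("RTE-2_DR", "LINE"),
        ("FooBar", "Unclassified"),
        ("", "Unclassified"),
    ])
    def test_family_lookup(self, family, expected):
        assert classify_family(family) == expected


class TestHeaderParsing:
    def test_canonical_dialect(self):
        rec = parse_te_header(">Gypsy-12#LTR/Gypsy::4:1000-1450(-)")
        assert (rec.name, rec.family, rec.te_class) == ("Gypsy-12", "Gypsy", "LTR")
        assert (rec.chrom, rec.start, rec.end, rec.strand) == ("4", 1000, 1450, "-")

    def test_bare_name_falls_back_to_inference(self):
        rec = parse_te_header(">L1-2_DRe")
        assert (rec.name, rec.family, rec.te_class) == ("L1-2_DRe", "L1", "LINE")
        assert not rec.has_locus
        assert rec.strand == "+"

    def test_missing_strand_defaults_plus(self):
        rec = parse_te_header(">X#DNA/hAT::chr2:5-25")
        assert rec.strand == "+" and rec.has_locus

    def test_unknown_family_uses_header_class_token(self):
        rec = parse_te_header(">Rep-1#LINE/Weird::1:0-10(+)")
        assert rec.te_class == "LINE" and rec.family == "Weird"

    def test_empty_name_rejected(self):
        with pytest.raises(HeaderParseError):
            parse_te_header(">")


class TestLoadTeFasta:
    def test_loads_records_in_order(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(
            ">Gypsy-1#LTR/Gypsy::chr1:0-8(+)\nACGTACGT\n"
            ">L1-1#LINE/L1::chr1:10-18(-)\nTTTTAAAA\n"
            ">Unknown-rep\nacgu\n")
        records = load_te_fasta(fa)
        assert [r.name for r in records] == ["Gypsy-1", "L1-1", "Unknown-rep"]
        assert records[2].te_class == "Unclassified"
        assert records[2].sequence == "ACGT"  # normalized on load

    def test_empty_file_rejected(self, tmp_path):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        with pytest.raises(EmptyReference):
            load_te_fasta(fa)


RMSK_HEADER = ("#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart\t"
               "genoEnd\tgenoLeft\tstrand\trepName\trepClass\trepFamily\t"
               "repStart\trepEnd\trepLeft\tid\n")


def rmsk_line(chrom, start, end, strand, name, cls, fam):
    return "\t".join(map(str, [0, 0, 0, 0, 0, chrom, start, end, 0, strand,
                               name, cls, fam, 0, 0, 0, 0])) + "\n"


class TestRmskToBed:
    def test_column_mapping(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(RMSK_HEADER
                        + rmsk_line("chr4", 1000, 1450, "-", "Gypsy-12", "LTR", "Gypsy"))
        beds = rmsk_to_bed(parse_rmsk(path))
        assert len(beds) == 1
        assert beds[0].to_line() == "chr4\t1000\t1450\tGypsy-12#LTR/Gypsy\t0\t-"

    def test_header_skipped_and_c_strand_mapped(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(RMSK_HEADER
                        + rmsk_line("chr1", 0, 10, "C", "L1-1", "LINE", "L1"))
        beds = rmsk_to_bed(parse_rmsk(path))
        assert beds[0].strand == "-"

    def test_empty_interval_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(RMSK_HEADER
                        + rmsk_line("chr1", 5, 5, "+", "L1-1", "LINE", "L1"))
        with pytest.raises(MalformedRow, match="line 2"):
            list(parse_rmsk(path))


class TestExtraction:
    @pytest.fixture
    def genome(self, tmp_path):
        path = tmp_path / "genome.fa"
        path.write_text(">chr1\nAACCGGTT\n")
        return path

    def test_plus_strand_is_slice(self, genome):
        recs = extract_te_sequences(genome, [BedRecord("chr1", 0, 4, "X#DNA/hAT", 0, "+")])
        assert recs[0].sequence == "AACC"

    def test_minus_strand_is_reverse_complement(self, genome):
        recs = extract_te_sequences(genome, [BedRecord("chr1", 0, 4, "X#DNA/hAT", 0, "-")])
        assert recs[0].sequence == "GGTT"
        assert recs[0].sequence == reverse_complement("AACC")

    def test_bounds_and_chromosome_checked(self, genome):
        with pytest.raises(IntervalOutOfBounds):
            extract_te_sequences(genome, [BedRecord("chr1", 0, 9, "X", 0, "+")])
        with pytest.raises(UnknownChromosome):
            extract_te_sequences(genome, [BedRecord("chr9", 0, 4, "X", 0, "+")])

    def test_prep_round_trip_preserves_records(self, tmp_path):
        """rmsk -> BED -> strand-aware FASTA -> load reproduces every field."""
        genome = tmp_path / "genome.fa"
        genome.write_text(">chr1\nAACCGGTTAACCGGTTAACC\n>chr2\nACACACACACACACACACAC\n")
        rmsk = tmp_path / "rmsk.tsv"
        rmsk.write_text(
            RMSK_HEADER
            + rmsk_line("chr1", 2, 10, "+", "Gypsy-1", "LTR", "Gypsy")
            + rmsk_line("chr1", 12, 19, "-", "hAT-1", "DNA", "hAT")
            + rmsk_line("chr2", 0, 6, "-", "Weird-1", "Unknown", "FooBar"))
        beds = rmsk_to_bed(parse_rmsk(rmsk))
        bed_path = tmp_path / "te.bed"
        write_bed(beds, bed_path)
        extracted = extract_te_sequences(genome, beds)
        fa_path = tmp_path / "te.fa"
        write_te_fasta(extracted, fa_path)
        loaded = load_te_fasta(fa_path)
        key = lambda r: (r.name, r.family, r.te_class, r.chrom, r.start,
                         r.end, r.strand, r.sequence)
        assert [key(r) for r in loaded] == [key(r) for r in extracted]
        assert loaded[2].te_class == "Unclassified"


class TestChromTable:
    def test_two_column_table(self, tmp_path):
        path = tmp_path / "chrom.txt"
        path.write_text("chr1\t1000\nchr2\t800\n")
        table = parse_chrom_lengths(path)
        assert table.get("chr1") == 1000 and table.get("chr2") == 800

    def test_band_table_takes_max_end(self, tmp_path):
        path = tmp_path / "cyto.txt"
        path.write_text("chr1\t0\t500\tp1\tgneg\nchr1\t500\t1000\tq1\tgpos50\n")
        assert parse_chrom_lengths(path).get("chr1") == 1000

    def test_chr_prefix_stripped_for_matching(self, tmp_path):
        path = tmp_path / "chrom.txt"
        path.write_text("chr4\t5000\n")
        table = parse_chrom_lengths(path)
        assert table.get("4") == 5000
        assert table.display_name("4") == "chr4"

    def test_non_numeric_length_rejected(self, tmp_path):
        path = tmp_path / "chrom.txt"
        path.write_text("chr1\tabc\n")
        with pytest.raises(MalformedRow, match="line 1"):
            parse_chrom_lengths(path)


def test_natural_sort_orders_numerically():
    names = ["chr10", "chr2", "chr1", "chrM"]
    assert sorted(names, key=natural_sort_key) == ["chr1", "chr2", "chr10", "chrM"]
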