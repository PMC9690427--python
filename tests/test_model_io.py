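"""Domain model, gene-name canonicalization and table/GenBank I/O."""

import io

import numpy as np
import pytest

import mitocharter as mc
from mitocharter.model import ALL_TOKENS, feature_length


class TestCanonicalize:
    @pytest.mark.parametrize("raw, anticodon, expected", [
        ("cox1", None, "cox1"),
        ("COI", None, "cox1"),
        ("CYTB", None, "cob"),
        ("cyt b", None, "cob"),
        ("16S RNA", None, "rrnL"),
        ("l-rRNA", None, "rrnL"),
        ("12S", None, "rrnS"),
        ("ND4L", None, "nad4l"),
        ("tRNA-Ser(UCA)", "TGA", "trnS1"),
        ("tRNA-Ser(UCA)", None, "trnS1"),   # codon in the label suffices
        ("tRNA-Ser(AGC)", "GCT", "trnS2"),
        ("tRNA-Leu(CUA)", None, "trnL1"),
        ("tRNA-Leu(UUA)", None, "trnL2"),
        ("trnL", "TAA", "trnL2"),
        ("trnS1", None, "trnS1"),
        ("tRNA-Cys", None, "trnC"),
        ("tRNA-Trp", None, "trnW"),
        ("trnM", None, "trnM"),
    ])
    def test_mapping(self, raw, anticodon, expected):
        assert mc.canonicalize_gene_name(raw, anticodon) == expected

    @pytest.mark.parametrize("raw, anticodon", [
        ("mystery gene", None),
        ("trnS", None),      # duplicated tRNA without disambiguation
        ("", None),
    ])
    def test_unmappable(self, raw, anticodon):
        with pytest.raises(mc.UnknownGeneError):
            mc.canonicalize_gene_name(raw, anticodon)

    def test_error_names_the_label(self):
        with pytest.raises(mc.UnknownGeneError, match="mystery"):
            mc.canonicalize_gene_name("mystery gene")


class TestFeatureLength:
    @pytest.mark.parametrize("start, end, expected", [
        (9811, 11196, 1386),   # the large rRNA
        (1, 1, 1),
        (15790, 5, 11),        # wraps the origin of a 15,795 bp circle
    ])
    def test_examples(self, start, end, expected):
        assert feature_length(start, end, 15795, circular=True) == expected

    def test_linear_wrap_rejected(self):
        with pytest.raises(ValueError):
            feature_length(100, 5, 1000, circular=False)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            feature_length(0, 10, 1000)

    def test_against_position_enumeration(self, rng):
        """Brute force: count positions walked from start to end around
        the circle, for 1000 random circular features."""
        for _ in range(1000):
            n = int(rng.integers(2, 500))
            start = int(rng.integers(1, n + 1))
            end = int(rng.integers(1, n + 1))
            walked, pos = 1, start
            while pos != end:
                pos = pos % n + 1
                walked += 1
            assert feature_length(start, end, n, circular=True) == walked


class TestFeatureTable:
    def test_fixture_loads_with_expected_census(self, erumphii):
        assert len(erumphii) == 37
        assert erumphii.category_counts() == {"PCG": 13, "tRNA": 22, "rRNA": 2}
        assert erumphii.genome_length == 15795
        # thousands separators in the packaged table parsed correctly
        assert erumphii.get("rrnL").end == 11196

    def test_vocabulary_closed(self, erumphii):
        assert {f.name for f in erumphii} <= set(ALL_TOKENS)

    def test_single_row_values(self, erumphii):
        f = erumphii.get("nad4l")
        assert (f.start, f.end, f.strand) == (6535, 6834, "L")
        assert f.stop_codon == "TAG"

    def test_empty_table(self):
        ann = mc.read_feature_table(io.StringIO("Gene\tFrom\tTo\tStrand\n"),
                                    genome_length=1000)
        assert len(ann) == 0

    def test_duplicate_gene_rejected(self):
        text = ("Gene\tFrom\tTo\tStrand\n"
                "cox1\t1\t100\tH\ncox1\t200\t300\tH\n")
        with pytest.raises(ValueError, match="duplicate"):
            mc.read_feature_table(io.StringIO(text), genome_length=1000)

    def test_out_of_range_coordinate_rejected(self):
        text = "Gene\tFrom\tTo\tStrand\ncox1\t1\t5000\tH\n"
        with pytest.raises(ValueError, match="outside"):
            mc.read_feature_table(io.StringIO(text), genome_length=1000)

    def test_length_mismatch_warns_but_loads(self, caplog):
        text = "Gene\tFrom\tTo\tLength\tStrand\ncox1\t1\t99\t1536\tH\n"
        with caplog.at_level("WARNING", logger="mitocharter"):
            ann = mc.read_feature_table(io.StringIO(text), genome_length=1000)
        assert len(ann) == 1
        assert "stored length" in caplog.text

    def test_round_trip_fixture(self, erumphii):
        text = mc.write_feature_table(erumphii)
        again = mc.read_feature_table(io.StringIO(text),
                                      genome_length=erumphii.genome_length)
        assert again.features == erumphii.features

    def test_round_trip_simulated(self, sim_genome):
        ann = sim_genome.annotation
        text = mc.write_feature_table(ann)
        again = mc.read_feature_table(io.StringIO(text),
                                      genome_length=ann.genome_length)
        assert again.features == ann.features

    def test_written_intergenic_matches_published_column(self, erumphii):
        """The recomputed Intergenic column reproduces the printed one."""
        from importlib import resources
        raw = (resources.files("mitocharter") / "data"
               / "erumphii_features.tsv").read_text().splitlines()[1:]
        printed = [int(line.split("\t")[7]) for line in raw]
        report = mc.organization_report(erumphii)
        assert list(report["Intergenic"]) == printed


GENBANK_2GENE = """\
LOCUS       TEST0001                1200 bp    DNA     circular INV 01-JAN-2022
DEFINITION  synthetic two-gene test record.
ACCESSION   TEST0001
FEATURES             Location/Qualifiers
     source          1..1200
                     /organism="synthetic construct"
     CDS             10..189
                     /gene="cox1"
     CDS             complement(300..500)
                     /gene="ND4"
     tRNA            join(1150..1200,1..20)
                     /product="tRNA-Met"
ORIGIN
"""


def _with_origin(header: str, length: int) -> str:
    seq = ("acgt" * (length // 4 + 1))[:length]
    lines = []
    for i in range(0, length, 60):
        chunk = seq[i:i + 60]
        grouped = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped}")
    return header + "\n".join(lines) + "\n//\n"


class TestGenBank:
    def test_minimal_record(self):
        genome = mc.read_genbank(io.StringIO(_with_origin(GENBANK_2GENE, 1200)))
        ann = genome.annotation
        assert ann.genome_length == 1200
        assert genome.sequence is not None and len(genome.sequence) == 1200
        cox1 = ann.get("cox1")
        assert (cox1.start, cox1.end, cox1.strand) == (10, 189, "H")
        nad4 = ann.get("nad4")
        assert (nad4.start, nad4.end, nad4.strand) == (300, 500, "L")

    def test_join_across_origin_becomes_wraparound(self):
        genome = mc.read_genbank(io.StringIO(_with_origin(GENBANK_2GENE, 1200)))
        trnM = genome.annotation.get("trnM")
        assert (trnM.start, trnM.end) == (1150, 20)
        assert trnM.wraps_origin()
        assert trnM.length(1200) == 71

    def test_unknown_label_skipped_with_warning(self, caplog):
        text = GENBANK_2GENE.replace('/gene="cox1"', '/gene="ORF-unknown"')
        with caplog.at_level("WARNING", logger="mitocharter"):
            genome = mc.read_genbank(io.StringIO(_with_origin(text, 1200)))
        assert "ORF-unknown" in caplog.text
        assert {f.name for f in genome.annotation} == {"nad4", "trnM"}


class TestContainers:
    def test_pcg_with_anticodon_rejected(self):
        with pytest.raises(ValueError, match="anticodon"):
            mc.GeneFeature(name="cox1", start=1, end=9, strand="H",
                           anticodon="TGA")

    def test_trna_with_codons_rejected(self):
        with pytest.raises(ValueError, match="start/stop"):
            mc.GeneFeature(name="trnA", start=1, end=60, strand="H",
                           start_codon="ATG")

    def test_sequence_length_must_match(self, erumphii):
        with pytest.raises(ValueError, match="length"):
            mc.MitoGenome(annotation=erumphii, sequence="ACGT")

    def test_features_sorted_by_start(self, sim_genome):
        starts = [f.start for f in sim_genome.annotation]
        assert starts == sorted(starts)
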