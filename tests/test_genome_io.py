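"""FASTA/GFF3 I/O, spliced CDS assembly, ORF finding and translation."""

import numpy as np
import pytest

from tpsfam import genome_io as gio
from tpsfam.simulate import CODONS


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_single_record_parse(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">chr1\nACGT\n")
        recs = gio.read_fasta(p)
        assert list(recs) == ["chr1"]
        assert len(recs["chr1"]) == 4

    def test_lowercase_normalized(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">chr1\nacgtn\n")
        assert gio.read_fasta(p)["chr1"].sequence == "ACGTN"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = write(tmp_path, "a.fasta", ">g1\nAC\n>g1\nGT\n")
        with pytest.raises(gio.GenomeIOError, match="duplicate"):
            gio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = write(tmp_path, "a.fasta", "")
        with pytest.raises(gio.GenomeIOError):
            gio.read_fasta(p)

    def test_write_read_round_trip(self, tmp_path, small_genome):
        path = tmp_path / "genome.fasta"
        seqs = {c: small_genome.genome[c].sequence for c in sorted(small_genome.genome)}
        gio.write_fasta(seqs, path)
        back = gio.read_fasta(path)
        assert {c: back[c].sequence for c in back} == seqs


class TestGff3:
    def test_cds_grouped_per_transcript(self, tmp_path):
        rows = ["##gff-version 3"]
        rows.append("chr1\tx\tgene\t1\t700\t.\t+\t.\tID=g1")
        rows.append("chr1\tx\tmRNA\t1\t700\t.\t+\t.\tID=g1.1;Parent=g1")
        for i in range(7):
            s = 1 + i * 100
            rows.append(f"chr1\tx\tCDS\t{s}\t{s + 50}\t.\t+\t0\tID=c{i};Parent=g1.1")
        p = write(tmp_path, "a.gff3", "\n".join(rows) + "\n")
        models = gio.read_gff3(p)
        assert len(models) == 1
        assert models[0].n_exons == 7

    def test_cds_without_parent_rejected(self, tmp_path):
        p = write(tmp_path, "a.gff3", "chr1\tx\tCDS\t1\t9\t.\t+\t0\tID=c1\n")
        with pytest.raises(gio.GenomeIOError, match="Parent"):
            gio.read_gff3(p)

    def test_mixed_strand_rejected(self, tmp_path):
        text = (
            "chr1\tx\tmRNA\t1\t100\t.\t+\t.\tID=m1\n"
            "chr1\tx\tCDS\t1\t30\t.\t+\t0\tParent=m1\n"
            "chr1\tx\tCDS\t50\t80\t.\t-\t0\tParent=m1\n"
        )
        with pytest.raises(gio.GenomeIOError, match="strand"):
            gio.read_gff3(write(tmp_path, "a.gff3", text))

    def test_cds_beyond_chromosome_rejected(self, tmp_path):
        text = (
            "chr1\tx\tmRNA\t1\t500\t.\t+\t.\tID=m1\n"
            "chr1\tx\tCDS\t1\t500\t.\t+\t0\tParent=m1\n"
        )
        genome = {"chr1": gio.GenomeSequence("chr1", "ACGT" * 25)}
        with pytest.raises(gio.GenomeIOError, match="beyond"):
            gio.read_gff3(write(tmp_path, "a.gff3", text), genome=genome)

    def test_synthetic_round_trip_matches_planted_models(self, tmp_path, small_genome):
        path = tmp_path / "genes.gff3"
        gio.write_gff3(small_genome.models, path)
        back = gio.read_gff3(path)
        orig = sorted(small_genome.models, key=lambda m: m.transcript_id)
        back = sorted(back, key=lambda m: m.transcript_id)
        assert len(orig) == len(back)
        for a, b in zip(orig, back):
            assert (a.chrom_id, a.strand, a.exons) == (b.chrom_id, b.strand, b.exons)


class TestExtractCds:
    def test_plus_strand_concatenation(self):
        genome = gio.GenomeSequence("c", "ATGAAA" + "GTCCAG" + "TGA")
        model = gio.GeneModel("g", "g.1", "c", "+", [(1, 6), (13, 15)])
        assert gio.extract_cds(model, genome).cds == "ATGAAATGA"

    def test_strand_symmetry(self, small_genome):
        """Reverse-complementing a locus and flipping strand yields the same CDS."""
        for model in small_genome.models[:5]:
            chrom = small_genome.genome[model.chrom_id]
            cds = gio.extract_cds(model, chrom).cds
            flipped_seq = gio.reverse_complement(chrom.sequence)
            L = len(chrom.sequence)
            flipped_exons = sorted((L - e + 1, L - s + 1) for s, e in model.exons)
            flipped = gio.GeneModel(
                model.gene_id, model.transcript_id, model.chrom_id,
                "-" if model.strand == "+" else "+", flipped_exons,
            )
            assert gio.extract_cds(flipped, gio.GenomeSequence(model.chrom_id, flipped_seq)).cds == cds

    def test_out_of_bounds_exon_rejected(self):
        genome = gio.GenomeSequence("c", "ATGAAATGA")
        model = gio.GeneModel("g", "g.1", "c", "+", [(1, 12)])
        with pytest.raises(gio.GenomeIOError):
            gio.extract_cds(model, genome)

    def test_complete_flag_on_planted_genes(self, small_genome):
        for model in small_genome.models:
            truth = small_genome.genes[model.gene_id]
            tr = gio.extract_cds(model, small_genome.genome)
            if truth.functional:
                assert tr.complete, model.gene_id


class TestTranslate:
    def test_minimal_orf(self):
        p = gio.translate("ATGTGA")
        assert p.residues == "M" and p.complete

    @pytest.mark.parametrize("orf_nt,expected_aa", [(1680, 559), (1689, 562), (1683, 560), (1668, 555)])
    def test_complete_orf_length_arithmetic(self, orf_nt, expected_aa, rng):
        """A complete ORF of 3(L+1) nt encodes L residues (stop uncounted)."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        body = "".join(CODONS[aas[i]][0] for i in rng.integers(0, 20, size=expected_aa - 1))
        cds = "ATG" + body + "TAA"
        assert len(cds) == orf_nt
        p = gio.translate(cds)
        assert p.length == expected_aa and p.complete

    def test_frame_error(self):
        with pytest.raises(gio.GenomeIOError, match="divisible"):
            gio.translate("ATGA")

    def test_internal_stop_incomplete(self):
        p = gio.translate("ATGTAAAAATGA")
        assert p.residues == "M" and not p.complete

    def test_ambiguous_codon_is_x(self):
        assert gio.translate("ATGANTTGA").residues == "MX"

    def test_length_equals_cds_thirds_minus_one(self, rng):
        """Over 1,000 random complete ORFs: len(protein) == len(cds)/3 - 1."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(1000):
            n_aa = int(rng.integers(1, 40))
            body = "".join(
                CODONS[aas[i]][int(rng.integers(0, len(CODONS[aas[i]])))]
                for i in rng.integers(0, 20, size=n_aa)
            )
            cds = "ATG" + body + ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            p = gio.translate(cds)
            assert p.complete and p.length == len(cds) // 3 - 1


class TestFindLongestOrf:
    def test_embedded_orf_found(self):
        seq = "CC" + "ATGAAATGA" + "CCCC"
        assert gio.find_longest_orf(seq, 6).cds == "ATGAAATGA"

    def test_longest_wins(self, rng):
        """Between ORFs of 300 and 1,683 nt, the 1,683-nt one is returned."""
        aas = "ACDEFGHIKLMNPQRSTVWY"

        def orf(n_nt):
            body = "".join(CODONS[aas[i]][0] for i in rng.integers(0, 20, size=n_nt // 3 - 2))
            return "ATG" + body + "TAA"

        short, long = orf(300), orf(1683)
        seq = "TAGTAATGA" + short + "TAGTAATGA" + long + "TAGTAA"
        found = gio.find_longest_orf(seq, 300)
        assert len(found.cds) == 1683

    def test_reverse_strand_orf(self):
        orf = "ATGAAATGA"
        seq = "GG" + gio.reverse_complement(orf) + "GG"
        assert gio.find_longest_orf(seq, 6).cds == orf

    def test_all_n_input_empty(self):
        result = gio.find_longest_orf("N" * 100, 30)
        assert result.cds == "" and not result.complete
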