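"""Intron phases, class assignment, exon/intron statistics, splice consensus."""

import numpy as np
import pytest

from tpsfam import architecture as arch
from tpsfam.genome_io import GeneModel, GenomeSequence
from oracles import codon_walk_phases, shannon_column_bits


def model_from_exon_lengths(exon_nt, intron_nt, strand="+"):
    exons = []
    pos = 1
    for i, e in enumerate(exon_nt):
        exons.append((pos, pos + e - 1))
        pos += e
        if i < len(intron_nt):
            pos += intron_nt[i]
    return GeneModel("g", "g.1", "chr", strand, exons)


class TestIntronPhases:
    @pytest.mark.parametrize("first_exon,expected", [(45, 0), (46, 1), (47, 2)])
    def test_first_intron_phase(self, first_exon, expected):
        m = model_from_exon_lengths([first_exon, 60], [100])
        assert arch.intron_phases(m)[0] == expected

    def test_matches_codon_walk_oracle(self):
        exon_nt = [120, 300, 132, 246, 375, 132, 375]
        m = model_from_exon_lengths(exon_nt, [100] * 6)
        assert arch.intron_phases(m) == codon_walk_phases(exon_nt)

    def test_random_models_match_oracle(self, rng):
        for _ in range(50):
            n_exons = int(rng.integers(2, 10))
            exon_nt = [int(rng.integers(10, 400)) for _ in range(n_exons)]
            intron_nt = [int(rng.integers(20, 300)) for _ in range(n_exons - 1)]
            m = model_from_exon_lengths(exon_nt, intron_nt)
            assert arch.intron_phases(m) == codon_walk_phases(exon_nt)

    def test_phase_invariant_under_strand_reversal(self, small_genome):
        """Flipping the whole locus leaves the phase vector unchanged."""
        for model in small_genome.models[:6]:
            if model.n_introns == 0:
                continue
            phases = arch.intron_phases(model)
            L = small_genome.genome[model.chrom_id].sequence
            total = len(L)
            flipped_exons = sorted((total - e + 1, total - s + 1) for s, e in model.exons)
            flipped = GeneModel(
                model.gene_id, model.transcript_id, model.chrom_id,
                "-" if model.strand == "+" else "+", flipped_exons,
            )
            assert arch.intron_phases(flipped) == phases

    def test_no_introns_error(self):
        m = model_from_exon_lengths([90], [])
        with pytest.raises(ValueError):
            arch.intron_phases(m)


class TestClassAssignment:
    def test_exhaustive_0_to_20(self):
        expected = {6: "III", 9: "II", 11: "I", 12: "I", 13: "I", 14: "I"}
        for n in range(21):
            assert arch.classify_tps_class(n) == expected.get(n, "unclassified")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            arch.classify_tps_class(-1)

    def test_planted_classes_recovered(self, small_genome):
        for m in small_genome.models:
            truth = small_genome.genes[m.gene_id]
            if truth.functional:
                assert arch.classify_tps_class(m.n_introns) == truth.tps_class


class TestExonLengthsAa:
    def test_remainder_carried(self):
        # 100 nt -> 33 aa with 1 nt carried; next exon 101 nt + 1 = 34 aa
        m = model_from_exon_lengths([100, 101, 99], [50, 50])
        assert arch.exon_lengths_aa(m) == [33, 34, 33]
        assert sum(arch.exon_lengths_aa(m)) == (100 + 101 + 99) // 3

    def test_sum_matches_cds_for_planted(self, small_genome):
        for m in small_genome.models:
            total_nt = sum(e - s + 1 for s, e in m.exons)
            assert sum(arch.exon_lengths_aa(m)) == total_nt // 3


class TestStats:
    def test_single_gene_medians(self):
        m = model_from_exon_lengths([120, 300], [100])
        stats = arch.exon_intron_stats([arch.gene_architecture(m)])
        assert stats["exon_stats"].loc[1, "median_aa"] == 40
        assert stats["intron_stats"]["min_nt"] == 100

    def test_minimum_intron_reported(self):
        m1 = model_from_exon_lengths([120, 300], [16])
        m2 = model_from_exon_lengths([120, 300], [2335])
        stats = arch.exon_intron_stats([arch.gene_architecture(m) for m in (m1, m2)])
        assert stats["intron_stats"]["min_nt"] == 16
        assert stats["intron_stats"]["max_nt"] == 2335

    def test_cohort_medians_near_template(self, default_genome):
        """Per-position exon-length medians of the planted cohort fall in 44-125 aa."""
        archs = [
            arch.gene_architecture(m)
            for m in default_genome.models
            if default_genome.genes[m.gene_id].functional
            and default_genome.genes[m.gene_id].tps_class == "III"
        ]
        stats = arch.exon_intron_stats(archs)
        medians = stats["exon_stats"]["median_aa"]
        assert ((medians >= 40) & (medians <= 130)).all()

    def test_planted_intron_band(self, default_genome):
        stats = arch.exon_intron_stats(
            [arch.gene_architecture(m) for m in default_genome.models]
        )
        assert stats["intron_stats"]["frac_in_81_400"] > 0.6

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            arch.exon_intron_stats([])


def _intron_cohort(n, rng, donor_minus1=None):
    """n single-intron genes with canonical GT..AG introns and random flanks."""
    models, genome = [], {}
    for i in range(n):
        exon1 = "".join("ACGT"[j] for j in rng.integers(0, 4, size=30))
        if donor_minus1 is not None:
            exon1 = exon1[:-1] + donor_minus1[i % len(donor_minus1)]
        intron = "GT" + "".join("ACGT"[j] for j in rng.integers(0, 4, size=40)) + "TAG"
        exon2 = "".join("ACGT"[j] for j in rng.integers(0, 4, size=30))
        seq = exon1 + intron + exon2
        chrom = f"c{i}"
        genome[chrom] = GenomeSequence(chrom, seq)
        models.append(
            GeneModel(f"g{i}", f"g{i}.1", chrom, "+", [(1, 30), (31 + len(intron), len(seq))])
        )
    return models, genome


class TestSpliceConsensus:
    def test_invariant_gt_ag_columns(self, rng):
        models, genome = _intron_cohort(50, rng)
        cons = arch.splice_consensus(models, genome, flank_nt=10)
        en = arch.small_sample_correction(50)
        assert cons.donor_bits.loc[1] == pytest.approx(2 - en)
        assert cons.donor_bits.loc[2] == pytest.approx(2 - en)
        assert cons.acceptor_bits.loc[-2] == pytest.approx(2 - en)
        assert cons.acceptor_bits.loc[-1] == pytest.approx(2 - en)
        assert cons.donor_pfm.loc[1, "G"] == 1.0 and cons.donor_pfm.loc[2, "T"] == 1.0

    def test_random_flanks_near_zero_bits(self, rng):
        models, genome = _intron_cohort(400, rng)
        cons = arch.splice_consensus(models, genome, flank_nt=8)
        flank_cols = cons.donor_bits.loc[[-8, -7, -6, -5]]
        assert (flank_cols < 0.1).all()

    def test_planted_purine_split_half_bit(self, rng):
        """50% A / 50% G at donor -1 gives ~1 bit (closed-form entropy check)."""
        models, genome = _intron_cohort(200, rng, donor_minus1="AG")
        cons = arch.splice_consensus(models, genome, flank_nt=10)
        expected = shannon_column_bits({"A": 0.5, "G": 0.5}, 200)
        assert cons.donor_bits.loc[-1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.0, abs=0.02)

    def test_pfm_columns_sum_to_one(self, rng):
        models, genome = _intron_cohort(20, rng)
        cons = arch.splice_consensus(models, genome, flank_nt=10)
        assert np.allclose(cons.donor_pfm.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(cons.acceptor_pfm.sum(axis=1), 1.0, atol=1e-9)

    def test_short_intron_skipped_with_warning(self, rng):
        models, genome = _intron_cohort(3, rng)
        # one extra gene with a 6-nt intron
        seq = "A" * 30 + "GTAAAG" + "C" * 30
        genome["cx"] = GenomeSequence("cx", seq)
        models.append(GeneModel("gx", "gx.1", "cx", "+", [(1, 30), (37, 66)]))
        with pytest.warns(UserWarning, match="shorter than flank"):
            cons = arch.splice_consensus(models, genome, flank_nt=10)
        assert cons.n_sites == 3
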