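"""Exon/intron architecture: intron phases, TPS class assignment, splice consensus.

Plant terpene synthase genes fall into three architectural classes defined by
intron count: class I (11-14 introns, diterpene-synthase-like), class II
(9 introns, gymnosperm-specific) and class III (6 introns, the mono-/sesqui-
terpene synthase architecture). Intron phase is the position of an intron
relative to the reading frame: phase 0 falls between codons, phase 1 after
the first codon nucleotide, phase 2 after the second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeSequence, reverse_complement, to_slice

TPS_CLASSES = ("I", "II", "III", "unclassified")

#: intron-count ranges per architectural class (inclusive)
CLASS_I_INTRONS = range(11, 15)
CLASS_II_INTRONS = (9,)
CLASS_III_INTRONS = (6,)


@dataclass
class GeneArchitecture:
    """Per-transcript architecture summary (lengths in transcript order)."""

    transcript_id: str
    exon_lengths_aa: list[int]
    intron_lengths_nt: list[int]
    intron_phases: list[int]
    n_introns: int
    tps_class: str


@dataclass
class SpliceConsensus:
    """Donor/acceptor position frequency matrices with per-column information.

    Rows of each PFM are window positions, columns are A, C, G, T.
    Information content per column is 2 - (Shannon entropy + e_n) bits,
    where e_n = 3 / (2 ln2 n) is the small-sample correction, floored at 0.
    """

    donor_pfm: pd.DataFrame
    acceptor_pfm: pd.DataFrame
    donor_bits: pd.Series
    acceptor_bits: pd.Series
    n_sites: int


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron: cumulative upstream coding length (nt) mod 3."""
    if model.n_introns < 1:
        raise ValueError(f"{model.transcript_id}: no introns")
    lens = model.exon_lengths_nt()
    if any(n == 0 for n in lens):
        raise ValueError(f"{model.transcript_id}: zero-length exon")
    cum = np.cumsum(lens[:-1])
    return [int(c % 3) for c in cum]


def classify_tps_class(n_introns: int) -> str:
    """Map intron count to architectural class (I: 11-14, II: 9, III: 6)."""
    if n_introns < 0:
        raise ValueError(f"negative intron count {n_introns}")
    if n_introns in CLASS_I_INTRONS:
        return "I"
    if n_introns in CLASS_II_INTRONS:
        return "II"
    if n_introns in CLASS_III_INTRONS:
        return "III"
    return "unclassified"


def exon_lengths_aa(model: GeneModel) -> list[int]:
    """Exon coding lengths in amino acids.

    Each exon contributes floor(nt/3) with the fractional codon's remainder
    carried into the next exon, so the total equals total_nt // 3.
    """
    out = []
    carry = 0
    for n in model.exon_lengths_nt():
        n += carry
        out.append(n // 3)
        carry = n % 3
    return out


def gene_architecture(model: GeneModel) -> GeneArchitecture:
    phases = intron_phases(model) if model.n_introns else []
    return GeneArchitecture(
        transcript_id=model.transcript_id,
        exon_lengths_aa=exon_lengths_aa(model),
        intron_lengths_nt=model.intron_lengths_nt(),
        intron_phases=phases,
        n_introns=model.n_introns,
        tps_class=classify_tps_class(model.n_introns),
    )


def exon_intron_stats(
    architectures: Iterable[GeneArchitecture],
    intron_band: tuple[int, int] = (81, 400),
) -> dict[str, pd.DataFrame | pd.Series]:
    """Cohort summary: per-exon-position length stats and intron-length histogram.

    ``exon_stats`` rows are exon positions (1-based, transcript order) with
    median/min/max amino-acid lengths and the number of genes contributing.
    ``intron_stats`` reports min/max/median intron length plus the count and
    fraction inside ``intron_band`` (defaults to the 81-400 nt band where most
    plant TPS introns fall).
    """
    archs = list(architectures)
    if not archs:
        raise ValueError("no architectures given")
    max_exons = max(len(a.exon_lengths_aa) for a in archs)
    rows = []
    for pos in range(max_exons):
        vals = [a.exon_lengths_aa[pos] for a in archs if len(a.exon_lengths_aa) > pos]
        rows.append(
            {
                "exon_position": pos + 1,
                "n": len(vals),
                "median_aa": float(np.median(vals)),
                "min_aa": int(np.min(vals)),
                "max_aa": int(np.max(vals)),
            }
        )
    exon_stats = pd.DataFrame(rows).set_index("exon_position")

    introns = np.array([n for a in archs for n in a.intron_lengths_nt], dtype=int)
    lo, hi = intron_band
    if introns.size:
        in_band = int(((introns >= lo) & (introns <= hi)).sum())
        intron_stats = pd.Series(
            {
                "n_introns": introns.size,
                "min_nt": int(introns.min()),
                "max_nt": int(introns.max()),
                "median_nt": float(np.median(introns)),
                f"n_in_{lo}_{hi}": in_band,
                f"frac_in_{lo}_{hi}": in_band / introns.size,
            }
        )
    else:
        intron_stats = pd.Series(dtype=float)

    phase_rows = []
    max_introns = max((a.n_introns for a in archs), default=0)
    for pos in range(max_introns):
        phs = [a.intron_phases[pos] for a in archs if a.n_introns > pos]
        counts = {f"phase_{p}": phs.count(p) for p in (0, 1, 2)}
        phase_rows.append({"intron_position": pos + 1, **counts})
    phase_stats = pd.DataFrame(phase_rows).set_index("intron_position") if phase_rows else pd.DataFrame()

    class_counts = pd.Series([a.tps_class for a in archs]).value_counts()
    return {
        "exon_stats": exon_stats,
        "intron_stats": intron_stats,
        "phase_stats": phase_stats,
        "class_counts": class_counts,
    }


# ---------------------------------------------------------------------------
# Splice-site consensus
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def small_sample_correction(n: int) -> float:
    """e_n = 3 / (2 ln2 n): expected entropy excess for n sampled sequences."""
    return 3.0 / (2.0 * math.log(2) * n)


def _site_windows(
    model: GeneModel, genome: GenomeSequence, flank: int
) -> tuple[list[str], list[str]]:
    """Donor/acceptor windows in transcript orientation.

    Donor window: last ``flank`` exonic nt + first ``flank`` intronic nt.
    Acceptor window: last ``flank`` intronic nt + first ``flank`` exonic nt.
    Sites whose intron is shorter than ``flank`` are skipped with a warning.
    """
    donors: list[str] = []
    acceptors: list[str] = []
    seq = genome.sequence
    exons = model.exons
    for i, (istart, iend) in enumerate(model.introns()):
        ilen = iend - istart + 1
        if ilen < flank:
            warnings.warn(
                f"{model.transcript_id}: intron {i + 1} shorter than flank window, skipped"
            )
            continue
        left_exon_end = exons[i][1]
        right_exon_start = exons[i + 1][0]
        if left_exon_end - flank + 1 < 1 or right_exon_start + flank - 1 > len(seq):
            warnings.warn(f"{model.transcript_id}: flank outside chromosome, site skipped")
            continue
        up = seq[to_slice(left_exon_end - flank + 1, istart + flank - 1)]
        down = seq[to_slice(iend - flank + 1, right_exon_start + flank - 1)]
        if model.strand == "+":
            donors.append(up)
            acceptors.append(down)
        else:
            donors.append(reverse_complement(down))
            acceptors.append(reverse_complement(up))
    return donors, acceptors


def _pfm(windows: Sequence[str], flank: int) -> tuple[pd.DataFrame, pd.Series]:
    width = 2 * flank
    counts = np.zeros((width, 4))
    lookup = {b: j for j, b in enumerate(_BASES)}
    n_used = np.zeros(width)
    for w in windows:
        for i, b in enumerate(w):
            j = lookup.get(b)
            if j is not None:  # N excluded from the frequency model
                counts[i, j] += 1
                n_used[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n_used[:, None] > 0, counts / np.maximum(n_used, 1)[:, None], 0.25)
    positions = list(range(-flank, 0)) + list(range(1, flank + 1))
    pfm = pd.DataFrame(freqs, index=positions, columns=list(_BASES))
    n = len(windows)
    en = small_sample_correction(n) if n else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0), axis=1)
    bits = np.maximum(2.0 - (h + en), 0.0)
    return pfm, pd.Series(bits, index=positions)


def splice_consensus(
    models: Iterable[GeneModel],
    genome: Mapping[str, GenomeSequence],
    flank_nt: int = 10,
) -> SpliceConsensus:
    """Position frequency matrices around donor and acceptor splice sites.

    Window positions are labeled -flank..-1 (exonic for donors, intronic for
    acceptors) and +1..+flank (intronic for donors, exonic for acceptors);
    canonical introns show invariant G,T at donor +1,+2 and A,G at acceptor
    -2,-1, and the plant-typical purine at donor -1 (the R of "R/GT") and
    pyrimidine at acceptor -3 (the Y of "YAG/") appear as enriched columns.
    """
    donors: list[str] = []
    acceptors: list[str] = []
    for model in models:
        chrom = genome[model.chrom_id] if not isinstance(genome, GenomeSequence) else genome
        d, a = _site_windows(model, chrom, flank_nt)
        donors.extend(d)
        acceptors.extend(a)
    if len(donors) < 2:
        raise ValueError("need at least 2 introns for a consensus")
    donor_pfm, donor_bits = _pfm(donors, flank_nt)
    acceptor_pfm, acceptor_bits = _pfm(acceptors, flank_nt)
    return SpliceConsensus(donor_pfm, acceptor_pfm, donor_bits, acceptor_bits, len(donors))


def consensus_to_tsv(cons: SpliceConsensus, donor_path, acceptor_path) -> None:
    for pfm, bits, path in (
        (cons.donor_pfm, cons.donor_bits, donor_path),
        (cons.acceptor_pfm, cons.acceptor_bits, acceptor_path),
    ):
        out = pfm.copy()
        out["bits"] = bits
        out.index.name = "position"
        out.to_csv(path, sep="\t", float_format="%.6f")
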