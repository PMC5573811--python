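"""Synthetic TPS-family genomes with planted, fully known ground truth.

The generator emits a genome (FASTA + GFF3), a subfamily-anchored protein
reference set, and an RPKM expression matrix whose statistical structure
matches what the characterization pipeline assumes:

* multi-exon gene models of class I (13 introns here) and class III
  (6 introns), GT...AG introns with R/GT donor and YAG/ acceptor context,
  intron lengths mostly in the 81-400 nt band (range 16-2335);
* per-subfamily conserved motifs planted at fixed exon-relative positions;
* pseudogenes whose predicted products fall below 400 residues;
* paralog pairs at controlled protein identity, tandem and cross-chromosome;
* tandem clusters with intra-cluster boundary gaps below, and inter-cluster
  gaps above, the 67 kb clustering threshold;
* planted tissue-specific, high- and low-expression genes.

The default family shape mirrors a large citrus-type TPS family: 28 TPS-a,
18 TPS-b, 2 TPS-c, 2 TPS-e/f and 5 TPS-g putative functional genes plus 40
pseudogenes, 61 genes in 19 clusters, 24 genes on unplaced scaffolds.

All randomness flows from one seeded numpy Generator; the same FamilySpec
(seed included) reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    GeneModel,
    GenomeSequence,
    reverse_complement,
    translate,
    write_fasta,
    write_gff3,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> codons (standard code), deterministic order
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

SUBFAMILIES = ("tps-a", "tps-b", "tps-c", "tps-ef", "tps-g")

#: concrete motif instantiations planted per subfamily: (name, sequence, residue pos)
#: positions are 0-based fractions of protein length resolved at build time
SUBFAMILY_MOTIFS: dict[str, tuple[tuple[str, str, float], ...]] = {
    # class III, sesquiterpene synthases: full generic kit
    "tps-a": (
        ("RRX8W", "RRSASFHPSIW", 0.072),
        ("RDR", "RDR", 0.540),
        ("DDXXD", "DDIYD", 0.566),
        ("NSE/DTE", "DDIYSHKFE", 0.818),
    ),
    # class III, cyclic monoterpene synthases
    "tps-b": (
        ("RRX8W", "RRSANYQPSIW", 0.072),
        ("RDR", "RDR", 0.540),
        ("DDXXD", "DDIYD", 0.566),
        ("NSE/DTE", "DDLGTSSDE", 0.818),
    ),
    # class III, acyclic monoterpene synthases: no arginine motif, degraded RDR
    "tps-g": (
        ("RDQ", "RDQ", 0.540),
        ("DDXXD", "DDIFD", 0.566),
        ("NSE/DTE", "DDLGSAKDE", 0.818),
    ),
    # class I, copalyl diphosphate synthases: DXDD instead of DDXXD
    "tps-c": (
        ("SAYDTAW", "SAYDTAW", 0.075),
        ("QXXDGSWG", "QDTDGSWG", 0.113),
        ("DXDD", "DIDD", 0.538),
    ),
    # class I, ent-kaurene / geranyl linalool synthases: DDXXD, diterpene N-term kit
    "tps-ef": (
        ("SAYDTAW", "SAYDTAW", 0.075),
        ("QXXDGSWG", "QDTDGSWG", 0.113),
        ("DDXXD", "DDIYD", 0.538),
    ),
}

SUBFAMILY_LENGTH_AA = {"tps-a": 556, "tps-b": 600, "tps-c": 780, "tps-ef": 800, "tps-g": 570}
SUBFAMILY_CLASS = {"tps-a": "III", "tps-b": "III", "tps-c": "I", "tps-ef": "I", "tps-g": "III"}

#: subfamilies whose members carry an N-terminal plastid transit peptide
TRANSIT_SUBFAMILIES = {"tps-b", "tps-g"}


@dataclass
class ClassTemplate:
    """Architecture template: fixed intron-phase vector + cumulative split fractions."""

    n_introns: int
    phases: tuple[int, ...]
    split_fractions: tuple[float, ...]  # cumulative, len == n_introns

    def __post_init__(self) -> None:
        assert len(self.phases) == self.n_introns == len(self.split_fractions)


CLASS_TEMPLATES: dict[str, ClassTemplate] = {
    "III": ClassTemplate(
        n_introns=6,
        phases=(0, 1, 0, 2, 0, 0),
        split_fractions=(0.22, 0.35, 0.43, 0.59, 0.70, 0.89),
    ),
    "I": ClassTemplate(
        n_introns=13,
        phases=(0, 0, 1, 2, 0, 1, 0, 2, 0, 0, 1, 0, 2),
        split_fractions=(
            0.07, 0.14, 0.22, 0.29, 0.36, 0.43, 0.50, 0.58, 0.65, 0.72, 0.80, 0.87, 0.94,
        ),
    ),
}


@dataclass
class FamilySpec:
    """Blueprint of a synthetic TPS family; the seed is mandatory."""

    seed: int
    subfamily_counts: dict = field(
        default_factory=lambda: {"tps-a": 28, "tps-b": 18, "tps-c": 2, "tps-ef": 2, "tps-g": 5}
    )
    n_pseudogenes: int = 40
    pseudogene_subfamily_weights: dict = field(
        default_factory=lambda: {"tps-a": 0.5, "tps-b": 0.3, "tps-g": 0.1, "tps-c": 0.05, "tps-ef": 0.05}
    )
    cluster_sizes: tuple = (6, 5, 5, 4, 4, 4, 4, 3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2)
    n_unplaced: int = 24
    intra_cluster_gap_nt: tuple = (1_000, 50_000)
    inter_cluster_gap_nt: tuple = (80_000, 200_000)
    max_gap_nt: int = 67_000
    within_subfamily_identity: tuple = (80.0, 92.0)
    n_tandem_paralog_pairs: int = 5
    tandem_paralog_identity: float = 96.0
    n_cross_paralog_pairs: int = 1
    cross_paralog_identity: float = 92.0
    pseudogene_truncation_aa: tuple = (120, 340)
    reference_identity: float = 88.0
    n_references_per_subfamily: int = 2
    tissues: tuple = ("leaf", "flower", "fruit")
    tissue_specific_counts: dict = field(
        default_factory=lambda: {"leaf": 4, "flower": 1, "fruit": 3}
    )
    n_high_expression: int = 6
    n_low_expression: int = 8
    expression_lognormal: tuple = (1.6, 1.0)  # (mean, sigma) of log RPKM baseline

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("FamilySpec.seed is mandatory")
        if sum(self.cluster_sizes) + self.n_unplaced > self.n_genes:
            raise ValueError("cluster layout larger than gene roster")
        if any(s < 2 or s > 6 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be within 2..6")

    @property
    def n_functional(self) -> int:
        return sum(self.subfamily_counts.values())

    @property
    def n_genes(self) -> int:
        return self.n_functional + self.n_pseudogenes

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FamilySpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in (
            "cluster_sizes", "intra_cluster_gap_nt", "inter_cluster_gap_nt",
            "within_subfamily_identity", "pseudogene_truncation_aa", "tissues",
            "expression_lognormal",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticGene:
    """One emitted gene plus its ground truth."""

    gene_id: str
    subfamily: str
    tps_class: str
    functional: bool
    protein: str
    cds: str
    locus: str  # exons + introns, plus-strand locus orientation
    exon_spans: list[tuple[int, int]]  # 1-based inclusive, locus coordinates
    motif_positions: dict[str, int]  # 1-based residue starts
    paralog_partner: str | None = None
    paralog_identity: float | None = None  # planted pair identity (both members)
    target_identity: float | None = None  # divergence target from the source template
    chrom: str | None = None
    strand: str = "+"
    cluster_id: str | None = None


class TPSFamilySimulator:
    """Builds one synthetic family; all randomness from the spec seed."""

    def __init__(self, spec: FamilySpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.ancestors: dict[str, str] = {}
        self.motif_spans: dict[str, list[tuple[int, int]]] = {}
        self.motif_starts: dict[str, dict[str, int]] = {}
        for sub in SUBFAMILIES:
            self._build_ancestor(sub)

    # -- ancestors ---------------------------------------------------------

    def _build_ancestor(self, subfamily: str) -> None:
        length = SUBFAMILY_LENGTH_AA[subfamily]
        aa = list(self._random_protein(length))
        aa[0] = "M"
        if subfamily in TRANSIT_SUBFAMILIES:
            # serine/threonine-rich, net-positive N-terminus (transit peptide)
            for i in range(2, 40):
                r = self.rng.random()
                if r < 0.30:
                    aa[i] = "S" if self.rng.random() < 0.6 else "T"
                elif r < 0.42:
                    aa[i] = "R" if self.rng.random() < 0.5 else "K"
        spans: list[tuple[int, int]] = []
        starts: dict[str, int] = {}
        for name, seq, frac in SUBFAMILY_MOTIFS[subfamily]:
            start = int(round(frac * length))
            aa[start : start + len(seq)] = list(seq)
            spans.append((start, start + len(seq)))
            starts[name] = start + 1
        self.ancestors[subfamily] = "".join(aa)
        self.motif_spans[subfamily] = spans
        self.motif_starts[subfamily] = starts

    def _random_protein(self, length: int) -> str:
        idx = self.rng.integers(0, len(AA_ORDER), size=length)
        return "".join(AA_ORDER[i] for i in idx)

    # -- protein / CDS construction ---------------------------------------

    def _mutate_protein(
        self, protein: str, subfamily: str, target_identity: float, preserve_motifs: bool = True
    ) -> str:
        length = len(protein)
        n_sub = int(round(length * (1.0 - target_identity / 100.0)))
        blocked: set[int] = {0}
        if preserve_motifs:
            for s, e in self.motif_spans[subfamily]:
                blocked.update(range(s, e))
        allowed = np.array([i for i in range(length) if i not in blocked])
        n_sub = min(n_sub, len(allowed))
        positions = self.rng.choice(allowed, size=n_sub, replace=False)
        aa = list(protein)
        for pos in positions:
            current = aa[pos]
            choices = [c for c in AA_ORDER if c != current]
            aa[pos] = choices[int(self.rng.integers(0, len(choices)))]
        return "".join(aa)

    def _encode_cds(self, protein: str) -> str:
        codons = []
        for r in protein:
            options = CODONS[r]
            codons.append(options[int(self.rng.integers(0, len(options)))])
        codons.append(("TAA", "TAG", "TGA")[int(self.rng.integers(0, 3))])
        return "".join(codons)

    # -- gene assembly -----------------------------------------------------

    def make_gene(
        self,
        subfamily: str,
        gene_id: str,
        protein: str | None = None,
        target_identity: float | None = None,
    ) -> SyntheticGene:
        """Build a complete gene: CDS with planted motifs, split into exons.

        Introns carry GT...AG cores with a pyrimidine before the terminal AG
        (the YAG/ acceptor context); the exonic base preceding each donor is
        recoded synonymously to a purine where the code allows (the R/GT
        donor context).
        """
        spec = self.spec
        if protein is None:
            lo, hi = spec.within_subfamily_identity
            target_identity = float(self.rng.uniform(lo, hi))
            protein = self._mutate_protein(self.ancestors[subfamily], subfamily, target_identity)
        cds = self._encode_cds(protein)
        tps_class = SUBFAMILY_CLASS[subfamily]
        template = CLASS_TEMPLATES[tps_class]
        splits = self._split_points(len(protein), template)
        cds = self._purine_before_donors(cds, splits, protein)
        exon_seqs = []
        prev = 0
        for c in splits:
            exon_seqs.append(cds[prev:c])
            prev = c
        exon_seqs.append(cds[prev:])
        introns = [self._intron() for _ in range(template.n_introns)]
        locus_parts: list[str] = []
        exon_spans: list[tuple[int, int]] = []
        pos = 0
        for i, exon in enumerate(exon_seqs):
            exon_spans.append((pos + 1, pos + len(exon)))
            locus_parts.append(exon)
            pos += len(exon)
            if i < len(introns):
                locus_parts.append(introns[i])
                pos += len(introns[i])
        motif_positions = {
            name: self.motif_starts[subfamily][name] for name in self.motif_starts[subfamily]
        }
        return SyntheticGene(
            gene_id=gene_id,
            subfamily=subfamily,
            tps_class=tps_class,
            functional=True,
            protein=protein,
            cds=cds,
            locus="".join(locus_parts),
            exon_spans=exon_spans,
            motif_positions=motif_positions,
            target_identity=target_identity,
        )

    def _split_points(self, protein_len: int, template: ClassTemplate) -> list[int]:
        """Cumulative CDS split points (nt) realizing the template phase vector."""
        total_nt = 3 * (protein_len + 1)  # includes the stop codon
        points = []
        prev = 0
        for frac, phase in zip(template.split_fractions, template.phases):
            aa_target = int(round(frac * protein_len)) + int(self.rng.integers(-6, 7))
            c = 3 * aa_target + phase
            c = max(prev + 30, min(c, total_nt - 30 * (template.n_introns - len(points))))
            # re-impose the phase after clamping
            c += (phase - c % 3) % 3
            points.append(c)
            prev = c
        if points[-1] > total_nt - 30:
            raise ValueError("protein too short for architecture template")
        return points

    def _purine_before_donors(self, cds: str, splits: Sequence[int], protein: str) -> str:
        out = list(cds)
        for c in splits:
            pos = c - 1  # last exonic base before this donor
            if out[pos] in "AG":
                continue
            codon_idx = pos // 3
            if codon_idx >= len(protein):
                continue
            residue = protein[codon_idx]
            offset = pos % 3
            current = "".join(out[codon_idx * 3 : codon_idx * 3 + 3])
            for alt in CODONS[residue]:
                if alt != current and alt[offset] in "AG":
                    # keep the other two bases' impact minimal: any synonymous swap is fine
                    out[codon_idx * 3 : codon_idx * 3 + 3] = list(alt)
                    break
        return "".join(out)

    def _intron(self) -> str:
        r = self.rng.random()
        if r < 0.10:
            length = int(self.rng.integers(16, 81))
        elif r < 0.90:
            length = int(self.rng.integers(81, 401))
        else:
            length = int(self.rng.integers(401, 2336))
        interior = "".join(
            "ACGT"[i] for i in self.rng.integers(0, 4, size=max(0, length - 5))
        )
        y = "C" if self.rng.random() < 0.5 else "T"
        return "GT" + interior + y + "AG"

    # -- divergent copies and pseudogenes ---------------------------------

    def mutate_to_identity(
        self, gene: SyntheticGene, target_identity: float, gene_id: str,
        preserve_motifs: bool = True,
    ) -> SyntheticGene:
        """A divergent paralog copy at the requested protein identity (+-0.5)."""
        if not 50.0 <= target_identity <= 100.0:
            raise ValueError("target identity must be within [50, 100]")
        protein = self._mutate_protein(
            gene.protein, gene.subfamily, target_identity, preserve_motifs=preserve_motifs
        )
        copy = self.make_gene(gene.subfamily, gene_id, protein=protein, target_identity=target_identity)
        copy.paralog_partner = gene.gene_id
        return copy

    def truncate_to_pseudogene(self, gene: SyntheticGene, mode: str | None = None) -> SyntheticGene:
        """Pseudogenized copy with a product below 400 residues.

        ``premature_stop`` swaps one early codon for a stop; ``exon_deletion``
        drops an internal exon (frameshift). Falls back to a premature stop
        whenever a deletion would still leave a >= 400-residue product. The
        input gene is not modified.
        """
        spec = self.spec
        if mode is None:
            mode = "premature_stop" if self.rng.random() < 0.6 else "exon_deletion"
        lo, hi = spec.pseudogene_truncation_aa
        if mode == "exon_deletion" and len(gene.exon_spans) > 2:
            k = int(self.rng.integers(1, min(3, len(gene.exon_spans) - 1)))
            spans = gene.exon_spans
            locus = gene.locus
            new_spans = spans[:k] + spans[k + 1 :]
            cds = "".join(locus[s - 1 : e] for s, e in new_spans)
            cds = cds[: len(cds) - len(cds) % 3]
            product = translate(cds)
            if product.length < 400:
                pg = SyntheticGene(
                    gene_id=gene.gene_id,
                    subfamily=gene.subfamily,
                    tps_class=gene.tps_class,
                    functional=False,
                    protein=product.residues,
                    cds=cds,
                    locus=locus,
                    exon_spans=new_spans,
                    motif_positions=gene.motif_positions,
                    target_identity=gene.target_identity,
                )
                return pg
            # deletion left a long in-frame product: fall through to stop insertion
        stop_aa = int(self.rng.integers(lo, hi + 1))
        # pick a codon fully inside one exon
        locus = list(gene.locus)
        for candidate in range(stop_aa, stop_aa + 50):
            cds_start = candidate * 3  # 0-based nt in CDS
            located = self._locate_in_locus(gene.exon_spans, cds_start)
            if located is None:
                continue
            span_idx, locus_pos = located
            s, e = gene.exon_spans[span_idx]
            if locus_pos + 2 <= e - 1:  # codon fits in this exon
                locus[locus_pos : locus_pos + 3] = list("TAA")
                new_locus = "".join(locus)
                cds = "".join(new_locus[a - 1 : b] for a, b in gene.exon_spans)
                product = translate(cds)
                return SyntheticGene(
                    gene_id=gene.gene_id,
                    subfamily=gene.subfamily,
                    tps_class=gene.tps_class,
                    functional=False,
                    protein=product.residues,
                    cds=cds,
                    locus=new_locus,
                    exon_spans=list(gene.exon_spans),
                    motif_positions=gene.motif_positions,
                    target_identity=gene.target_identity,
                )
        raise ValueError("could not place premature stop codon")

    @staticmethod
    def _locate_in_locus(
        exon_spans: Sequence[tuple[int, int]], cds_pos: int
    ) -> tuple[int, int] | None:
        """Map a 0-based CDS nt offset to (exon index, 0-based locus offset)."""
        cum = 0
        for idx, (s, e) in enumerate(exon_spans):
            exon_len = e - s + 1
            if cds_pos < cum + exon_len:
                return idx, (s - 1) + (cds_pos - cum)
            cum += exon_len
        return None


# ---------------------------------------------------------------------------
# Whole-genome assembly
# ---------------------------------------------------------------------------

#: chromosomes that receive clusters (cycled, first listed filled first) and
#: chromosomes that receive singleton genes
CLUSTER_CHROMS = ("chr4", "chr2", "chr3", "chr5", "chr7")
SINGLETON_CHROMS = ("chr4", "chr2", "chr5", "chr3", "chr7", "chr8")


def _chrom_layout(n_clusters: int, n_singletons: int) -> dict[str, tuple[int, int]]:
    """Distribute cluster and singleton counts cyclically over chromosomes."""
    layout = {c: [0, 0] for c in dict.fromkeys(CLUSTER_CHROMS + SINGLETON_CHROMS)}
    for i in range(n_clusters):
        layout[CLUSTER_CHROMS[i % len(CLUSTER_CHROMS)]][0] += 1
    for i in range(n_singletons):
        layout[SINGLETON_CHROMS[i % len(SINGLETON_CHROMS)]][1] += 1
    return {c: (v[0], v[1]) for c, v in layout.items()}


@dataclass
class SyntheticGenome:
    genome: dict[str, GenomeSequence]
    models: list[GeneModel]
    genes: dict[str, SyntheticGene]
    ground_truth: pd.DataFrame
    references: dict[str, str]
    reference_labels: dict[str, str]
    spec: FamilySpec


def assemble_genome(spec: FamilySpec) -> SyntheticGenome:
    """Generate the full synthetic genome honoring the cluster layout.

    Placed genes go to chromosomes 2/3/4/5/7/8 (chr3 all but one gene on the
    plus strand, chr7 all minus — mirroring observed strand biases);
    unplaced genes each sit on their own small "Un" scaffold. Tandem paralog
    pairs occupy adjacent slots of chosen clusters; intra-cluster boundary
    gaps are drawn below the clustering threshold and inter-unit gaps above
    it.
    """
    sim = TPSFamilySimulator(spec)
    rng = sim.rng

    # 1. roster of (subfamily, functional)
    roster: list[tuple[str, bool]] = []
    for sub in SUBFAMILIES:
        roster.extend([(sub, True)] * spec.subfamily_counts.get(sub, 0))
    weights = spec.pseudogene_subfamily_weights
    subs = list(weights)
    p = np.array([weights[s] for s in subs], dtype=float)
    p /= p.sum()
    for _ in range(spec.n_pseudogenes):
        roster.append((subs[int(rng.choice(len(subs), p=p))], False))
    order = rng.permutation(len(roster))
    roster = [roster[i] for i in order]

    n_clustered = sum(spec.cluster_sizes)
    n_placed = spec.n_genes - spec.n_unplaced
    n_singletons = n_placed - n_clustered
    if n_singletons < 0:
        raise ValueError("not enough genes for the cluster layout")

    # 2. slot assignment; reserve same-subfamily functional pairs for tandem paralogs
    clustered_slots = roster[:n_clustered]
    singleton_slots = roster[n_clustered : n_clustered + n_singletons]
    unplaced_slots = roster[n_clustered + n_singletons :]

    # 3. build genes for every slot
    def build(slotlist: list[tuple[str, bool]], prefix: str) -> list[SyntheticGene]:
        out = []
        for i, (sub, functional) in enumerate(slotlist):
            gene = sim.make_gene(sub, f"{prefix}{i:03d}")
            if not functional:
                gene = sim.truncate_to_pseudogene(gene)
            out.append(gene)
        return out

    clustered_genes = build(clustered_slots, "tmpC")
    singleton_genes = build(singleton_slots, "tmpS")
    unplaced_genes = build(unplaced_slots, "tmpU")

    # 4. carve clusters and plant tandem paralog pairs in the first suitable ones
    clusters: list[list[SyntheticGene]] = []
    cursor = 0
    for size in spec.cluster_sizes:
        clusters.append(clustered_genes[cursor : cursor + size])
        cursor += size
    paralog_links: list[tuple[SyntheticGene, SyntheticGene]] = []  # (source, copy)
    for cluster in clusters:
        if len(paralog_links) >= spec.n_tandem_paralog_pairs:
            break
        for i in range(len(cluster) - 1):
            a, b = cluster[i], cluster[i + 1]
            if a.functional and b.functional and a.subfamily == b.subfamily:
                copy = sim.mutate_to_identity(a, spec.tandem_paralog_identity, b.gene_id)
                cluster[i + 1] = copy
                paralog_links.append((a, copy))
                break

    # 5. cross-chromosome paralog pairs among singletons
    planted_cross = 0
    func_singles = [i for i, g in enumerate(singleton_genes) if g.functional and g.paralog_partner is None]
    for a_idx, b_idx in zip(func_singles[0::2], func_singles[1::2]):
        if planted_cross >= spec.n_cross_paralog_pairs:
            break
        src = singleton_genes[a_idx]
        if singleton_genes[b_idx].subfamily != src.subfamily:
            continue
        copy = sim.mutate_to_identity(
            src, spec.cross_paralog_identity, singleton_genes[b_idx].gene_id
        )
        singleton_genes[b_idx] = copy
        paralog_links.append((src, copy))
        planted_cross += 1

    # 6. lay genes on chromosomes
    genome: dict[str, GenomeSequence] = {}
    models: list[GeneModel] = []
    genes: dict[str, SyntheticGene] = {}
    cluster_iter = iter(clusters)
    singleton_iter = iter(singleton_genes)
    cluster_counter = 0
    for chrom, (n_clu, n_sing) in _chrom_layout(len(clusters), len(singleton_genes)).items():
        units: list[tuple[str, list[SyntheticGene]]] = []
        for _ in range(n_clu):
            cluster_counter += 1
            units.append((f"cluster_{cluster_counter:02d}", next(cluster_iter)))
        for _ in range(n_sing):
            units.append((None, [next(singleton_iter)]))
        seq_parts: list[str] = []
        pos = 0
        gene_number = 0
        lead = int(rng.integers(10_000, 30_000))
        seq_parts.append(_random_dna(rng, lead))
        pos += lead
        for cluster_id, members in units:
            for j, gene in enumerate(members):
                gene_number += 10
                gene_id = f"Cs{chrom[3:]}g{gene_number:05d}"
                strand = _choose_strand(rng, chrom)
                placed = _place_gene(gene, gene_id, chrom, strand, pos, cluster_id)
                genes[gene_id] = placed[0]
                models.append(placed[1])
                seq_parts.append(placed[2])
                pos += len(placed[2])
                if j < len(members) - 1:
                    gap = int(rng.integers(*spec.intra_cluster_gap_nt))
                    seq_parts.append(_random_dna(rng, gap))
                    pos += gap
            gap = int(rng.integers(*spec.inter_cluster_gap_nt))
            seq_parts.append(_random_dna(rng, gap))
            pos += gap
        genome[chrom] = GenomeSequence(chrom, "".join(seq_parts))

    # chr3 strand rule: all but one gene on '+' — enforced in _choose_strand via rng,
    # so instead rewrite deterministically here
    _apply_strand_biases(models, genes, genome, rng)

    # 7. unplaced scaffolds, one gene each
    for i, gene in enumerate(unplaced_genes):
        chrom = f"Un{i + 1:02d}"
        gene_id = f"orange1.1t{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lead = int(rng.integers(2_000, 8_000))
        tail = int(rng.integers(2_000, 8_000))
        placed = _place_gene(gene, gene_id, chrom, strand, lead, None)
        scaffold = _random_dna(rng, lead) + placed[2] + _random_dna(rng, tail)
        genes[gene_id] = placed[0]
        models.append(placed[1])
        genome[chrom] = GenomeSequence(chrom, scaffold)

    # paralog partner ids are only final after placement renames genes
    for src, copy in paralog_links:
        copy.paralog_partner = src.gene_id
        src.paralog_partner = copy.gene_id
        src.paralog_identity = copy.paralog_identity = copy.target_identity

    # 8. references
    references: dict[str, str] = {}
    reference_labels: dict[str, str] = {}
    for sub in SUBFAMILIES:
        for i in range(spec.n_references_per_subfamily):
            rid = f"REF_{sub.replace('tps-', '').upper()}_{i + 1}"
            references[rid] = sim._mutate_protein(
                sim.ancestors[sub], sub, spec.reference_identity
            )
            reference_labels[rid] = sub

    truth = _ground_truth_table(genes)
    return SyntheticGenome(
        genome=genome,
        models=models,
        genes=genes,
        ground_truth=truth,
        references=references,
        reference_labels=reference_labels,
        spec=spec,
    )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _choose_strand(rng: np.random.Generator, chrom: str) -> str:
    if chrom == "chr7":
        return "-"
    if chrom == "chr3":
        return "+"
    return "+" if rng.random() < 0.5 else "-"


def _apply_strand_biases(models, genes, genome, rng) -> None:
    """chr3 carries exactly one minus-strand gene (strand bias flavor)."""
    chr3_models = [m for m in models if m.chrom_id == "chr3"]
    if len(chr3_models) > 1:
        flip = chr3_models[int(rng.integers(0, len(chr3_models)))]
        _flip_strand_in_place(flip, genes[flip.gene_id], genome)


def _flip_strand_in_place(model: GeneModel, gene: SyntheticGene, genome) -> None:
    """Reverse-complement a gene's locus region on its chromosome."""
    chrom = genome[model.chrom_id]
    start, end = model.start, model.end
    seq = chrom.sequence
    locus = seq[start - 1 : end]
    flipped = reverse_complement(locus)
    genome[model.chrom_id] = GenomeSequence(chrom.chrom_id, seq[: start - 1] + flipped + seq[end:])
    length = end - start + 1
    new_exons = [
        (start + (length - (e - start + 1)), start + (length - (s - start + 1)))
        for s, e in model.exons
    ]
    model.exons = sorted(new_exons)
    model.strand = "-" if model.strand == "+" else "+"
    gene.strand = model.strand


def _place_gene(
    gene: SyntheticGene,
    gene_id: str,
    chrom: str,
    strand: str,
    offset: int,
    cluster_id: str | None,
) -> tuple[SyntheticGene, GeneModel, str]:
    """Anchor a gene at ``offset`` (0-based) on a chromosome; returns its locus seq."""
    locus = gene.locus
    spans = gene.exon_spans
    if strand == "-":
        locus = reverse_complement(locus)
        L = len(locus)
        spans = sorted((L - e + 1, L - s + 1) for s, e in spans)
    exons = [(offset + s, offset + e) for s, e in spans]
    gene.gene_id = gene_id
    gene.chrom = chrom
    gene.strand = strand
    gene.cluster_id = cluster_id
    model = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.1",
        chrom_id=chrom,
        strand=strand,
        exons=exons,
        biotype="putative_functional" if gene.functional else "pseudogene",
    )
    return gene, model, locus


def _ground_truth_table(genes: Mapping[str, SyntheticGene]) -> pd.DataFrame:
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        rows.append(
            {
                "gene_id": gid,
                "subfamily": g.subfamily,
                "tps_class": g.tps_class,
                "functional": g.functional,
                "protein_length": len(g.protein),
                "chrom": g.chrom,
                "strand": g.strand,
                "cluster_id": g.cluster_id or "",
                "paralog_partner": g.paralog_partner or "",
                "paralog_identity": g.paralog_identity if g.paralog_identity is not None else "",
                "motif_positions": ";".join(
                    f"{k}:{v}" for k, v in sorted(g.motif_positions.items())
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    gene_ids: Sequence[str], spec: FamilySpec, seed_offset: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM matrix with planted tissue-specific, high- and low-expression genes.

    Baseline genes draw each tissue from a clipped log-normal (heavy-tailed,
    like real RPKM) kept within the "moderate" band and detected in all
    tissues; planted tissue-specific genes exceed the 0.5 RPKM detection
    threshold in exactly one tissue; planted high genes reach >= 60 RPKM in
    at least one tissue; planted low genes stay at or below 0.5 everywhere.
    Returns (matrix, ground truth table).
    """
    spec_counts = spec.tissue_specific_counts
    tissues = list(spec.tissues)
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(spec.seed + seed_offset)
    ids = list(gene_ids)
    n_special = sum(spec_counts.values()) + spec.n_high_expression + spec.n_low_expression
    if n_special > len(ids):
        raise ValueError("more planted genes than genes available")
    chosen = list(rng.choice(len(ids), size=n_special, replace=False))
    it = iter(chosen)
    specific: dict[str, str] = {}
    for tissue, count in spec_counts.items():
        for _ in range(count):
            specific[ids[next(it)]] = tissue
    high = {ids[next(it)] for _ in range(spec.n_high_expression)}
    low = {ids[next(it)] for _ in range(spec.n_low_expression)}

    mu, sigma = spec.expression_lognormal
    rows = []
    truth_rows = []
    for gid in ids:
        if gid in specific:
            tissue = specific[gid]
            vals = {t: float(rng.uniform(0.0, 0.4)) for t in tissues}
            vals[tissue] = float(rng.uniform(5.0, 80.0))
            label = f"specific:{tissue}"
        elif gid in high:
            vals = {t: float(np.clip(rng.lognormal(mu, sigma), 0.6, 59.0)) for t in tissues}
            vals[tissues[int(rng.integers(0, len(tissues)))]] = float(rng.uniform(60.0, 200.0))
            label = "high"
        elif gid in low:
            vals = {t: float(rng.uniform(0.0, 0.4)) for t in tissues}
            label = "low"
        else:
            vals = {t: float(np.clip(rng.lognormal(mu, sigma), 0.6, 59.0)) for t in tissues}
            label = "baseline"
        rows.append({"gene_id": gid, **vals})
        truth_rows.append({"gene_id": gid, "expression_label": label})
    matrix = pd.DataFrame(rows).set_index("gene_id")
    truth = pd.DataFrame(truth_rows)
    return matrix, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_genome_bundle(result: SyntheticGenome, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/GFF3/reference/truth/expression files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "references": outdir / "references.fasta",
        "reference_labels": outdir / "reference_labels.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "expression": outdir / "expression.tsv",
        "expression_truth": outdir / "expression_truth.tsv",
        "spec": outdir / "family_spec.yaml",
    }
    ordered = {c: result.genome[c].sequence for c in sorted(result.genome)}
    write_fasta(ordered, paths["genome"])
    write_gff3(result.models, paths["gff3"], seq_lengths={c: len(s) for c, s in ordered.items()})
    write_fasta(result.references, paths["references"])
    pd.Series(result.reference_labels, name="subfamily").rename_axis("reference").to_csv(
        paths["reference_labels"], sep="\t"
    )
    result.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    functional_ids = sorted(
        result.ground_truth[result.ground_truth["functional"]]["gene_id"]
    )
    matrix, truth = simulate_expression(functional_ids, result.spec)
    matrix.to_csv(paths["expression"], sep="\t", float_format="%.4f")
    truth.to_csv(paths["expression_truth"], sep="\t", index=False)
    result.spec.to_yaml(paths["spec"])
    return paths
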