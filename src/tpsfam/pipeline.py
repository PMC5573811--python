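"""End-to-end TPS family characterization pipeline.

Stages, in order: load genome + gene models → assemble and translate coding
sequences → gate TPS candidates against a reference protein set → split
candidates into putative-functional (>= 400 aa) and pseudogenes →
exon/intron architecture and splice consensus → motif completeness →
physicochemical properties → tandem clusters and chromosome distribution →
identity matrix and paralog pairs → progressive MSA, NJ tree with bootstrap,
reference-anchored subfamily assignment → expression summaries.

Every stage writes its table under the output directory; a failure halts the
run naming the stage, with earlier outputs retained. Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import consensus_to_tsv, gene_architecture, splice_consensus
from .clusters import clusters_to_bed, detect_clusters, distribution_summary, membership_table
from .expression import category_table, read_expression_tsv, tissue_specificity_table
from .genome_io import ProteinRecord, extract_cds, read_fasta, read_gff3, read_protein_fasta, translate
from .homology import find_paralog_pairs, identity_matrix, reference_search
from .motifs import (
    compile_library,
    default_required_patterns,
    hits_table,
    load_motif_library,
    motif_completeness,
)
from .phylogeny import assign_subfamily, bootstrap_supports, progressive_msa
from .protein_props import protein_properties


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genome_fasta: str
    gff3: str
    reference_fasta: str
    outdir: str
    seed: int
    reference_labels: str | None = None
    expression_tsv: str | None = None
    motif_library: str | None = None
    min_protein_len: int = 400
    cluster_gap: int = 67_000
    paralog_identity: float = 94.0
    bootstrap_reps: int = 1000
    min_candidate_identity: float = 40.0
    min_candidate_coverage: float = 0.5
    detect_threshold: float = 0.5
    unplaced_prefix: str = "Un"
    splice_flank_nt: int = 10

    def validate(self) -> None:
        for name in ("genome_fasta", "gff3", "reference_fasta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file {p!r}")
        for name in ("reference_labels", "expression_tsv", "motif_library"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file {p!r}")
        for name in ("min_protein_len", "cluster_gap", "bootstrap_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config.{name} must be positive")
        if self.seed is None:
            raise ValueError("config.seed must be set")

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: PipelineConfig
    summary: dict
    dispositions: pd.DataFrame
    subfamily_counts: dict
    class_counts: dict
    outdir: Path
    tree_newick: str | None = None
    log: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str):
        log.append({"stage": name, "t": time.time()})

    def fail(name: str, exc: Exception):
        raise PipelineError(name, exc) from exc

    # ---------------- load ----------------
    stage("load")
    try:
        genome = read_fasta(config.genome_fasta)
        models = read_gff3(config.gff3, genome=genome)
        references = read_protein_fasta(config.reference_fasta)
        ref_labels: dict[str, str] = {}
        if config.reference_labels:
            lab = pd.read_csv(config.reference_labels, sep="\t", index_col=0)
            ref_labels = lab.iloc[:, 0].to_dict()
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("load", exc)

    # ---------------- translate ----------------
    stage("translate")
    try:
        proteins: dict[str, ProteinRecord] = {}
        model_by_gene = {}
        for m in models:
            tr = extract_cds(m, genome)
            cds = tr.cds[: len(tr.cds) - len(tr.cds) % 3]
            prot = translate(cds, m.gene_id)
            proteins[m.gene_id] = prot
            model_by_gene[m.gene_id] = m
        with open(outdir / "proteins.fasta", "w") as fh:
            for gid in sorted(proteins):
                fh.write(f">{gid}\n{proteins[gid].residues}\n")
    except Exception as exc:
        fail("translate", exc)

    # ---------------- candidate gating ----------------
    stage("candidates")
    try:
        disposition: dict[str, str] = {}
        best_ref: dict[str, str] = {}
        for gid in sorted(proteins):
            prot = proteins[gid]
            if not prot.residues:
                disposition[gid] = "non_tps"
                continue
            hits = reference_search(prot, references, min_identity=config.min_candidate_identity)
            hits = hits[hits["coverage"] >= config.min_candidate_coverage]
            if hits.empty:
                disposition[gid] = "non_tps"
            else:
                best_ref[gid] = str(hits.iloc[0]["reference"])
                disposition[gid] = (
                    "functional"
                    if prot.length >= config.min_protein_len
                    else "pseudogene"
                )
        disp = pd.DataFrame(
            {
                "gene_id": sorted(proteins),
                "disposition": [disposition[g] for g in sorted(proteins)],
                "length_aa": [proteins[g].length for g in sorted(proteins)],
                "placed": [
                    not model_by_gene[g].chrom_id.startswith(config.unplaced_prefix)
                    for g in sorted(proteins)
                ],
                "best_reference": [best_ref.get(g, "") for g in sorted(proteins)],
            }
        )
        disp.to_csv(outdir / "dispositions.tsv", sep="\t", index=False)
        tps_genes = [g for g in sorted(proteins) if disposition[g] != "non_tps"]
        functional = [g for g in tps_genes if disposition[g] == "functional"]
    except Exception as exc:
        fail("candidates", exc)

    # ---------------- architecture ----------------
    stage("architecture")
    try:
        archs = {g: gene_architecture(model_by_gene[g]) for g in tps_genes}
        arch_rows = [
            {
                "gene_id": g,
                "n_introns": a.n_introns,
                "tps_class": a.tps_class,
                "intron_phases": ",".join(map(str, a.intron_phases)),
                "exon_lengths_aa": ",".join(map(str, a.exon_lengths_aa)),
                "intron_lengths_nt": ",".join(map(str, a.intron_lengths_nt)),
            }
            for g, a in archs.items()
        ]
        pd.DataFrame(arch_rows).to_csv(outdir / "architecture.tsv", sep="\t", index=False)
        class_counts = (
            pd.Series([archs[g].tps_class for g in functional]).value_counts().to_dict()
        )
        func_models = [model_by_gene[g] for g in functional if model_by_gene[g].n_introns > 0]
        cons = splice_consensus(func_models, genome, flank_nt=config.splice_flank_nt)
        consensus_to_tsv(cons, outdir / "splice_donor.tsv", outdir / "splice_acceptor.tsv")
    except Exception as exc:
        fail("architecture", exc)

    # ---------------- motifs ----------------
    stage("motifs")
    try:
        if config.motif_library:
            required = compile_library(load_motif_library(config.motif_library), "generic")
        else:
            required = default_required_patterns()
        comp_rows = []
        for g in functional:
            comp = motif_completeness(proteins[g], required)
            comp_rows.append(
                {
                    "gene_id": g,
                    **{f"has_{k.replace('/', '_')}": v for k, v in comp.presence.items()},
                    "complete": comp.complete,
                    "canonical_order": comp.in_canonical_order,
                }
            )
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(outdir / "motif_completeness.tsv", sep="\t", index=False)
        hits = hits_table([proteins[g] for g in functional], required)
        hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("motifs", exc)

    # ---------------- properties ----------------
    stage("properties")
    try:
        prop_rows = []
        for g in functional:
            p = protein_properties(proteins[g])
            prop_rows.append(
                {
                    "protein_id": g,
                    "length_aa": p.length_aa,
                    "mw_kda": p.mw_kda,
                    "pi": p.pi,
                    "functional": p.putative_functional,
                    "transit_peptide": p.transit_peptide,
                    "tps_type_hint": p.tps_type_hint,
                }
            )
        pd.DataFrame(prop_rows).to_csv(
            outdir / "properties.tsv", sep="\t", index=False, float_format="%.2f"
        )
    except Exception as exc:
        fail("properties", exc)

    # ---------------- clusters ----------------
    stage("clusters")
    try:
        unplaced_chroms = {
            c for c in genome if c.startswith(config.unplaced_prefix)
        }
        tps_models = [model_by_gene[g] for g in tps_genes]
        clus = detect_clusters(tps_models, config.cluster_gap, unplaced_chroms=unplaced_chroms)
        clusters_to_bed(clus, outdir / "clusters.bed")
        membership_table(clus).to_csv(outdir / "cluster_members.tsv", sep="\t", index=False)
        distribution = distribution_summary(tps_models, clus, unplaced_chroms=unplaced_chroms)
        (outdir / "distribution.json").write_text(json.dumps(distribution, indent=2, sort_keys=True))
    except Exception as exc:
        fail("clusters", exc)

    # ---------------- identity / paralogs ----------------
    stage("homology")
    try:
        func_prots = {g: proteins[g].residues for g in functional}
        idm = identity_matrix(func_prots)
        idm.to_csv(outdir / "identity_matrix.tsv", sep="\t")
        positions = {
            g: (model_by_gene[g].chrom_id, model_by_gene[g].start, model_by_gene[g].end)
            for g in functional
        }
        paralogs = find_paralog_pairs(idm, positions, identity_threshold=config.paralog_identity)
        paralogs.to_csv(outdir / "paralogs.tsv", sep="\t", index=False)
    except Exception as exc:
        fail("homology", exc)

    # ---------------- phylogeny ----------------
    stage("phylogeny")
    try:
        seqs = dict(func_prots)
        for rid, rec in references.items():
            seqs[rid] = rec.residues
        tree_newick = None
        subfam: dict[str, str] = {}
        if len(seqs) >= 4:
            msa = progressive_msa(seqs)
            msa.write_fasta(outdir / "alignment.fasta")
            tree = bootstrap_supports(msa, n_reps=config.bootstrap_reps, seed=config.seed)
            tree_newick = tree.to_newick(outdir / "tree.nwk")
            if ref_labels:
                subfam = assign_subfamily(tree, ref_labels)
        sub_df = pd.DataFrame(
            {"gene_id": functional, "subfamily": [subfam.get(g, "unassigned") for g in functional]}
        )
        sub_df.to_csv(outdir / "subfamilies.tsv", sep="\t", index=False)
        subfamily_counts = sub_df["subfamily"].value_counts().to_dict()
    except Exception as exc:
        fail("phylogeny", exc)

    # ---------------- expression ----------------
    stage("expression")
    try:
        expression_summary = {}
        if config.expression_tsv:
            matrix = read_expression_tsv(config.expression_tsv)
            category_table(matrix).to_csv(outdir / "expression_categories.tsv", sep="\t")
            specificity = tissue_specificity_table(matrix, config.detect_threshold)
            specificity.to_csv(outdir / "tissue_specificity.tsv", sep="\t")
            calls = specificity.dropna()
            expression_summary = {
                "n_genes": int(len(matrix)),
                "tissue_specific_counts": calls.value_counts().to_dict(),
                "n_all_low": int((matrix.le(0.5).all(axis=1)).sum()),
                "n_any_high": int((matrix.ge(60.0).any(axis=1)).sum()),
            }
    except Exception as exc:
        fail("expression", exc)

    # ---------------- summary ----------------
    stage("summary")
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_genes": len(proteins),
        "n_tps_genes": len(tps_genes),
        "n_functional": len(functional),
        "n_pseudogenes": int((disp["disposition"] == "pseudogene").sum()),
        "n_non_tps": int((disp["disposition"] == "non_tps").sum()),
        "n_unplaced": int((~disp["placed"]).sum()),
        "class_counts": class_counts,
        "subfamily_counts": subfamily_counts,
        "n_motif_complete": int(comp_df["complete"].sum()) if len(comp_df) else 0,
        "n_clusters": distribution["n_clusters"],
        "n_clustered_genes": distribution["n_clustered_genes"],
        "percent_clustered": distribution["percent_clustered"],
        "percent_clustered_of_all": distribution["percent_clustered_of_all"],
        "mean_identity": idm.attrs.get("mean_identity"),
        "n_paralog_pairs": int(len(paralogs)),
        "expression": expression_summary,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [entry["stage"] for entry in log],
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))

    return PipelineResult(
        config=config,
        summary=summary,
        dispositions=disp,
        subfamily_counts=subfamily_counts,
        class_counts=class_counts,
        outdir=outdir,
        tree_newick=tree_newick,
        log=log,
    )
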