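"""Tandem gene-cluster detection and chromosome/strand distribution summaries.

Gene-family expansions leave tandem arrays on the chromosome; here genes are
chained into a cluster (single linkage per chromosome, strand ignored) when
the gap between nearest boundaries of consecutive genes is strictly below a
threshold, 67 kb by default. Singletons are not clusters. Genes on unplaced
scaffolds are excluded from chaining and counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Sequence

import pandas as pd

from .genome_io import GeneModel

DEFAULT_MAX_GAP_NT = 67_000


@dataclass
class GeneCluster:
    cluster_id: str
    chrom_id: str
    members: list[str]  # gene ids ordered by genomic position
    start: int
    end: int

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def size(self) -> int:
        return len(self.members)


def detect_clusters(
    models: Iterable[GeneModel],
    max_gap_nt: int = DEFAULT_MAX_GAP_NT,
    unplaced_chroms: Collection[str] = (),
) -> list[GeneCluster]:
    """Single-linkage chaining of genes whose boundary gap is < ``max_gap_nt``.

    gap = next gene's start - running cluster end - 1 (overlaps count as
    gap 0 and join, with a warning). Output order is (chrom, start) and is
    invariant to input order.
    """
    placed = [m for m in models if m.chrom_id not in set(unplaced_chroms)]
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in placed:
        by_chrom.setdefault(m.chrom_id, []).append(m)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.gene_id))
        run: list[GeneModel] = [genes[0]]
        run_end = genes[0].end
        for g in genes[1:]:
            gap = g.start - run_end - 1
            if gap < 0:
                warnings.warn(f"overlapping genes {run[-1].gene_id}/{g.gene_id}, gap treated as 0")
                gap = 0
            if gap < max_gap_nt:
                run.append(g)
                run_end = max(run_end, g.end)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run, len(clusters)))
                run = [g]
                run_end = g.end
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run, len(clusters)))
    return clusters


def _make_cluster(chrom: str, run: list[GeneModel], index: int) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster_{index + 1:02d}",
        chrom_id=chrom,
        members=[g.gene_id for g in run],
        start=min(g.start for g in run),
        end=max(g.end for g in run),
    )


def distribution_summary(
    models: Iterable[GeneModel],
    clusters: Sequence[GeneCluster],
    unplaced_chroms: Collection[str] = (),
) -> dict:
    """Per-chromosome and per-strand counts plus the clustered percentage.

    percent_clustered = clustered members / genes considered (placed genes),
    to 2 decimals. Unplaced genes are counted but not in the denominator's
    cluster census.
    """
    models = list(models)
    unplaced_set = set(unplaced_chroms)
    placed = [m for m in models if m.chrom_id not in unplaced_set]
    unplaced = [m for m in models if m.chrom_id in unplaced_set]
    clustered_ids = {gid for c in clusters for gid in c.members}
    per_chrom = (
        pd.Series([m.chrom_id for m in placed]).value_counts().sort_index()
        if placed
        else pd.Series(dtype=int)
    )
    per_strand = {
        chrom: {
            "+": sum(1 for m in placed if m.chrom_id == chrom and m.strand == "+"),
            "-": sum(1 for m in placed if m.chrom_id == chrom and m.strand == "-"),
        }
        for chrom in per_chrom.index
    }
    n_considered = len(placed)
    n_clustered = sum(1 for m in placed if m.gene_id in clustered_ids)
    return {
        "n_genes": len(models),
        "n_placed": n_considered,
        "n_unplaced": len(unplaced),
        "n_clusters": len(clusters),
        "n_clustered_genes": n_clustered,
        "percent_clustered": round(100.0 * n_clustered / n_considered, 2)
        if n_considered
        else 0.0,
        # same numerator over all genes incl. unplaced, the other published convention
        "percent_clustered_of_all": round(100.0 * n_clustered / len(models), 2)
        if models
        else 0.0,
        "genes_per_chromosome": per_chrom.to_dict(),
        "strand_per_chromosome": per_strand,
        "cluster_sizes": sorted((c.size for c in clusters), reverse=True),
    }


def clusters_to_bed(clusters: Sequence[GeneCluster], path: str | Path) -> None:
    """BED (0-based half-open) rows: chrom, start, end, cluster_id, member count."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom_id}\t{c.start - 1}\t{c.end}\t{c.cluster_id}\t{c.size}\n")


def membership_table(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = [
        {"cluster_id": c.cluster_id, "chrom": c.chrom_id, "gene_id": gid, "position": i + 1}
        for c in clusters
        for i, gid in enumerate(c.members)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "chrom", "gene_id", "position"])
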