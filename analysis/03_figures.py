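"""Figures for the characterized family.

Renders (a) donor/acceptor splice-site logos from the pipeline's consensus
tables, (b) the per-position exon-length distribution of the functional
class III genes, and (c) the clustered log2(RPKM+1) expression heatmap,
under results/figures/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from tpsfam.expression import heatmap_matrix, read_expression_tsv

PIPE = REPO / "results" / "pipeline"
FIG = REPO / "results" / "figures"

BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def splice_logo(table_path: Path, title: str, out_path: Path) -> None:
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    for x, (pos, row) in enumerate(df.iterrows()):
        heights = sorted(
            ((row[b] * row["bits"], b) for b in "ACGT"), key=lambda t: t[0]
        )
        y = 0.0
        for h, base in heights:
            if h <= 0:
                continue
            ax.text(x, y, base, fontsize=6 + 22 * h / 2, color=BASE_COLORS[base],
                    ha="center", va="bottom", fontweight="bold")
            y += h
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df.index, fontsize=7)
    ax.set_ylim(0, 2.05)
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def exon_length_figure(out_path: Path) -> None:
    arch = pd.read_csv(PIPE / "architecture.tsv", sep="\t")
    class_iii = arch[arch["tps_class"] == "III"]
    lengths = [
        [int(x) for x in row.split(",")] for row in class_iii["exon_lengths_aa"]
    ]
    n_exons = max(len(l) for l in lengths)
    per_position = [
        [l[i] for l in lengths if len(l) > i] for i in range(n_exons)
    ]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.boxplot(per_position, tick_labels=[str(i + 1) for i in range(n_exons)])
    ax.set_xlabel("exon position")
    ax.set_ylabel("exon length (aa)")
    ax.set_title("Class III exon lengths")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def expression_heatmap(out_path: Path) -> None:
    matrix = read_expression_tsv(REPO / "results" / "synthetic" / "expression.tsv")
    transformed, order = heatmap_matrix(matrix)
    fig, ax = plt.subplots(figsize=(4, 8))
    im = ax.imshow(transformed.to_numpy(), aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(transformed.columns)))
    ax.set_xticklabels(transformed.columns, fontsize=8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=4)
    fig.colorbar(im, label="log2(RPKM+1)")
    ax.set_title("Expression")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def main() -> None:
    if not (PIPE / "splice_donor.tsv").exists():
        sys.exit("run analysis/02_characterize_family.py first")
    FIG.mkdir(parents=True, exist_ok=True)
    splice_logo(PIPE / "splice_donor.tsv", "Donor (exon | intron)", FIG / "donor_logo.png")
    splice_logo(PIPE / "splice_acceptor.tsv", "Acceptor (intron | exon)", FIG / "acceptor_logo.png")
    exon_length_figure(FIG / "exon_lengths.png")
    expression_heatmap(FIG / "expression_heatmap.png")
    for f in sorted(FIG.glob("*.png")):
        print("wrote", f.relative_to(REPO))


if __name__ == "__main__":
    main()
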