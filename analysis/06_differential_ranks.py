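"""Differential expression between assigned clones and signed rank output.

Takes the scRNA cells assigned by 03_assign_rna_clones.py, runs the
two-sided Wilcoxon rank-sum test between clones on log-normalized
expression (|logFC| >= 0.10), adjusts with Benjamini-Hochberg, and writes
both the DE table and the -log10(FDR) x sign(logFC) ranking as an RNK file
ready for pre-ranked enrichment tools. Dosage genes on the discriminating
arms should dominate both tails.
"""

import sys
from pathlib import Path

import pandas as pd

from occultclone import diffrank as dr
from occultclone import io_formats as io
from occultclone.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    counts = io.read_counts_mtx(DATA / "rna_matrix.mtx", DATA / "rna_features.tsv",
                                DATA / "rna_barcodes.tsv")
    calls = pd.read_csv(OUT / "rna_clone_assignments.tsv", sep="\t").set_index("barcode")
    labels = calls.loc[counts.barcodes, "clone"].to_numpy(object)
    keep = labels != "unassigned"
    cm = counts.subset_cells(keep)
    labels = labels[keep]
    groups = sorted(set(labels))
    print(f"DE between clones {groups[0]} and {groups[1]} "
          f"({(labels == groups[0]).sum()} vs {(labels == groups[1]).sum()} cells)")

    de = dr.wilcoxon_de(cm, labels, groups[0], groups[1], min_lfc=cfg.min_lfc)
    de.to_csv(OUT / "de_clone_markers.tsv", sep="\t", index=False)
    ranked = dr.rank_statistic(de, cap=cfg.rank_cap)
    dr.write_rnk(ranked, OUT / "clone_markers.rnk")
    n_sig = int((de.fdr < 0.05).sum())
    print(f"{len(de)} genes pass |logFC| >= {cfg.min_lfc}; {n_sig} at FDR < 0.05")
    print("top upregulated:", ", ".join(ranked.gene.head(3)))
    print("top downregulated:", ", ".join(ranked.gene.tail(3)[::-1]))
    print("ranking written to results/clone_markers.rnk")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
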