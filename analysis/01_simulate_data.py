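"""Generate the synthetic study datasets with known ground truth.

Emits, under results/data/: a 3-clone scCNV dataset (segment calls, mappable
regions, per-cell QC) at 5% segment noise with 5% noisy cells; a matched
2-clone scRNA count set under the gene-dosage model; and a 4-sample count
set with the planted hierarchy ((MP2-A, MP2-B), (Panc1-2D, Panc1-3D)).
Ground-truth labels are written alongside for the downstream drivers.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from occultclone import io_formats as io
from occultclone import synthetic_data as sd
from occultclone.config import PipelineConfig
from occultclone.genome import toy_arms

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    arm_table = toy_arms(n_chrom=4)

    # --- scCNV: three subclones at 0.5 / 0.3 / 0.2 on a triploid background
    st3 = sd.simulate_clonal_structure(
        3, base_ploidy=3, events_per_clone=2, seed=cfg.child_seed("simulate"),
        arm_table=arm_table, clone_frequencies=[0.5, 0.3, 0.2],
    )
    seg, regions, qc, truth = sd.simulate_cnv_cells(
        st3, n_cells=500, segment_noise_rate=0.05, noisy_fraction=0.05,
        seed=cfg.child_seed("simulate") + 1,
    )
    io.write_segment_calls(seg, OUT / "node_cnv_calls.bed")
    io.write_mappable_regions(regions, OUT / "mappable_regions.bed")
    io.write_cell_qc(qc, OUT / "per_cell_summary_metrics.csv")
    st3.arm_cn.to_csv(OUT / "truth_clone_arm_cn.tsv", sep="\t")
    pd.DataFrame({"cell_id": np.arange(500), "clone": truth.clone_labels}).to_csv(
        OUT / "truth_cnv_clone_labels.csv", index=False
    )
    print(f"scCNV: 500 cells, {len(regions)} mappable regions, "
          f"{qc.is_noisy.sum()} noisy cells flagged")
    print("planted clone arm CN:")
    print(st3.arm_cn.to_string())

    # --- scRNA under the dosage model, from a 2-clone structure
    st2 = sd.simulate_clonal_structure(
        2, base_ploidy=3, events_per_clone=2, seed=cfg.child_seed("simulate") + 2,
        arm_table=arm_table,
    )
    genes = sd.genes_for_arms(arm_table, genes_per_arm=100)
    genes.to_csv(OUT / "gene_annotation.tsv", sep="\t", index=False)
    counts, rna_truth = sd.simulate_rna_counts(
        st2, genes, n_cells=1000, depth_per_cell=5000,
        seed=cfg.child_seed("simulate") + 3,
    )
    io.write_counts_mtx(counts, OUT / "rna_matrix.mtx", OUT / "rna_features.tsv",
                        OUT / "rna_barcodes.tsv")
    seg2, regions2, qc2, _ = sd.simulate_cnv_cells(
        st2, n_cells=300, seed=cfg.child_seed("simulate") + 4
    )
    io.write_segment_calls(seg2, OUT / "node_cnv_calls_2clone.bed")
    io.write_mappable_regions(regions2, OUT / "mappable_regions_2clone.bed")
    io.write_cell_qc(qc2, OUT / "per_cell_summary_metrics_2clone.csv")
    pd.DataFrame({"barcode": counts.barcodes, "clone": rna_truth.clone_labels}).to_csv(
        OUT / "truth_rna_clone_labels.csv", index=False
    )
    print(f"scRNA: 1000 cells x {len(genes)} genes at depth 5000 "
          f"(dosage-coupled on copy-variant arms)")

    # --- multi-sample set with planted hierarchy
    tree = (("MP2-A", "MP2-B"), ("Panc1-2D", "Panc1-3D"))
    samples, _ = sd.simulate_sample_set(
        tree, cells_per_sample=300, n_genes=400, seed=cfg.child_seed("phenodist")
    )
    for name, cm in samples.items():
        io.write_counts_mtx(cm, OUT / f"sample_{name}.mtx",
                            OUT / f"sample_{name}_features.tsv",
                            OUT / f"sample_{name}_barcodes.tsv")
    (OUT / "truth_sample_tree.txt").write_text(repr(tree) + "\n")
    print(f"samples: {list(samples)} at 300 cells each, planted tree {tree}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
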