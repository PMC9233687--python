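"""End-to-end orchestration of the synthetic study.

``run_pipeline`` wires the stages together — simulate, scCNV clone
calling, pseudo-bulk profiling, gene-locus statistics, dosage-based clone
assignment, phenotypic distances, subtype scoring, and differential
expression with signed ranks — on generator output with known ground
truth. Every output table carries the config hash and seed in its header;
identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clone_assignment, cnv_clones, diffrank, phenodist, subtype, synthetic_data
from .config import PipelineConfig
from .genome import toy_arms

log = logging.getLogger("occultclone")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages: set[str] | None = None,
    n_cnv_cells: int = 500,
    n_rna_cells: int = 1000,
    rna_depth: int = 5000,
    sample_tree=(("MP2-A", "MP2-B"), ("Panc1-2D", "Panc1-3D")),
    cells_per_sample: int = 300,
) -> dict:
    """Run the synthetic study end to end; returns a result bundle.

    ``stages`` restricts execution (downstream stages needing a disabled
    stage's products refuse to run). Outputs land under ``out_dir``.
    """
    all_stages = {"simulate", "cnv", "assign", "phenodist", "subtype", "diffrank"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    if "simulate" not in stages and stages & {"cnv", "assign"}:
        raise ValueError("cnv/assign stages require the simulate stage")

    arm_table = toy_arms(n_chrom=4)
    if "simulate" in stages:
        structure = synthetic_data.simulate_clonal_structure(
            n_clones=3, base_ploidy=3, events_per_clone=2,
            seed=config.child_seed("simulate"), arm_table=arm_table,
            clone_frequencies=[0.5, 0.3, 0.2],
        )
        seg, regions, qc, cnv_truth = synthetic_data.simulate_cnv_cells(
            structure, n_cells=n_cnv_cells, segment_noise_rate=0.05,
            noisy_fraction=0.05, seed=config.child_seed("simulate") + 1,
        )
        genes = synthetic_data.genes_for_arms(arm_table)
        counts, rna_truth = synthetic_data.simulate_rna_counts(
            structure, genes, n_cells=n_rna_cells, depth_per_cell=rna_depth,
            seed=config.child_seed("simulate") + 2,
        )
        bundle.update(
            structure=structure, segments=seg, regions=regions, qc=qc,
            cnv_truth=cnv_truth, genes=genes, counts=counts, rna_truth=rna_truth,
        )
        log.info("simulate: %d CNV cells, %d RNA cells, %d genes",
                 n_cnv_cells, n_rna_cells, len(genes))

    if "cnv" in stages:
        mat = cnv_clones.consensus_region_cn(
            bundle["segments"], bundle["regions"], min_region_bp=config.region_min_bp
        )
        mat = cnv_clones.filter_cells_qc(mat, bundle["qc"], mode="clone-calling")
        log.info("cnv: %d cells after noisy filter", mat.n_cells)
        arms = cnv_clones.arm_profile(mat, arm_table)
        ploidy = cnv_clones.estimate_ploidy(arms)
        kept = cnv_clones.CellRegionMatrix(
            mat.cn[ploidy.keep], mat.cell_ids[ploidy.keep], mat.regions
        )
        arms_kept = cnv_clones.arm_profile(kept, arm_table)
        clones = cnv_clones.define_clones(
            arms_kept, config.min_variant_fraction, config.min_clone_size
        )
        ploidy_kept = cnv_clones.estimate_ploidy(arms_kept)
        profile = cnv_clones.pseudobulk_profile(kept, ploidy_kept)
        table, gene_stats = cnv_clones.gene_locus_stats(
            bundle["segments"], bundle["genes"], bundle["qc"],
            subsample_n=config.subsample_n, seed=config.child_seed("gene_cn"),
        )
        bundle.update(
            region_matrix=kept, arm_profile=arms_kept, ploidy=ploidy_kept,
            clones=clones, pseudobulk=profile, gene_cn_table=table,
            gene_stats=gene_stats,
        )
        assigned = pd.DataFrame(
            {"cell_id": clones.cell_ids, "clone": clones.labels}
        )
        _write_tsv(assigned, out / "clone_assignments_cnv.tsv", config)
        _write_tsv(profile, out / "pseudobulk_profile.tsv", config)
        _write_tsv(gene_stats, out / "gene_locus_stats.tsv", config)
        log.info("cnv: %d clones of sizes %s", len(clones.sizes), clones.sizes.tolist())

    if "assign" in stages:
        if "clones" not in bundle:
            raise ValueError("assign stage requires the cnv stage")
        cn_mat, filtered = clone_assignment.build_gene_clone_matrix(
            bundle["clones"], bundle["genes"], bundle["counts"],
            config.min_gene_umi, config.min_cell_umi,
        )
        model = clone_assignment.fit_dosage_model(
            filtered, cn_mat, init_seed=config.child_seed("assign_clones")
        )
        calls = clone_assignment.assign_cells(model, config.assign_threshold)
        bundle.update(gene_clone_cn=cn_mat, dosage_model=model, rna_calls=calls,
                      filtered_counts=filtered)
        _write_tsv(calls.to_frame(), out / "clone_assignments_rna.tsv", config)
        log.info("assign: %d/%d cells assigned at threshold %.2f",
                 int((calls.labels >= 0).sum()), len(calls.labels),
                 config.assign_threshold)

    if "phenodist" in stages:
        samples, tree_truth = synthetic_data.simulate_sample_set(
            sample_tree, cells_per_sample=cells_per_sample,
            seed=config.child_seed("phenodist"),
        )
        coords, labels = phenodist.embed_cells(
            samples, n_pcs=min(config.n_pcs, 30), mito_threshold=config.mito_max
        )
        op = phenodist.diffusion_operator(coords, k=config.knn_k, ka=config.ka)
        emb = phenodist.rescaled_coords(op, m=config.n_components)
        dists = phenodist.sample_distance_matrix(
            emb, labels, subsample_n=config.subsample_n,
            seed=config.child_seed("phenodist") + 1,
        )
        clad = phenodist.build_cladogram(dists)
        pearson = phenodist.pearson_distance(samples)
        bundle.update(sample_counts=samples, tree_truth=tree_truth,
                      sample_distances=dists, cladogram=clad,
                      pearson_distances=pearson)
        _write_tsv(dists, out / "sample_distances.tsv", config, index=True)
        (out / "cladogram.nwk").write_text(clad.newick() + "\n")
        log.info("phenodist: cladogram %s", clad.newick())

    if "subtype" in stages:
        if "sample_counts" not in bundle:
            raise ValueError("subtype stage requires the phenodist stage")
        sets = _synthetic_subtype_sets(bundle["sample_counts"])
        frames = []
        for name, cm in sorted(bundle["sample_counts"].items()):
            calls = subtype.assign_subtype(cm, sets)
            summ, _ = subtype.admixture_summary(calls, np.full(cm.n_cells, name))
            frames.append(summ)
        admix = pd.concat(frames, ignore_index=True)
        bundle["subtype_admixture"] = admix
        _write_tsv(admix, out / "subtype_admixture.tsv", config)

    if "diffrank" in stages:
        if "sample_counts" not in bundle:
            raise ValueError("diffrank stage requires the phenodist stage")
        names = sorted(bundle["sample_counts"])
        a, b = names[0], names[1]
        cm_a, cm_b = bundle["sample_counts"][a], bundle["sample_counts"][b]
        import scipy.sparse as sp
        from .io_formats import CountMatrix

        merged = CountMatrix(
            sp.hstack([cm_a.matrix, cm_b.matrix]).tocsr(),
            cm_a.gene_ids,
            np.concatenate([cm_a.barcodes, cm_b.barcodes]),
            cm_a.gene_names,
        )
        groups = np.array([a] * cm_a.n_cells + [b] * cm_b.n_cells, object)
        de = diffrank.wilcoxon_de(merged, groups, a, b, min_lfc=config.min_lfc)
        ranked = diffrank.rank_statistic(de, cap=config.rank_cap)
        bundle.update(de_table=de, ranked_genes=ranked)
        _write_tsv(de, out / "de_table.tsv", config)
        diffrank.write_rnk(ranked, out / "ranked_genes.rnk")
        log.info("diffrank: %d genes tested between %s and %s", len(de), a, b)

    return bundle


def _synthetic_subtype_sets(samples: dict) -> dict[str, list[str]]:
    """Split the synthetic gene space into two placeholder program sets."""
    ref = next(iter(samples.values()))
    genes = [str(g) for g in ref.gene_ids]
    half = max(len(genes) // 20, 5)
    return {"program-A": genes[:half], "program-B": genes[half : 2 * half]}
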