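"""Synthetic clonal scCNV and scRNA data with known ground truth.

The generators emulate the statistical structure every downstream stage
assumes, at desk scale:

* a clonal structure — a small tree of subclones differing by arm-level
  +-1 copy-number events on top of a uniform base ploidy, mirroring the
  arm-scale events seen in cultured cell lines (e.g. a clone carrying four
  copies of 7p against a triploid background);
* per-cell CNV segment calls in the 10x ``node_cnv_calls.bed`` dialect,
  one segment per mappable region, with optional per-segment noise and a
  fraction of "noisy" cells whose profiles are randomized (these must be
  recognizably excluded by QC);
* gene x cell UMI counts whose per-gene expected expression is
  proportional to clone copy number (the gene-dosage assumption) for a
  configurable fraction of genes on copy-variant arms;
* multi-sample count sets with a planted sample hierarchy, generated by
  Brownian-style perturbation of log-rates along an ultrametric tree, for
  validating the phenotypic-distance cladogram.

Every generator is deterministic given its seed, and every emitted file
parses through :mod:`occultclone.io_formats` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import toy_arms
from .io_formats import SEGMENT_COLUMNS, CountMatrix

NOISY_CN_MAX = 8  # noisy cells draw region CN uniformly in {0..8}


@dataclass
class ClonalStructure:
    """Planted subclone tree: arm-level integer CN per clone plus frequencies."""

    arm_cn: pd.DataFrame  # clones x arms, integer CN
    clone_frequencies: np.ndarray
    base_ploidy: int
    lineage: np.ndarray  # parent clone index per clone; -1 for the root
    arm_table: pd.DataFrame

    @property
    def n_clones(self) -> int:
        return len(self.arm_cn)

    def __post_init__(self) -> None:
        f = np.asarray(self.clone_frequencies, float)
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("clone frequencies must sum to 1")
        if (self.arm_cn.values < 0).any():
            raise ValueError("arm copy numbers must be >= 0")
        if int(np.sum(self.lineage < 0)) != 1:
            raise ValueError("exactly one root clone required")
        self.clone_frequencies = f


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    clone_labels: np.ndarray | None = None
    noisy: np.ndarray | None = None
    mu: np.ndarray | None = None  # per-gene baseline rates
    sample_tree: object = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def simulate_clonal_structure(
    n_clones: int,
    base_ploidy: int = 3,
    events_per_clone: int = 2,
    seed: int = 0,
    arm_table: pd.DataFrame | None = None,
    clone_frequencies=None,
) -> ClonalStructure:
    """Plant a clone tree where each child differs from its parent by exactly
    ``events_per_clone`` arm-level +-1 CN events (never driving an arm below 0).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if events_per_clone < 0:
        raise ValueError("events_per_clone must be >= 0")
    rng = np.random.default_rng(seed)
    if arm_table is None:
        arm_table = toy_arms()
    arms = arm_table["arm"].tolist()
    cn = np.full((n_clones, len(arms)), base_ploidy, dtype=int)
    lineage = np.full(n_clones, -1, dtype=int)
    for c in range(1, n_clones):
        parent = int(rng.integers(0, c))
        lineage[c] = parent
        cn[c] = cn[parent]
        # distinct arms per event so the child differs on exactly that many arms
        candidates = [a for a in range(len(arms))]
        rng.shuffle(candidates)
        applied = 0
        for a in candidates:
            if applied == events_per_clone:
                break
            direction = int(rng.choice([-1, 1]))
            if cn[c, a] + direction < 0:
                direction = 1
            cn[c, a] += direction
            applied += 1
        if applied < events_per_clone:
            raise ValueError("event budget exceeds available arms")
    if clone_frequencies is None:
        clone_frequencies = np.full(n_clones, 1.0 / n_clones)
    arm_cn = pd.DataFrame(cn, columns=arms)
    return ClonalStructure(arm_cn, np.asarray(clone_frequencies, float), base_ploidy, lineage, arm_table)


def mappable_regions_for(arm_table: pd.DataFrame, region_length_bp: int) -> pd.DataFrame:
    """Tile every arm into fixed-length mappable regions (last partial tile dropped)."""
    rows = []
    for _, r in arm_table.iterrows():
        pos = int(r.start)
        while pos + region_length_bp <= r.end:
            rows.append((r.chrom, pos, pos + region_length_bp))
            pos += region_length_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_cnv_cells(
    structure: ClonalStructure,
    n_cells: int,
    segment_noise_rate: float = 0.0,
    noisy_fraction: float = 0.0,
    region_length_bp: int = 2_500_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Emit per-cell segment calls, mappable regions, and a QC table.

    Each cell is drawn from the clone frequencies and emits one segment per
    mappable region at its clone's arm CN; a ``segment_noise_rate`` fraction
    of segments is perturbed by +-1 (floored at 0). ``round(noisy_fraction *
    n_cells)`` cells are flagged noisy and given region CN drawn uniformly
    in {0..8}. The QC mean ploidy is the length-weighted mean CN of the
    emitted segments.

    Returns (segments, regions, qc, truth).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    for name, rate in [("segment_noise_rate", segment_noise_rate), ("noisy_fraction", noisy_fraction)]:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    regions = mappable_regions_for(structure.arm_table, region_length_bp)
    n_regions = len(regions)
    # map each region to its arm's column in arm_cn
    arm_index = {a: i for i, a in enumerate(structure.arm_cn.columns)}
    region_arm = np.empty(n_regions, dtype=int)
    for j, reg in regions.iterrows():
        hit = structure.arm_table[
            (structure.arm_table.chrom == reg.chrom)
            & (structure.arm_table.start <= reg.start)
            & (reg.start < structure.arm_table.end)
        ]
        region_arm[j] = arm_index[hit.iloc[0]["arm"]]

    labels = rng.choice(structure.n_clones, size=n_cells, p=structure.clone_frequencies)
    n_noisy = int(round(noisy_fraction * n_cells))
    noisy = np.zeros(n_cells, dtype=bool)
    noisy[rng.choice(n_cells, size=n_noisy, replace=False)] = True

    cn = structure.arm_cn.values[labels][:, region_arm]  # cells x regions
    if segment_noise_rate > 0:
        flip = rng.random(cn.shape) < segment_noise_rate
        delta = rng.choice([-1, 1], size=cn.shape)
        cn = np.where(flip, np.maximum(cn + delta, 0), cn)
    if n_noisy:
        cn[noisy] = rng.integers(0, NOISY_CN_MAX + 1, size=(n_noisy, n_regions))

    lengths = (regions.end - regions.start).to_numpy()
    mean_ploidy = (cn * lengths).sum(axis=1) / lengths.sum()

    seg = pd.DataFrame(
        {
            "chrom": np.tile(regions.chrom.to_numpy(object), n_cells),
            "start": np.tile(regions.start.to_numpy(), n_cells),
            "end": np.tile(regions.end.to_numpy(), n_cells),
            "cell_id": np.repeat(np.arange(n_cells), n_regions),
            "cn": cn.ravel(),
            "confidence": np.full(n_cells * n_regions, 100.0),
        }
    )[SEGMENT_COLUMNS]
    seg = seg.sort_values(["cell_id", "chrom", "start"], kind="stable").reset_index(drop=True)

    qc = pd.DataFrame(
        {
            "barcode": [f"CELL{i:05d}" for i in range(n_cells)],
            "cell_id": np.arange(n_cells),
            "mean_ploidy": mean_ploidy,
            "is_noisy": noisy,
        }
    )
    truth = SimTruth(clone_labels=labels, noisy=noisy, seed=seed)
    return seg, regions, qc, truth


def genes_for_arms(
    arm_table: pd.DataFrame, genes_per_arm: int = 25, gene_length: int = 10_000
) -> pd.DataFrame:
    """Place an even grid of genes along each arm (synthetic annotation)."""
    rows = []
    g = 0
    for _, r in arm_table.iterrows():
        span = r.end - r.start
        step = span // (genes_per_arm + 1)
        for i in range(genes_per_arm):
            start = int(r.start + (i + 1) * step)
            rows.append((f"GENE{g:05d}", f"Gene{g}", r.chrom, start, start + gene_length, "+"))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"])


def simulate_rna_counts(
    structure: ClonalStructure,
    gene_annotation: pd.DataFrame,
    n_cells: int,
    depth_per_cell: int = 5_000,
    dosage_gene_fraction: float = 1.0,
    seed: int = 0,
    overdispersion: float | None = None,
    clone_labels: np.ndarray | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Draw gene x cell UMI counts under the copy-number dosage model.

    Per cell of clone ``c``, counts are multinomial over genes with
    ``p_gc ∝ mu_g * cn(g, c)`` for dosage-coupled genes on copy-variant arms
    and ``mu_g * base_ploidy`` otherwise; ``mu_g`` is log-normal(0, 0.5) and
    recorded in the returned truth. ``overdispersion`` switches the draw to
    a Dirichlet-multinomial with that concentration multiplier, to test
    robustness to model misspecification.
    """
    if depth_per_cell <= 0:
        raise ValueError("depth_per_cell must be positive")
    if not 0.0 <= dosage_gene_fraction <= 1.0:
        raise ValueError("dosage_gene_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = gene_annotation.reset_index(drop=True)
    n_genes = len(genes)
    arm_index = {a: i for i, a in enumerate(structure.arm_cn.columns)}

    gene_arm = np.full(n_genes, -1, dtype=int)
    for j, g in genes.iterrows():
        hit = structure.arm_table[
            (structure.arm_table.chrom == g.chrom)
            & (structure.arm_table.start <= g.start)
            & (g.start < structure.arm_table.end)
        ]
        if not hit.empty:
            gene_arm[j] = arm_index[hit.iloc[0]["arm"]]

    mu = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    variant_arms = np.where(structure.arm_cn.values.std(axis=0) > 0)[0]
    on_variant = np.isin(gene_arm, variant_arms)
    dosage = on_variant & (rng.random(n_genes) < dosage_gene_fraction)

    # per-clone unnormalized rates
    rates = np.empty((structure.n_clones, n_genes))
    for c in range(structure.n_clones):
        cn_g = np.where(
            (gene_arm >= 0) & dosage,
            structure.arm_cn.values[c][np.maximum(gene_arm, 0)],
            structure.base_ploidy,
        )
        rates[c] = mu * cn_g
    if np.any(rates.sum(axis=1) <= 0):
        raise ValueError("all-zero rate vector for a clone")

    if clone_labels is None:
        clone_labels = rng.choice(
            structure.n_clones, size=n_cells, p=structure.clone_frequencies
        )
    else:
        clone_labels = np.asarray(clone_labels, int)
        if len(clone_labels) != n_cells:
            raise ValueError("clone_labels length must equal n_cells")

    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    for n in range(n_cells):
        p = rates[clone_labels[n]]
        p = p / p.sum()
        if overdispersion is not None:
            p = rng.dirichlet(p * overdispersion)
        counts[n] = rng.multinomial(depth_per_cell, p)

    cm = CountMatrix(
        sp.csr_matrix(counts.T),
        genes.gene_id.to_numpy(object),
        np.array([f"RNACELL{i:05d}" for i in range(n_cells)], dtype=object),
        genes.gene_name.to_numpy(object),
    )
    truth = SimTruth(
        clone_labels=clone_labels,
        mu=mu,
        seed=seed,
        extras={"dosage_genes": dosage, "rates": rates},
    )
    return cm, truth


def _tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    left, right = tree
    return _tree_leaves(left) + _tree_leaves(right)


def _tree_depth(tree) -> int:
    if isinstance(tree, str):
        return 0
    return 1 + max(_tree_depth(tree[0]), _tree_depth(tree[1]))


def tree_distances(tree) -> pd.DataFrame:
    """Ultrametric leaf-to-leaf distances implied by a nested-tuple tree
    (every leaf at depth 1; each internal split halves the remaining height).
    """
    leaves = _tree_leaves(tree)
    d = pd.DataFrame(0.0, index=leaves, columns=leaves)

    def recurse(node, height):
        if isinstance(node, str):
            return [node]
        l = recurse(node[0], height / 2)
        r = recurse(node[1], height / 2)
        for a in l:
            for b in r:
                d.loc[a, b] = d.loc[b, a] = 2 * height
        return l + r

    recurse(tree, 1.0)
    return d


def simulate_sample_set(
    sample_tree,
    cells_per_sample: int = 300,
    n_genes: int = 400,
    between_scale: float = 0.2,
    within_scale: float = 0.3,
    depth_per_cell: int = 2_000,
    seed: int = 0,
) -> tuple[dict[str, CountMatrix], SimTruth]:
    """Generate per-sample count matrices with a planted sample hierarchy.

    ``sample_tree`` is a nested tuple of sample names, e.g.
    ``(("A", "B"), ("C", "D"))``, interpreted as an ultrametric binary tree
    of unit height. Each sample's mean log-rate vector is produced by
    Brownian perturbation along the tree (variance proportional to branch
    length times ``between_scale``); cells add i.i.d. Gaussian log-rate
    noise of scale ``within_scale`` and draw multinomial counts at
    ``depth_per_cell``. Expected pairwise sample distances are monotone in
    tree distance.
    """
    leaves = _tree_leaves(sample_tree)
    if len(leaves) < 2:
        raise ValueError("sample_tree must contain at least 2 samples")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate sample names in tree")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=n_genes)

    means: dict[str, np.ndarray] = {}

    def walk(node, mean, height):
        # Brownian step over this branch
        if isinstance(node, str):
            means[node] = mean
            return
        for child in node:
            step = rng.normal(0.0, np.sqrt(max(height / 2, 1e-12) * between_scale), n_genes)
            walk(child, mean + step, height / 2)

    walk(sample_tree, base, 1.0)

    gene_ids = np.array([f"GENE{g:05d}" for g in range(n_genes)], dtype=object)
    out: dict[str, CountMatrix] = {}
    for name in leaves:
        logrates = means[name][None, :] + rng.normal(
            0.0, within_scale, size=(cells_per_sample, n_genes)
        )
        p = np.exp(logrates)
        p /= p.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(depth_per_cell, row) for row in p])
        out[name] = CountMatrix(
            sp.csr_matrix(counts.T),
            gene_ids,
            np.array([f"{name}-{i:04d}" for i in range(cells_per_sample)], dtype=object),
            gene_ids,
        )
    truth = SimTruth(sample_tree=sample_tree, seed=seed, extras={"means": means})
    return out, truth
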