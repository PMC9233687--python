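"""Single-cell CNV processing: region consensus, QC, arms, ploidy, clones.

The workflow turns per-cell segment calls into interpretable objects:

1. intersect segments with mappable regions and take, per cell per region,
   the integer copy number covering the most bases of the region (ties go
   to the lower CN — conservative against false amplification); keep only
   autosomal regions of at least 2 Mb;
2. drop cells flagged noisy by the instrument QC (and, for gene-locus
   analyses, haploid cells with mean ploidy < 1.5);
3. summarize each cell over chromosome arms by length-weighted mean CN;
4. estimate per-cell ploidy as the median of length-weighted
   whole-chromosome means and drop cells more than one cohort SD from the
   cohort mean;
5. call clones as the distinct rounded-CN signatures over discriminating
   arms (arms where a sizeable fraction of cells departs from the modal
   state), or over a user-supplied arm list with optional coordinate
   windows;
6. summarize samples as pseudo-bulk CN-ratio profiles with a per-region
   heterogeneity score (trichotomous state entropy), and compute per-gene
   consensus CN and amplified-cell fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import is_autosome

MISSING = -1  # marker for region x cell entries with no overlapping segment

REGION_MIN_BP = 2_000_000
HAPLOID_PLOIDY_CUT = 1.5


@dataclass
class CellRegionMatrix:
    """Cells x regions integer copy number; ``MISSING`` where no segment overlaps."""

    cn: np.ndarray  # int, cells x regions
    cell_ids: np.ndarray
    regions: pd.DataFrame  # chrom, start, end

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        if self.cn.shape != (len(self.cell_ids), len(self.regions)):
            raise ValueError("cn shape inconsistent with cell_ids / regions")

    @property
    def n_cells(self) -> int:
        return self.cn.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions.itertuples()]
        return pd.DataFrame(self.cn, index=self.cell_ids, columns=cols)


@dataclass
class ArmProfile:
    """Cells x arms length-weighted mean CN (NaN where an arm has no data)."""

    means: np.ndarray  # float, cells x arms
    weights: np.ndarray  # float, cells x arms: total bp of non-missing regions
    arms: list[str]
    cell_ids: np.ndarray
    arm_coords: pd.DataFrame  # arm, chrom, start, end (windows already applied)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.cell_ids, columns=self.arms)


@dataclass
class PloidyEstimate:
    ploidy: np.ndarray  # per cell
    cell_ids: np.ndarray
    cohort_mean: float
    cohort_sd: float
    keep: np.ndarray  # bool per cell


@dataclass
class CloneDefinition:
    """Clones as rounded-CN signatures over discriminating arms."""

    discriminating_arms: list[str]
    signatures: pd.DataFrame  # clones x discriminating arms, int
    labels: np.ndarray  # per cell clone index, -1 unassigned
    cell_ids: np.ndarray
    sizes: np.ndarray
    arm_coords: pd.DataFrame  # coordinates of the discriminating arms/windows


def consensus_region_cn(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    min_region_bp: int = REGION_MIN_BP,
    autosomes_only: bool = True,
) -> CellRegionMatrix:
    """Cell x region consensus CN: the integer CN covering the most bases.

    Ties break to the lower CN. Regions shorter than ``min_region_bp`` or
    (by default) off the autosomes are dropped; a region with no
    overlapping segment for a cell is ``MISSING``.
    """
    keep = (regions.end - regions.start) >= min_region_bp
    if autosomes_only:
        keep &= regions.chrom.map(is_autosome)
    regions = regions.loc[keep].sort_values(["chrom", "start"]).reset_index(drop=True)

    cell_ids = np.unique(segments.cell_id.to_numpy()) if len(segments) else np.array([], int)
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    cn = np.full((len(cell_ids), len(regions)), MISSING, dtype=int)
    if len(segments) == 0 or len(regions) == 0:
        return CellRegionMatrix(cn, cell_ids, regions)

    overlaps = []
    for chrom, reg in regions.groupby("chrom", sort=False):
        seg = segments[segments.chrom == chrom]
        if seg.empty:
            continue
        rstart = reg.start.to_numpy()
        rend = reg.end.to_numpy()
        ridx = reg.index.to_numpy()
        s = seg.start.to_numpy()
        e = seg.end.to_numpy()
        # regions overlapping each segment: first with end > seg.start,
        # last with start < seg.end (regions sorted, non-overlapping)
        first = np.searchsorted(rend, s, side="right")
        last = np.searchsorted(rstart, e, side="left")
        n_hit = np.maximum(last - first, 0)
        if n_hit.sum() == 0:
            continue
        seg_rep = np.repeat(np.arange(len(seg)), n_hit)
        offsets = np.concatenate([np.arange(k) for k in n_hit if k > 0])
        local = np.repeat(first, n_hit) + offsets
        ov = pd.DataFrame(
            {
                "cell_id": seg.cell_id.to_numpy()[seg_rep],
                "region": ridx[local],
                "cn": seg.cn.to_numpy()[seg_rep],
                "bases": np.minimum(e[seg_rep], rend[local])
                - np.maximum(s[seg_rep], rstart[local]),
            }
        )
        overlaps.append(ov[ov.bases > 0])
    if not overlaps:
        return CellRegionMatrix(cn, cell_ids, regions)

    ov = pd.concat(overlaps, ignore_index=True)
    ov = ov.groupby(["cell_id", "region", "cn"], as_index=False)["bases"].sum()
    # majority bases wins; ties break to the lower CN
    ov = ov.sort_values(
        ["cell_id", "region", "bases", "cn"], ascending=[True, True, False, True]
    ).drop_duplicates(["cell_id", "region"])
    rows = ov.cell_id.map(cell_pos).to_numpy()
    cn[rows, ov.region.to_numpy()] = ov.cn.to_numpy()
    return CellRegionMatrix(cn, cell_ids, regions)


def filter_cells_qc(
    matrix: CellRegionMatrix, qc: pd.DataFrame, mode: str = "clone-calling"
) -> CellRegionMatrix:
    """Drop cells the instrument QC disqualifies.

    ``clone-calling`` removes noisy cells only (the ploidy-SD filter comes
    later); ``clonal-gene-analysis`` additionally removes haploid cells
    (mean ploidy < 1.5).
    """
    if mode not in ("clone-calling", "clonal-gene-analysis"):
        raise ValueError(f"unknown QC mode: {mode!r}")
    qc = qc.set_index("cell_id")
    missing = set(matrix.cell_ids) - set(qc.index)
    if missing:
        raise ValueError(f"QC records missing for cells {sorted(missing)[:5]}...")
    noisy = qc.loc[matrix.cell_ids, "is_noisy"].to_numpy(bool)
    keep = ~noisy
    if mode == "clonal-gene-analysis":
        keep &= qc.loc[matrix.cell_ids, "mean_ploidy"].to_numpy() >= HAPLOID_PLOIDY_CUT
    return CellRegionMatrix(matrix.cn[keep], matrix.cell_ids[keep], matrix.regions)


def _split_regions_by_arm(
    regions: pd.DataFrame, arm_table: pd.DataFrame
) -> pd.DataFrame:
    """Region pieces after cutting at arm boundaries: region index, arm, piece bp."""
    pieces = []
    for j, reg in regions.iterrows():
        arms = arm_table[arm_table.chrom == reg.chrom]
        for _, a in arms.iterrows():
            lo, hi = max(reg.start, a.start), min(reg.end, a.end)
            if hi > lo:
                pieces.append((j, a.arm, hi - lo))
    return pd.DataFrame(pieces, columns=["region", "arm", "bp"])


def arm_profile(matrix: CellRegionMatrix, arm_table: pd.DataFrame) -> ArmProfile:
    """Length-weighted mean CN per cell per chromosome arm.

    A region straddling an arm boundary is split at the boundary before
    aggregation; arms with no retained regions are NaN.
    """
    pieces = _split_regions_by_arm(matrix.regions, arm_table)
    arms = [a for a in arm_table.arm if a in set(pieces.arm)] if len(pieces) else []
    means = np.full((matrix.n_cells, len(arms)), np.nan)
    weights = np.zeros((matrix.n_cells, len(arms)))
    valid = matrix.cn != MISSING
    cnv = np.where(valid, matrix.cn, 0)
    for k, arm in enumerate(arms):
        p = pieces[pieces.arm == arm]
        ridx = p.region.to_numpy()
        bp = p.bp.to_numpy()
        w = valid[:, ridx] * bp  # cells x pieces
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means[:, k] = (cnv[:, ridx] * w).sum(axis=1) / tot
        means[tot == 0, k] = np.nan
        weights[:, k] = tot
    coords = arm_table[arm_table.arm.isin(arms)][["arm", "chrom", "start", "end"]]
    return ArmProfile(means, weights, arms, matrix.cell_ids, coords.reset_index(drop=True))


def estimate_ploidy(arms: ArmProfile) -> PloidyEstimate:
    """Per-cell ploidy: median of length-weighted whole-chromosome mean CNs.

    Cells farther than one cohort SD from the cohort mean are flagged
    ``keep=False`` (boundary inclusive, so an SD-0 cohort is kept intact).
    """
    chrom_of = arms.arm_coords.set_index("arm")["chrom"]
    chroms = chrom_of.loc[arms.arms].to_numpy()
    uniq = pd.unique(chroms)
    n_cells = len(arms.cell_ids)
    chrom_means = np.full((n_cells, len(uniq)), np.nan)
    for k, ch in enumerate(uniq):
        cols = np.where(chroms == ch)[0]
        w = arms.weights[:, cols]
        m = np.nan_to_num(arms.means[:, cols])
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            chrom_means[:, k] = (m * w).sum(axis=1) / tot
        chrom_means[tot == 0, k] = np.nan
    if np.all(np.isnan(chrom_means), axis=1).any():
        raise ValueError("a cell has no whole-chromosome data")
    ploidy = np.nanmedian(chrom_means, axis=1)
    if n_cells < 2:
        warnings.warn("single cell: ploidy SD undefined, keeping all cells")
        return PloidyEstimate(ploidy, arms.cell_ids, float(ploidy.mean()), 0.0,
                              np.ones(n_cells, bool))
    mean, sd = float(ploidy.mean()), float(ploidy.std(ddof=0))
    keep = np.abs(ploidy - mean) <= sd
    return PloidyEstimate(ploidy, arms.cell_ids, mean, sd, keep)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (portable, unlike banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def define_clones(
    arms: ArmProfile,
    min_variant_fraction: float = 0.10,
    min_clone_size: int = 20,
    discriminating_arms: list[str] | None = None,
) -> CloneDefinition:
    """Partition cells into clones by rounded CN over discriminating arms.

    Discriminating arms are those where at least ``min_variant_fraction``
    of cells have a rounded CN differing from the modal rounded CN (or an
    explicit arm list, mirroring a curated per-sample choice). Each
    distinct signature is a clone; clones smaller than ``min_clone_size``
    leave their members unassigned (-1). Clone labels are ordered by
    decreasing size, then signature, so they are stable under permutation
    of cell order.
    """
    mat = arms.to_frame()
    rounded = _round_half_away(mat.to_numpy())
    if discriminating_arms is None:
        disc = []
        for k, arm in enumerate(arms.arms):
            col = rounded[:, k]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                continue
            vals, counts = np.unique(col, return_counts=True)
            modal = vals[np.argmax(counts)]
            if np.mean(col != modal) >= min_variant_fraction:
                disc.append(arm)
    else:
        unknown = set(discriminating_arms) - set(arms.arms)
        if unknown:
            raise ValueError(f"arms not present in profile: {sorted(unknown)}")
        disc = list(discriminating_arms)

    n_cells = len(arms.cell_ids)
    if not disc:
        sig = pd.DataFrame([[]], index=[0])
        return CloneDefinition([], sig, np.zeros(n_cells, int), arms.cell_ids,
                               np.array([n_cells]), arms.arm_coords.iloc[0:0])

    cols = [arms.arms.index(a) for a in disc]
    sigs = rounded[:, cols]
    complete = ~np.isnan(sigs).any(axis=1)
    labels = np.full(n_cells, -1, dtype=int)
    sig_tuples = [tuple(int(v) for v in row) for row in sigs[complete]]
    counts: dict[tuple, int] = {}
    for t in sig_tuples:
        counts[t] = counts.get(t, 0) + 1
    kept = [t for t, c in counts.items() if c >= min_clone_size]
    kept.sort(key=lambda t: (-counts[t], t))
    index_of = {t: i for i, t in enumerate(kept)}
    lab_complete = np.array([index_of.get(t, -1) for t in sig_tuples], int)
    labels[np.where(complete)[0]] = lab_complete
    signatures = pd.DataFrame(kept, columns=disc) if kept else pd.DataFrame(columns=disc)
    sizes = np.array([counts[t] for t in kept], int)
    coords = arms.arm_coords[arms.arm_coords.arm.isin(disc)].reset_index(drop=True)
    return CloneDefinition(disc, signatures, labels, arms.cell_ids, sizes, coords)


def restrict_regions(
    matrix: CellRegionMatrix, windows: dict[str, tuple[str, int, int]]
) -> CellRegionMatrix:
    """Keep only regions inside per-arm coordinate windows.

    ``windows`` maps arm name -> (chrom, start, end); regions on listed
    chromosomes outside every window for that chromosome are dropped,
    regions on unlisted chromosomes are kept. This expresses curated
    sub-arm choices such as restricting 12q to 93.5-126.3 Mb.
    """
    keep = np.ones(len(matrix.regions), bool)
    listed_chroms = {c for c, _, _ in windows.values()}
    for j, reg in matrix.regions.iterrows():
        if reg.chrom not in listed_chroms:
            continue
        keep[j] = any(
            reg.chrom == c and reg.start >= s and reg.end <= e
            for c, s, e in windows.values()
        )
    return CellRegionMatrix(
        matrix.cn[:, keep], matrix.cell_ids, matrix.regions.loc[keep].reset_index(drop=True)
    )


def pseudobulk_profile(
    matrix: CellRegionMatrix, ploidy: PloidyEstimate
) -> pd.DataFrame:
    """Pseudo-bulk CN-ratio profile with per-region heterogeneity.

    Per region: ``ratio`` is the mean over cells of CN divided by the
    cell's ploidy; each cell is in one of three states relative to its own
    ploidy (deleted: CN < ploidy - 0.5; amplified: CN > ploidy + 0.5;
    neutral otherwise); ``heterogeneity`` is the Shannon entropy of the
    state frequencies normalized by ln 3, so uniform amplification at any
    magnitude scores 0 and an equal three-way split scores 1.
    """
    order = {c: i for i, c in enumerate(ploidy.cell_ids)}
    rows = [order[c] for c in matrix.cell_ids]
    pl = ploidy.ploidy[rows]
    valid = matrix.cn != MISSING
    cn = matrix.cn.astype(float)
    ratio = np.where(valid, cn / pl[:, None], np.nan)
    deleted = valid & (cn < (pl[:, None] - 0.5))
    amplified = valid & (cn > (pl[:, None] + 0.5))
    neutral = valid & ~deleted & ~amplified
    n_valid = valid.sum(axis=0).astype(float)
    out = matrix.regions.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.nanmean(ratio, axis=0)
        freqs = np.stack(
            [deleted.sum(0) / n_valid, neutral.sum(0) / n_valid, amplified.sum(0) / n_valid]
        )
    ent = np.zeros(len(out))
    for f in freqs:
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(f > 0, -f * np.log(f), 0.0)
        ent += np.nan_to_num(term)
    out["heterogeneity"] = ent / np.log(3)
    states = np.array(["deleted", "neutral", "amplified"])
    out["modal_state"] = states[np.argmax(freqs, axis=0)]
    return out


def gene_locus_stats(
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    qc: pd.DataFrame,
    subsample_n: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene per-cell consensus CN and per-gene amplified-cell fraction.

    Noisy and haploid (mean ploidy < 1.5) cells are excluded first. The
    gene CN is the majority-bases consensus over the gene interval; a cell
    is amplified for a gene when its gene CN exceeds its mean ploidy + 1.
    When ``subsample_n`` is set, a seeded uniform subsample of cells feeds
    the returned visualization table; the amplified fractions are computed
    on all retained cells.

    Returns (gene x cell CN table, per-gene stats with ``amplified_fraction``).
    """
    qc_ok = qc[(~qc.is_noisy) & (qc.mean_ploidy >= HAPLOID_PLOIDY_CUT)]
    seg = segments[segments.cell_id.isin(set(qc_ok.cell_id))]
    gene_regions = genes[["chrom", "start", "end"]].copy()
    mat = consensus_region_cn(seg, gene_regions, min_region_bp=0, autosomes_only=False)
    # consensus sorts regions; map back to gene ids by coordinates
    key = {(r.chrom, r.start, r.end): i for i, r in enumerate(mat.regions.itertuples(index=False))}
    col_of_gene = [key[(g.chrom, g.start, g.end)] for g in genes.itertuples(index=False)]
    cn = mat.cn[:, col_of_gene]

    ploidy = qc_ok.set_index("cell_id").loc[mat.cell_ids, "mean_ploidy"].to_numpy()
    valid = cn != MISSING
    amplified = valid & (cn > (ploidy[:, None] + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = amplified.sum(axis=0) / valid.sum(axis=0)
    stats = genes[["gene_id", "gene_name"]].copy()
    stats["amplified_fraction"] = frac
    stats["n_cells"] = valid.sum(axis=0)

    cells = mat.cell_ids
    if subsample_n is not None and subsample_n < len(cells):
        rng = np.random.default_rng(seed)
        cells = np.sort(rng.choice(cells, size=subsample_n, replace=False))
    rows = [np.where(mat.cell_ids == c)[0][0] for c in cells]
    table = pd.DataFrame(cn[rows], index=cells, columns=genes.gene_id.tolist())
    return table, stats
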