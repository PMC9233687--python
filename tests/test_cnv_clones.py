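import numpy as np
import pandas as pd
import pytest

from occultclone import cnv_clones as cc
from occultclone import synthetic_data as sd
from occultclone.cnv_clones import MISSING, CellRegionMatrix
from occultclone.genome import toy_arms

from conftest import match_partition_accuracy


def seg_frame(rows):
    """rows: (chrom, start, end, cell_id, cn)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_id", "cn"])
    df["confidence"] = 100.0
    return df


def brute_force_consensus(segments, regions, scale=1):
    """Per-base majority oracle: enumerate every base of every region.

    Ties to the lower CN. Coordinates may be divided by ``scale`` first
    (segments/regions must align to the scale) to keep enumeration cheap.
    """
    cells = sorted(segments.cell_id.unique())
    out = np.full((len(cells), len(regions)), MISSING, dtype=int)
    for ci, cell in enumerate(cells):
        sub = segments[segments.cell_id == cell]
        for rj, reg in enumerate(regions.itertuples(index=False)):
            counts = {}
            for b in range(reg.start // scale, reg.end // scale):
                base = b * scale
                hit = sub[
                    (sub.chrom == reg.chrom) & (sub.start <= base) & (base < sub.end)
                ]
                for cn in hit.cn:
                    counts[cn] = counts.get(cn, 0) + 1
            if counts:
                best = max(counts.values())
                out[ci, rj] = min(cn for cn, n in counts.items() if n == best)
    return out


class TestConsensusRegionCn:
    def test_majority_bases_wins(self):
        seg = seg_frame([("chr1", 0, 1_500_000, 0, 2), ("chr1", 1_500_000, 2_000_000, 0, 3)])
        reg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2_000_000]})
        mat = cc.consensus_region_cn(seg, reg)
        assert mat.cn[0, 0] == 2

    def test_exact_tie_breaks_to_lower_cn(self):
        seg = seg_frame([("chr1", 0, 1_000_000, 0, 3), ("chr1", 1_000_000, 2_000_000, 0, 2)])
        reg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2_000_000]})
        mat = cc.consensus_region_cn(seg, reg)
        assert mat.cn[0, 0] == 2

    def test_sex_chromosome_and_short_regions_dropped(self):
        seg = seg_frame(
            [("chrX", 0, 3_000_000, 0, 2), ("chr1", 0, 3_000_000, 0, 2),
             ("chr2", 0, 1_000_000, 0, 2)]
        )
        reg = pd.DataFrame(
            {"chrom": ["chrX", "chr1", "chr2"], "start": [0, 0, 0],
             "end": [3_000_000, 3_000_000, 1_000_000]}
        )
        mat = cc.consensus_region_cn(seg, reg)
        assert mat.regions.chrom.tolist() == ["chr1"]

    def test_no_overlap_is_missing(self):
        seg = seg_frame([("chr1", 0, 3_000_000, 0, 2)])
        reg = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [3_000_000, 3_000_000]}
        )
        mat = cc.consensus_region_cn(seg, reg)
        assert mat.cn[0, 1] == MISSING

    def test_matches_per_base_oracle_on_random_instances(self):
        """Randomized segments vs exhaustive base counting (coarse 1 kb grid)."""
        rng = np.random.default_rng(0)
        scale = 1000
        reg = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"],
             "start": [0, 20 * scale, 0],
             "end": [20 * scale, 45 * scale, 30 * scale]}
        )
        rows = []
        for cell in range(40):
            for chrom, hi in [("chr1", 50), ("chr2", 35)]:
                cuts = np.sort(rng.choice(np.arange(1, hi), size=3, replace=False))
                bounds = [0, *cuts.tolist(), hi]
                for s, e in zip(bounds[:-1], bounds[1:]):
                    if rng.random() < 0.15:
                        continue  # leave gaps -> missing entries
                    rows.append((chrom, s * scale, e * scale, cell, int(rng.integers(0, 6))))
        seg = seg_frame(rows)
        mat = cc.consensus_region_cn(seg, reg, min_region_bp=0, autosomes_only=True)
        oracle = brute_force_consensus(seg, reg, scale=scale)
        np.testing.assert_array_equal(mat.cn, oracle)

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        reg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5_000_000]})
        rows = [("chr1", 0, 5_000_000, c, int(rng.integers(1, 5))) for c in range(10)]
        seg = seg_frame(rows)
        shuffled = seg.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a = cc.consensus_region_cn(seg, reg, min_region_bp=0)
        b = cc.consensus_region_cn(shuffled, reg, min_region_bp=0)
        np.testing.assert_array_equal(a.cn, b.cn)
        np.testing.assert_array_equal(a.cell_ids, b.cell_ids)


class TestQcFilter:
    @pytest.fixture()
    def matrix_and_qc(self):
        reg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [3_000_000]})
        mat = CellRegionMatrix(np.array([[2], [2], [2]]), np.array([0, 1, 2]), reg)
        qc = pd.DataFrame(
            {"barcode": ["a", "b", "c"], "cell_id": [0, 1, 2],
             "mean_ploidy": [2.0, 1.4, 2.0], "is_noisy": [False, False, True]}
        )
        return mat, qc

    def test_noisy_removed_in_both_modes(self, matrix_and_qc):
        mat, qc = matrix_and_qc
        for mode in ("clone-calling", "clonal-gene-analysis"):
            out = cc.filter_cells_qc(mat, qc, mode)
            assert 2 not in out.cell_ids

    def test_haploid_removed_only_in_gene_analysis_mode(self, matrix_and_qc):
        mat, qc = matrix_and_qc
        assert 1 in cc.filter_cells_qc(mat, qc, "clone-calling").cell_ids
        assert 1 not in cc.filter_cells_qc(mat, qc, "clonal-gene-analysis").cell_ids

    def test_unknown_mode_errors(self, matrix_and_qc):
        with pytest.raises(ValueError, match="mode"):
            cc.filter_cells_qc(*matrix_and_qc, mode="whatever")


class TestArmProfile:
    def test_weighted_mean_closed_form(self, arm_table):
        # 3 Mb at CN 2 + 2 Mb at CN 4 on one arm -> (6 + 8) / 5 = 2.8
        reg = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 3_000_000],
             "end": [3_000_000, 5_000_000]}
        )
        mat = CellRegionMatrix(np.array([[2, 4]]), np.array([0]), reg)
        prof = cc.arm_profile(mat, arm_table)
        assert prof.means[0, prof.arms.index("1p")] == pytest.approx(2.8, abs=1e-12)

    def test_region_straddling_boundary_split(self, arm_table):
        # toy arm boundary at 20 Mb: 19-21 Mb region contributes 1 Mb to each arm
        reg = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [19_000_000, 21_000_000],
             "end": [21_000_000, 25_000_000]}
        )
        mat = CellRegionMatrix(np.array([[6, 2]]), np.array([0]), reg)
        prof = cc.arm_profile(mat, arm_table)
        assert prof.means[0, prof.arms.index("1p")] == pytest.approx(6.0)
        # 1q: 1 Mb at CN 6 + 4 Mb at CN 2 -> 14/5
        assert prof.means[0, prof.arms.index("1q")] == pytest.approx(14 / 5, abs=1e-12)

    def test_matches_direct_weighted_average_oracle(self, arm_table):
        rng = np.random.default_rng(3)
        regions = sd.mappable_regions_for(arm_table, 2_500_000)
        cn = rng.integers(0, 6, size=(20, len(regions)))
        cn[rng.random(cn.shape) < 0.1] = MISSING
        mat = CellRegionMatrix(cn, np.arange(20), regions)
        prof = cc.arm_profile(mat, arm_table)
        lengths = (regions.end - regions.start).to_numpy()
        for i in range(20):
            for k, arm in enumerate(prof.arms):
                coords = arm_table[arm_table.arm == arm].iloc[0]
                in_arm = (
                    (regions.chrom == coords.chrom)
                    & (regions.start >= coords.start)
                    & (regions.end <= coords.end)
                ).to_numpy()
                valid = in_arm & (cn[i] != MISSING)
                if not valid.any():
                    assert np.isnan(prof.means[i, k])
                    continue
                expect = (cn[i, valid] * lengths[valid]).sum() / lengths[valid].sum()
                assert prof.means[i, k] == pytest.approx(expect, abs=1e-12)

    def test_mean_bounded_by_observed_cn(self, arm_table):
        rng = np.random.default_rng(4)
        regions = sd.mappable_regions_for(arm_table, 2_500_000)
        cn = rng.integers(1, 7, size=(10, len(regions)))
        mat = CellRegionMatrix(cn, np.arange(10), regions)
        prof = cc.arm_profile(mat, arm_table)
        assert np.nanmin(prof.means) >= cn.min()
        assert np.nanmax(prof.means) <= cn.max()


class TestPloidy:
    def _profile_from_chrom_means(self, chrom_cns, arm_table):
        """One region per arm, constant CN per chromosome per cell."""
        regions = sd.mappable_regions_for(arm_table, 20_000_000)  # one per arm
        cn = np.repeat(np.asarray(chrom_cns), 2, axis=1)  # p and q arms
        mat = CellRegionMatrix(cn, np.arange(len(cn)), regions)
        return cc.arm_profile(mat, arm_table)

    def test_ploidy_is_median_of_chromosome_means(self, arm_table):
        prof = self._profile_from_chrom_means([[2, 2, 3, 5]], arm_table)
        est = cc.estimate_ploidy(prof)
        assert est.ploidy[0] == pytest.approx(2.5)  # median of {2,2,3,5}

    def test_one_sd_filter_drops_exactly_the_outliers(self, arm_table):
        rows = [[2, 2, 2, 2]] * 98 + [[4, 4, 4, 4]] + [[1, 1, 1, 1]]
        prof = self._profile_from_chrom_means(rows, arm_table)
        est = cc.estimate_ploidy(prof)
        ploidy = est.ploidy
        sd_ = ploidy.std(ddof=0)
        assert est.cohort_sd == pytest.approx(sd_)
        assert (~est.keep).sum() == 2
        assert set(np.where(~est.keep)[0]) == {98, 99}

    def test_zero_sd_cohort_kept_intact(self, arm_table):
        prof = self._profile_from_chrom_means([[3, 3, 3, 3]] * 5, arm_table)
        est = cc.estimate_ploidy(prof)
        assert est.keep.all()

    def test_single_cell_warns_and_keeps(self, arm_table):
        prof = self._profile_from_chrom_means([[2, 2, 2, 2]], arm_table)
        with pytest.warns(UserWarning, match="single cell"):
            est = cc.estimate_ploidy(prof)
        assert est.keep.all()

    def test_pure_triploid_simulation_gives_exactly_three(self, arm_table):
        st = sd.simulate_clonal_structure(1, base_ploidy=3, seed=0, arm_table=arm_table)
        seg, regions, qc, _ = sd.simulate_cnv_cells(st, 30, 0.0, 0.0, seed=1)
        mat = cc.consensus_region_cn(seg, regions)
        est = cc.estimate_ploidy(cc.arm_profile(mat, arm_table))
        np.testing.assert_allclose(est.ploidy, 3.0)


class TestDefineClones:
    def test_two_clones_by_construction(self, arm_table):
        # 10 cells: arm 1p CN 6x4 / 4x3 correlated with arm 2q CN 6x2 / 4x3
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        base = np.full((10, 8), 3)
        arm_idx = {a: i for i, a in enumerate(arm_table.arm)}
        base[:6, arm_idx["1p"]] = 4
        base[6:, arm_idx["1p"]] = 3
        base[:6, arm_idx["2q"]] = 2
        base[6:, arm_idx["2q"]] = 3
        mat = CellRegionMatrix(base, np.arange(10), regions)
        clones = cc.define_clones(cc.arm_profile(mat, arm_table), 0.10, 2)
        assert clones.discriminating_arms == ["1p", "2q"]
        assert sorted(clones.sizes.tolist()) == [4, 6]
        sigs = {tuple(r) for r in clones.signatures.to_numpy()}
        assert sigs == {(4, 2), (3, 3)}

    def test_constant_arm_not_discriminating(self, arm_table):
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        mat = CellRegionMatrix(np.full((10, 8), 3), np.arange(10), regions)
        clones = cc.define_clones(cc.arm_profile(mat, arm_table), 0.10, 2)
        assert clones.discriminating_arms == []
        assert (clones.labels == 0).all()  # single clone of everyone

    def test_small_clones_left_unassigned(self, arm_table):
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        base = np.full((30, 8), 3)
        base[:15, 0] = 4
        base[29, 0] = 7  # singleton signature
        mat = CellRegionMatrix(base, np.arange(30), regions)
        clones = cc.define_clones(cc.arm_profile(mat, arm_table), 0.10, 5)
        assert clones.labels[29] == -1

    def test_recovery_with_noise(self, three_clone_structure):
        """3 planted clones (0.5/0.3/0.2), 500 cells, 5% segment noise."""
        st = three_clone_structure
        seg, regions, qc, truth = sd.simulate_cnv_cells(st, 500, 0.05, 0.0, seed=2)
        mat = cc.consensus_region_cn(seg, regions)
        mat = cc.filter_cells_qc(mat, qc, "clone-calling")
        prof = cc.arm_profile(mat, st.arm_table)
        clones = cc.define_clones(prof, 0.10, 20)
        acc = match_partition_accuracy(truth.clone_labels[mat.cell_ids], clones.labels)
        frac_assigned = (clones.labels >= 0).mean()
        assert acc * frac_assigned >= 0.95

    def test_noise_free_recovery_exact(self, three_clone_structure):
        st = three_clone_structure
        seg, regions, qc, truth = sd.simulate_cnv_cells(st, 200, 0.0, 0.0, seed=3)
        mat = cc.consensus_region_cn(seg, regions)
        prof = cc.arm_profile(mat, st.arm_table)
        clones = cc.define_clones(prof, 0.10, 5)
        assert (clones.labels >= 0).all()
        assert match_partition_accuracy(truth.clone_labels, clones.labels) == 1.0
        # signatures equal planted arm CN restricted to discriminating arms
        planted = {
            tuple(st.arm_cn.loc[c, clones.discriminating_arms]) for c in range(3)
        }
        called = {tuple(r) for r in clones.signatures.to_numpy()}
        assert called == planted

    def test_label_stability_under_cell_permutation(self, three_clone_structure):
        st = three_clone_structure
        seg, regions, qc, truth = sd.simulate_cnv_cells(st, 100, 0.0, 0.0, seed=4)
        mat = cc.consensus_region_cn(seg, regions)
        prof = cc.arm_profile(mat, st.arm_table)
        a = cc.define_clones(prof, 0.10, 5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.n_cells)
        mat2 = CellRegionMatrix(mat.cn[perm], mat.cell_ids[perm], mat.regions)
        b = cc.define_clones(cc.arm_profile(mat2, st.arm_table), 0.10, 5)
        order = {c: l for c, l in zip(mat2.cell_ids, b.labels)}
        relabeled = np.array([order[c] for c in mat.cell_ids])
        np.testing.assert_array_equal(a.labels, relabeled)
        pd.testing.assert_frame_equal(a.signatures, b.signatures)


class TestPseudobulk:
    def _matrix(self, cn_rows, arm_table):
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        cn = np.asarray(cn_rows)
        mat = CellRegionMatrix(cn, np.arange(len(cn)), regions)
        prof = cc.arm_profile(mat, arm_table)
        return mat, cc.estimate_ploidy(prof)

    def test_uniform_amplification_scores_zero(self, arm_table):
        import warnings

        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        cn = np.full((5, 8), 2)
        cn[:, 0] = 4  # all cells amplified on one region
        mat = CellRegionMatrix(cn, np.arange(5), regions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ploidy = cc.PloidyEstimate(
                np.full(5, 2.0), np.arange(5), 2.0, 0.0, np.ones(5, bool)
            )
        out = cc.pseudobulk_profile(mat, ploidy)
        assert out.ratio.iloc[0] == pytest.approx(2.0)
        assert out.heterogeneity.iloc[0] == pytest.approx(0.0)
        assert out.modal_state.iloc[0] == "amplified"

    def test_half_half_entropy(self, arm_table):
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        cn = np.full((10, 8), 2)
        cn[:5, 0] = 4
        mat = CellRegionMatrix(cn, np.arange(10), regions)
        ploidy = cc.PloidyEstimate(np.full(10, 2.0), np.arange(10), 2.0, 0.0,
                                   np.ones(10, bool))
        out = cc.pseudobulk_profile(mat, ploidy)
        assert out.heterogeneity.iloc[0] == pytest.approx(np.log(2) / np.log(3))

    def test_equal_thirds_maximal_entropy(self, arm_table):
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        cn = np.full((9, 8), 2)
        cn[:3, 0] = 0
        cn[3:6, 0] = 2
        cn[6:, 0] = 4
        mat = CellRegionMatrix(cn, np.arange(9), regions)
        ploidy = cc.PloidyEstimate(np.full(9, 2.0), np.arange(9), 2.0, 0.0,
                                   np.ones(9, bool))
        out = cc.pseudobulk_profile(mat, ploidy)
        assert out.heterogeneity.iloc[0] == pytest.approx(1.0)

    def test_heterogeneity_bounds(self, arm_table):
        rng = np.random.default_rng(5)
        regions = sd.mappable_regions_for(arm_table, 20_000_000)
        cn = rng.integers(0, 6, size=(30, 8))
        mat = CellRegionMatrix(cn, np.arange(30), regions)
        ploidy = cc.PloidyEstimate(np.full(30, 2.0), np.arange(30), 2.0, 0.0,
                                   np.ones(30, bool))
        out = cc.pseudobulk_profile(mat, ploidy)
        assert ((out.heterogeneity >= 0) & (out.heterogeneity <= 1.0 + 1e-12)).all()


class TestGeneLocusStats:
    def test_amplified_fraction_counts(self, arm_table):
        # 10 cells at ploidy 2; 7 with gene CN 4 (> 2 + 1), 3 with CN 2
        rows = []
        for cell in range(10):
            cn = 4 if cell < 7 else 2
            rows.append(("chr1", 0, 5_000_000, cell, cn))
        seg = seg_frame(rows)
        genes = pd.DataFrame(
            [("TP53", "TP53", "chr1", 1_000_000, 1_010_000, "+")],
            columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"],
        )
        qc = pd.DataFrame(
            {"barcode": [f"c{i}" for i in range(10)], "cell_id": range(10),
             "mean_ploidy": [2.0] * 10, "is_noisy": [False] * 10}
        )
        table, stats = cc.gene_locus_stats(seg, genes, qc)
        assert stats.amplified_fraction.iloc[0] == pytest.approx(0.7)
        assert table.shape == (10, 1)

    def test_subsample_cap(self, arm_table):
        rows = [("chr1", 0, 5_000_000, cell, 2) for cell in range(8)]
        seg = seg_frame(rows)
        genes = pd.DataFrame(
            [("G", "G", "chr1", 0, 10_000, "+")],
            columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"],
        )
        qc = pd.DataFrame(
            {"barcode": [f"c{i}" for i in range(8)], "cell_id": range(8),
             "mean_ploidy": [2.0] * 8, "is_noisy": [False] * 8}
        )
        table, _ = cc.gene_locus_stats(seg, genes, qc, subsample_n=1000)
        assert len(table) == 8  # cap: fewer cells than requested uses all
        table2, _ = cc.gene_locus_stats(seg, genes, qc, subsample_n=3, seed=1)
        assert len(table2) == 3

    def test_noisy_and_haploid_excluded(self):
        rows = [("chr1", 0, 5_000_000, cell, 2) for cell in range(4)]
        seg = seg_frame(rows)
        genes = pd.DataFrame(
            [("G", "G", "chr1", 0, 10_000, "+")],
            columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"],
        )
        qc = pd.DataFrame(
            {"barcode": list("abcd"), "cell_id": range(4),
             "mean_ploidy": [2.0, 1.2, 2.0, 2.0],
             "is_noisy": [False, False, True, False]}
        )
        table, stats = cc.gene_locus_stats(seg, genes, qc)
        assert set(table.index) == {0, 3}
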