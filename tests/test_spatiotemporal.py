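"""Temporal ratios, wave assignment, zone profiles and UPGMA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from nodentropy import (
    assign_waves,
    heatmap_matrix,
    hierarchical_cluster,
    temporal_ratios,
    timepoint_correlation,
    zone_relative_profile,
)
from nodentropy.compendium_io import Compendium, MappingError, ValidationError
from nodentropy.spatiotemporal import timecourse_means


def timecourse_compendium(rows, dpis=(0, 3, 4, 6, 10, 14, 28), gene_ids=None):
    """One condition per dpi (no replication) for rule-level tests."""
    rows = np.asarray(rows, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(1, len(rows) + 1)]
    cids = [f"tc_{d:g}dpi" for d in dpis]
    signals = pd.DataFrame(rows, index=gene_ids, columns=cids)
    meta = pd.DataFrame(
        {
            "organ": ["root" if d <= 3 else "nodule" for d in dpis],
            "treatment": "none",
            "timepoint": list(dpis),
            "timepoint_unit": "dpi",
            "sample_class": "whole_organ",
            "replicate_group": cids,
        },
        index=pd.Index(cids, name="condition_id"),
    )
    return Compendium(signals, meta)


def zone_compendium(rows, gene_ids=None):
    from nodentropy.compendium_io import ZONE_CLASSES

    rows = np.asarray(rows, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(1, len(rows) + 1)]
    cids = list(ZONE_CLASSES)
    signals = pd.DataFrame(rows, index=gene_ids, columns=cids)
    meta = pd.DataFrame(
        {
            "organ": "nodule",
            "treatment": "none",
            "timepoint": 28,
            "timepoint_unit": "dpi",
            "sample_class": cids,
            "replicate_group": cids,
        },
        index=pd.Index(cids, name="condition_id"),
    )
    return Compendium(signals, meta)


class TestTemporalRatios:
    def test_simple_ratio(self):
        comp = timecourse_compendium([[9, 9, 5000, 8000, 9500, 10000, 10000]])
        ratios = temporal_ratios(comp)
        assert ratios.ratios.loc["g1", 4.0] == pytest.approx(0.5)
        assert ratios.ratios.loc["g1", 10.0] == pytest.approx(0.95)

    def test_constant_gene_all_ratios_one(self):
        comp = timecourse_compendium([[100] * 7])
        ratios = temporal_ratios(comp, timepoints=(4, 6, 10), reference=14)
        np.testing.assert_allclose(ratios.ratios.loc["g1"], 1.0)

    def test_missing_timepoint_named(self):
        comp = timecourse_compendium([[1, 2, 3]], dpis=(0, 4, 14))
        with pytest.raises(MappingError, match="6"):
            temporal_ratios(comp, timepoints=(4, 6), reference=14)

    def test_replicates_averaged_before_ratio(self, compendium):
        means = timecourse_means(compendium)
        meta = compendium.conditions
        reps = meta.index[meta["replicate_group"] == "nodule_4dpi"]
        np.testing.assert_allclose(
            means[4.0], compendium.signals[list(reps)].mean(axis=1)
        )

    def test_wave3_lags_wave1_at_4dpi(self, compendium, truth):
        ratios = temporal_ratios(compendium)
        fam = truth.genes[truth.genes["family"]]
        w1 = ratios.ratios.loc[fam.index[fam["wave"] == "1"], 4.0]
        w3 = ratios.ratios.loc[fam.index[fam["wave"] == "3"], 4.0]
        assert w3.median() < w1.median()


class TestTimepointCorrelation:
    def test_identical_and_opposed_vectors(self):
        comp = timecourse_compendium(
            [[1, 1, 5, 9, 9, 9, 9], [2, 2, 6, 1, 1, 1, 1], [3, 3, 1, 5, 5, 5, 5]]
        )
        corr = timepoint_correlation(comp, timepoints=(0, 3, 14))
        assert corr.loc[0.0, 3.0] == pytest.approx(1.0)
        assert corr.loc[0.0, 0.0] == 1.0
        # symmetric
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_anticorrelated_pair(self):
        comp = timecourse_compendium([[1, 5, 0, 0, 0, 0, 0], [5, 1, 0, 0, 0, 0, 0]])
        corr = timepoint_correlation(comp, timepoints=(0, 3))
        assert corr.loc[0.0, 3.0] == pytest.approx(-1.0)

    def test_zero_variance_vector_gives_na(self):
        comp = timecourse_compendium([[7, 1, 0, 0, 0, 0, 0], [7, 5, 0, 0, 0, 0, 0]])
        corr = timepoint_correlation(comp, timepoints=(0, 3))
        assert np.isnan(corr.loc[0.0, 3.0])
        assert corr.loc[0.0, 0.0] == 1.0

    def test_family_correlation_block_structure(self, compendium, truth):
        """Adjacent stages correlate strongly; early vs late does not.

        The pre-activation stages (0, 3 dpi) and the fully active stages
        (10, 14 dpi) each form a near-unit correlation block, while the
        0/3 dpi transcriptome is uncorrelated with the mature one.
        Thresholds derived from the generator's noise model (replicate-
        averaged CV 0.115 bounds attainable r at 0.987).
        """
        corr = timepoint_correlation(compendium, gene_subset=truth.family_genes)
        assert corr.loc[0.0, 3.0] > 0.95
        assert corr.loc[10.0, 14.0] > 0.90
        assert corr.loc[3.0, 14.0] < 0.5
        vals = corr.to_numpy()
        # symmetric PSD up to numerical tolerance
        np.testing.assert_allclose(vals, vals.T, atol=1e-12)
        assert np.linalg.eigvalsh(vals).min() > -1e-9


class TestZoneProfile:
    def test_flat_gene_maps_to_zero(self):
        profile = zone_relative_profile(zone_compendium([[10, 10, 10, 10, 10]]))
        np.testing.assert_allclose(profile.values.iloc[0], 0.0, atol=1e-12)

    def test_double_mean_gives_plus_one(self):
        profile = zone_relative_profile(zone_compendium([[16, 8, 4, 2, 2]]))
        row = profile.values.iloc[0]
        assert row.iloc[0] == pytest.approx(np.log2(16 / 6.4), abs=1e-12)
        assert row.iloc[0] == pytest.approx(1.3219280948873622, abs=1e-12)
        comp2 = zone_compendium([[4, 2, 2, 1, 1]])  # zone I at 2x the mean
        assert zone_relative_profile(comp2).values.iloc[0, 0] == pytest.approx(1.0)

    def test_back_transform_has_unit_mean(self, compendium):
        profile = zone_relative_profile(compendium)
        back = np.exp2(profile.values[profile.defined])
        np.testing.assert_allclose(back.mean(axis=1), 1.0, rtol=1e-9)

    def test_missing_zone_named(self):
        comp = timecourse_compendium([[1, 2, 3, 4, 5, 6, 7]])
        with pytest.raises(MappingError, match="zone_I"):
            zone_relative_profile(comp)

    def test_wave_to_zone_correspondence(self, compendium, truth):
        """Wave-1 genes peak apically, wave-3 genes proximally."""
        profile = zone_relative_profile(compendium)
        fam = truth.genes[truth.genes["family"]]
        w1 = profile.values.loc[fam.index[fam["wave"] == "1"]]
        w3 = profile.values.loc[fam.index[fam["wave"] == "3"]]
        assert w1["zone_I"].median() > w3["zone_I"].median()
        assert w3["zone_III"].median() > w1["zone_III"].median()


class TestAssignWaves:
    def test_rule_on_constructed_profiles(self):
        comp = timecourse_compendium(
            [
                [9, 9, 10000, 10000, 10000, 10000, 10000],  # full from 4 dpi
                [9, 9, 500, 6000, 9000, 10000, 10000],      # on at 6 dpi
                [9, 9, 9, 20, 8000, 10000, 10000],          # on at 10 dpi
                [9, 9, 9, 9, 9, 9, 9],                      # never above floor
                [9, 9, 8000, 8000, 8000, 8000, 100],        # declining at 28
            ]
        )
        waves = assign_waves(temporal_ratios(comp))
        frame = waves.frame
        assert list(frame["wave"]) == ["1", "2", "3", "unassigned", "1"]
        assert frame.loc["g1", "maintenance"] == "maintained"
        assert frame.loc["g5", "maintenance"] == "declining"
        assert frame.loc["g1", "activation_dpi"] == 4.0
        assert np.isnan(frame.loc["g4", "activation_dpi"])

    def test_increasing_activation_fraction_never_moves_wave_earlier(self):
        rng = np.random.default_rng(5)
        rows = rng.uniform(0, 1000, size=(40, 7))
        comp = timecourse_compendium(rows)
        order = {"1": 1, "2": 2, "3": 3, "unassigned": 4}
        previous = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            waves = assign_waves(temporal_ratios(comp), activation_fraction=frac)
            codes = waves.frame["wave"].map(order)
            if previous is not None:
                assert (codes >= previous).all()
            previous = codes

    def test_planted_wave_recovery(self, compendium, truth):
        """>=90% of planted family genes get their planted wave label."""
        waves = assign_waves(temporal_ratios(compendium))
        fam = truth.family_genes
        called = waves.frame.loc[fam, "wave"]
        planted = truth.genes.loc[fam, "wave"]
        assert (called == planted).mean() >= 0.90


def brute_force_upgma(matrix, metric="euclidean"):
    """Independent average-linkage oracle.

    Maintains explicit clusters and recomputes every inter-cluster average
    distance from the original pairwise matrix at each step (no
    Lance-Williams update), so it shares no code path with the package.
    """
    n = len(matrix)
    base = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if metric == "euclidean":
            d = float(np.linalg.norm(matrix[i] - matrix[j]))
        else:
            d = 1.0 - float(np.corrcoef(matrix[i], matrix[j])[0, 1])
        base[i, j] = base[j, i] = d
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([base[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        frame = pd.DataFrame(
            [[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]], index=["a", "b", "c"]
        )
        dendro = hierarchical_cluster(frame)
        left, right, height = dendro.merges[0]
        assert {left, right} == {0, 2}
        assert height == 0.0

    def test_four_points_on_a_line(self):
        frame = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]])
        dendro = hierarchical_cluster(frame)
        heights = [m[2] for m in dendro.merges]
        assert heights == pytest.approx([1.0, 1.0, 10.0])
        # tie at height 1: the pair containing row 0 merges first
        assert {dendro.merges[0][0], dendro.merges[0][1]} == {0, 1}

    def test_permutation_invariance_up_to_tie_break(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(7, 4))
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(7)])
        perm = [3, 0, 6, 1, 5, 2, 4]
        shuffled = frame.iloc[perm]
        a = hierarchical_cluster(frame)
        b = hierarchical_cluster(shuffled)
        assert sorted(m[2] for m in a.merges) == pytest.approx(
            sorted(m[2] for m in b.merges)
        )
        assert sorted(a.leaf_order) == sorted(b.leaf_order)

    @pytest.mark.parametrize("metric", ["euclidean", "pearson"])
    def test_merge_heights_match_brute_force(self, metric):
        rng = np.random.default_rng(123)
        for _ in range(20):
            values = rng.normal(size=(6, 4))
            frame = pd.DataFrame(values)
            dendro = hierarchical_cluster(frame, distance=metric)
            expected = brute_force_upgma(values, metric)
            got = [m[2] for m in dendro.merges]
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_merge_heights_match_scipy(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(12, 5))
        dendro = hierarchical_cluster(pd.DataFrame(values))
        link = hierarchy.linkage(values, method="average", metric="euclidean")
        np.testing.assert_allclose(
            [m[2] for m in dendro.merges], link[:, 2], atol=1e-9
        )

    def test_heights_non_decreasing_and_leaves_complete(self, compendium, truth):
        profile = zone_relative_profile(compendium)
        fam = sorted(truth.family_genes)
        dendro = hierarchical_cluster(profile.values.loc[fam], distance="pearson")
        heights = [m[2] for m in dendro.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        assert sorted(dendro.leaf_order) == fam
        newick = dendro.to_newick()
        assert newick.endswith(";") and newick.count("(") == len(fam) - 1

    def test_zero_variance_row_rejected_under_pearson(self):
        frame = pd.DataFrame([[1.0, 1.0], [1.0, 2.0]], index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            hierarchical_cluster(frame, distance="pearson")


class TestHeatmapMatrix:
    def test_row_max_scaling(self):
        frame = pd.DataFrame([[0.0, 5.0, 10.0], [0.0, 0.0, 0.0]])
        scaled, flagged = heatmap_matrix(frame, "row_max")
        np.testing.assert_allclose(scaled.iloc[0], [0, 0.5, 1.0])
        np.testing.assert_allclose(scaled.iloc[1], 0.0)
        assert list(flagged) == [1]

    def test_none_is_identity(self):
        frame = pd.DataFrame([[1.0, 2.0]])
        scaled, flagged = heatmap_matrix(frame, "none")
        pd.testing.assert_frame_equal(scaled, frame)
        assert len(flagged) == 0

    def test_log2_ratio_matches_zone_profile(self, compendium):
        profile = zone_relative_profile(compendium)
        scaled, _ = heatmap_matrix(profile.zone_means, "log2_ratio")
        defined = profile.defined
        np.testing.assert_allclose(
            scaled[defined].to_numpy(), profile.values[defined].to_numpy(), rtol=1e-9
        )
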