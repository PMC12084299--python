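"""Interaction counting, permutation testing and association analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imcspace as m
from conftest import random_typed_roi
from test_neighborhoods import brute_force_knn


class TestCountInteractions:
    def test_hand_counted_toy(self):
        """Two A cells whose windows contain {A,A,B,B} and {A,B,B,B}:
        mean A->B = (2 + 3) / 2 = 2.5."""
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, 8),
                "roi_id": "r",
                # A at x=0 with neighbors A(1),B(2),B(3); A at x=10 with B,B,B
                "x": [0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                "y": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 13.0],
                "cell_type": ["A", "A", "B", "B", "A", "B", "B"],
            }
        )
        g = m.spatial_knn(cells, k=3)
        counts = m.count_interactions(g, cells)
        ab = counts[(counts.from_type == "A") & (counts.to_type == "B")]
        win = m.neighborhoods.window_indices(g.per_roi["r"])
        types = cells.cell_type.to_numpy()
        expected = np.mean(
            [(types[w] == "B").sum() for w, t in zip(win, types) if t == "A"]
        )
        assert ab.observed.iloc[0] == pytest.approx(expected)

    def test_matches_brute_force_double_loop(self):
        cells = random_typed_roi(11, n=300)
        g = m.spatial_knn(cells, k=20)
        counts = m.count_interactions(g, cells)
        oracle_nbrs = brute_force_knn(cells, 20)["r1"]
        types = cells.cell_type.to_numpy()
        for row in counts.itertuples():
            vals = [
                sum(types[j] == row.to_type for j in [i] + oracle_nbrs[i])
                for i in range(len(cells))
                if types[i] == row.from_type
            ]
            assert row.observed == pytest.approx(np.mean(vals))

    def test_single_type_saturation(self):
        cells = random_typed_roi(12, n=60, types=("A",))
        g = m.spatial_knn(cells, k=20)
        counts = m.count_interactions(g, cells)
        assert (counts.observed == 21).all()
        assert set(counts.to_type) == {"A"}  # A->other pairs absent, not zero

    def test_count_conservation(self):
        """Summing mean counts over to_types returns the window size for
        every from_type."""
        cells = random_typed_roi(13, n=120)
        g = m.spatial_knn(cells, k=20)
        counts = m.count_interactions(g, cells)
        sums = counts.groupby("from_type")["observed"].sum()
        np.testing.assert_allclose(sums, 21.0, atol=1e-9)


class TestPermutationTest:
    def test_pvalue_floor_and_bounds(self, typed_roi):
        g = m.spatial_knn(typed_roi, k=10)
        res = m.permutation_test(g, typed_roi, n_perm=99, seed=0)
        assert (res.p_enrich >= 1 / 100).all()
        assert (res.p_avoid >= 1 / 100).all()
        assert (res.p_enrich <= 1).all()
        assert (res.p_avoid <= 1).all()
        assert (res.p_enrich + res.p_avoid >= 1 - 1e-12).all()

    def test_deterministic_under_seed(self, typed_roi):
        g = m.spatial_knn(typed_roi, k=10)
        a = m.permutation_test(g, typed_roi, n_perm=49, seed=5)
        b = m.permutation_test(g, typed_roi, n_perm=49, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_preserves_label_multiset(self):
        """The machinery shuffles labels within the ROI: the null mean of
        the all-pairs count total matches the fixed window size."""
        cells = random_typed_roi(14, n=90, types=("A", "B"))
        g = m.spatial_knn(cells, k=10)
        res = m.permutation_test(g, cells, n_perm=60, seed=1)
        total = res.groupby("from_type").null_mean.sum()
        np.testing.assert_allclose(total, 11.0, atol=1e-9)

    def test_single_type_roi_skipped_with_warning(self):
        cells = random_typed_roi(15, n=40, types=("A",))
        g = m.spatial_knn(cells, k=5)
        with pytest.warns(RuntimeWarning, match="fewer than 2"):
            res = m.permutation_test(g, cells, n_perm=19, seed=0)
        assert len(res) == 0

    def test_null_calibration_on_csr(self):
        """Under CSR with random labels the empirical rejection rate of
        p_enrich < 0.05 stays inside the 95% binomial band. One directed
        pair per ROI keeps the replicates independent (100 ROIs here; the
        full 400-ROI check runs in the acceptance suite)."""
        rng = np.random.default_rng(3)
        rej = tot = 0
        for rep in range(100):
            n = 300
            cells = pd.DataFrame(
                {
                    "cell_id": np.arange(1, n + 1),
                    "roi_id": "r",
                    "x": rng.uniform(0, 300, n),
                    "y": rng.uniform(0, 300, n),
                    "cell_type": rng.choice(["A", "B"], n),
                }
            )
            g = m.spatial_knn(cells, k=20)
            res = m.permutation_test(g, cells, n_perm=199, seed=rep)
            row = res[(res.from_type == "A") & (res.to_type == "B")]
            rej += int(row.p_enrich.iloc[0] < 0.05)
            tot += 1
        lo, hi = stats.binom.interval(0.95, tot, 0.05)
        assert lo <= rej <= hi

    def test_planted_attraction_detected(self):
        spec = m.SyntheticCohortSpec(
            n_samples_per_group={"g": 1},
            rois_per_sample=1,
            attraction_pairs=[m.AttractionPair("macrophage", "CD8+ T", 15.0, 5)],
            proportions={"g": dict(m.synthetic.DEFAULT_PROPORTIONS["pSS"])},
        )
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            pts = m.sample_roi_points(spec, "g", 100 + rep)
            pts["cell_id"] = np.arange(1, len(pts) + 1)
            pts["roi_id"] = "r"
            pts["cell_type"] = pts["true_type"]
            g = m.spatial_knn(pts, k=20)
            res = m.permutation_test(g, pts, n_perm=199, seed=rep)
            row = res[(res.from_type == "CD8+ T") & (res.to_type == "macrophage")]
            hits += bool(len(row)) and (row.classification == "interaction").all()
        assert hits / n_rep >= 0.8

    def test_planted_avoidance_detected(self):
        spec = m.SyntheticCohortSpec(
            n_samples_per_group={"g": 1},
            rois_per_sample=1,
            avoidance_pairs=[m.AvoidancePair("macrophage", "B", 40.0)],
            proportions={"g": dict(m.synthetic.DEFAULT_PROPORTIONS["pSS"])},
        )
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            pts = m.sample_roi_points(spec, "g", 200 + rep)
            pts["cell_id"] = np.arange(1, len(pts) + 1)
            pts["roi_id"] = "r"
            pts["cell_type"] = pts["true_type"]
            g = m.spatial_knn(pts, k=20)
            res = m.permutation_test(g, pts, n_perm=199, seed=rep)
            row = res[(res.from_type == "B") & (res.to_type == "macrophage")]
            hits += bool(len(row)) and (row.classification == "avoidance").all()
        assert hits / n_rep >= 0.8


class TestCompareGroups:
    @staticmethod
    def results_from(values: dict[str, list[float]]):
        rows = []
        for group, obs in values.items():
            for i, v in enumerate(obs):
                rows.append(
                    {
                        "roi_id": f"{group}_{i}",
                        "from_type": "A",
                        "to_type": "B",
                        "observed": v,
                    }
                )
        res = pd.DataFrame(rows)
        groups = {f"{g}_{i}": g for g, obs in values.items() for i in range(len(obs))}
        return res, groups

    def test_equal_means_give_t_zero_p_one(self):
        res, groups = self.results_from({"g1": [2.0, 2.0, 2.0], "g2": [2.0, 2.0, 2.0]})
        out = m.compare_interactions_groups(res, groups)
        assert out.t.iloc[0] == 0.0
        assert out.p_value.iloc[0] == 1.0
        assert out.degenerate.iloc[0]

    def test_symmetric_under_group_relabeling(self):
        res, groups = self.results_from({"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 6.0]})
        out1 = m.compare_interactions_groups(res, groups)
        flipped = {k: ("b" if v == "a" else "a") for k, v in groups.items()}
        out2 = m.compare_interactions_groups(res, flipped)
        assert out1.p_value.iloc[0] == pytest.approx(out2.p_value.iloc[0])
        assert out1.direction.iloc[0] == -out2.direction.iloc[0]

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            res, groups = self.results_from(
                {"a": list(rng.normal(2, 1, 8)), "b": list(rng.normal(2, 1, 8))}
            )
            out = m.compare_interactions_groups(res, groups)
            rej += out.p_value.iloc[0] < 0.05
        assert rej / n_rep <= 0.07

    def test_planted_group_difference_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            res, groups = self.results_from(
                {"a": list(rng.normal(2, 0.5, 8)), "b": list(rng.normal(3, 0.5, 8))}
            )
            out = m.compare_interactions_groups(res, groups)
            hits += out.p_value.iloc[0] < 0.05
        assert hits / n_rep >= 0.8


class TestDensityQuartiles:
    @staticmethod
    def cohort(densities, marker_by_density=None, seed=0, cells_per_roi=50):
        rng = np.random.default_rng(seed)
        frames = []
        for i, d in enumerate(densities):
            n_target = d
            n_other = cells_per_roi - n_target
            types = ["CD8+ T"] * n_target + ["epithelial"] * n_other
            marker = (
                np.linspace(0, marker_by_density(d), cells_per_roi)
                if marker_by_density
                else rng.uniform(0, 1, cells_per_roi)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(cells_per_roi),
                        "roi_id": f"img{i:02d}",
                        "cell_type": types,
                        "norm_GranzymeB": marker,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_rank_split_with_absent_bin(self):
        cells = self.cohort([0, 0, 1, 2, 3, 4, 5, 6])
        image_table, _ = m.density_quartile_association(
            cells, "CD8+ T", ["GranzymeB"]
        )
        sizes = image_table.groupby("bin_rank").size()
        assert list(sizes) == [2, 2, 2, 2]
        assert (image_table.loc[image_table.bin_rank == 0, "bin"] == "absent").all()

    def test_monotone_marker_gives_rho_one(self):
        # per-image marker grid widens with density, so the positive
        # fraction rises strictly across bins
        cells = self.cohort(
            [0, 1, 2, 3, 6, 9, 12, 15],
            marker_by_density=lambda d: 0.55 + 0.05 * d,
        )
        _, trend = m.density_quartile_association(cells, "CD8+ T", ["GranzymeB"])
        assert trend.spearman_rho.iloc[0] == pytest.approx(1.0)

    def test_null_trend_rejection_at_most_nominal(self):
        """With 4 bins the exact two-sided Spearman p can never drop below
        0.05, so the null rejection rate is 0 <= nominal."""
        rej = 0
        for rep in range(50):
            cells = self.cohort([0, 1, 2, 3, 4, 5, 6, 7], seed=rep)
            _, trend = m.density_quartile_association(cells, "CD8+ T", ["GranzymeB"])
            rej += (trend.trend_p < 0.05).any()
        assert rej == 0

    def test_too_few_images_rejected(self):
        cells = self.cohort([1, 2, 3])
        with pytest.raises(ValueError, match="at least 4"):
            m.density_quartile_association(cells, "CD8+ T", ["GranzymeB"])


class TestCompositionCorrelation:
    def test_two_type_complement_gives_minus_one(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.2, 0.8, 10)
        fractions = pd.DataFrame({"epithelial": a, "immune": 1 - a})
        out = m.composition_correlation(fractions, "epithelial")
        assert out.r.iloc[0] == pytest.approx(-1.0)

    def test_constant_anchor_gives_na(self):
        fractions = pd.DataFrame(
            {"epithelial": [0.5, 0.5, 0.5], "B": [0.2, 0.3, 0.1], "T": [0.3, 0.2, 0.4]}
        )
        out = m.composition_correlation(fractions, "epithelial")
        assert out.r.isna().all()

    def test_matches_closed_form_covariance(self):
        rng = np.random.default_rng(7)
        raw = rng.dirichlet([2, 3, 4], size=30)
        fractions = pd.DataFrame(raw, columns=["epithelial", "B", "T"])
        out = m.composition_correlation(fractions, "epithelial")
        x = raw[:, 0]
        for i, ct in enumerate(["B", "T"], start=1):
            y = raw[:, i]
            r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            got = out.loc[out.cell_type == ct, "r"].iloc[0]
            assert got == pytest.approx(r_oracle, abs=1e-12)

    def test_spearman_option(self):
        rng = np.random.default_rng(8)
        raw = rng.dirichlet([2, 3], size=12)
        fractions = pd.DataFrame(raw, columns=["epithelial", "B"])
        out = m.composition_correlation(fractions, "epithelial", method="spearman")
        assert out.r.iloc[0] == pytest.approx(-1.0)
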