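"""Marker discovery, reference building, and simplex-QP proportion recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twindmr as t
from twindmr.deconvolution import (
    build_reference,
    compare_proportions,
    estimate_proportions,
    find_cell_type_dmrs,
    proportion_covariates,
    select_informative,
    solve_simplex_qp,
    CellReferenceProfile,
    MarkerInterval,
)


@pytest.fixture(scope="module")
def noiseless_panel():
    design = t.generate_array_design(100, (8, 12), 0.0, seed=51)
    panel, labels, truth = t.generate_cell_reference(
        design, n_marker_regions=40, n_replicates=2, noise_sd=0.0, seed=52
    )
    return design, panel, labels, truth


class TestMarkerDiscovery:
    def test_noiseless_markers_cover_planted_regions_exactly(self, noiseless_panel):
        design, panel, labels, truth = noiseless_panel
        markers = find_cell_type_dmrs(panel, labels, design)
        table = design.analysis_table()
        found_regions = set()
        for mk in markers:
            probes = table[(table["pos"] >= mk.start) & (table["pos"] <= mk.end)]
            found_regions.update(probes["region_id"].unique())
        assert found_regions == set(int(r) for r in truth.marker_region_ids)

    def test_identical_cell_types_yield_no_markers(self):
        design = t.generate_array_design(30, (8, 12), 0.0, seed=53)
        panel, labels, truth = t.generate_cell_reference(
            design, n_marker_regions=0, n_replicates=2, noise_sd=0.0, seed=54
        )
        assert find_cell_type_dmrs(panel, labels, design) == []

    def test_overlapping_contrast_candidates_merged(self, noiseless_panel):
        design, panel, labels, truth = noiseless_panel
        markers = find_cell_type_dmrs(panel, labels, design)
        # oracle: the pooled list must be pairwise disjoint after union-merge
        by_chrom = {}
        for mk in markers:
            by_chrom.setdefault(mk.chrom, []).append((mk.start, mk.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 > e1

    def test_absent_cell_type_rejected(self, noiseless_panel):
        design, panel, labels, _ = noiseless_panel
        with pytest.raises(ValueError, match="absent"):
            find_cell_type_dmrs(panel, labels, design, cell_types=["neutrophil", "basophil"])


class TestReference:
    def test_entries_are_plain_averages(self):
        meth = t.MethylationMatrix(
            pd.DataFrame({"a_rep1": [0.2, 0.4], "b_rep1": [0.6, 0.8]}, index=["p0", "p1"])
        )
        markers = [MarkerInterval("chr1", 1, 10, 0, np.array(["p0", "p1"]))]
        ref = build_reference(meth, markers, ["a", "b"])
        assert ref.B.loc["a", "m0"] == pytest.approx(0.3)
        assert ref.B.loc["b", "m0"] == pytest.approx(0.7)

    def test_single_probe_single_replicate(self):
        meth = t.MethylationMatrix(pd.DataFrame({"a_rep1": [0.42]}, index=["p0"]))
        markers = [MarkerInterval("chr1", 1, 10, 0, np.array(["p0"]))]
        ref = build_reference(meth, markers, ["a"])
        assert ref.B.loc["a", "m0"] == pytest.approx(0.42)

    def test_noiseless_reference_matches_truth(self, noiseless_panel):
        design, panel, labels, truth = noiseless_panel
        markers = find_cell_type_dmrs(panel, labels, design)
        ref = build_reference(panel, markers, labels)
        for j, mk in enumerate(ref.markers):
            true_means = truth.profiles[list(mk.probe_ids)].mean(axis=1)
            np.testing.assert_allclose(
                ref.B.iloc[:, j].to_numpy(), true_means.to_numpy(), atol=1e-9
            )

    def test_empty_markers_rejected(self, noiseless_panel):
        _, panel, labels, _ = noiseless_panel
        with pytest.raises(ValueError, match="non-empty"):
            build_reference(panel, [], labels)


class TestSelectInformative:
    def test_identity_when_k_covers_all(self, noiseless_panel):
        design, panel, labels, _ = noiseless_panel
        markers = find_cell_type_dmrs(panel, labels, design)
        ref = build_reference(panel, markers, labels)
        sel = select_informative(ref, panel, labels, k=len(markers))
        pd.testing.assert_frame_equal(sel.B, ref.B)

    def test_zero_variance_marker_ranked_last(self, noiseless_panel):
        design, panel, labels, _ = noiseless_panel
        markers = find_cell_type_dmrs(panel, labels, design)
        # add a flat marker: every cell type identical there
        table = design.analysis_table()
        flat_region = table.loc[~table["region_id"].isin(
            [mk.region_id for mk in markers]), "region_id"].iloc[0]
        probes = table.loc[table["region_id"] == flat_region, "probe_id"].to_numpy()
        flat = MarkerInterval("chr1", 0, 0, int(flat_region), probes)
        ref = build_reference(panel, markers + [flat], labels)
        sel = select_informative(ref, panel, labels, k=len(markers))
        assert flat_region not in [mk.region_id for mk in sel.markers]

    def test_matches_anova_oracle(self, noiseless_panel):
        design, panel, labels, _ = noiseless_panel
        rng = np.random.default_rng(55)
        noisy = t.MethylationMatrix(
            (panel.data + rng.normal(0, 0.02, size=panel.data.shape)).clip(0, 1)
        )
        markers = find_cell_type_dmrs(panel, labels, design)
        ref = build_reference(noisy, markers, labels)
        sel = select_informative(ref, noisy, labels, k=10)
        # oracle: per-marker one-way ANOVA F on the noisy panel, top 10
        lab = np.asarray(labels)
        fs = []
        for mk in markers:
            x = noisy.data.loc[list(mk.probe_ids)].to_numpy().mean(axis=0)
            f, _ = stats.f_oneway(*[x[lab == ct] for ct in dict.fromkeys(labels)])
            fs.append(f)
        top = np.argsort(-np.asarray(fs), kind="mergesort")[:10]
        expected = {markers[i].start for i in top}
        assert {mk.start for mk in sel.markers} == expected


def grid_search_simplex(B, x, step=0.001, coarse=0.02):
    """Independent QP oracle: coarse simplex grid then local refinement."""
    K = B.shape[0]

    def sweep(centers, width, s):
        best, best_obj = None, np.inf
        ticks = [np.arange(max(0.0, c - width), min(1.0, c + width) + s / 2, s) for c in centers]
        from itertools import product

        for combo in product(*ticks[:-1]):
            last = 1.0 - sum(combo)
            if last < -1e-9:
                continue
            w = np.array(list(combo) + [max(last, 0.0)])
            obj = np.sum((x - B.T @ w) ** 2)
            if obj < best_obj:
                best, best_obj = w, obj
        return best

    w0 = sweep(np.full(K, 0.5), 0.5, coarse)
    return sweep(w0, 2 * coarse, step)


class TestProportionQP:
    def _reference(self, K=4, M=30, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0.05, 0.95, size=(K, M))

    def test_pure_profile_recovers_unit_vector(self):
        B = self._reference()
        for k in range(4):
            w, r = solve_simplex_qp(B, B[k])
            expected = np.zeros(4)
            expected[k] = 1.0
            np.testing.assert_allclose(w, expected, atol=1e-9)
            assert r < 1e-9

    def test_two_component_mixture_matches_grid_oracle(self):
        B = self._reference(seed=1)
        x = 0.6 * B[0] + 0.4 * B[1]
        w, _ = solve_simplex_qp(B, x)
        np.testing.assert_allclose(w, [0.6, 0.4, 0.0, 0.0], atol=1e-6)
        w_grid = grid_search_simplex(B, x)
        np.testing.assert_allclose(w, w_grid, atol=0.002)

    def test_noiseless_mixture_recovery_exact(self):
        B = self._reference(seed=2)
        rng = np.random.default_rng(3)
        for _ in range(10):
            w_true = rng.dirichlet(np.ones(4))
            w, _ = solve_simplex_qp(B, B.T @ w_true)
            np.testing.assert_allclose(w, w_true, atol=1e-8)

    def test_kkt_no_descent_direction_on_simplex(self):
        B = self._reference(seed=4)
        rng = np.random.default_rng(5)
        x = B.T @ rng.dirichlet(np.ones(4)) + rng.normal(0, 0.05, size=B.shape[1])
        w, _ = solve_simplex_qp(B, x)
        obj = np.sum((x - B.T @ w) ** 2)
        for _ in range(500):
            step = rng.dirichlet(np.ones(4)) - w
            for eps in (1e-4, 1e-3):
                w2 = w + eps * step
                if np.all(w2 >= -1e-12):
                    assert np.sum((x - B.T @ w2) ** 2) >= obj - 1e-12

    def test_marker_order_invariance(self):
        B = self._reference(seed=6)
        rng = np.random.default_rng(7)
        x = B.T @ np.array([0.3, 0.3, 0.2, 0.2]) + rng.normal(0, 0.02, size=B.shape[1])
        w1, _ = solve_simplex_qp(B, x)
        perm = rng.permutation(B.shape[1])
        w2, _ = solve_simplex_qp(B[:, perm], x[perm])
        np.testing.assert_allclose(w1, w2, atol=1e-9)

    def test_underdetermined_rejected(self):
        ref = CellReferenceProfile(
            markers=[MarkerInterval("chr1", 1, 5, 0, np.array(["p0", "p1"]))] * 3,
            B=pd.DataFrame(np.full((4, 3), 0.5), index=list("abcd")),
        )
        means = pd.DataFrame([[0.5, np.nan, np.nan]], index=["s1"], columns=ref.B.columns)
        with pytest.raises(ValueError, match="usable markers"):
            estimate_proportions(means, ref)

    def test_end_to_end_mixture_mae(self, design500, panel500):
        panel, labels, truth = panel500
        mix = t.CellMixtureModel(panel, labels, design500).fit(k_markers=300)
        cfg = t.SimulationConfig(n_pairs=10, n_regions=500, noise_sd=0.02, seed=58)
        meth, _, gt = t.simulate_twin_cohort(design500, truth.profiles, cfg)
        est = mix.estimate(meth)
        err = np.abs(est.w.to_numpy() - gt.proportions.loc[est.w.index].to_numpy())
        assert err.mean() < 0.05


class TestCovariatesAndComparison:
    def test_covariate_triple_arithmetic(self):
        w = pd.DataFrame(
            [[0.5, 0.2, 0.2, 0.1]], index=["s1"],
            columns=["neutrophil", "CD4T", "CD8T", "CD56NK"],
        )
        cov = proportion_covariates(w)
        np.testing.assert_allclose(cov.loc["s1"], [0.5, 0.1, 0.4])

    def test_pure_neutrophil(self):
        w = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0]], index=["s1"],
            columns=["neutrophil", "CD4T", "CD8T", "CD56NK"],
        )
        np.testing.assert_allclose(proportion_covariates(w).loc["s1"], [1.0, 0.0, 0.0])

    def test_triple_sums_to_one(self):
        rng = np.random.default_rng(59)
        w = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=10),
            columns=["neutrophil", "CD4T", "CD8T", "CD56NK"],
        )
        np.testing.assert_allclose(proportion_covariates(w).sum(axis=1), 1.0, atol=1e-12)

    def test_unmappable_names_rejected(self):
        w = pd.DataFrame([[0.5, 0.5]], columns=["x", "y"])
        with pytest.raises(ValueError, match="mapping"):
            proportion_covariates(w)

    def test_identical_proportions_give_p_one(self):
        w = pd.DataFrame(
            np.tile([0.5, 0.2, 0.2, 0.1], (6, 1)),
            index=[f"s{i}" for i in range(6)],
            columns=["neutrophil", "CD4T", "CD8T", "CD56NK"],
        )
        res = compare_proportions(w, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res["p"] == 1.0).all()

    def test_matches_closed_form_paired_t(self):
        rng = np.random.default_rng(60)
        n = 5
        d = 0.1 + rng.normal(0, 1e-3, size=n)
        w = pd.DataFrame(
            {"neutrophil": np.concatenate([0.5 + d, np.full(n, 0.5)])},
            index=[f"c{i}" for i in range(n)] + [f"k{i}" for i in range(n)],
        )
        res = compare_proportions(
            w, [f"c{i}" for i in range(n)], [f"k{i}" for i in range(n)]
        )
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t_stat), n - 1)
        assert res.loc["neutrophil", "t"] == pytest.approx(t_stat, abs=1e-9)
        assert res.loc["neutrophil", "p"] == pytest.approx(p, abs=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(61)
        n_pairs, reps, alpha = 7, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            case = rng.normal(0.5, 0.05, size=n_pairs)
            ctrl = rng.normal(0.5, 0.05, size=n_pairs)
            t_stat, p = stats.ttest_rel(case, ctrl)
            rejections += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se

    def test_too_few_pairs_rejected(self):
        w = pd.DataFrame([[0.5], [0.5]], index=["a", "b"], columns=["neutrophil"])
        with pytest.raises(ValueError, match="pairs"):
            compare_proportions(w, ["a"], ["b"])
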