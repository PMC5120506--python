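"""Sign-flip permutation p-values, the exclusion filter, and stratified FWER."""

import itertools

import numpy as np
import pytest

import twindmr as t
from twindmr.dmr import CandidateDMR
from twindmr.significance import (
    FWERResult,
    PermutationResult,
    bootstrap_null,
    call_dmrs,
    pair_differences,
    permutation_filter,
    sign_flip_pvalue,
    stratified_fwer,
    within_pair_permutation_p,
)


def sign_flip_oracle(d):
    """Brute-force enumeration over all 2^n within-pair label assignments."""
    d = np.asarray(d, float)
    obs = abs(d.mean())
    count = total = 0
    for signs in itertools.product([1.0, -1.0], repeat=len(d)):
        total += 1
        if abs(np.mean(np.array(signs) * d)) >= obs * (1 - 1e-12):
            count += 1
    return count / total, total


class TestSignFlip:
    def test_assignment_counts_five_and_seven_pairs(self):
        _, n5, ex5 = sign_flip_pvalue(np.arange(1.0, 6.0))
        _, n7, ex7 = sign_flip_pvalue(np.arange(1.0, 8.0))
        assert (n5, ex5) == (32, True)
        assert (n7, ex7) == (128, True)

    def test_constant_differences_only_two_extremes(self):
        p, n, _ = sign_flip_pvalue(np.full(5, 0.1))
        assert n == 32
        assert p == pytest.approx(2 / 32)

    def test_outlier_pair_not_significant(self):
        # one extreme pair among nulls: every assignment reaches |0.2|
        p, _, _ = sign_flip_pvalue(np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
        assert p == 1.0

    @pytest.mark.parametrize("n_pairs", [2, 3, 5, 8, 10])
    def test_matches_enumeration_oracle(self, n_pairs):
        rng = np.random.default_rng(n_pairs)
        for _ in range(20):
            d = rng.normal(0, 0.1, size=n_pairs)
            p, n, exhaustive = sign_flip_pvalue(d, cap=2048)
            p_oracle, n_oracle = sign_flip_oracle(d)
            assert exhaustive == (n == n_oracle)
            if exhaustive:
                assert p == p_oracle

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.05, 0.1, size=8)
        p_ex, _, _ = sign_flip_pvalue(d, cap=4096)
        p_mc, n_mc, exhaustive = sign_flip_pvalue(d, cap=200, rng=np.random.default_rng(7))
        assert not exhaustive and n_mc == 200
        se = np.sqrt(p_ex * (1 - p_ex) / n_mc)
        assert abs(p_mc - p_ex) < 3 * se + 1 / n_mc

    def test_exhaustive_granularity(self):
        rng = np.random.default_rng(8)
        for n_pairs in (4, 5, 6):
            d = rng.normal(0, 1, size=n_pairs)
            p, n, _ = sign_flip_pvalue(d)
            assert (p * n) == int(round(p * n))  # multiple of 1/2^n

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sign_flip_pvalue(np.array([0.3]))


class TestCandidatePermutation:
    def _candidate(self, diffs, n_pairs=5):
        n = len(diffs)
        prop = np.full((n, 2 * n_pairs), 0.4)
        case_idx = np.arange(0, 2 * n_pairs, 2)
        control_idx = np.arange(1, 2 * n_pairs, 2)
        prop[:, case_idx] += np.asarray(diffs)[:, None]
        return np.arange(n), prop, case_idx, control_idx

    def test_summaries_feed_the_statistic(self):
        idx, prop, case_idx, control_idx = self._candidate([0.1, 0.2, 0.3])
        d_avg = pair_differences(idx, prop, case_idx, control_idx, "avg")
        d_max = pair_differences(idx, prop, case_idx, control_idx, "max")
        np.testing.assert_allclose(d_avg, 0.2)
        np.testing.assert_allclose(d_max, 0.3)

    def test_permutation_result_fields(self):
        idx, prop, case_idx, control_idx = self._candidate([0.1] * 4)
        res = within_pair_permutation_p(idx, prop, case_idx, control_idx)
        assert isinstance(res, PermutationResult)
        assert res.n_permutations == 32 and res.exhaustive
        assert res.p_avg == pytest.approx(2 / 32)

    def test_empty_candidate_rejected(self):
        _, prop, case_idx, control_idx = self._candidate([0.1])
        with pytest.raises(ValueError, match="no probes"):
            within_pair_permutation_p(np.array([], int), prop, case_idx, control_idx)


def _cand(nprobes=5, avg=0.1, p_avg=0.05, p_max=0.5, mx=None):
    c = CandidateDMR(
        chrom="chr1", start=100, end=400, region_id=0,
        probe_index=np.arange(nprobes), nprobes=nprobes,
        avg=avg, max=mx if mx is not None else avg, area_raw=nprobes * avg,
    )
    c.perm = PermutationResult(p_avg=p_avg, p_max=p_max, n_permutations=32, exhaustive=True)
    return c


class TestPermutationFilter:
    def test_conjunction_rule(self):
        keep_one = _cand(p_avg=0.05, p_max=0.5)  # only one exceeds: retained
        drop_both = _cand(p_avg=0.2, p_max=0.2)  # both exceed: excluded
        retained, excluded, reasons = permutation_filter([keep_one, drop_both], threshold=0.1)
        assert retained == [keep_one]
        assert excluded == [drop_both]
        assert "both statistics" in reasons[id(drop_both)]

    def test_boundary_not_excluded_at_threshold(self):
        c = _cand(p_avg=0.1, p_max=0.1)  # strictly greater required
        retained, excluded, _ = permutation_filter([c], threshold=0.1)
        assert retained == [c]

    def test_outlier_driven_candidate_excluded(self):
        # a single extreme pair: permuted p = 1 for both summaries
        n_pairs = 5
        prop = np.full((4, 2 * n_pairs), 0.3)
        case_idx = np.arange(0, 2 * n_pairs, 2)
        control_idx = np.arange(1, 2 * n_pairs, 2)
        prop[:, 0] += 0.5  # one case extreme, all other pairs null
        c = CandidateDMR(
            chrom="chr1", start=1, end=4, region_id=0, probe_index=np.arange(4),
            nprobes=4, avg=0.1, max=0.1, area_raw=0.4,
        )
        c.perm = within_pair_permutation_p(c.probe_index, prop, case_idx, control_idx)
        assert c.perm.p_avg == 1.0  # oracle: all 32 assignments tie
        retained, excluded, _ = permutation_filter([c], threshold=0.1)
        assert excluded == [c]


class TestStratifiedFWER:
    def test_hand_built_pool(self):
        # 10 iterations with stratum maxima 0.1..1.0; observed avg 0.35
        pool = [[(5, 0.1 * (i + 1), 0.1 * (i + 1), 0.5 * (i + 1))] for i in range(10)]
        c = _cand(nprobes=5, avg=0.35)
        res = stratified_fwer([c], pool, strata_edges=np.array([]))[0]
        assert res.fwer["avg"] == pytest.approx(7 / 10)
        assert res.B == 10

    def test_zero_observed_gives_fwer_one(self):
        pool = [[(5, 0.01, 0.01, 0.05)] for _ in range(10)]
        c = _cand(nprobes=5, avg=0.0)
        res = stratified_fwer([c], pool, strata_edges=np.array([]))[0]
        assert all(v == 1.0 for v in res.fwer.values())

    def test_observed_above_all_maxima_flagged_below_resolution(self):
        pool = [[(5, 0.01, 0.01, 0.05)] for _ in range(20)]
        c = _cand(nprobes=5, avg=0.9, mx=0.9)
        res = stratified_fwer([c], pool, strata_edges=np.array([]))[0]
        assert res.fwer["avg"] == 0.0
        assert res.below_resolution["avg"]

    def test_empty_iterations_contribute_zero_maxima(self):
        pool = [[(5, 0.5, 0.5, 2.5)]] + [[] for _ in range(9)]
        c = _cand(nprobes=5, avg=0.2)
        res = stratified_fwer([c], pool, strata_edges=np.array([]))[0]
        assert res.fwer["avg"] == pytest.approx(1 / 10)

    def test_stratification_separates_probe_counts(self):
        # small-stratum nulls are weak, large-stratum nulls strong
        pool = [[(3, 0.05, 0.05, 0.15), (20, 0.5, 0.5, 10.0)] for _ in range(10)]
        small = _cand(nprobes=3, avg=0.2, mx=0.2)
        big = _cand(nprobes=20, avg=0.2, mx=0.2)
        res = stratified_fwer([small, big], pool, strata_edges=np.array([10.0]))
        assert res[0].fwer["avg"] == 0.0  # judged against weak small-candidate nulls
        assert res[1].fwer["avg"] == 1.0  # judged against strong long-candidate nulls

    def test_fwer_monotone_within_stratum(self):
        rng = np.random.default_rng(12)
        pool = [
            [(5, rng.normal(0, 0.1), rng.normal(0, 0.15), rng.normal(0, 0.5))]
            for _ in range(50)
        ]
        cands = [_cand(nprobes=5, avg=a, mx=a) for a in (0.05, 0.1, 0.2, 0.4)]
        res = stratified_fwer(cands, pool, strata_edges=np.array([]))
        for name in ("avg", "max", "area_raw"):
            vals = [r.fwer[name] for r in res]
            assert vals == sorted(vals, reverse=True)


class TestBootstrapNull:
    def _fit(self, planted_cohort, design500):
        meth, cohort, _ = planted_cohort
        model = t.TwinDMRModel(meth, cohort, design500)
        from twindmr.dmr import fit_probe_model

        fit = fit_probe_model(model.m_values, model.pair_codes, model.phenotype)
        return model, fit

    def test_b_zero_rejected(self, planted_cohort, design500):
        model, fit = self._fit(planted_cohort, design500)
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_null(fit, model.positions, model.region_codes,
                           model.case_idx, model.control_idx, B=0)

    def test_same_seed_reproduces_pool_bitwise(self, planted_cohort, design500):
        model, fit = self._fit(planted_cohort, design500)
        kwargs = dict(B=20, seed=5)
        a = bootstrap_null(fit, model.positions, model.region_codes,
                           model.case_idx, model.control_idx, **kwargs)
        b = bootstrap_null(fit, model.positions, model.region_codes,
                           model.case_idx, model.control_idx, **kwargs)
        assert a == b

    def test_pairflip_scheme_runs(self, planted_cohort, design500):
        model, fit = self._fit(planted_cohort, design500)
        pool = bootstrap_null(fit, model.positions, model.region_codes,
                              model.case_idx, model.control_idx, B=10,
                              scheme="pairflip", seed=3)
        assert len(pool) == 10

    def test_planted_effect_exceeds_null_maxima(self, design500, panel500):
        """A strong planted effect beats the per-iteration stratum maxima."""
        _, _, truth = panel500
        cfg = t.SimulationConfig(
            n_pairs=5, n_regions=500, planted_dmrs=[t.PlantedDMR(11, 0.2)],
            noise_sd=0.05, seed=55,
        )
        meth, cohort, _ = t.simulate_twin_cohort(design500, truth.profiles, cfg)
        model = t.TwinDMRModel(meth, cohort, design500)
        from twindmr.dmr import fit_probe_model

        fit = fit_probe_model(model.m_values, model.pair_codes, model.phenotype)
        planted = model.region_ids == 11
        block = model.prop_values[planted]
        obs_avg = abs(
            block[:, model.case_idx].mean(axis=1).mean()
            - block[:, model.control_idx].mean(axis=1).mean()
        )
        pool = bootstrap_null(fit, model.positions, model.region_codes,
                              model.case_idx, model.control_idx, B=200, seed=6)
        beaten = sum(
            1 for stats in pool if all(abs(a) < obs_avg for (_, a, _, _) in stats)
        )
        assert beaten >= 0.95 * len(pool)

    def test_filter_never_inflates_fwer(self, planted_cohort, design500):
        """In-iteration filtering only removes null candidates, so FWER
        estimates from the filtered pool are <= the unfiltered ones."""
        model, fit = self._fit(planted_cohort, design500)
        common = dict(B=40, seed=9)
        filtered = bootstrap_null(fit, model.positions, model.region_codes,
                                  model.case_idx, model.control_idx,
                                  apply_perm_filter=True, **common)
        unfiltered = bootstrap_null(fit, model.positions, model.region_codes,
                                    model.case_idx, model.control_idx,
                                    apply_perm_filter=False, **common)
        for avg in (0.02, 0.05, 0.1):
            c1, c2 = _cand(nprobes=4, avg=avg, mx=avg), _cand(nprobes=4, avg=avg, mx=avg)
            f1 = stratified_fwer([c1], filtered, strata_edges=np.array([]))[0]
            f2 = stratified_fwer([c2], unfiltered, strata_edges=np.array([]))[0]
            for name in ("avg", "max", "area_raw"):
                assert f1.fwer[name] <= f2.fwer[name]


class TestCalls:
    def test_pass_requires_one_fwer_and_permutation(self):
        c = _cand(p_avg=0.06, p_max=0.5)
        c.fwer = FWERResult(
            fwer={"avg": 0.05, "max": 0.5, "area_raw": 0.5},
            below_resolution={"avg": False, "max": False, "area_raw": False},
            stratum=0, B=100,
        )
        calls = call_dmrs([c], fwer_threshold=0.10, perm_threshold=0.1)
        assert calls[0].passed

    def test_fail_when_no_statistic_clears_fwer(self):
        c = _cand(p_avg=0.06, p_max=0.5)
        c.fwer = FWERResult(
            fwer={"avg": 0.15, "max": 0.15, "area_raw": 0.15},
            below_resolution={"avg": False, "max": False, "area_raw": False},
            stratum=0, B=100,
        )
        calls = call_dmrs([c], fwer_threshold=0.10)
        assert not calls[0].passed
        assert any("FWER" in r for r in calls[0].reasons)

    def test_fail_when_permutation_criterion_fails(self):
        c = _cand(p_avg=0.5, p_max=0.5)
        c.fwer = FWERResult(
            fwer={"avg": 0.0, "max": 0.0, "area_raw": 0.0},
            below_resolution={"avg": True, "max": True, "area_raw": True},
            stratum=0, B=100,
        )
        calls = call_dmrs([c])
        assert not calls[0].passed
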