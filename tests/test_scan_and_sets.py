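import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photoqtl import (GenotypeMatrix, TraitTrajectories, build_potential_key_set,
                      detect_pleiotropy, genome_scan, intersect_models, kinship_matrix,
                      ks_normality, select_significant, simulate_genotypes, static_scan)
from photoqtl.simulate import _ar1_noise


@pytest.fixture(scope="module")
def null_scan(grid11, etr_mean):
    """Scan of 300 phenotypically null SNPs on one 98-sample study."""
    rng = np.random.default_rng(77)
    Y = etr_mean + _ar1_noise(rng, 98, grid11.L, 2.25, 0.6)
    traj = TraitTrajectories("ETR", Y, grid11)
    gm = simulate_genotypes(98, 300, (0.2, 0.5), seed=78)
    traj = TraitTrajectories("ETR", Y, grid11, sample_ids=gm.sample_ids)
    return genome_scan(traj, gm, "logistic", False)


def test_null_pvalues_approximately_uniform(null_scan):
    p = null_scan.loc[null_scan.status == "ok", "pvalue"].to_numpy()
    assert len(p) > 250
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 1.628 / np.sqrt(len(p))  # critical value at alpha = 0.01


def test_scan_deterministic_and_order_invariant(grid11, small_study):
    traj = small_study.trajectories["ETR"]
    gm = small_study.genotypes.subset(snp_index=range(40))
    s1 = genome_scan(traj, gm, "logistic", False)
    s2 = genome_scan(traj, gm, "logistic", False)
    pd.testing.assert_frame_equal(s1, s2)
    perm = np.random.default_rng(0).permutation(40)
    s3 = genome_scan(traj, gm.subset(snp_index=perm), "logistic", False)
    merged = s1.set_index("snp_id")["lr"].sort_index()
    merged3 = s3.set_index("snp_id")["lr"].sort_index()
    assert np.allclose(merged.to_numpy(), merged3.to_numpy(), atol=1e-9, equal_nan=True)


def test_planted_qtls_dominate_ranking(small_study):
    traj = small_study.trajectories["ETR"]
    scan = genome_scan(traj, small_study.genotypes, "logistic", False)
    ranked = build_potential_key_set(scan, k=scan.shape[0])
    causal = set(small_study.truth["causal_snps"]["ETR"])
    assert causal <= set(ranked[:6])


def test_scan_requires_aligned_samples(grid11, small_study):
    traj = small_study.trajectories["ETR"]
    bad = TraitTrajectories("ETR", traj.values, grid11)  # default sample ids
    bad.sample_ids = bad.sample_ids[::-1]
    with pytest.raises(ValueError):
        genome_scan(bad, small_study.genotypes)


class TestSignificanceSets:
    def _toy_scan(self, lrs):
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(lrs))],
            "lr": lrs, "status": "ok",
        })

    def test_key_set_larger_than_panel_keeps_all(self):
        scan = self._toy_scan([3.0, 1.0, 2.0])
        assert build_potential_key_set(scan, k=10) == ["s0", "s2", "s1"]

    def test_tie_break_is_stable_by_scan_order(self):
        scan = self._toy_scan([9.0, 7.0, 7.0, 2.0])
        assert build_potential_key_set(scan, k=3) == ["s0", "s1", "s2"]

    def test_top_fraction_counts(self):
        scan = self._toy_scan(list(range(100)))
        assert len(select_significant(scan, 0.05)) == 5
        assert len(select_significant(scan, 0.03)) == 3
        # ceiling semantics on a 10k panel: 3% -> 300
        big = self._toy_scan(list(np.arange(10000, dtype=float)))
        assert len(select_significant(big, 0.03)) == 300

    def test_equal_statistics_resolved_by_order(self):
        scan = self._toy_scan([5.0] * 10)
        assert select_significant(scan, 0.25) == ["s0", "s1", "s2"]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_significant(self._toy_scan([1.0]), 1.5)

    def test_intersection_semantics(self):
        assert intersect_models(["a", "b"], ["c"]) == []
        assert intersect_models(["a", "b"], ["b", "a"]) == ["a", "b"]
        assert intersect_models(["a", "b", "c"], ["c", "b"]) == ["b", "c"]

    def test_pleiotropy_table(self):
        sets = {"ETR": ["a", "x"], "qP": ["x", "y", "p"], "qN": ["y", "x"]}
        table = detect_pleiotropy(sets).set_index("snp_id")
        assert set(table.index) == {"x", "y"}
        assert table.loc["x", "n_traits"] == 3
        assert set(table.loc["y", "traits"]) == {"qP", "qN"}

    def test_pleiotropy_empty_when_disjoint(self):
        table = detect_pleiotropy({"ETR": ["a"], "qP": ["b"]})
        assert table.empty

    def test_pleiotropy_needs_two_traits(self):
        with pytest.raises(ValueError):
            detect_pleiotropy({"ETR": ["a"]})


class TestStaticScan:
    def test_effect_growing_with_light_detected_only_at_high_levels(self, grid11, etr_mean):
        """A planted effect proportional to (l - l_min) has no power at the
        lowest level but high power at the top level."""
        ramp = (grid11.log_levels - grid11.log_levels[0])
        ramp = 1.2 * ramp / ramp[-1]
        hits_low = hits_high = 0
        n_rep = 50
        for r in range(n_rep):
            rng = np.random.default_rng(6000 + r)
            codes = rng.binomial(2, 0.4, size=98).astype(np.int8)
            Y = etr_mean + _ar1_noise(rng, 98, grid11.L, 2.25, 0.6)
            Y = Y + np.outer(codes, ramp)
            traj = TraitTrajectories("ETR", Y, grid11)
            gm = GenotypeMatrix(np.array(["s0"]), traj.sample_ids, codes[None, :])
            low = static_scan(traj, gm, 0).iloc[0]
            high = static_scan(traj, gm, grid11.L - 1).iloc[0]
            hits_low += low["pvalue"] < 0.05
            hits_high += high["pvalue"] < 0.05
        assert hits_high >= 0.6 * n_rep
        assert hits_low <= 0.2 * n_rep

    def test_null_rejection_rate_near_alpha(self, null_scan, grid11, etr_mean):
        rng = np.random.default_rng(8)
        Y = etr_mean + _ar1_noise(rng, 98, grid11.L, 2.25, 0.6)
        gm = simulate_genotypes(98, 200, (0.2, 0.5), seed=9)
        traj = TraitTrajectories("ETR", Y, grid11, sample_ids=gm.sample_ids)
        res = static_scan(traj, gm, 5)
        p = res.loc[res.status == "ok", "pvalue"]
        assert 0.005 <= (p < 0.05).mean() <= 0.12

    def test_degenerate_zero_variance_skipped(self, grid11):
        Y = np.ones((12, grid11.L))
        traj = TraitTrajectories("t", Y, grid11)
        codes = np.array([0] * 6 + [2] * 6, dtype=np.int8)[None, :]
        gm = GenotypeMatrix(np.array(["s0"]), traj.sample_ids, codes)
        res = static_scan(traj, gm, 0)
        assert res.iloc[0]["status"] == "degenerate"

    def test_invalid_level_rejected(self, grid11, small_study):
        with pytest.raises(ValueError):
            static_scan(small_study.trajectories["ETR"], small_study.genotypes, 99)


class TestDiagnostics:
    def test_normal_sample_passes_ks(self):
        x = np.random.default_rng(0).normal(3.0, 2.0, size=400)
        stat, p = ks_normality(x)
        assert p > 0.05

    def test_heavy_tails_fail_ks(self):
        x = np.random.default_rng(1).standard_t(df=1, size=200)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_small_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ks_normality([2.0] * 10)

    def test_kinship_duplicate_sample_has_unit_correlation(self):
        gm = simulate_genotypes(10, 400, (0.2, 0.5), seed=3)
        codes = gm.codes.copy()
        codes[:, 1] = codes[:, 0]
        dup = GenotypeMatrix(gm.snp_ids, gm.sample_ids, codes)
        K, summary = kinship_matrix(dup)
        assert K[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_kinship_independent_samples_concentrate_near_zero(self):
        gm = simulate_genotypes(30, 3000, (0.2, 0.5), seed=4)
        K, summary = kinship_matrix(gm)
        off = K[~np.eye(30, dtype=bool)]
        assert off.min() >= 0.0  # negatives floored
        assert np.median(off) < 0.08
        assert summary["fraction_below_threshold"] > 0.95

    def test_kinship_monomorphic_panel_rejected(self):
        gm = GenotypeMatrix(np.array(["a", "b"]), np.array(["s1", "s2", "s3"]),
                            np.zeros((2, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            kinship_matrix(gm)
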