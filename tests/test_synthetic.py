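"""Ground-truth bookkeeping and recoverability of the cohort generator."""

import math

import numpy as np
import pandas as pd
import pytest

from tnbcomics.cna import GenomicInterval
from tnbcomics.expression import average_replicates, noise_floor_filter
from tnbcomics.survival import cox_fit
from tnbcomics.synthetic import (DRIVER_GENE, CohortDesign, simulate_cn_tracks,
                                 simulate_cohort, simulate_expression,
                                 simulate_rppa, simulate_survival)


def tnbc_only(n, **kwargs):
    return CohortDesign(
        n_per_subgroup={"TNBC": n, "Her2": 0, "LB": 0, "LA": 0, "healthy": 0},
        **kwargs)


class TestDesignValidation:
    def test_default_counts_match_cohort_census(self):
        d = CohortDesign()
        assert d.n_per_subgroup == {"TNBC": 46, "Her2": 33, "LB": 40,
                                    "LA": 35, "healthy": 18}

    @pytest.mark.parametrize("kwargs", [
        {"n_per_subgroup": {"TNBC": -1, "healthy": 0}},
        {"gain_prob_per_subgroup": {"TNBC": 1.5, "healthy": 0}},
        {"latent_mrna_protein_rho": 1.0},
        {"censoring_rate": 1.5},
        {"n_batches": 0, "batch_offsets": ()},
        {"probe_noise_sd": -0.1},
        {"true_log_hr": math.inf},
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortDesign(**kwargs)


class TestCnTracks:
    def test_reproducible_with_same_seed(self, small_design):
        a, ta, _ = simulate_cn_tracks(small_design, n_probes=120)
        b, tb, _ = simulate_cn_tracks(small_design, n_probes=120)
        for s in a:
            np.testing.assert_array_equal(a[s].values, b[s].values)
        assert ta.true_breakpoints == tb.true_breakpoints

    def test_zero_gain_probability_gives_no_breakpoints(self):
        d = CohortDesign(gain_prob_per_subgroup={g: 0.0 for g in
                         ("TNBC", "Her2", "LB", "LA", "healthy")}, seed=3)
        _, truth, _ = simulate_cn_tracks(d, n_probes=100)
        assert all(len(v) == 0 for v in truth.true_breakpoints.values())
        assert all(len(v) == 0 for v in truth.true_gain_segments.values())

    def test_certain_gain_forces_fraction_one(self):
        d = tnbc_only(200, gain_prob_per_subgroup={
            "TNBC": 1.0, "Her2": 0.0, "LB": 0.0, "LA": 0.0, "healthy": 0.0},
            seed=5)
        _, truth, _ = simulate_cn_tracks(d, n_probes=100)
        amps = [truth.cn_amplitude_at_locus[s] for s in truth.subgroup]
        assert all(a > 0 for a in amps)

    def test_gain_fraction_within_binomial_error(self):
        d = tnbc_only(1000, gain_prob_per_subgroup={
            "TNBC": 0.3, "Her2": 0.0, "LB": 0.0, "LA": 0.0, "healthy": 0.0},
            seed=11)
        _, truth, _ = simulate_cn_tracks(d, n_probes=100)
        frac = np.mean([truth.cn_amplitude_at_locus[s] > 0
                        for s in truth.subgroup])
        se = math.sqrt(0.3 * 0.7 / 1000)
        assert abs(frac - 0.3) <= 3 * se

    def test_healthy_samples_never_altered(self):
        d = CohortDesign(seed=2)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        for s, g in truth.subgroup.items():
            if g == "healthy":
                assert truth.true_gain_segments[s] == []

    def test_every_gain_overlaps_locus_and_breakpoints_sorted(self):
        d = CohortDesign(seed=4)
        tracks, truth, locus = simulate_cn_tracks(d, n_probes=200)
        spacing = 1000
        lo = int(np.searchsorted(tracks[next(iter(tracks))].positions, locus.start))
        hi = int(np.searchsorted(tracks[next(iter(tracks))].positions, locus.end,
                                 side="right")) - 1
        for s, segs in truth.true_gain_segments.items():
            bps = truth.true_breakpoints[s]
            assert bps == sorted(bps)
            if segs:
                first = segs[0]
                assert first[0] <= hi and first[1] >= lo

    def test_locus_outside_range_rejected(self, small_design):
        with pytest.raises(ValueError, match="outside"):
            simulate_cn_tracks(small_design, n_probes=100,
                               locus=GenomicInterval("6", 10**9, 10**9 + 10))

    def test_too_few_probes_rejected(self, small_design):
        with pytest.raises(ValueError):
            simulate_cn_tracks(small_design, n_probes=30)


class TestExpression:
    def test_subgroup_means_hit_design_targets(self):
        d = CohortDesign(seed=9)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=50)
        drv = m.values.loc[DRIVER_GENE]
        grp = m.sample_info["subgroup"]
        for g, target in d.driver_mean_log2_per_subgroup.items():
            got = float(drv[grp[grp == g].index].mean())
            assert got == pytest.approx(target, abs=0.5)

    def test_zero_noise_floor_fraction_gives_no_filterable_genes(self):
        d = CohortDesign(seed=9, noise_floor_fraction=0.0)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=60)
        m = average_replicates(m)
        _, discarded = noise_floor_filter(m)
        assert len(discarded) == 0

    def test_planted_noise_floor_census_is_exact(self):
        d = CohortDesign(seed=9, noise_floor_fraction=0.25)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=82)
        assert len(truth.noise_floor_features) == 20
        m = average_replicates(m)
        _, discarded = noise_floor_filter(m)
        assert set(discarded) == set(truth.noise_floor_features)

    def test_zero_batch_offsets_leave_no_batch_structure(self):
        d = CohortDesign(seed=13, n_batches=2, batch_offsets=(0.0, 0.0))
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=30)
        drv = m.values.loc[DRIVER_GENE]
        info = m.sample_info
        tnbc = info[(info["subgroup"] == "TNBC")]
        means, ses = [], []
        for b, idx in tnbc.groupby("batch").groups.items():
            vals = drv[idx]
            means.append(vals.mean())
            ses.append(vals.std(ddof=1) / math.sqrt(len(vals)))
        if len(means) == 2:
            se = math.hypot(*ses)
            assert abs(means[0] - means[1]) <= 3 * se

    def test_replicates_share_annotations(self):
        d = CohortDesign(seed=21, replicate_fraction=0.3)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=20)
        info = m.sample_info
        dupes = info[info.index != info["replicate_group"]]
        assert len(dupes) > 0
        for rep_id, row in dupes.iterrows():
            orig = info.loc[row["replicate_group"]]
            assert row["subgroup"] == orig["subgroup"]
            assert row["batch"] == orig["batch"]

    def test_fewer_than_two_genes_rejected(self):
        d = CohortDesign(seed=1)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        with pytest.raises(ValueError):
            simulate_expression(d, truth, n_genes=1)

    def test_mrna_cn_rank_correlation_calibrated(self):
        # single-subgroup design isolates the calibration from subgroup structure
        from scipy import stats
        rhos = []
        for seed in range(25):
            d = tnbc_only(130, gain_prob_per_subgroup={
                "TNBC": 0.5, "Her2": 0, "LB": 0, "LA": 0, "healthy": 0},
                seed=seed)
            _, truth, _ = simulate_cn_tracks(d, n_probes=100)
            m = simulate_expression(d, truth, n_genes=5)
            originals = [s for s in m.values.columns
                         if m.sample_info.loc[s, "replicate_group"] == s]
            drv = m.values.loc[DRIVER_GENE, originals].to_numpy()
            amp = np.array([truth.cn_amplitude_at_locus[s] for s in originals])
            rhos.append(stats.spearmanr(drv, amp).statistic)
        assert np.mean(rhos) == pytest.approx(0.65, abs=0.08)


class TestRppa:
    def test_noise_free_series_are_exact_ladders(self):
        d = tnbc_only(5, seed=3)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=5)
        t = simulate_rppa(d, m, n_arrays=3, n_dilutions=5,
                          loading_sd=0.0, spot_noise_sd=0.0)
        for (_, _), sub in t.groupby(["array_id", "sample_id"]):
            logs = np.log2(sub.sort_values("dilution_step")["intensity"].to_numpy())
            np.testing.assert_allclose(np.diff(logs), -1.0, atol=1e-10)

    def test_single_sample_single_array_row_count(self):
        d = tnbc_only(1, seed=3)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=5)
        t = simulate_rppa(d, m, n_arrays=1, n_dilutions=4)
        assert len(t) == 4

    def test_invalid_dilution_count_rejected(self):
        d = tnbc_only(3, seed=3)
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        m = simulate_expression(d, truth, n_genes=5)
        with pytest.raises(ValueError):
            simulate_rppa(d, m, n_dilutions=0)


class TestSurvival:
    def _expression(self, d):
        _, truth, _ = simulate_cn_tracks(d, n_probes=120)
        return simulate_expression(d, truth, n_genes=5)

    def test_zero_censoring_all_events(self):
        d = tnbc_only(40, censoring_rate=0.0, seed=5)
        m = self._expression(d)
        rec = simulate_survival(d, m)
        assert (rec["event"] == 1).all()

    def test_censoring_rate_approximately_achieved(self):
        d = tnbc_only(3000, censoring_rate=0.3, seed=5)
        m = self._expression(d)
        rec = simulate_survival(d, m, endpoints=("OS",))
        assert float(1 - rec["event"].mean()) == pytest.approx(0.3, abs=0.05)

    def test_null_hazard_recovered_as_zero(self):
        d = tnbc_only(600, true_log_hr=0.0, censoring_rate=0.0, seed=5)
        m = self._expression(d)
        rec = simulate_survival(d, m, endpoints=("OS",))
        drv = m.values.loc[DRIVER_GENE, rec["sample_id"]].to_numpy()
        z = (drv - drv.mean()) / drv.std()
        fit = cox_fit(rec["time"].to_numpy(), rec["event"].to_numpy(), z)
        assert abs(fit.beta_hat) < 3 * fit.se

    def test_invalid_censoring_rejected(self):
        d = tnbc_only(10, seed=5)
        m = self._expression(d)
        object.__setattr__(d, "censoring_rate", 1.0)
        with pytest.raises(ValueError):
            simulate_survival(d, m)

    def test_endpoints_flagged(self):
        d = tnbc_only(10, seed=5)
        m = self._expression(d)
        rec = simulate_survival(d, m)
        assert set(rec["endpoint"]) == {"OS", "DFI", "metastasis"}


class TestCohortBundle:
    def test_bitwise_reproducibility(self, small_design):
        a = simulate_cohort(small_design, n_probes=120, n_genes=20, seed=42)
        b = simulate_cohort(small_design, n_probes=120, n_genes=20, seed=42)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.rppa, b.rppa)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        for s in a.tracks:
            np.testing.assert_array_equal(a.tracks[s].values, b.tracks[s].values)

    def test_different_seeds_differ(self, small_design):
        a = simulate_cohort(small_design, n_probes=120, n_genes=20, seed=1)
        b = simulate_cohort(small_design, n_probes=120, n_genes=20, seed=2)
        assert not a.expression.values.equals(b.expression.values)
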