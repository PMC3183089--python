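import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_call_set
from twinmeth.discovery import PairedDiffMatrix, call_mvps, paired_differences
from twinmeth.variability import (
    AmpliconSummary,
    amplicon_groupwise_test,
    control_pair_variance,
    replication_test,
    variance_enrichment_test,
)


def diff_matrix(values, cohort="control_twins"):
    values = np.asarray(values, dtype=float)
    return PairedDiffMatrix(
        pd.DataFrame(
            values,
            index=[f"cg{i:04d}" for i in range(values.shape[0])],
            columns=[f"P{j:02d}" for j in range(values.shape[1])],
        ),
        cohort=cohort,
    )


class TestControlPairVariance:
    def test_hand_computed_two_pair_variance(self):
        profile = control_pair_variance(diff_matrix([[-0.1, 0.1]]))
        assert profile.table.iloc[0]["variance"] == pytest.approx(0.02)

    def test_constant_probe_has_zero_variance_and_minimum_rank(self, rng):
        d = rng.normal(0, 0.02, size=(10, 9))
        d[3] = 0.01
        profile = control_pair_variance(diff_matrix(d))
        row = profile.table.set_index("probe_id").loc["cg0003"]
        assert row["variance"] == 0.0
        assert row["rank"] == 1

    def test_one_row_per_probe(self, rng):
        d = rng.normal(0, 0.02, size=(25, 9))
        profile = control_pair_variance(diff_matrix(d))
        assert len(profile.table) == 25
        assert sorted(profile.table["rank"]) == list(range(1, 26))

    def test_invariant_to_global_index_reassignment(self, rng):
        # swapping every pair's index co-twin negates all differences;
        # the variance profile (around the mean) is unchanged exactly.
        # A single pair's flip is only neutral in distribution, since the
        # variance is taken around the cross-pair mean.
        d = rng.normal(0, 0.02, size=(40, 9))
        v1 = control_pair_variance(diff_matrix(d)).table["variance"]
        v2 = control_pair_variance(diff_matrix(-d)).table["variance"]
        np.testing.assert_allclose(v1, v2)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError, match="2 pairs"):
            control_pair_variance(diff_matrix([[0.1]]))


class TestVarianceEnrichment:
    def test_low_noise_mvps_detected(self, rng):
        d = rng.normal(0, 0.02, size=(500, 9))
        d[:40] = rng.normal(0, 0.01, size=(40, 9))  # MVP probes at half the noise
        dm = diff_matrix(d)
        calls = make_call_set(list(dm.probe_ids[:40]), ["hyper"] * 40)
        p = variance_enrichment_test(control_pair_variance(dm), calls)
        assert p < 1e-4

    def test_random_mvp_set_is_null(self, rng):
        ps = []
        for _ in range(6):
            d = rng.normal(0, 0.02, size=(400, 9))
            dm = diff_matrix(d)
            pick = rng.choice(400, 40, replace=False)
            calls = make_call_set(list(dm.probe_ids[pick]), ["hyper"] * 40)
            ps.append(variance_enrichment_test(control_pair_variance(dm), calls))
        assert min(ps) > 1e-3 and np.mean(ps) > 0.15

    def test_single_probe_fallback_warns(self, rng):
        d = rng.normal(0, 0.02, size=(50, 9))
        dm = diff_matrix(d)
        calls = make_call_set([dm.probe_ids[0]], ["hyper"])
        with pytest.warns(UserWarning, match="one-sample"):
            p = variance_enrichment_test(control_pair_variance(dm), calls)
        assert 0.0 <= p <= 1.0

    def test_empty_call_set_rejected(self, rng):
        dm = diff_matrix(rng.normal(0, 0.02, size=(20, 9)))
        with pytest.raises(ValueError, match="empty"):
            variance_enrichment_test(
                control_pair_variance(dm), make_call_set([], [])
            )


class TestReplication:
    def replication_data(self, rng, effect=0.04):
        d = rng.normal(0, 0.015, size=(300, 4))
        d[:25] += effect
        d[25:50] -= effect
        dm = diff_matrix(d, cohort="replication_twins")
        calls = make_call_set(
            list(dm.probe_ids[:50]), ["hyper"] * 25 + ["hypo"] * 25
        )
        return dm, calls

    def test_shared_effects_replicate(self, rng):
        dm, calls = self.replication_data(rng)
        res = replication_test(dm, calls, n_boot=2000, seed=0)
        assert res.p_value < 0.01
        g = res.groups.set_index("direction")
        assert g.at["hyper", "ci95_low"] > g.at["hypo", "ci95_high"]

    def test_null_cohort_straddles_zero(self, rng):
        dm, calls = self.replication_data(rng, effect=0.0)
        res = replication_test(dm, calls, n_boot=2000, seed=0)
        g = res.groups.set_index("direction")
        for direction in ("hyper", "hypo"):
            assert g.at[direction, "ci95_low"] < 0 < g.at[direction, "ci95_high"]

    def test_p_invariant_to_probe_order(self, rng):
        dm, calls = self.replication_data(rng)
        shuffled = PairedDiffMatrix(
            dm.data.sample(frac=1, random_state=1), cohort=dm.cohort
        )
        r1 = replication_test(dm, calls, n_boot=500, seed=0)
        r2 = replication_test(shuffled, calls, n_boot=500, seed=0)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_ci_narrows_with_more_mvps(self, rng):
        d = rng.normal(0.04, 0.015, size=(400, 4))
        dm = diff_matrix(d, cohort="replication_twins")
        widths = {}
        for n in (20, 200):
            calls = make_call_set(
                list(dm.probe_ids[:n]) + list(dm.probe_ids[-4:]),
                ["hyper"] * n + ["hypo"] * 4,
            )
            g = replication_test(dm, calls, n_boot=3000, seed=2).groups
            row = g.set_index("direction").loc["hyper"]
            widths[n] = row["ci95_high"] - row["ci95_low"]
        assert widths[200] < widths[20]

    def test_absent_probes_excluded_with_warning(self, rng):
        dm, calls = self.replication_data(rng)
        trimmed = PairedDiffMatrix(dm.data.iloc[1:], cohort=dm.cohort)
        with pytest.warns(UserWarning, match="absent"):
            res = replication_test(trimmed, calls, n_boot=200, seed=0)
        assert res.excluded == [dm.probe_ids[0]]

    def test_zero_bootstrap_rejected(self, rng):
        dm, calls = self.replication_data(rng)
        with pytest.raises(ValueError, match="n_boot"):
            replication_test(dm, calls, n_boot=0, seed=0)


class TestAmpliconGroupwise:
    def test_well_separated_groups(self):
        summaries = [
            AmpliconSummary(f"h{i}", "hyper", 0.05 + 0.001 * i) for i in range(5)
        ] + [AmpliconSummary(f"l{i}", "hypo", -0.05 - 0.001 * i) for i in range(8)]
        assert amplicon_groupwise_test(summaries) < 1e-6

    def test_all_equal_means_give_half(self):
        summaries = [AmpliconSummary(f"h{i}", "hyper", 0.02) for i in range(3)] + [
            AmpliconSummary(f"l{i}", "hypo", 0.02) for i in range(3)
        ]
        assert amplicon_groupwise_test(summaries) == pytest.approx(0.5)

    def test_matches_scipy_welch(self, rng):
        for _ in range(20):
            h = rng.normal(0.02, 0.01, 5)
            l = rng.normal(-0.02, 0.02, 8)
            summaries = [
                AmpliconSummary(f"h{i}", "hyper", v) for i, v in enumerate(h)
            ] + [AmpliconSummary(f"l{i}", "hypo", v) for i, v in enumerate(l)]
            expected = stats.ttest_ind(h, l, equal_var=False, alternative="greater").pvalue
            assert amplicon_groupwise_test(summaries) == pytest.approx(expected)

    def test_requires_two_per_direction(self):
        summaries = [
            AmpliconSummary("h0", "hyper", 0.02),
            AmpliconSummary("l0", "hypo", -0.02),
            AmpliconSummary("l1", "hypo", -0.03),
        ]
        with pytest.raises(ValueError, match="2 amplicons"):
            amplicon_groupwise_test(summaries)


def test_full_variability_stage_on_simulated_cohort(effect_cohort):
    """End-to-end: discovery calls replicate in the replication cohort."""
    _, m, sheet, ann, truth = effect_cohort
    from twinmeth.preprocessing import probe_filter, quantile_normalize, sample_qc

    qc = sample_qc(m)
    filtered, _ = probe_filter(m, ann, qc.retained_samples)
    norm = quantile_normalize(filtered)
    calls = call_mvps(paired_differences(norm, sheet, "discovery_twins"), 0.01)
    rdiffs = paired_differences(norm, sheet, "replication_twins")
    res = replication_test(rdiffs, calls, n_boot=1000, seed=5)
    assert res.p_value < 0.05
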