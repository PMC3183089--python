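import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_call_set
from twinmeth.enrichment import (
    bootstrap_enrichment,
    directional_ranksum,
    directionality_fraction,
    paired_pre_post,
    ranksum_pvalues,
    scale_statistic,
)
from twinmeth.io_formats import BetaMatrix
from twinmeth.synthetic import SimConfig, simulate_cohort


class TestDirectionalRanksum:
    def test_complete_separation_hyper(self):
        p = directional_ranksum(np.arange(30, 37), np.arange(18), "hyper")
        assert p == pytest.approx(1 / math.comb(25, 7), rel=1e-12)

    def test_opposite_direction_near_one(self):
        p = directional_ranksum(np.arange(30, 37), np.arange(18), "hypo")
        assert p == pytest.approx(1.0, rel=1e-12)

    def test_matches_enumeration_small_groups(self):
        rng = np.random.default_rng(8)
        for n1, n2 in [(3, 4), (5, 5), (6, 6), (4, 6)]:
            for _ in range(30):
                x, y = rng.normal(0.2, 1, n1), rng.normal(0, 1, n2)
                ranks = np.arange(1, n1 + n2 + 1)
                u_obs = stats.rankdata(np.concatenate([x, y]))[:n1].sum() - n1 * (
                    n1 + 1
                ) / 2
                us = np.array(
                    [sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(ranks, n1)]
                )
                assert directional_ranksum(x, y, "hyper") == pytest.approx(
                    np.mean(us >= u_obs), rel=1e-10
                )
                assert directional_ranksum(x, y, "hypo") == pytest.approx(
                    np.mean(us <= u_obs), rel=1e-10
                )

    def test_overlapping_sample_sets_rejected(self, null_cohort):
        _, m, sheet, _, _ = null_cohort
        case = sheet.samples("pre_t1d")
        dirs = pd.Series(["hyper"] * 3, index=m.probe_ids[:3])
        with pytest.raises(ValueError, match="overlap"):
            ranksum_pvalues(m, case, case[:2] + ["C01A"], dirs)

    def test_behrens_fisher_alternative(self, rng):
        x, y = rng.normal(0.3, 1, 10), rng.normal(0, 2, 15)
        p = directional_ranksum(x, y, "hyper", test="behrens-fisher")
        expected = stats.brunnermunzel(x, y, alternative="greater").pvalue
        assert p == pytest.approx(expected)

    def test_behrens_fisher_falls_back_on_separation(self):
        with pytest.warns(UserWarning, match="falling back"):
            p = directional_ranksum(
                np.arange(30, 37), np.arange(18), "hyper", test="behrens-fisher"
            )
        assert p == pytest.approx(1 / math.comb(25, 7), rel=1e-12)


class TestScaleStatistic:
    def test_all_ones_give_zero(self):
        assert scale_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_geometric_ladder(self):
        assert scale_statistic(np.exp([-1.0, -2.0, -3.0])) == pytest.approx(2.0)

    def test_uniform_p_values_average_to_one(self, rng):
        p = rng.uniform(0, 1, 100_000)
        p = np.maximum(p, 1e-300)
        assert scale_statistic(p) == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            scale_statistic([0.5, 0.0])


def control_samples_of(sheet):
    pairs = sheet.pairs("control_twins")
    return [s for r in pairs.itertuples() for s in (r.affected, r.unaffected)]


class TestNullCalibrationOfX:
    def test_approximation_branch_x_near_one(self, rng):
        """Null case/control data, approximation branch: X converges to the
        exponential-null expectation 1 (tolerance 0.05)."""
        cfg = SimConfig(
            n_probes=4000,
            n_discovery_pairs=0,
            n_control_pairs=9,
            n_replication_pairs=0,
            n_pre_post_subjects=7,
            n_abpos_singletons=0,
            n_true_mvps=0,
            missing_rate=0.0,
            frac_sex_probes=0.0,
            seed=123,
        )
        m, sheet, _, _ = simulate_cohort(cfg)
        dirs = pd.Series(
            np.where(np.arange(4000) % 2 == 0, "hyper", "hypo"), index=m.probe_ids
        )
        p = ranksum_pvalues(
            m, sheet.samples("pre_t1d"), control_samples_of(sheet), dirs, method="approx"
        )
        assert scale_statistic(p) == pytest.approx(1.0, abs=0.05)


class TestBootstrapEnrichment:
    def run(self, seed, effects=True, n_boot=600, **kw):
        cfg = SimConfig(
            n_probes=800,
            n_true_mvps=60 if effects else 0,
            effect_range=(0.03, 0.06),
            missing_rate=0.0,
            frac_sex_probes=0.0,
            seed=seed,
        )
        m, sheet, _, truth = simulate_cohort(cfg)
        if effects:
            t = truth.table.set_index("probe_id")["direction"]
            calls = make_call_set(list(t.index), t.to_numpy())
        else:
            rng = np.random.default_rng(seed)
            probes = rng.choice(m.probe_ids, 60, replace=False)
            calls = make_call_set(
                probes, np.where(rng.random(60) < 0.5, "hyper", "hypo")
            )
        return m, sheet, calls, bootstrap_enrichment(
            m, sheet, "pre_t1d", calls, n_boot=n_boot, seed=seed, **kw
        )

    def test_injected_effects_detected(self):
        _, _, _, s = self.run(seed=21)
        assert s.X > 1.5
        assert s.p_one_sided < 0.05
        assert s.directionality_fraction > 0.6

    def test_null_data_not_rejected(self):
        ps = [self.run(seed=k, effects=False)[3].p_one_sided for k in (1, 2, 3)]
        assert min(ps) > 0.2
        _, _, _, s = self.run(seed=1, effects=False)
        assert s.ci_low < 1.0  # interval reaches the null value

    def test_deterministic_given_seed(self):
        _, _, _, a = self.run(seed=5, n_boot=150)
        _, _, _, b = self.run(seed=5, n_boot=150)
        assert a.X == b.X and a.p_one_sided == b.p_one_sided
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_p_monotone_in_effect_size(self):
        ps = []
        for eff in (0.0, 0.02, 0.05):
            cfg = SimConfig(
                n_probes=600,
                n_true_mvps=50,
                effect_range=(eff, eff) if eff else (0.0, 0.0),
                missing_rate=0.0,
                frac_sex_probes=0.0,
                seed=77,
            )
            m, sheet, _, truth = simulate_cohort(cfg)
            t = truth.table.set_index("probe_id")["direction"]
            calls = make_call_set(list(t.index), t.to_numpy())
            ps.append(
                bootstrap_enrichment(
                    m, sheet, "pre_t1d", calls, n_boot=400, seed=7
                ).p_one_sided
            )
        assert ps[0] >= ps[1] >= ps[2]

    def test_pair_resampling_wider_than_individual(self):
        _, _, _, by_pair = self.run(seed=9)
        _, _, _, by_ind = self.run(seed=9, control_resampling="individual")
        assert (by_pair.ci_high - by_pair.ci_low) > (by_ind.ci_high - by_ind.ci_low)


class TestPairedPrePost:
    def test_identical_pre_and_post_is_degenerate(self, null_cohort):
        _, m, sheet, _, _ = null_cohort
        subjects = sheet.pre_post_subjects()
        data = m.data.copy()
        data[subjects["post"].tolist()] = data[subjects["pre"].tolist()].to_numpy()
        m2 = BetaMatrix(data)
        rng = np.random.default_rng(0)
        probes = rng.choice(m.probe_ids, 50, replace=False)
        calls = make_call_set(probes, ["hyper"] * 25 + ["hypo"] * 25)
        s = paired_pre_post(m2, sheet, calls, n_boot=200, seed=0)
        assert s.degenerate
        assert s.X == 0.0
        assert s.p_one_sided > 0.9

    def test_null_pre_post_not_rejected(self, null_cohort):
        _, m, sheet, _, _ = null_cohort
        rng = np.random.default_rng(4)
        probes = rng.choice(m.probe_ids, 60, replace=False)
        calls = make_call_set(probes, np.where(rng.random(60) < 0.5, "hyper", "hypo"))
        s = paired_pre_post(m, sheet, calls, n_boot=300, seed=4)
        assert s.p_one_sided > 0.2
        assert s.ci_low < 1.0

    def test_deterministic(self, null_cohort):
        _, m, sheet, _, _ = null_cohort
        probes = list(m.probe_ids[:40])
        calls = make_call_set(probes, ["hyper"] * 20 + ["hypo"] * 20)
        a = paired_pre_post(m, sheet, calls, n_boot=150, seed=3)
        b = paired_pre_post(m, sheet, calls, n_boot=150, seed=3)
        assert a.X == b.X and a.p_one_sided == b.p_one_sided


class TestDirectionalityFraction:
    def make_matrix(self, rng, n_probes=100, n_case=4, n_ctrl=6):
        base = rng.random(n_probes) * 0.6 + 0.2
        case = np.tile(base[:, None], (1, n_case))
        ctrl = np.tile(base[:, None], (1, n_ctrl))
        cols = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
        return base, case, ctrl, cols

    def test_constructed_shift_gives_fraction_one(self, rng):
        base, case, ctrl, cols = self.make_matrix(rng)
        dirs = np.where(np.arange(100) % 2 == 0, "hyper", "hypo")
        case = case + np.where(dirs == "hyper", 0.01, -0.01)[:, None]
        m = BetaMatrix(
            pd.DataFrame(
                np.hstack([case, ctrl]),
                index=[f"cg{i}" for i in range(100)],
                columns=cols,
            )
        )
        calls = make_call_set(list(m.probe_ids), dirs)
        f = directionality_fraction(m, cols[:4], cols[4:], calls)
        assert f == 1.0

    def test_swapping_groups_complements_fraction(self, rng):
        base, case, ctrl, cols = self.make_matrix(rng)
        case = case + rng.normal(0, 0.02, case.shape)
        ctrl = ctrl + rng.normal(0, 0.02, ctrl.shape)
        m = BetaMatrix(
            pd.DataFrame(
                np.hstack([case, ctrl]).clip(0, 1),
                index=[f"cg{i}" for i in range(100)],
                columns=cols,
            )
        )
        dirs = np.where(rng.random(100) < 0.5, "hyper", "hypo")
        calls = make_call_set(list(m.probe_ids), dirs)
        f1 = directionality_fraction(m, cols[:4], cols[4:], calls)
        f2 = directionality_fraction(m, cols[4:], cols[:4], calls)
        assert f1 + f2 == pytest.approx(1.0)  # no exact zero differences here

    def test_null_fraction_near_half(self, null_cohort):
        _, m, sheet, _, _ = null_cohort
        rng = np.random.default_rng(11)
        fs = []
        for k in range(5):
            probes = rng.choice(m.probe_ids, 80, replace=False)
            calls = make_call_set(
                probes, np.where(rng.random(80) < 0.5, "hyper", "hypo")
            )
            fs.append(
                directionality_fraction(
                    m, sheet.samples("pre_t1d"), control_samples_of(sheet), calls
                )
            )
        assert np.mean(fs) == pytest.approx(0.5, abs=0.1)
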