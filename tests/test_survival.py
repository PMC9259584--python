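"""Kaplan-Meier, log-rank, competing-risks CIF and Gray's test."""

from itertools import combinations

import numpy as np
import pytest

from blcohort.survival import (
    CENSORED,
    cumulative_incidence,
    gray_test,
    kaplan_meier,
    logrank_test,
)


def random_competing_data(rng, n, p_relapse=0.6, with_competing=True):
    t = rng.exponential(3, n)
    cens = rng.uniform(0, 8, n)
    if with_competing:
        raw = np.where(rng.random(n) < p_relapse, "relapse", "death")
    else:
        raw = np.full(n, "relapse", dtype=object)
    et = np.where(t <= cens, raw, CENSORED).astype(object)
    time = np.minimum(t, cens)
    group = rng.choice(["A", "B"], n)
    return time, et, group


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        km = kaplan_meier([1, 2, 3], [False, False, False])
        assert km.estimate_at(10) == 1.0

    def test_no_censoring_reduces_to_empirical_survival(self, rng):
        t = rng.exponential(2, 200)
        km = kaplan_meier(t, np.ones(200, bool))
        for q in (0.5, 1.0, 2.0):
            assert km.estimate_at(q) == pytest.approx((t > q).mean())

    def test_hand_product_limit(self):
        # events at 1 and 3, censored at 2
        km = kaplan_meier([1, 2, 3], [True, False, True])
        assert km.estimate_at(1.5) == pytest.approx(2 / 3)
        assert km.estimate_at(3.5) == pytest.approx(0.0)

    def test_greenwood_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(2, 150)
        obs = rng.random(150) < 0.7
        km = kaplan_meier(t, obs)
        kmf = lifelines.KaplanMeierFitter().fit(t, obs)
        sf = kmf.survival_function_.iloc[:, 0]
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx(sf.loc[tt], abs=1e-10)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        obs = [True, True, False] * 2
        g = ["A"] * 3 + ["B"] * 3
        res = logrank_test(t, obs, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_event_hand_formula(self):
        # one event in A at t=1, B at risk: O-E = 0.5, V = 0.25, chi2 = 1
        res = logrank_test([1, 1], [True, False], ["A", "B"])
        assert res.statistic == pytest.approx(1.0)

    def test_matches_lifelines_k_sample(self, rng):
        lifelines = pytest.importorskip("lifelines.statistics")
        t = rng.exponential(3, 120)
        obs = rng.random(120) < 0.8
        g = rng.choice(["A", "B", "C"], 120)
        ours = logrank_test(t, obs, g)
        ref = lifelines.multivariate_logrank_test(t, g, obs)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.df == 2

    def test_large_hazard_contrast_is_significant(self, rng):
        n = 400
        g = np.array(["mut"] * 100 + ["wt"] * 300)
        lam = np.where(g == "mut", 0.5, 0.05)
        t = rng.exponential(1 / lam)
        obs = t < 8
        t = np.minimum(t, 8)
        assert logrank_test(t, obs, g).p < 1e-6


class TestCIF:
    def test_no_competing_reduces_to_one_minus_km(self, rng):
        t = rng.exponential(2, 100)
        cens = rng.uniform(0, 5, 100)
        et = np.where(t <= cens, "relapse", CENSORED).astype(object)
        time = np.minimum(t, cens)
        cif = cumulative_incidence(time, et, "relapse")
        km = kaplan_meier(time, et != CENSORED)
        for tt in cif.times:
            assert cif.estimate_at(tt) == pytest.approx(1 - km.estimate_at(tt), abs=1e-12)

    def test_two_subject_hand_example(self):
        time = [1.0, 2.0]
        et = np.array(["relapse", "death"], dtype=object)
        rel = cumulative_incidence(time, et, "relapse")
        dth = cumulative_incidence(time, et, "death")
        assert rel.estimate_at(1) == pytest.approx(0.5)
        assert rel.estimate_at(5) == pytest.approx(0.5)
        assert dth.estimate_at(1.5) == pytest.approx(0.0)
        assert dth.estimate_at(2) == pytest.approx(0.5)

    def test_conservation_identity(self, rng):
        time, et, _ = random_competing_data(rng, 200)
        km = kaplan_meier(time, et != CENSORED)
        cif_r = cumulative_incidence(time, et, "relapse")
        cif_d = cumulative_incidence(time, et, "death")
        for i, tt in enumerate(km.times):
            total = km.survival[i] + cif_r.estimate_at(tt) + cif_d.estimate_at(tt)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_monotone_and_se_zero_before_first_event(self, rng):
        time, et, _ = random_competing_data(rng, 150)
        cif = cumulative_incidence(time, et, "relapse")
        assert (np.diff(cif.cif) >= -1e-15).all()
        assert cif.estimate_at(-1) == 0.0 and cif.se_at(-1) == 0.0

    def test_estimates_match_cmprsk(self, rng):
        """Point estimates agree exactly with R cmprsk::cuminc; variances to ~5%."""
        import subprocess

        pytest.importorskip("pandas")
        import pandas as pd

        time, et, group = random_competing_data(rng, 120)
        df = pd.DataFrame({
            "time": time,
            "status": np.where(et == CENSORED, 0, np.where(et == "relapse", 1, 2)),
        })
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            rcode = (
                f'd<-read.csv("{csv}");library(cmprsk);'
                'ci<-cuminc(d$time,d$status);tp<-timepoints(ci,c(1,2,4));'
                'cat(tp$est["1 1",],tp$var["1 1",])'
            )
            out = subprocess.run(["Rscript", "-e", rcode],
                                 capture_output=True, text=True)
            vals = [float(x) for x in out.stdout.split()]
        cif = cumulative_incidence(time, et, "relapse")
        for t_eval, est_r, var_r in zip((1, 2, 4), vals[:3], vals[3:]):
            # R prints ~7 significant digits; point estimates agree to that
            assert cif.estimate_at(t_eval) == pytest.approx(est_r, rel=1e-5)
            assert cif.se_at(t_eval) ** 2 == pytest.approx(var_r, rel=0.06)

    def test_se_matches_bootstrap(self):
        """Delta-method SE within 10% of a bootstrap oracle."""
        rng = np.random.default_rng(0)
        time, et, _ = random_competing_data(rng, 300)
        cif = cumulative_incidence(time, et, "relapse")
        se_est = cif.se_at(2.0)
        boots = []
        for _ in range(400):
            idx = rng.integers(0, len(time), len(time))
            b = cumulative_incidence(time[idx], et[idx], "relapse")
            boots.append(b.estimate_at(2.0))
        assert se_est == pytest.approx(np.std(boots), rel=0.10)


class TestGray:
    def test_identical_groups(self):
        t = [1, 2, 3, 4] * 2
        et = np.array(["relapse", "death", CENSORED, "relapse"] * 2, dtype=object)
        g = ["A"] * 4 + ["B"] * 4
        res = gray_test(t, et, g, "relapse")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_reduces_to_logrank_without_competing_events(self, rng):
        agree = 0
        for _ in range(50):
            time, et, group = random_competing_data(rng, int(rng.integers(20, 60)),
                                                    with_competing=False)
            if (et != CENSORED).sum() == 0 or len(set(group)) < 2:
                continue
            lr = logrank_test(time, et != CENSORED, group)
            gr = gray_test(time, et, group, "relapse")
            assert abs(gr.p - lr.p) < 1e-6
            agree += 1
        assert agree >= 40

    def test_exhaustive_permutation_oracle_small_n(self, rng):
        """On n <= 12 the permutation p equals an independent enumeration of
        the Gray statistic over all group-label assignments."""
        from blcohort.survival import _gray_statistic

        for _ in range(4):
            n = 10
            time, et, _ = random_competing_data(rng, n)
            group = np.array(["A"] * 5 + ["B"] * 5)
            if (et == "relapse").sum() == 0:
                continue
            res = gray_test(time, et, group, "relapse", p_method="permutation")
            labels = np.unique(group)
            stat_obs, _ = _gray_statistic(time, et, group, labels, "relapse")
            n_ge = n_tot = 0
            for combo in combinations(range(n), 5):
                g = np.full(n, "B", dtype=object)
                g[list(combo)] = "A"
                s, _ = _gray_statistic(time, et, g, labels, "relapse")
                n_ge += s >= stat_obs - 1e-12
                n_tot += 1
            assert res.p == pytest.approx(n_ge / n_tot)

    def test_group_label_swap_invariance(self, rng):
        time, et, group = random_competing_data(rng, 80)
        a = gray_test(time, et, group, "relapse")
        swapped = np.where(group == "A", "B", "A")
        b = gray_test(time, et, swapped, "relapse")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_agrees_with_cmprsk(self, rng):
        import subprocess
        import pandas as pd
        import tempfile, os

        time, et, group = random_competing_data(rng, 150)
        df = pd.DataFrame({
            "time": time,
            "status": np.where(et == CENSORED, 0, np.where(et == "relapse", 1, 2)),
            "grp": group,
        })
        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            rcode = (f'd<-read.csv("{csv}");library(cmprsk);'
                     'ci<-cuminc(d$time,d$status,d$grp);cat(ci$Tests[1,1:2])')
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
            stat_r, p_r = (float(x) for x in out.stdout.split())
        ours = gray_test(time, et, group, "relapse")
        assert ours.statistic == pytest.approx(stat_r, rel=0.10)
        assert ours.p == pytest.approx(p_r, abs=0.02)

    def test_no_events_of_interest_raises(self):
        et = np.array(["death", CENSORED], dtype=object)
        with pytest.raises(ValueError):
            gray_test([1, 2], et, ["A", "B"], "relapse")
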