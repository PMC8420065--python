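import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from emtrn.bicliques import BicliqueModule
from emtrn.errors import ParameterError
from emtrn.survival import (
    fit_cox,
    logrank_test,
    risk_scores_and_split,
    screen_prognostic_modules,
    split_samples,
)


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events})


class TestSplit:
    def test_even_split_is_half_half(self):
        part = split_samples([f"s{i}" for i in range(10)], seed=3)
        assert (part == "train").sum() == 5 and (part == "test").sum() == 5

    def test_odd_split_puts_extra_in_train(self):
        part = split_samples([f"s{i}" for i in range(9)], seed=3)
        assert (part == "train").sum() == 5 and (part == "test").sum() == 4

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(12)]
        assert split_samples(ids, 7).equals(split_samples(ids, 7))
        assert not split_samples(ids, 7).equals(split_samples(ids, 8))

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            split_samples(["a", "b", "c"], 0)


class TestFitCox:
    def test_four_subject_example_matches_grid_oracle(self):
        """Single binary covariate, times (1,2,3,4), all events, x=(1,0,1,0):
        the partial-likelihood MLE is ~0.940 by golden-section search."""
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True] * 4
        x = [1.0, 0.0, 1.0, 0.0]
        beta_ref = oracles.cox_grid_mle(times, events, x)
        assert beta_ref == pytest.approx(0.940, abs=2e-3)
        expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(4)])
        coef = fit_cox(expr, _surv(times, events))
        assert coef[0] == pytest.approx(beta_ref, abs=1e-3)

    def test_random_instances_match_grid_oracle_and_zero_score(self, rng):
        for _ in range(5):
            n = 40
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.2 * np.exp(0.7 * x)))
            ev = rng.random(n) < 0.85
            if ev.sum() < 5:
                continue
            expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(n)])
            coef = fit_cox(expr, _surv(t, ev))
            ref = oracles.cox_grid_mle(t, ev, x)
            assert coef[0] == pytest.approx(ref, abs=1e-3)
            score = oracles.cox_score(coef, t, ev, x[:, None])
            assert np.linalg.norm(score) < 1e-6

    def test_constant_covariate_rejected(self):
        expr = pd.DataFrame([[1.0] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ParameterError):
            fit_cox(expr, _surv([1, 2, 3, 4, 5, 6], [True] * 6))

    def test_no_events_rejected(self):
        expr = pd.DataFrame([[0.1, 0.5, 0.9, 0.2]], index=["g"],
                            columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ParameterError, match="no events"):
            fit_cox(expr, _surv([1, 2, 3, 4], [False] * 4))

    def test_null_covariate_estimates_near_zero(self):
        """Independent covariate, n = 200: the MLE concentrates near 0."""
        gen = np.random.default_rng(42)
        hits = 0
        reps = 12
        for _ in range(reps):
            n = 200
            x = gen.normal(size=n)
            t = gen.exponential(10.0, size=n)
            ev = gen.random(n) < 0.9
            expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(n)])
            coef = fit_cox(expr, _surv(t, ev))
            hits += abs(coef[0]) < 0.15
        assert hits >= int(0.75 * reps)


class TestRiskScores:
    def test_linear_score_arithmetic(self):
        expr = pd.DataFrame(
            [[2.0], [1.0]], index=["g1", "g2"], columns=["s0"]
        )
        part = pd.Series(["train"], index=["s0"])
        out = risk_scores_and_split(np.array([0.5, -1.2]), expr, part)
        assert out.loc["s0", "score"] == pytest.approx(-0.2)

    def test_median_cutoff_and_tie_rule(self):
        expr = pd.DataFrame(
            [np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.0])],
            index=["g"], columns=[f"s{i}" for i in range(6)],
        )
        part = pd.Series(["train"] * 4 + ["test"] * 2, index=expr.columns)
        out = risk_scores_and_split(np.array([1.0]), expr, part)
        assert out.attrs["cutoff"] == pytest.approx(2.5)
        assert out.loc["s2", "risk_group"] == "high"    # 3 > 2.5
        assert out.loc["s4", "risk_group"] == "low"     # exactly at the cutoff
        assert out.loc["s5", "risk_group"] == "high"    # test scored identically

    def test_median_split_balances_training_groups(self, rng):
        n = 20
        expr = pd.DataFrame([rng.normal(size=n)], index=["g"],
                            columns=[f"s{i}" for i in range(n)])
        part = pd.Series(["train"] * n, index=expr.columns)
        out = risk_scores_and_split(np.array([1.0]), expr, part)
        counts = out["risk_group"].value_counts()
        assert counts["high"] == 10 and counts["low"] == 10


class TestLogrank:
    def test_four_subject_worked_example(self):
        """Group A events at (1,2), group B at (3,4): O_A = 2, E_A ~ 0.8333,
        V ~ 0.4722, chi-square ~ 2.88."""
        chi2_ref, O, E, V = oracles.logrank_hand([1, 2], [1, 1], [3, 4], [1, 1])
        assert O == 2 and E == pytest.approx(0.8333, abs=1e-4)
        assert V == pytest.approx(0.4722, abs=1e-4)
        assert chi2_ref == pytest.approx(2.88, abs=0.01)
        groups = pd.Series(["high", "high", "low", "low"],
                           index=["s0", "s1", "s2", "s3"])
        chi2, p = logrank_test(groups, _surv([1, 2, 3, 4], [True] * 4))
        assert chi2 == pytest.approx(chi2_ref, abs=1e-6)

    def test_matches_hand_oracle_on_random_data(self, rng):
        for _ in range(10):
            n = 30
            t = rng.exponential(5, size=n).round(1) + 0.1  # induce ties
            ev = rng.random(n) < 0.7
            lab = np.where(rng.random(n) < 0.5, "high", "low")
            if len(set(lab)) < 2 or ev.sum() == 0:
                continue
            groups = pd.Series(lab, index=[f"s{i}" for i in range(n)])
            chi2, p = logrank_test(groups, _surv(t, ev))
            ref, *_ = oracles.logrank_hand(
                t[lab == "high"], ev[lab == "high"], t[lab == "low"], ev[lab == "low"]
            )
            assert chi2 == pytest.approx(ref, rel=1e-6, abs=1e-9)

    def test_label_permutation_is_null(self):
        gen = np.random.default_rng(0)
        chis = []
        for _ in range(60):
            t = gen.exponential(5, size=24)
            ev = gen.random(24) < 0.8
            lab = np.array(["high"] * 12 + ["low"] * 12)
            gen.shuffle(lab)
            groups = pd.Series(lab, index=[f"s{i}" for i in range(24)])
            chi2, _p = logrank_test(groups, _surv(t, ev))
            chis.append(chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.5)  # E[chi2_1] = 1

    def test_separated_hazards_detected(self):
        """HR = 3 between groups of 100: the test is essentially always
        significant (scaled-down power check)."""
        gen = np.random.default_rng(1)
        hits = 0
        reps = 10
        for _ in range(reps):
            t_hi = gen.exponential(1 / 0.3, size=100)
            t_lo = gen.exponential(1 / 0.1, size=100)
            groups = pd.Series(["high"] * 100 + ["low"] * 100,
                               index=[f"s{i}" for i in range(200)])
            surv = _surv(np.concatenate([t_hi, t_lo]), [True] * 200)
            _chi2, p = logrank_test(groups, surv)
            hits += p <= 0.05
        assert hits >= 9

    def test_no_events_returns_p_one(self):
        groups = pd.Series(["high", "low"], index=["a", "b"])
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(groups, _surv([1.0, 2.0], [False, False], ["a", "b"]))
        assert p == 1.0 and np.isnan(chi2)


class TestScreen:
    def _strong_study(self, seed, coef=2.5):
        """A 4-gene module whose expression drives an (artificially strong)
        exponential hazard; used to exercise the screen mechanics."""
        gen = np.random.default_rng(seed)
        n = 60
        f = gen.normal(size=n)
        genes = [f"LNC_{i}" for i in range(2)] + [f"MRNA_{i}" for i in range(2)]
        expr = pd.DataFrame(
            [f + 0.3 * gen.normal(size=n) for _ in genes],
            index=genes, columns=[f"s{i}" for i in range(n)],
        )
        t = gen.exponential(1.0 / (0.1 * np.exp(coef * f)))
        surv = _surv(t, [True] * n, list(expr.columns))
        module = BicliqueModule("M0001", frozenset(genes[:2]), frozenset(genes[2:]))
        return expr.iloc[:2], expr.iloc[2:], surv, module

    def test_strong_module_retained_and_reported(self):
        lnc, mrna, surv, module = self._strong_study(0)
        models = screen_prognostic_modules([module], lnc, mrna, surv, seed=0)
        (m,) = models
        assert m.retained
        assert m.p_train <= 0.05 and m.p_test <= 0.05
        assert len(m.coefficients) == 4

    def test_null_module_rarely_retained(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            gen = np.random.default_rng(1000 + seed)
            n = 60
            genes = ["LNC_a", "LNC_b", "MRNA_a", "MRNA_b"]
            expr = pd.DataFrame(gen.normal(size=(4, n)) + 5, index=genes,
                                columns=[f"s{i}" for i in range(n)])
            t = gen.exponential(10.0, size=n)
            surv = _surv(t, [True] * n, list(expr.columns))
            module = BicliqueModule("M0001", frozenset(genes[:2]), frozenset(genes[2:]))
            models = screen_prognostic_modules([module], expr.iloc[:2], expr.iloc[2:],
                                               surv, seed=seed)
            hits += models[0].retained
        # two independent 5%-level tests must both reject: ~0.25% nominal
        assert hits <= 2

    def test_unfittable_module_flagged_not_retained(self):
        lnc, mrna, surv, module = self._strong_study(3)
        lnc = lnc.copy()
        lnc.iloc[0] = 1.0  # constant covariate
        models = screen_prognostic_modules([module], lnc, mrna, surv, seed=0)
        assert not models[0].retained and models[0].flags

    def test_empty_module_list(self):
        lnc, mrna, surv, _module = self._strong_study(4)
        assert screen_prognostic_modules([], lnc, mrna, surv, seed=0) == []
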