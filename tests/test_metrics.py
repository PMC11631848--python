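"""Metric-suite tests: closed-form cases, loop oracles, method comparison."""

import numpy as np
import pytest
from scipy import stats

import stesi
from stesi.data import SimulationSample
from stesi.inverse import InverseSolution
from stesi.metrics import PSNR_CAP_DB


class TestEvaluationInstant:
    def test_gaussian_peak_on_grid(self):
        t = np.arange(100) / 500.0
        X = np.zeros((3, 100))
        X[1] = np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
        assert stesi.evaluation_instant(X, 2) == 50

    def test_tie_takes_first_index(self):
        X = np.zeros((2, 10))
        X[0, [3, 7]] = 5.0
        assert stesi.evaluation_instant(X, 1) == 3

    def test_sign_flip_invariant(self):
        X = np.zeros((2, 10))
        X[0, 6] = -9.0
        X[0, 2] = 4.0
        assert stesi.evaluation_instant(X, 1) == 6

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            stesi.evaluation_instant(np.zeros((2, 5)), 1)


class TestLocalizationError:
    def test_perfect_estimate(self, rng):
        x = rng.standard_normal(10)
        pos = rng.standard_normal((10, 3))
        le, deg = stesi.localization_error(x, x, pos)
        assert le == 0.0 and not deg

    def test_three_four_five(self):
        pos = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        le, _ = stesi.localization_error(np.array([1.0, 0.1]),
                                         np.array([0.1, 1.0]), pos)
        assert le == pytest.approx(5.0)

    def test_loop_oracle(self, rng):
        for _ in range(30):
            x = rng.standard_normal(12)
            xh = rng.standard_normal(12)
            pos = rng.standard_normal((12, 3)) * 40
            le, _ = stesi.localization_error(x, xh, pos)
            # brute force
            bi, bj, bv, bw = 0, 0, -1.0, -1.0
            for i in range(12):
                if abs(x[i]) > bv:
                    bv, bi = abs(x[i]), i
                if abs(xh[i]) > bw:
                    bw, bj = abs(xh[i]), i
            assert le == pytest.approx(np.linalg.norm(pos[bi] - pos[bj]))

    def test_zero_estimate_degenerate(self, rng):
        pos = rng.standard_normal((5, 3))
        le, deg = stesi.localization_error(np.ones(5), np.zeros(5), pos)
        assert deg


class TestExtentAUC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        assert stesi.extent_auc(scores, scores, {1, 2}) == 100.0

    def test_anti_separation(self):
        x = np.array([0.1, 0.2, 0.9, 0.8])
        assert stesi.extent_auc(x, x, {1, 2}) == 0.0

    def test_half_auc_case(self):
        # labels (1,1,0), scores (0.9, 0.1, 0.8): one of two positive-negative
        # pairs ranked correctly
        xh = np.array([0.9, 0.1, 0.8])
        assert stesi.extent_auc(xh, xh, {1, 2}) == pytest.approx(50.0)

    def test_rank_pair_oracle(self, rng):
        # AUC == Mann-Whitney U / (n_pos * n_neg)
        for _ in range(200):
            n = int(rng.integers(5, 25))
            scores = rng.standard_normal(n)
            n_pos = int(rng.integers(1, n))
            members = set(rng.choice(np.arange(1, n + 1), n_pos,
                                     replace=False).tolist())
            auc = stesi.extent_auc(scores, scores, members)
            s = np.abs(scores)
            pos = [s[m - 1] for m in members]
            neg = [s[i] for i in range(n) if (i + 1) not in members]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(100.0 * u / (len(pos) * len(neg)))

    def test_all_labels_identical_rejected(self):
        with pytest.raises(ValueError):
            stesi.extent_auc(np.ones(3), np.ones(3), {1, 2, 3})


class TestNMSE:
    def test_scale_invariance(self, rng):
        x = rng.standard_normal(20)
        assert stesi.nmse(x, 7.3 * x) == pytest.approx(0.0, abs=1e-30)

    def test_sign_flip_value(self, rng):
        x = rng.standard_normal(20)
        expected = np.mean((2 * x / np.max(np.abs(x))) ** 2)
        assert stesi.nmse(x, -x) == pytest.approx(expected)

    def test_loop_oracle(self, rng):
        x = rng.standard_normal(15)
        xh = rng.standard_normal(15)
        got = stesi.nmse(x, xh)
        nt, nh = np.max(np.abs(x)), np.max(np.abs(xh))
        acc = sum((x[i] / nt - xh[i] / nh) ** 2 for i in range(15)) / 15
        assert got == pytest.approx(acc)


class TestPSNR:
    def test_perfect_reconstruction_capped(self, rng):
        X = rng.standard_normal((6, 9))
        assert stesi.psnr(X, X) == PSNR_CAP_DB

    def test_uniform_error_twenty_db(self):
        # both matrices already max-normalized (peaks 1.0), estimate offset
        # by a uniform 0.1: PSNR = 10 log10(1 / 0.01) = 20 dB
        X = np.full((5, 4), 0.2)
        X[2, 1] = 1.0
        X[0, 0] = -0.9
        X_hat = X - 0.1  # contains -1.0 -> its own max-abs stays 1
        assert np.max(np.abs(X)) == 1.0 and np.max(np.abs(X_hat)) == 1.0
        assert stesi.psnr(X, X_hat) == pytest.approx(20.0)

    def test_loop_oracle(self, rng):
        X = rng.standard_normal((4, 6))
        Xh = rng.standard_normal((4, 6))
        got = stesi.psnr(X, Xh)
        Xn = X / np.max(np.abs(X))
        Xhn = Xh / np.max(np.abs(Xh))
        acc = 0.0
        for i in range(4):
            for t in range(6):
                acc += (Xn[i, t] - Xhn[i, t]) ** 2
        mse = acc / 24
        assert got == pytest.approx(10 * np.log10(np.max(Xn ** 2) / mse),
                                    abs=1e-10)


class TestTimeError:
    def test_identity_zero(self, rng):
        X = rng.standard_normal((5, 40))
        te, deg = stesi.time_error(X, X, 500.0)
        assert te == 0.0 and not deg

    def test_ten_sample_shift(self, rng):
        X = np.zeros((3, 50))
        X[1, 20] = 1.0
        Xh = np.zeros((3, 50))
        Xh[1, 30] = 1.0
        te, _ = stesi.time_error(X, Xh, 500.0)
        assert te == pytest.approx(20.0)

    def test_column_sum_oracle(self, rng):
        X = rng.standard_normal((6, 30))
        Xh = rng.standard_normal((6, 30))
        te, _ = stesi.time_error(X, Xh, 250.0)
        ta = max(range(30), key=lambda t: sum(abs(X[i, t]) for i in range(6)))
        tb = max(range(30), key=lambda t: sum(abs(Xh[i, t]) for i in range(6)))
        assert te == pytest.approx(abs(ta - tb) * 1000 / 250.0)

    def test_zero_estimate_flagged(self, rng):
        X = rng.standard_normal((3, 20))
        te, deg = stesi.time_error(X, np.zeros((3, 20)), 500.0)
        assert deg and te == pytest.approx(20 / 500 * 1000)


def _sample_from(head, X, fs=500.0, seed_region=None, order=0, members=None):
    seed_region = seed_region or int(np.argmax(np.abs(X).max(axis=1))) + 1
    members = members or [seed_region]
    Y = head.leadfield_regional @ X
    return SimulationSample(X=X, Y_clean=Y, Y=Y,
                            active_regions=[(seed_region, order, members)],
                            snr_db=300.0, generator_tag="sereega", rng_seed=0,
                            fs=fs)


class TestEvaluateSample:
    def test_perfect_solution(self, toy_head, rng):
        X = np.zeros((50, 30))
        X[4] = np.exp(-0.5 * ((np.arange(30) - 11) / 4.0) ** 2)
        sample = _sample_from(toy_head, X, seed_region=5)
        sol = InverseSolution(X_hat=X.copy(), method="oracle", config={})
        rep = stesi.evaluate_sample(sample, sol, toy_head)
        assert rep.le_mm == 0.0
        assert rep.auc_pct == 100.0
        assert rep.nmse == pytest.approx(0.0, abs=1e-30)
        assert rep.psnr_db == PSNR_CAP_DB
        assert rep.time_error_ms == 0.0
        assert rep.t0 == pytest.approx(11 / 500.0)

    def test_zero_solution_guards(self, toy_head):
        X = np.zeros((50, 30))
        X[4, 10] = 1.0
        sample = _sample_from(toy_head, X, seed_region=5)
        sol = InverseSolution(X_hat=np.zeros_like(X), method="null", config={})
        rep = stesi.evaluate_sample(sample, sol, toy_head)
        assert rep.auc_pct == 50.0
        assert rep.degenerate_flags.get("le") or rep.le_mm >= 0
        assert rep.degenerate_flags.get("te")
        assert np.isfinite([rep.le_mm, rep.auc_pct, rep.nmse, rep.psnr_db,
                            rep.time_error_ms]).all()

    def test_scale_invariance_of_all_metrics(self, toy_head, rng):
        X = np.zeros((50, 30))
        X[7] = np.exp(-0.5 * ((np.arange(30) - 15) / 5.0) ** 2)
        sample = _sample_from(toy_head, X, seed_region=8)
        Xh = X + 0.05 * rng.standard_normal(X.shape)
        r1 = stesi.evaluate_sample(
            sample, InverseSolution(X_hat=Xh, method="a", config={}), toy_head)
        r2 = stesi.evaluate_sample(
            sample, InverseSolution(X_hat=123.4 * Xh, method="a", config={}),
            toy_head)
        for f in ("le_mm", "auc_pct", "nmse", "psnr_db", "time_error_ms"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f))


class TestCompareMethods:
    def _reports(self, method, values):
        return [stesi.MetricReport(sample_id=i, method=method, t0=0.0,
                                   le_mm=v, auc_pct=50.0, nmse=0.1,
                                   psnr_db=20.0, time_error_ms=1.0)
                for i, v in enumerate(values)]

    def test_identical_methods_f_zero(self):
        reps = self._reports("a", [1.0, 2.0, 3.0]) + \
            self._reports("b", [1.0, 2.0, 3.0])
        table = stesi.compare_methods(reps)
        assert table.anova.loc["auc_pct", "F"] == 0.0
        assert table.anova.loc["auc_pct", "p"] == 1.0
        assert np.allclose(table.tukey["auc_pct"].values, 1.0)

    def test_separated_distributions_significant(self, rng):
        a = rng.normal(5.0, 1.0, 100)
        b = rng.normal(50.0, 1.0, 100)
        table = stesi.compare_methods(self._reports("a", a)
                                      + self._reports("b", b))
        assert table.anova.loc["le_mm", "p"] < 1e-6
        assert table.tukey["le_mm"].loc["a", "b"] < 0.05

    def test_three_methods_pairwise_entries(self, rng):
        reps = sum((self._reports(m, rng.normal(size=5))
                    for m in ("a", "b", "c")), [])
        table = stesi.compare_methods(reps)
        t = table.tukey["le_mm"]
        assert t.shape == (3, 3)
        assert np.allclose(t.values, t.values.T)

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            stesi.compare_methods(self._reports("a", [1.0, 2.0]))
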