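import itertools

import numpy as np
import pandas as pd
import pytest

from riborhythm.rhythm_stats import (
    TimeCourse,
    bh_adjust,
    cosinor_fit,
    exact_kendall_null,
    jtk_scan,
    jtk_test,
    kendall_tau_b,
    lomb_scargle,
    rhythm_table,
)


class TestKendallTauB:
    def test_perfect_concordance(self):
        tau, S = kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4])
        assert (tau, S) == (1.0, 6.0)

    def test_perfect_discordance(self):
        tau, S = kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1])
        assert (tau, S) == (-1.0, -6.0)

    def test_tie_corrected_denominator(self):
        # pairs: (1,1)~(2,1) tied y; (1,1)<(3,2); (2,1)<(3,2) -> S = 2
        tau, S = kendall_tau_b([1, 2, 3], [1, 1, 2])
        assert S == 2.0
        assert tau == pytest.approx(2 / np.sqrt(3 * 2))

    def test_all_tied_y_undefined(self):
        tau, S = kendall_tau_b([1, 2, 3], [5, 5, 5])
        assert np.isnan(tau)
        assert S == 0.0

    def test_agrees_with_scipy(self, rng):
        from scipy import stats

        for _ in range(50):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            tau, _ = kendall_tau_b(x, y)
            ref = stats.kendalltau(x, y).statistic
            assert tau == pytest.approx(ref, abs=1e-12)


def brute_force_null(template):
    """Exact S distribution by enumerating every permutation of the data."""
    n = len(template)
    counts = {}
    for perm in itertools.permutations(range(n)):
        _, S = kendall_tau_b(np.array(perm, dtype=float), template)
        counts[S] = counts.get(S, 0) + 1
    total = sum(counts.values())
    support = np.array(sorted(counts))
    pmf = np.array([counts[s] / total for s in support])
    return support, pmf


class TestExactKendallNull:
    def test_n3_no_ties_enumeration(self):
        support, pmf = exact_kendall_null(3)
        dist = dict(zip(support, pmf))
        assert dist[3.0] == pytest.approx(1 / 6)
        assert dist[3.0] + dist[-3.0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_permutation_enumeration_untied(self, n):
        support, pmf = exact_kendall_null(n)
        ref_support, ref_pmf = brute_force_null(np.arange(n, dtype=float))
        nz = pmf > 0
        assert np.array_equal(support[nz], ref_support)
        assert np.allclose(pmf[nz], ref_pmf)

    @pytest.mark.parametrize(
        "template",
        [
            (0.0, 0.0, 1.0, 1.0, -1.0),
            (1.0, 0.5, -0.5, -1.0, -0.5, 0.5, 1.0),
            (2.0, 2.0, 2.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_matches_permutation_enumeration_tied_templates(self, template):
        template = np.array(template)
        _, counts = np.unique(template, return_counts=True)
        support, pmf = exact_kendall_null(
            len(template), tuple(sorted(int(c) for c in counts))
        )
        ref_support, ref_pmf = brute_force_null(template)
        nz = pmf > 0
        assert np.array_equal(support[nz], ref_support)
        assert np.allclose(pmf[nz], ref_pmf)

    def test_probabilities_sum_to_one(self):
        for pattern in [(1,) * 10, (2, 2, 2, 2, 2), (4, 4, 4, 2)]:
            _, pmf = exact_kendall_null(sum(pattern), pattern)
            assert pmf.sum() == pytest.approx(1.0)

    def test_infeasible_n_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            exact_kendall_null(30)


class TestJTK:
    def test_noiseless_cosine_recovers_phase(self, ct_times):
        y = np.cos(2 * np.pi * (ct_times - 8) / 24)
        res = jtk_test(TimeCourse("x", ct_times, y))
        assert res.phase == 8.0
        assert res.period == 24.0
        # better than any other template on the grid
        others = jtk_scan(y[None, :], ct_times, periods=(24.0,), phase_step=4.0)
        assert res.p == pytest.approx(others["p"].iloc[0])
        assert res.amplitude == pytest.approx(1.0)
        assert res.mesor == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_p_one(self, ct_times):
        res = jtk_test(TimeCourse("x", ct_times, np.full(len(ct_times), 3.0)))
        assert res.p == 1.0
        assert np.isnan(res.tau)

    def test_antiphase_series_detected(self, ct_times):
        """A trough at CT8 matches the CT20 peak template."""
        y = -np.cos(2 * np.pi * (ct_times - 8) / 24)
        res = jtk_test(TimeCourse("x", ct_times, y))
        assert res.phase == 20.0
        assert res.p < 1e-4

    def test_too_few_points_missing_result(self):
        res = jtk_test(TimeCourse("x", np.array([0.0, 4, 8]), np.array([1.0, 2, 3])))
        assert np.isnan(res.period)
        assert res.p == 1.0

    def test_null_calibration(self, ct_times, rng):
        """Realized type-I error close to nominal on iid Gaussian series."""
        Y = rng.standard_normal((4000, len(ct_times)))
        df = jtk_scan(Y, ct_times)
        rate = float((df["p"] < 0.05).mean())
        assert 0.02 < rate < 0.08

    def test_phase_recovery_under_noise(self, ct_times, rng):
        M, A = 10.0, 0.5
        sigma = M * A / 2  # amplitude-to-noise ratio 2
        Y = M * (1 + A * np.cos(2 * np.pi * (ct_times - 8) / 24))
        Y = Y + sigma * rng.standard_normal((400, len(ct_times)))
        df = jtk_scan(Y, ct_times)
        d = np.abs(df["phase"] - 8) % 24
        d = np.minimum(d, 24 - d)
        assert (d <= 4).mean() >= 0.9
        assert df["phase"].mode()[0] == 8.0

    def test_replicates_share_template_value(self):
        """Splitting each point into two replicates preserves the winner."""
        t7 = np.arange(0.0, 25.0, 4.0)
        y7 = np.cos(2 * np.pi * (t7 - 12) / 24)
        t14 = np.repeat(t7, 2)
        y14 = np.repeat(y7, 2)
        r7 = jtk_test(TimeCourse("a", t7, y7))
        r14 = jtk_test(TimeCourse("a", t14, y14))
        assert r7.phase == r14.phase == 12.0


class TestCosinor:
    def test_closed_form_recovery(self, ct_times):
        y = 5 + 2 * np.cos(2 * np.pi * (ct_times - 8) / 24)
        M, A, phi, p = cosinor_fit((ct_times, y), 24.0)
        assert M == pytest.approx(5.0, abs=1e-9)
        assert A == pytest.approx(2.0, abs=1e-9)
        assert phi == pytest.approx(8.0, abs=1e-9)
        assert p == 0.0

    def test_shift_equivariance(self, ct_times, rng):
        y = 3 + np.cos(2 * np.pi * (ct_times - 5) / 24) + 0.1 * rng.standard_normal(
            len(ct_times)
        )
        M1, A1, phi1, _ = cosinor_fit((ct_times, y), 24.0)
        M2, A2, phi2, _ = cosinor_fit((ct_times, y + 7.0), 24.0)
        assert M2 == pytest.approx(M1 + 7.0)
        assert A2 == pytest.approx(A1)
        assert phi2 == pytest.approx(phi1)

    def test_amplitude_unbiased_on_simulation(self, ct_times, rng):
        """Mean amplitude estimate ~ 1 within Monte-Carlo error (A=1, sd=0.25)."""
        amps = []
        base = np.cos(2 * np.pi * (ct_times - 6) / 24)
        for _ in range(1000):
            y = 2 + base + 0.25 * rng.standard_normal(len(ct_times))
            _, A, _, _ = cosinor_fit((ct_times, y), 24.0)
            amps.append(A)
        assert np.mean(amps) == pytest.approx(1.0, abs=0.02)

    def test_null_p_roughly_uniform(self, ct_times, rng):
        ps = [
            cosinor_fit((ct_times, rng.standard_normal(len(ct_times))), 24.0)[3]
            for _ in range(1000)
        ]
        assert abs(np.mean(ps) - 0.5) < 0.05
        assert 0.03 < np.mean(np.array(ps) < 0.05) < 0.08

    def test_singular_design_raises(self):
        t = np.array([0.0, 24.0, 48.0, 72.0])
        with pytest.raises(np.linalg.LinAlgError):
            cosinor_fit((t, np.array([1.0, 2, 3, 4])), 24.0)


class TestLombScargle:
    def test_peak_at_24h_for_long_series(self):
        # 12 simulated days in 6-min bins
        t = np.arange(0, 12 * 24, 0.1)
        y = np.cos(2 * np.pi * (t - 3) / 24)
        pg = lomb_scargle((t, y))
        peak = pg.loc[pg["is_peak"], "period_hours"].iloc[0]
        assert peak == pytest.approx(24.0, abs=0.1)

    def test_noise_peak_below_cosine_peak(self, rng):
        t = np.arange(0, 12 * 24, 0.1)
        cos_power = lomb_scargle((t, np.cos(2 * np.pi * t / 24)))["power"].max()
        noise_power = lomb_scargle((t, rng.standard_normal(len(t))))["power"].max()
        assert noise_power < cos_power

    def test_constant_series_zero_power(self):
        t = np.arange(0, 48, 1.0)
        pg = lomb_scargle((t, np.full(len(t), 2.0)))
        assert (pg["power"] == 0).all()


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_monotone_and_at_least_p(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_fdr_control_on_planted_mixture(self, rng):
        """Realized FDR <= 0.05 within binomial error, 10% strong signals."""
        n, frac = 5000, 0.1
        is_alt = rng.random(n) < frac
        z = rng.standard_normal(n) + np.where(is_alt, 4.0, 0.0)
        from scipy import stats

        p = stats.norm.sf(z)
        adj = bh_adjust(p)
        rejected = adj < 0.05
        if rejected.sum():
            fdr = (rejected & ~is_alt).sum() / rejected.sum()
            assert fdr <= 0.05 + 0.02


def test_rhythm_table_output_contract(ct_times, rng):
    mat = pd.DataFrame(
        rng.poisson(20, (10, len(ct_times))).astype(float),
        index=[f"f{i}" for i in range(10)],
    )
    out = rhythm_table(mat, ct_times)
    assert list(out.columns) == [
        "feature_id", "period", "phase", "tau", "amplitude", "mesor", "p", "p_adj",
    ]
    assert (out["p_adj"] >= out["p"] - 1e-12).all()
    assert ((out["phase"] >= 0) & (out["phase"] < out["period"])).all()
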