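"""Diffusion primitives, expected counts, likelihood and model fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import comb

from gcforces.sfsmodel import (
    SfsModel,
    SpectrumParams,
    binned_sfs,
    equilibrium_gc,
    expected_counts,
    fit_sfs_model,
    fixation_factor,
    joint_model_scan,
    loglik,
    lrt,
    nested_force_tests,
    sfs_density,
    solve_lambda,
)
from gcforces.simulate import SimScenario, simulate_counts
from gcforces.spectra import CategorySfsSet


class TestSfsDensity:
    def test_neutral_limit_is_one_over_x(self):
        for x in (0.1, 0.3, 0.7, 0.95):
            assert sfs_density(x, 0.0) == pytest.approx(1 / x, rel=1e-12)

    def test_known_value(self):
        assert sfs_density(0.5, 1.0) == pytest.approx(2.4898, abs=1e-4)

    def test_positive_gamma_lifts_density(self):
        for x in np.linspace(0.05, 0.95, 10):
            assert sfs_density(x, 1.0) > sfs_density(x, 0.0) * (1 if x > 0.4 else 0)
        # monotone in gamma pointwise
        for x in (0.2, 0.5, 0.8):
            vals = [sfs_density(x, g) for g in (-2, -1, 0, 1, 2)]
            assert np.all(np.diff(vals) > 0)

    def test_series_switch_is_continuous(self):
        # straddle the switch by a negligible gamma increment: any residual
        # difference is the jump between the series and exact branches
        for x in (0.1, 0.5, 0.9):
            below = sfs_density(x, 1e-6 - 1e-12)
            above = sfs_density(x, 1e-6 + 1e-12)
            assert below == pytest.approx(above, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sfs_density(0.0, 1.0)
        with pytest.raises(ValueError):
            sfs_density(1.0, 1.0)


class TestBinnedSfs:
    @pytest.mark.parametrize("n", [2, 4, 20, 50])
    def test_neutral_closed_form(self, n):
        F = binned_sfs(0.0, n)
        assert np.max(np.abs(F - 1 / np.arange(1, n))) < 1e-9

    def test_matches_adaptive_quadrature_oracle(self):
        n, gamma = 4, 2.0
        F = binned_sfs(gamma, n)
        for i in range(1, n):
            oracle, _ = quad(
                lambda x: comb(n, i) * x**i * (1 - x) ** (n - i) * sfs_density(x, gamma),
                0, 1, epsrel=1e-12,
            )
            assert F[i - 1] == pytest.approx(oracle, abs=1e-8)

    def test_positive_gamma_shifts_mass_to_high_classes(self):
        n = 12
        ratio = binned_sfs(2.0, n) / binned_sfs(0.0, n)
        assert np.all(np.diff(ratio) > 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            binned_sfs(0.0, 1)


class TestFixationFactor:
    def test_neutral_value(self):
        assert fixation_factor(0.0) == pytest.approx(1.0)

    def test_known_value(self):
        assert fixation_factor(2.0) == pytest.approx(2.3130, abs=1e-4)

    def test_antisymmetry_identity(self):
        g = np.linspace(-30, 30, 201)
        assert np.max(np.abs(fixation_factor(g) - fixation_factor(-g) - g)) < 1e-12


class TestEquilibriumGc:
    def test_no_bias_values(self):
        assert equilibrium_gc(1.05, 0.0) == pytest.approx(0.49, abs=0.005)
        assert equilibrium_gc(1.0, 0.0) == pytest.approx(0.5)

    def test_solve_lambda_values(self):
        assert solve_lambda(0.42, 0.154) == pytest.approx(1.61, abs=0.005)
        assert solve_lambda(0.42, 0.243) == pytest.approx(1.76, abs=0.005)
        assert solve_lambda(0.5, 0.0) == pytest.approx(1.0)

    @given(st.floats(0.05, 0.95), st.floats(-3, 3))
    def test_round_trip_identity(self, gc, B):
        assert equilibrium_gc(solve_lambda(gc, B), B) == pytest.approx(gc, abs=1e-12)


class TestExpectedCounts:
    def test_neutral_poisson_random_field(self):
        p = SpectrumParams(n=10, set_name="gBGC", lam=2.0,
                           theta={"WS": 50.0, "NEUTRAL": 30.0}, tau=0.7)
        mu_sfs, mu_div = expected_counts(p)
        i = np.arange(1, 10)
        assert mu_sfs["WS"] == pytest.approx(50.0 / i, rel=1e-9)
        assert mu_sfs["SW"] == pytest.approx(100.0 / i, rel=1e-9)
        assert mu_sfs["NEUTRAL"] == pytest.approx(30.0 / i, rel=1e-9)
        assert mu_div["WS"] == pytest.approx(0.7 * 50)
        assert mu_div["SW"] == pytest.approx(0.7 * 100)

    def test_full_mixing_symmetry(self):
        """Near-total polarization error with lambda=1 mirrors the reverse
        spectra into each other."""
        common = dict(n=8, set_name="gBGC", lam=1.0, theta={"WS": 40.0, "NEUTRAL": 10.0},
                      b0=0.6, b1=0.6)
        mu_e, _ = expected_counts(SpectrumParams(e=0.499, **common))
        assert mu_e["WS"] == pytest.approx(mu_e["SW"][::-1], rel=1e-2)

    def test_pair_totals_invariant_in_error(self):
        totals = []
        for e in (0.0, 0.1, 0.3, 0.45):
            p = SpectrumParams(n=12, set_name="gBGC", lam=1.8,
                               theta={"WS": 60.0, "NEUTRAL": 25.0},
                               b0=0.4, b1=0.7, e=e, tau=0.5)
            mu_sfs, mu_div = expected_counts(p)
            totals.append(mu_sfs["WS"].sum() + mu_sfs["SW"].sum())
        assert np.ptp(totals) < 1e-8

    def test_demography_multiplies_classes(self):
        r = np.ones(9)
        r[4] = 3.0
        p0 = SpectrumParams(n=10, set_name="gBGC", lam=1.5,
                            theta={"WS": 50.0, "NEUTRAL": 30.0}, b1=0.3)
        p1 = SpectrumParams(n=10, set_name="gBGC", lam=1.5,
                            theta={"WS": 50.0, "NEUTRAL": 30.0}, b1=0.3, r=r)
        m0, _ = expected_counts(p0)
        m1, _ = expected_counts(p1)
        assert m1["WS"][4] == pytest.approx(3 * m0["WS"][4])
        assert m1["WS"][0] == pytest.approx(m0["WS"][0])

    def test_r_normalization_enforced(self):
        with pytest.raises(ValueError, match="r_1"):
            SpectrumParams(n=5, set_name="gBGC", r=np.array([2.0, 1, 1, 1]))


class TestLoglik:
    def test_data_at_expectation_is_a_stationary_point(self):
        """The Poisson score in any multiplicative parameter vanishes when
        observed counts equal their expectations."""
        p = SpectrumParams(n=10, set_name="gBGC", lam=1.7,
                           theta={"WS": 80.0, "NEUTRAL": 40.0}, b0=0.3, b1=0.5,
                           e=0.02, tau=0.5)
        mu_sfs, mu_div = expected_counts(p)
        data = CategorySfsSet(n=10, set_name="gBGC",
                              sfs={c: mu_sfs[c] for c in mu_sfs}, div=mu_div)
        base = loglik(p, data)
        for eps in (0.995, 1.005):
            q = SpectrumParams(n=10, set_name="gBGC", lam=p.lam,
                               theta={"WS": 80.0 * eps, "NEUTRAL": 40.0},
                               b0=0.3, b1=0.5, e=0.02, tau=0.5)
            assert loglik(q, data) < base

    def test_empty_data_zero_mu_limit(self):
        data = CategorySfsSet(n=6, set_name="gBGC")
        p = SpectrumParams(n=6, set_name="gBGC",
                           theta={"WS": 1e-12, "NEUTRAL": 1e-12}, tau=1e-12)
        assert loglik(p, data) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_n_rejected(self):
        data = CategorySfsSet(n=6, set_name="gBGC")
        p = SpectrumParams(n=8, set_name="gBGC")
        with pytest.raises(ValueError):
            loglik(p, data)


class TestFit:
    def test_parameter_recovery_single_replicate(self):
        sc = SimScenario(n=20, lam=1.7, b0=0.3, b1=0.5, e=0.02,
                         target_snps=5e4, seed=1)
        fr = fit_sfs_model(simulate_counts(sc), b0="free", b1="free",
                           n_starts=2, seed=0, compute_ci=True)
        assert fr.estimates["B0"] == pytest.approx(0.3, abs=0.1)
        assert fr.estimates["B1"] == pytest.approx(0.5, abs=0.1)
        assert fr.estimates["lambda"] == pytest.approx(1.7, abs=0.15)
        lo, hi = fr.conf_int["B0"]
        assert lo < fr.estimates["B0"] < hi

    def test_neutral_data_recovers_zero_force(self):
        """Under neutrality the force estimates centre on zero (each
        replicate's estimate carries sampling noise of order 0.1)."""
        b0s, b1s = [], []
        for seed in range(6):
            sc = SimScenario(n=12, lam=1.5, b0=0.0, b1=0.0, e=0.02,
                             target_snps=4e4, seed=seed)
            fr = fit_sfs_model(simulate_counts(sc), b0="free", b1="free",
                               n_starts=2, seed=0, compute_ci=False)
            b0s.append(fr.estimates["B0"])
            b1s.append(fr.estimates["B1"])
        assert abs(np.mean(b0s)) < 0.05
        assert abs(np.mean(b1s)) < 0.05
        assert np.max(np.abs(b0s + b1s)) < 0.3
        sc = SimScenario(n=12, lam=1.5, b0=0.0, b1=0.0, e=0.02,
                         target_snps=4e4, seed=0)
        fr = nested_force_tests(simulate_counts(sc), n_starts=2, seed=0,
                                compute_ci=False)
        assert fr.lrt_pvalues["recent=ancestral"] > 0.01

    def test_optimizer_stable_across_start_permutations(self):
        sc = SimScenario(n=10, lam=1.7, b0=0.3, b1=0.3, target_snps=2e4, seed=3)
        data = simulate_counts(sc)
        lls = [
            fit_sfs_model(data, b0="free", b1="free", n_starts=3, seed=s,
                          compute_ci=False).loglik
            for s in (0, 99)
        ]
        assert lls[0] == pytest.approx(lls[1], abs=1e-4)

    def test_set_mismatch_rejected(self):
        data = CategorySfsSet(n=6, set_name="SCU")
        with pytest.raises(ValueError):
            SfsModel(set_name="gBGC").fit(data)


class TestLrt:
    def _two_fits(self, seed):
        sc = SimScenario(n=10, lam=1.7, b0=0.3, b1=0.3, target_snps=2e4, seed=seed)
        data = simulate_counts(sc)
        null = fit_sfs_model(data, b0="free", b1="equal", n_starts=1, seed=0,
                             compute_ci=False)
        alt = fit_sfs_model(data, b0="free", b1="free", n_starts=1, seed=0,
                            compute_ci=False)
        return null, alt

    def test_chi2_mapping(self):
        null, alt = self._two_fits(5)
        p = lrt(null, alt)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(2 * (alt.loglik - null.loglik), 1))

    def test_equal_likelihood_p_one(self):
        null, alt = self._two_fits(6)
        alt.loglik = null.loglik
        assert lrt(null, alt) == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        null, alt = self._two_fits(7)
        null.loglik = alt.loglik + 1.0
        with pytest.raises(ValueError):
            lrt(null, alt)
        with pytest.raises(ValueError):
            lrt(alt, alt)


class TestJointScan:
    def test_b_only_data_selects_gbgc_model(self):
        sc = SimScenario(n=10, set_name="joint", lam=1.7, b0=0.4, b1=0.4,
                         target_snps=2.5e4, seed=8)
        scan = joint_model_scan(simulate_counts(sc), n_starts=1, seed=0)
        assert "B0" in scan.best_label_
        assert "S0" not in scan.best_label_ and "S1" not in scan.best_label_
        assert len(scan.scan_) == 16
        # AIC identity on the reported models
        ok = scan.scan_[scan.scan_["failed"] == ""]
        assert np.allclose(ok["aic"], 2 * ok["n_free"] - 2 * ok["loglik"])

    def test_tie_rule_prefers_fewer_parameters(self):
        sc = SimScenario(n=10, set_name="joint", lam=1.7, b0=0.4, b1=0.4,
                         target_snps=2.5e4, seed=9)
        scan = joint_model_scan(simulate_counts(sc), n_starts=1, seed=0)
        ok = scan.scan_[scan.scan_["failed"] == ""]
        amin = ok["aic"].min()
        near = ok[ok["aic"] - amin < 2.0]
        assert scan.best_.n_free == near["n_free"].min()
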