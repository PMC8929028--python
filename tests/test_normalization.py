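import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq, minimize

from hprep.io_formats import AnchorSet
from hprep import normalization as norm
from hprep.synthetic_data import simulate_ztp_pairs

BETA = (1.0, 0.3, -0.2, 0.1, 0.5)


def _pairs(bins, counts=3, **cov):
    rows = []
    for b1, b2 in bins:
        rows.append(
            dict(chrom="chr1", bin1=b1, bin2=b2, count=counts,
                 fl=cov.get("fl", 0.0), gc=0.0, ms=0.0, ip=0.0)
        )
    return pd.DataFrame(rows)


class TestClassification:
    def test_and_xor_not_by_anchor_membership(self):
        anchors = AnchorSet(10_000, {"chr1": np.array([0, 30_000])})
        pairs = _pairs([(0, 30_000), (0, 20_000), (10_000, 50_000)])
        parts = norm.classify_pairs(pairs, anchors)
        assert list(parts["AND"][["bin1", "bin2"]].itertuples(index=False, name=None)) == [(0, 30_000)]
        assert list(parts["XOR"][["bin1", "bin2"]].itertuples(index=False, name=None)) == [(0, 20_000)]
        assert list(parts["NOT"][["bin1", "bin2"]].itertuples(index=False, name=None)) == [(10_000, 50_000)]

    def test_empty_anchor_set_makes_everything_not(self):
        anchors = AnchorSet(10_000, {})
        pairs = _pairs([(0, 30_000), (0, 20_000)])
        parts = norm.classify_pairs(pairs, anchors)
        assert len(parts["NOT"]) == 2 and parts["AND"].empty and parts["XOR"].empty

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(4)
        anchors = AnchorSet(10_000, {"chr1": rng.choice(100, 20, replace=False).astype(np.int64) * 10_000})
        bins = rng.choice(100, size=(60, 2), replace=True) * 10_000
        bins = bins[bins[:, 0] != bins[:, 1]]
        pairs = _pairs([tuple(sorted(b)) for b in bins])
        parts = norm.classify_pairs(pairs, anchors)
        assert sum(len(p) for p in parts.values()) == len(pairs)


class TestShortLongSplit:
    def test_boundary_goes_to_short(self):
        df = pd.DataFrame({"chrom": "chr1", "pos1": [0, 0, 0], "pos2": [1000, 1001, 500]})
        short, long = norm.split_short_long(df)
        assert list(short["pos2"]) == [1000, 500]
        assert list(long["pos2"]) == [1001]

    def test_empty_input(self):
        df = pd.DataFrame({"chrom": [], "pos1": [], "pos2": []})
        short, long = norm.split_short_long(df)
        assert short.empty and long.empty

    def test_short_counts_aggregate_read_ends(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 2, "pos1": [100, 10_100], "pos2": [900, 10_500]})
        counts = norm.short_counts_per_bin(df, 10_000)
        got = dict(zip(counts["bin_start"], counts["short_count"]))
        assert got == {0: 2, 10_000: 2}


class TestZtpLoglik:
    def test_unit_mean_single_observation(self):
        # y=1, mu=1: pmf is e^-1 / (1 - e^-1), so loglik = -1 - log(1 - e^-1)
        df = _pairs([(0, 20_000)], counts=1)
        expected = -1.0 - np.log(1.0 - np.exp(-1.0))
        assert norm.ztp_loglik(np.zeros(5), df) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.541325, abs=1e-6)

    def test_order_invariance_and_additivity(self):
        df = simulate_ztp_pairs(BETA, 200, seed=5)
        beta = np.array(BETA)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert norm.ztp_loglik(beta, df) == pytest.approx(norm.ztp_loglik(beta, shuffled))
        both = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        single = norm.ztp_loglik(beta, df.iloc[[0]])
        assert norm.ztp_loglik(beta, both) == pytest.approx(norm.ztp_loglik(beta, df) + single)

    def test_overflow_guard(self):
        df = _pairs([(0, 20_000)], counts=1, fl=100.0)
        with pytest.raises(OverflowError):
            norm.ztp_loglik(np.array([0.0, 10.0, 0, 0, 0]), df)


class TestFitZtp:
    def test_matches_generic_optimizer(self):
        """Newton fit equals a BFGS maximization of the same likelihood."""
        for seed in (7, 8):
            df = simulate_ztp_pairs(BETA, 1500, seed=seed)
            fit = norm.fit_ztp(df)
            res = minimize(
                lambda b: -norm.ztp_loglik(b, df), np.zeros(5), method="BFGS",
                options={"gtol": 1e-9},
            )
            assert np.abs(fit.beta - res.x).max() < 1e-5

    def test_parameter_recovery_within_three_se(self):
        df = simulate_ztp_pairs(BETA, 50_000, seed=42)
        fit = norm.fit_ztp(df)
        assert np.all(np.abs(fit.beta - np.array(BETA)) < 3 * fit.standard_errors)

    def test_duplicating_records_leaves_estimate_unchanged(self):
        df = simulate_ztp_pairs(BETA, 400, seed=3)
        fit1 = norm.fit_ztp(df)
        fit2 = norm.fit_ztp(pd.concat([df, df], ignore_index=True))
        assert np.abs(fit1.beta - fit2.beta).max() < 1e-7

    def test_intercept_only_solves_score_equation(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(2.0, 500)
        y = y[y > 0][:300]
        df = _pairs([(0, 20_000)] * len(y))
        df["count"] = y
        fit = norm.fit_ztp(df)
        ybar = y.mean()
        mu_star = brentq(lambda m: m / (1 - np.exp(-m)) - ybar, 1e-8, 50.0)
        assert fit.beta[0] == pytest.approx(np.log(mu_star), abs=1e-7)
        assert np.all(fit.beta[1:] == 0.0)

    def test_mean_one_boundary_is_flagged(self):
        df = _pairs([(0, 20_000)] * 80, counts=1)
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit = norm.fit_ztp(df)
        assert fit.beta[0] < -10  # mu -> 0

    def test_too_few_records_refused(self):
        df = simulate_ztp_pairs(BETA, 20, seed=1)
        with pytest.raises(ValueError, match="minimum"):
            norm.fit_ztp(df)

    def test_collinear_design_rejected(self):
        df = simulate_ztp_pairs(BETA, 300, seed=2)
        df["gc"] = 2.0 * df["fl"]
        with pytest.raises(ValueError, match="rank"):
            norm.fit_ztp(df)

    def test_aic_bic_identities(self):
        df = simulate_ztp_pairs(BETA, 500, seed=9)
        fit = norm.fit_ztp(df)
        assert fit.aic == pytest.approx(2 * 5 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(5 * np.log(fit.n_obs) - 2 * fit.loglik)

    def test_mean_absolute_bias_over_replicates(self):
        """Repeated simulation: each coefficient is recovered nearly unbiasedly."""
        biases = []
        for rep in range(20):
            df = simulate_ztp_pairs(BETA, 20_000, seed=1000 + rep)
            biases.append(norm.fit_ztp(df).beta - np.array(BETA))
        mean_abs_bias = np.abs(np.mean(biases, axis=0))
        assert np.all(mean_abs_bias < 0.02)


class TestFittedValues:
    def test_truncated_mean_at_unit_mu(self):
        assert norm.truncated_mean(1.0) == pytest.approx(1.581977, abs=1e-6)

    def test_truncation_negligible_for_large_mu(self):
        mu = np.array([30.0, 50.0])
        assert np.allclose(norm.truncated_mean(mu), mu, rtol=1e-9)

    def test_fitted_strictly_exceeds_mu_and_is_monotone(self):
        mu = np.linspace(0.01, 20.0, 200)
        fitted = norm.truncated_mean(mu)
        assert np.all(fitted > mu)
        assert np.all(np.diff(fitted) > 0)


class TestNormalize:
    @pytest.mark.parametrize(
        "observed,fitted,expected",
        [(2, 2.0, 1.0), (6, 2.0, 2.0), (5, 1.581977, 2.056792)],
    )
    def test_normalized_value(self, observed, fitted, expected):
        df = _pairs([(0, 20_000)], counts=observed)
        out = norm.normalize_pairs(df, np.array([fitted]))
        assert out.loc[0, "normalized"] == pytest.approx(expected, abs=1e-5)

    def test_monotone_in_observed_at_fixed_fitted(self):
        df = _pairs([(0, 20_000)] * 5)
        df["count"] = [1, 2, 3, 5, 9]
        out = norm.normalize_pairs(df, np.full(5, 1.7))
        assert np.all(np.diff(out["normalized"]) > 0)

    def test_and_xor_fits_are_independent(self):
        and_df = simulate_ztp_pairs(BETA, 300, seed=21)
        xor_df = simulate_ztp_pairs((0.5, 0.1, 0.1, -0.1, 0.2), 300, seed=22)
        tables = {"sim1": {"AND": and_df, "XOR": xor_df}}
        fits1, _ = norm.normalize_sample(tables)
        shuffled = xor_df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fits2, _ = norm.normalize_sample({"sim1": {"AND": and_df, "XOR": shuffled}})
        b1 = next(f.beta for f in fits1 if f.pair_class == "AND")
        b2 = next(f.beta for f in fits2 if f.pair_class == "AND")
        assert np.array_equal(b1, b2)
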