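"""Sloan neutral community model: prediction, fit, classification, filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from neutralline import (
    CommunitySimConfig,
    FeatureTable,
    FilterConfig,
    TaxonNeutralRecord,
    classify,
    filter_zero_taxa,
    fit_m,
    fit_neutral,
    predict_freq,
    run_sncm,
    simulate_neutral_table,
    stringent_filter,
    summarize_table,
    wilson_interval,
)


class TestFilterZeroTaxa:
    def test_drops_all_zero_rows(self, small_table):
        out = filter_zero_taxa(small_table)
        assert out.taxon_ids == ["t0", "t1", "t3", "t4"]
        assert out.sample_ids == small_table.sample_ids

    def test_identity_when_no_zero_rows(self, rng):
        counts = rng.integers(1, 10, size=(5, 4))
        t = FeatureTable(counts, list("abcde"), [f"s{i}" for i in range(4)])
        assert filter_zero_taxa(t) is t

    def test_matches_set_oracle(self, rng):
        counts = rng.integers(0, 3, size=(40, 8))
        counts[rng.random((40, 8)) < 0.7] = 0
        counts[:, 0] = np.maximum(counts[:, 0], 1)  # no empty samples
        t = FeatureTable(counts, [f"t{i}" for i in range(40)], [f"s{j}" for j in range(8)])
        out = filter_zero_taxa(t)
        expect = {f"t{i}" for i in range(40) if counts[i].sum() > 0}
        assert set(out.taxon_ids) == expect


class TestSummarizeTable:
    def test_full_detection(self):
        t = FeatureTable(np.array([[1, 2], [3, 4]]), ["a", "b"], ["s1", "s2"])
        _, freq, _, _ = summarize_table(t)
        np.testing.assert_allclose(freq, 1.0)

    def test_mean_relative_abundance(self):
        # relative abundances of taxon a: 0.1 and 0.3 -> p = 0.2
        t = FeatureTable(np.array([[1, 3], [9, 7]]), ["a", "b"], ["s1", "s2"])
        p, _, N, n = summarize_table(t)
        assert p[0] == pytest.approx(0.2)
        assert N == pytest.approx(10.0)
        assert n == 2

    def test_matches_double_loop_oracle(self, rng):
        counts = rng.integers(0, 50, size=(200, 30))
        counts[:, counts.sum(axis=0) == 0] = 1
        t = FeatureTable(counts, [f"t{i}" for i in range(200)], [f"s{j}" for j in range(30)])
        p, freq, N, n = summarize_table(t)
        totals = [counts[:, j].sum() for j in range(30)]
        for i in range(200):
            p_naive = np.mean([counts[i, j] / totals[j] for j in range(30)])
            f_naive = sum(counts[i, j] > 0 for j in range(30)) / 30
            assert p[i] == pytest.approx(p_naive, abs=1e-14)
            assert freq[i] == pytest.approx(f_naive, abs=1e-14)
        assert N == pytest.approx(np.mean(totals))


class TestPredictFreq:
    def test_tiny_detection_limit_gives_one(self):
        assert predict_freq(0.01, 0.05, 15000, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_tiny_abundance_gives_zero(self):
        assert predict_freq(1e-10, 0.05, 15000, 0.5) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("p", [2e-4, 1e-3, 0.01])
    def test_matches_monte_carlo(self, rng, p):
        m, N = 0.05, 15000.0
        d = 1 / N
        a, b = N * m * p, N * m * (1 - p)
        draws = rng.beta(a, b, size=1_000_000)
        mc = (draws > d).mean()
        se = np.sqrt(mc * (1 - mc) / 1_000_000)
        assert abs(predict_freq(p, m, N, d) - mc) <= max(3 * se, 1e-9)

    def test_monotone_in_p_and_in_m_above_detection_limit(self):
        """Non-decreasing in p everywhere; non-decreasing in m for p > d
        (below the detection limit larger m concentrates abundance under d,
        so detection legitimately falls)."""
        N, d = 15000.0, 1 / 15000.0
        ps = np.logspace(-6, -0.5, 40)
        for m in (0.01, 0.05, 0.2, 0.8):
            f = predict_freq(ps, m, N, d)
            assert (np.diff(f) >= -1e-12).all()
        for p in (1e-4, 1e-3, 0.05):
            fs = [predict_freq(p, m, N, d) for m in np.linspace(0.001, 0.999, 30)]
            assert (np.diff(fs) >= -1e-12).all()
        # below the detection limit, monotonicity in m genuinely breaks
        fs = [predict_freq(1e-5, m, N, d) for m in np.linspace(0.001, 0.999, 30)]
        assert (np.diff(fs) < -1e-12).any()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            predict_freq(0.01, 0.0, 100, 0.01)
        with pytest.raises(ValueError):
            predict_freq(0.0, 0.1, 100, 0.01)
        with pytest.raises(ValueError):
            predict_freq(0.01, 0.1, 100, 1.5)


def _wilson_closed_form(successes, n, alpha):
    z = stats.norm.ppf(1 - alpha / 2)
    phat = successes / n
    return (
        (phat + z**2 / (2 * n) - z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))) / (1 + z**2 / n),
        (phat + z**2 / (2 * n) + z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))) / (1 + z**2 / n),
    )


class TestWilsonInterval:
    def test_zero_successes_lower_is_zero(self):
        lo, hi = wilson_interval(0, 10, 0.05)
        assert lo == 0.0
        assert hi > 0

    def test_symmetric_at_half(self):
        lo, hi = wilson_interval(5, 10, 0.05)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_non_integer_successes_closed_form(self):
        lo, hi = wilson_interval(7.5, 30, 0.05)
        elo, ehi = _wilson_closed_form(7.5, 30, 0.05)
        assert lo == pytest.approx(elo, abs=1e-12)
        assert hi == pytest.approx(ehi, abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (0, 9), (9, 9), (25, 60)]:
            lo, hi = wilson_interval(k, n, 0.05)
            elo, ehi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(float(elo), abs=1e-10)
            assert hi == pytest.approx(float(ehi), abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.integers(1, 500),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_ordering_and_bounds(self, frac, n, alpha):
        successes = frac * n
        lo, hi = wilson_interval(successes, n, alpha)
        # 1e-12 slack: catastrophic cancellation near phat = 0 or 1
        assert 0 <= lo <= successes / n + 1e-12
        assert successes / n - 1e-12 <= hi <= 1


class TestClassify:
    def _rec(self, freq, freq_pred):
        return TaxonNeutralRecord("t", 0.01, freq, freq_pred)

    def test_on_upper_bound_is_neutral(self):
        n = 30
        _, hi = wilson_interval(0.5 * n, n, 0.05)
        out = classify([self._rec(hi, 0.5)], n)
        assert out[0].partition == "Neutral"
        assert out[0].ci_lower <= out[0].freq_pred <= out[0].ci_upper

    def test_ubiquitous_with_tiny_prediction_is_above(self):
        out = classify([self._rec(1.0, 0.01)], 60)
        assert out[0].partition == "Above"

    def test_partitions_exhaustive_and_exclusive(self, rng):
        recs = [self._rec(rng.random(), rng.random()) for _ in range(200)]
        out = classify(recs, 60)
        assert all(r.partition in ("Neutral", "Above", "Below") for r in out)
        for r in out:
            above = r.freq > r.ci_upper
            below = r.freq < r.ci_lower
            assert r.partition == ("Above" if above else "Below" if below else "Neutral")


def _stringent_brute_force(records, cfg):
    removed = {"abundance": 0, "partition": 0, "freq": 0, "deviation": 0}
    survivors = []
    for r in records:
        if r.p <= cfg.min_abundance:
            removed["abundance"] += 1
        elif r.partition not in cfg.keep_partitions:
            removed["partition"] += 1
        elif r.freq < cfg.min_freq:
            removed["freq"] += 1
        elif (r.freq_pred <= cfg.min_deviation if cfg.literal_stage4
              else abs(r.freq - r.freq_pred) <= cfg.min_deviation):
            removed["deviation"] += 1
        else:
            survivors.append(r)
    return survivors, removed


class TestStringentFilter:
    def _random_records(self, rng, n=500):
        parts = np.array(["Neutral", "Above", "Below"])
        return [
            TaxonNeutralRecord(
                f"t{i}", float(rng.random() * 0.05), float(rng.random()),
                float(rng.random()), 0.0, 1.0, str(rng.choice(parts)),
            )
            for i in range(n)
        ]

    def test_low_abundance_removed_first(self):
        r = TaxonNeutralRecord("t", 0.005, 0.9, 0.5, 0.4, 0.6, "Above")
        survivors, audit = stringent_filter([r])
        assert survivors == []
        assert audit["removed_abundance"] == 1

    def test_neutral_removed_at_stage_two(self):
        r = TaxonNeutralRecord("t", 0.05, 0.9, 0.5, 0.4, 0.95, "Neutral")
        _, audit = stringent_filter([r])
        assert audit["removed_partition"] == 1

    @pytest.mark.parametrize("literal", [False, True])
    def test_matches_brute_force_oracle(self, rng, literal):
        cfg = FilterConfig(literal_stage4=literal)
        records = self._random_records(rng)
        survivors, audit = stringent_filter(records, cfg)
        expect_surv, expect_removed = _stringent_brute_force(records, cfg)
        assert [r.taxon_id for r in survivors] == [r.taxon_id for r in expect_surv]
        assert audit["removed_abundance"] == expect_removed["abundance"]
        assert audit["removed_partition"] == expect_removed["partition"]
        assert audit["removed_freq"] == expect_removed["freq"]
        assert audit["removed_deviation"] == expect_removed["deviation"]
        total = sum(v for k, v in audit.items() if k.startswith("removed")) + audit["survivors"]
        assert total == audit["input"] == 500


class TestFitNeutral:
    def test_self_consistency_recovers_m(self, rng):
        p = np.sort(rng.lognormal(0, 2, size=400))
        p = p / p.sum() / 2
        N, d = 15000.0, 1 / 15000.0
        freq = predict_freq(p, 0.04, N, d)
        assert fit_m(p, freq, N, d) == pytest.approx(0.04, abs=1e-4)

    def test_fit_diagnostics_match_residual_recomputation(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=300, n_samples=30, seed=5))
        fit = fit_neutral(table)
        freq = np.array([r.freq for r in fit.records])
        pred = np.array([r.freq_pred for r in fit.records])
        n = len(freq)
        sse = float(((freq - pred) ** 2).sum())
        sst = float(((freq - freq.mean()) ** 2).sum())
        assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-12)
        assert fit.rmse == pytest.approx(np.sqrt(sse / (n - 1)), abs=1e-12)
        loglik = -0.5 * n * (np.log(2 * np.pi * sse / n) + 1)
        assert fit.aic == pytest.approx(4 - 2 * loglik, abs=1e-9)
        assert fit.bic == pytest.approx(2 * np.log(n) - 2 * loglik, abs=1e-9)

    def test_partition_counts_cover_all_taxa(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=300, n_samples=30, seed=6))
        fit = fit_neutral(table)
        assert sum(fit.partition_counts().values()) == fit.n_taxa

    def test_too_few_taxa_rejected(self):
        t = FeatureTable(np.ones((3, 5), int), list("abc"), [f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="at least"):
            fit_neutral(t)

    def test_default_detection_limit_is_one_read(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=200, n_samples=20, seed=7))
        fit = fit_neutral(table)
        assert fit.d == pytest.approx(1.0 / fit.N)


class TestRunSncm:
    def test_one_summary_row_per_group(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=300, n_samples=36, seed=8))
        recs, summary, fits = run_sncm(table, group_by="sub_line")
        assert len(summary) == 6
        assert set(summary["group"]) == {"CF", "WILC", "WIL1", "WIL2", "WIL3", "WIL4"}
        # every record's partition tallies match the summary
        for _, row in summary.iterrows():
            sub = recs[recs.group == row.group]
            assert (sub.partition == "Neutral").sum() == row.n_neutral
            assert (sub.partition == "Above").sum() == row.n_above
            assert (sub.partition == "Below").sum() == row.n_below

    def test_small_groups_skipped(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=200, n_samples=10, seed=9))
        # 10 samples over 6 sub-lines -> every group has < 5 samples
        recs, summary, fits = run_sncm(table, group_by="sub_line")
        assert len(summary) == 0

    def test_whole_table_when_no_grouping(self):
        table, _ = simulate_neutral_table(CommunitySimConfig(n_taxa=200, n_samples=20, seed=10))
        _, summary, _ = run_sncm(table)
        assert list(summary["group"]) == ["all"]
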