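"""Empirical LIR counting against a brute-force pair enumerator, and
residence-model fitting (self-consistency, recovery, diagnostics)."""

import numpy as np
import pandas as pd
import pytest

from probassoc import (LIRCurve, ResidenceModelParams, ResidenceTimeModel,
                       default_offset, empirical_lir, fit_by_subset,
                       fit_residence_model, keyed_ordinal, lir_model,
                       make_fixture, simulate_identifications,
                       SimulationConfig)
from conftest import random_record_table


def brute_force_lir(df: pd.DataFrame) -> dict[float, tuple[int, int]]:
    """O(N^2) oracle over composite ordinals: lag -> (m, n), restricted to
    positive lags at most the largest within-event lag."""
    events = {e: i for i, e in enumerate(pd.unique(df["event"]))}
    max_within = 0.0
    for _, g in df.groupby("event"):
        o = g["ordinal"].to_numpy(dtype=float)
        if len(o) > 1:
            max_within = max(max_within, float(o.max() - o.min()))
    offset = default_offset(max_within)
    comp = np.array([keyed_ordinal(o, events[e], offset)
                     for o, e in zip(df["ordinal"], df["event"])], dtype=float)
    ids = df["individual"].to_numpy()
    counts: dict[float, list[int]] = {}
    for i in range(len(df)):
        for j in range(i + 1, len(df)):
            lag = abs(comp[i] - comp[j])
            if 0 < lag <= max_within:
                c = counts.setdefault(lag, [0, 0])
                c[1] += 1
                c[0] += int(ids[i] == ids[j])
    return {lag: (m, n) for lag, (m, n) in counts.items()}


class TestKeyedOrdinal:
    def test_composite_value(self):
        assert keyed_ordinal(35, 2, 10_000) == 20_035
        assert keyed_ordinal(0, 0, 10_000) == 0

    def test_offset_must_exceed_max_lag(self):
        with pytest.raises(ValueError):
            keyed_ordinal(35, 2, 500, max_within_event_lag=878)

    def test_cross_event_pairs_pushed_beyond_max_lag(self):
        # within-event ordinals <= 878: any cross-event composite lag is
        # at least 10000 - 878 = 9122 > 878
        lo = keyed_ordinal(878, 0, 10_000)
        hi = keyed_ordinal(0, 1, 10_000)
        assert abs(hi - lo) >= 9122 > 878

    def test_default_offset_power_of_ten(self):
        assert default_offset(878) == 1000
        assert default_offset(9) == 10
        assert default_offset(10) == 100
        assert default_offset(10_000) == 100_000


class TestEmpiricalLIR:
    def test_tiny_fixture(self):
        fx = make_fixture("tiny-lir")
        curve = empirical_lir(fx.data)
        assert list(curve.lags) == [fx.expected["lag"]]
        assert curve.same_count[0] == fx.expected["m"]
        assert curve.total_count[0] == fx.expected["n"]
        assert curve.rate[0] == pytest.approx(fx.expected["rate"])

    def test_single_individual_twice(self):
        df = pd.DataFrame({"individual": ["A", "A"], "event": ["e", "e"],
                           "ordinal": [1, 5], "date": ["2020-01-01"] * 2})
        curve = empirical_lir(df)
        assert curve.rate[curve.lags == 4][0] == 1.0

    def test_distinct_individuals_rate_zero(self):
        df = pd.DataFrame({"individual": ["A", "B"], "event": ["e", "e"],
                           "ordinal": [1, 3], "date": ["2020-01-01"] * 2})
        curve = empirical_lir(df)
        assert np.all(curve.same_count == 0)
        assert np.all(curve.rate == 0)

    def test_degenerate_clock_raises(self):
        df = pd.DataFrame({"individual": ["A", "B", "C"], "event": ["e"] * 3,
                           "ordinal": [7, 7, 7], "date": ["2020-01-01"] * 3})
        with pytest.raises(ValueError, match="lag 0|degenerate"):
            empirical_lir(df)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            empirical_lir(pd.DataFrame(columns=["individual", "event",
                                                "ordinal", "date"]))

    def test_cross_event_pairs_never_counted(self):
        # same individual 1 frame apart in *different* events: no pair
        df = pd.DataFrame({"individual": ["A", "A", "A", "B"],
                           "event": ["e1", "e2", "e1", "e1"],
                           "ordinal": [1, 2, 11, 5],
                           "date": ["2020-01-01"] * 4})
        curve = empirical_lir(df)
        # within e1: lags 10 (A-A), 4 (A-B), 6 (A-B); nothing at lag 1
        assert set(curve.lags) == {4.0, 6.0, 10.0}
        assert curve.n_pairs == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        df = random_record_table(rng, n_records=int(rng.integers(10, 200)))
        try:
            curve = empirical_lir(df)
        except ValueError:
            pytest.skip("degenerate draw")
        oracle = brute_force_lir(df)
        ours = {float(l): (int(m), int(n)) for l, m, n in
                zip(curve.lags, curve.same_count, curve.total_count)}
        assert ours == oracle

    def test_log_binning_conserves_counts(self):
        rng = np.random.default_rng(3)
        df = random_record_table(rng, 150)
        unbinned = empirical_lir(df)
        binned = empirical_lir(df, bins="log", n_bins=8)
        assert binned.total_count.sum() == unbinned.total_count.sum()
        assert binned.same_count.sum() == unbinned.same_count.sum()
        assert binned.binned


class TestResidenceFit:
    def exact_curve(self, a=20.0, b=14.0, c=200.0, n_per_lag=5000,
                    max_lag=800):
        lags = np.arange(1.0, max_lag + 1)
        n = np.full(max_lag, n_per_lag)
        true = ResidenceModelParams(a=a, b=b, c=c)
        m = np.round(lir_model(lags, true) * n).astype(int)
        return LIRCurve(lags, m, n, max_lag=max_lag)

    def test_self_consistency_recovery(self):
        fit = fit_residence_model(self.exact_curve())
        assert fit.converged and fit.informative
        assert fit.params.b == pytest.approx(14.0, rel=0.05)
        assert fit.threshold.threshold == 14

    def test_optimum_dominates_every_start(self):
        fit = fit_residence_model(self.exact_curve(), n_starts=8, seed=1)
        assert np.all(fit.llf >= fit.start_logliks - 1e-9)

    def test_flat_curve_flagged_non_informative(self):
        curve = LIRCurve(np.arange(1.0, 40), np.full(39, 60),
                         np.full(39, 600), max_lag=40)
        fit = fit_residence_model(curve)
        assert not fit.informative
        assert fit.threshold is None

    def test_recovery_from_simulated_stream(self, sim_default):
        fit = ResidenceTimeModel.from_records(sim_default).fit()
        assert fit.informative
        assert 8.0 <= fit.params.b <= 12.0

    def test_needs_three_lags(self):
        curve = LIRCurve([1.0, 2.0], [1, 1], [4, 4], max_lag=5)
        with pytest.raises(ValueError, match="3 distinct lags"):
            ResidenceTimeModel(curve)

    def test_summary_mentions_threshold(self, sim_default):
        fit = ResidenceTimeModel.from_records(sim_default).fit()
        text = fit.summary()
        assert "association threshold" in text
        assert f"{fit.params.b:.4g}" in text


class TestFitBySubset:
    def test_single_value_equals_global(self, sim_small):
        df, _ = sim_small
        df = df.assign(data_type="film")
        subset = fit_by_subset(df, "data_type")
        global_fit = ResidenceTimeModel.from_records(df).fit()
        assert set(subset) == {"film"}
        assert subset["film"].params.b == pytest.approx(global_fit.params.b)

    def test_two_subsets_fitted_independently(self, sim_small):
        df, _ = sim_small
        half = df["event"].rank(method="dense") <= df["event"].nunique() / 2
        df = df.assign(data_type=np.where(half, "film", "digital"))
        fits = fit_by_subset(df, "data_type")
        assert set(fits) == {"film", "digital"}
        for fit in fits.values():
            assert fit.subset_label in {"film", "digital"}

    def test_missing_attribute_rejected(self, sim_small):
        df, _ = sim_small
        with pytest.raises(ValueError, match="attribute"):
            fit_by_subset(df, "nonexistent")
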