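"""Population-vector decoder: splits, templates, errors, cumulative accuracy."""

import math

import numpy as np
import pytest
from scipy import stats

from dglat.decoding import (PopulationVectorDecoder, _segment_accuracy,
                            cumulative_context_accuracy, decode_session,
                            decode_timebins, error_vs_ensemble_size,
                            per_context_errors, split_runs,
                            template_mode_ratio, timebin_population)
from dglat.preprocess import preprocess_session, run_mask
from dglat.simulate import HemisphereProfile, simulate_behavior, simulate_session
from dglat.track import FAMILIAR, NOVEL


@pytest.fixture(scope="module")
def dense_session():
    """Strongly tuned, low-noise population for decoder integration tests."""
    profile = HemisphereProfile(frac_active=1.0, frac_place_of_active=1.0,
                                run_jitter_bins=0.3, noise_sigma_au=0.5,
                                infield_event_rate_hz=1.5)
    ses = simulate_session(profile, n_cells=40, seed=17,
                          n_runs_per_context=15)
    ext, inc, act = preprocess_session(ses)
    masked = np.vstack([t.masked_dff for t in ext.traces_])
    return ses, masked, inc


class TestSplitRuns:
    def test_fifteen_runs_split_eight_seven(self):
        beh = simulate_behavior(n_runs_per_context=15, seed=0)
        template, test = split_runs(beh)
        # per context: 8 template + 7 test
        for ctx in (FAMILIAR, NOVEL):
            ctx_runs = {int(r) for r in np.unique(
                beh.run_id[(beh.context_id == ctx) & (beh.run_id >= 0)])}
            assert len(ctx_runs & set(template)) == 8
            assert len(ctx_runs & set(test)) == 7
        assert not set(template) & set(test)
        assert len(template) + len(test) == 30

    def test_parity_swaps_roles(self):
        beh = simulate_behavior(n_runs_per_context=4, seed=1)
        t0, s0 = split_runs(beh, parity=0)
        t1, s1 = split_runs(beh, parity=1)
        assert t0 == s1 and s0 == t1

    def test_two_runs_split_one_one(self):
        beh = simulate_behavior(n_runs_per_context=1, seed=2)
        # one run per context: a template/test split is impossible
        with pytest.raises(ValueError):
            split_runs(beh)


class TestDecoderEstimator:
    def test_fit_computes_label_means(self):
        X = np.array([[1.0, 0.0], [3.0, 0.0], [0.0, 2.0], [0.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        dec = PopulationVectorDecoder().fit(X, y)
        assert np.allclose(dec.template_[:, 0], [2.0, 0.0])
        assert np.allclose(dec.template_[:, 1], [0.0, 3.0])

    def test_exact_template_vectors_recovered(self):
        rng = np.random.default_rng(0)
        T = rng.random((20, 5))          # 5 distinct patterns over 20 cells
        y = np.repeat(np.arange(5), 3)
        X = np.vstack([T[:, c] for c in y])
        dec = PopulationVectorDecoder().fit(X, y)
        assert np.array_equal(dec.predict(T.T), np.arange(5))

    def test_scale_and_offset_invariance(self):
        rng = np.random.default_rng(1)
        T = rng.random((30, 4))
        dec = PopulationVectorDecoder().fit(T.T, np.arange(4))
        # Pearson correlation ignores per-vector affine transforms
        assert np.array_equal(dec.predict(5.0 * T.T + 2.0), np.arange(4))

    def test_zero_variance_row_undecodable(self):
        rng = np.random.default_rng(2)
        T = rng.random((10, 3))
        dec = PopulationVectorDecoder().fit(T.T, np.arange(3))
        X = np.vstack([np.full(10, 4.2), T[:, 1]])
        out = dec.predict(X)
        assert out[0] == -1 and out[1] == 1

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            PopulationVectorDecoder().fit(np.zeros((4, 3)), np.zeros(5))


def test_symmetric_templates_give_chance_error():
    """Noise vectors against two mirror-image templates: fair coin."""
    rng = np.random.default_rng(3)
    n_cells, n_bins = 20, 10_000
    base = rng.random(n_cells)
    dec = PopulationVectorDecoder()
    dec.classes_ = np.arange(2)
    dec.template_ = np.column_stack([base, base[::-1]])  # symmetric pair
    dec.n_features_in_ = n_cells
    X = rng.standard_normal((n_bins, n_cells))
    labels = dec.predict(X)
    err = (labels != 0).mean()           # pretend truth is always label 0
    assert err == pytest.approx(0.5, abs=0.02)


class TestSegmentAccuracy:
    def test_hand_cases(self):
        err = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        # segments of 3: (0,0,1) correct, (1,0,1) wrong -> 0.5
        assert _segment_accuracy(err, 3) == pytest.approx(0.5)
        # single-bin segments: accuracy = 1 - mean error
        assert _segment_accuracy(err, 1) == pytest.approx(0.5)

    def test_tie_counts_as_incorrect(self):
        err = np.array([0.0, 1.0])        # mean 0.5 -> tie -> wrong
        assert _segment_accuracy(err, 2) == 0.0

    def test_too_short_is_nan(self):
        assert math.isnan(_segment_accuracy(np.zeros(3), 5))

    @pytest.mark.parametrize("p,k", [(0.3, 5), (0.2, 9), (0.4, 11)])
    def test_matches_binomial_majority_closed_form(self, p, k):
        """IID per-bin errors: majority accuracy = P(Binom(k,p) < k/2)."""
        rng = np.random.default_rng(42)
        n_seg = 4000
        err = (rng.random(n_seg * k) < p).astype(float)
        acc = _segment_accuracy(err, k)
        expect = stats.binom.cdf((k - 1) // 2, k, p)
        se = math.sqrt(expect * (1 - expect) / n_seg)
        assert abs(acc - expect) <= 3 * se


class TestTimebinPopulation:
    def test_window_means_match_hand_computation(self, dense_session):
        ses, masked, inc = dense_session
        beh = ses.behavior
        _, test_runs = split_runs(beh)
        X, ctx, pos, times = timebin_population(masked, beh, inc, test_runs)
        # recompute the first window directly
        sel = inc & np.isin(beh.run_id, test_runs)
        idx = np.flatnonzero(sel)
        w0 = np.floor(beh.times_s[idx] / 0.1).astype(int)
        first = idx[w0 == w0[0]]
        assert X[0] == pytest.approx(masked[:, first].mean(axis=1))
        assert pos[0] == pytest.approx(beh.position_cm[first].mean())
        assert times[0] == pytest.approx(w0[0] * 0.1)

    def test_contexts_are_pure_per_window(self, dense_session):
        ses, masked, inc = dense_session
        beh = ses.behavior
        _, test_runs = split_runs(beh)
        _, ctx, _, _ = timebin_population(masked, beh, inc, test_runs)
        assert set(np.unique(ctx)) <= {FAMILIAR, NOVEL}


class TestSessionDecoding:
    def test_decodes_far_above_chance(self, dense_session):
        ses, masked, inc = dense_session
        res = decode_session(masked, ses.behavior, inc)
        assert res.mean_context_error < 0.25          # chance = 0.5
        assert res.mean_spatial_error_cm < 60.0       # chance ~ 133 cm
        assert res.context_error.size > 100
        assert np.all((res.spatial_error_cm >= 0)
                      & (res.spatial_error_cm <= 400))

    def test_empty_ensemble_rejected(self, dense_session):
        ses, masked, inc = dense_session
        t, s = split_runs(ses.behavior)
        with pytest.raises(ValueError):
            decode_timebins(masked, ses.behavior, inc, t, s, np.array([]))

    def test_per_context_stratification(self, dense_session):
        ses, masked, inc = dense_session
        res = decode_session(masked, ses.behavior, inc)
        strat = per_context_errors(res)
        n_total = strat["familiar"]["n_bins"] + strat["novel"]["n_bins"]
        assert n_total == res.context_error.size
        pooled = (strat["familiar"]["context_error"]
                  * strat["familiar"]["n_bins"]
                  + strat["novel"]["context_error"]
                  * strat["novel"]["n_bins"]) / n_total
        assert pooled == pytest.approx(res.mean_context_error)

    def test_error_vs_ensemble_size_improves(self, dense_session):
        ses, masked, inc = dense_session
        out = error_vs_ensemble_size(masked, ses.behavior, inc,
                                     np.arange(40), sizes=(5, 40),
                                     n_draws=5, seed=0)
        # the full population should beat small random ensembles
        assert out[40][0] <= out[5][0]
        assert out[40][1] <= out[5][1]

    def test_template_mode_ratio_finite(self, dense_session):
        ses, masked, inc = dense_session
        ratio = template_mode_ratio(masked, ses.behavior, inc, np.arange(40))
        assert np.isfinite(ratio) and ratio >= 0


class TestCumulativeAccuracy:
    def test_accuracy_grows_and_t90_consistent(self, dense_session):
        ses, masked, inc = dense_session
        ca = cumulative_context_accuracy(
            masked, ses.behavior, inc, np.arange(40), ensemble_size=30,
            n_ensembles=5, seed=1, delta_t_grid=(0.1, 1, 5, 20, 60))
        assert ca.per_ensemble.shape == (5, 5)
        # integrating over longer windows must help on average
        assert ca.accuracy[-2] >= ca.accuracy[0]
        if ca.reached_90:
            first = np.flatnonzero(ca.accuracy > 0.9)[0]
            assert ca.time_to_90_s == pytest.approx(ca.delta_t_s[first])

    def test_not_enough_cells_rejected(self, dense_session):
        ses, masked, inc = dense_session
        with pytest.raises(ValueError):
            cumulative_context_accuracy(masked, ses.behavior, inc,
                                        np.arange(10), ensemble_size=50)
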