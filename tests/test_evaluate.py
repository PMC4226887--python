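import numpy as np
import pandas as pd
import pytest

import oroniche as o
from oroniche.evaluate import (
    CandidateResult,
    aicc,
    aicc_closed_form,
    apply_threshold,
    auc,
    jackknife_gains,
    mpa,
    percent_contribution,
    permutation_importance,
    rank_candidates,
    response_curve,
    select_representative_replicate,
    suitability_elevation_profile,
    threshold_max_sss,
)
from oroniche.grid import Grid
from oroniche.maxent import build_features, fit_maxent
from oroniche.terrain import PredictorStack


def brute_force_auc(pres, bg):
    wins = ties = 0
    for p in pres:
        for b in bg:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pres) * len(bg))


def brute_force_max_sss(pres, bg):
    best_t, best_s = None, -np.inf
    for t in sorted(set(np.concatenate([pres, bg]))):
        s = np.mean(pres >= t) + np.mean(bg < t)
        if s > best_s:  # strict: ties keep the lowest threshold
            best_t, best_s = t, s
    return best_t


class TestAUC:
    def test_separated_and_tied(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_pairwise_counting_example(self):
        assert auc([0.9, 0.4], [0.5, 0.3, 0.1]) == pytest.approx(5 / 6)

    def test_equals_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pres = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 30))
            bg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 170))
            assert auc(pres, bg) == pytest.approx(brute_force_auc(pres, bg))


class TestAICc:
    def test_closed_form(self):
        assert aicc_closed_form(-50.0, 3, 20) == pytest.approx(107.5)

    def test_boundary_and_zero_probability(self):
        v, reason = aicc(np.full(4, 0.1), k=3)  # n = k+1
        assert np.isnan(v) and "too few" in reason
        v, reason = aicc(np.array([0.1, 0.0, 0.2]), k=1)
        assert np.isnan(v) and "zero raw" in reason

    def test_toy_hand_trace(self):
        raw = np.array([0.4, 0.3, 0.1])  # 3 presences on a 4-cell model
        lnl = np.log(0.4) + np.log(0.3) + np.log(0.1)
        v, reason = aicc(raw, k=1)
        assert reason is None
        assert v == pytest.approx(-2 * lnl + 2 + 2 * 1 * 2 / (3 - 2))


class TestMaxSSS:
    def test_separated_scores_pick_lowest_qualifying(self):
        t = threshold_max_sss([0.8, 0.9], [0.1, 0.2])
        assert t == 0.8  # lowest observed score with perfect separation

    def test_degenerate_equal_scores(self):
        assert threshold_max_sss([0.5, 0.5], [0.5]) == 0.5

    def test_tie_rule_documented_example(self):
        # t=0.3 and t=0.6 both score sens+spec = 5/3; tie -> lowest
        t = threshold_max_sss([0.8, 0.6, 0.3], [0.5, 0.2, 0.1])
        assert t == 0.3

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pres = rng.choice(np.round(rng.random(8), 2), size=6)
            bg = rng.choice(np.round(rng.random(10), 2), size=12)
            assert threshold_max_sss(pres, bg) == pytest.approx(
                brute_force_max_sss(pres, bg))


class TestMPA:
    def test_constant_prediction_and_single_maximum(self):
        assert mpa(np.full(30, 0.4), [0.4, 0.4]) == 1.0
        cal = np.arange(25) / 25
        assert mpa(cal, [cal.max()]) == pytest.approx(1 / 25)

    def test_5x5_hand_counted(self):
        cal = np.arange(1.0, 26.0)  # 5x5 grid values 1..25
        presences = np.array([5.0, 10.0, 17.0])
        # inclusion 1.0: threshold = 5 -> 21 of 25 cells at or above
        assert mpa(cal, presences, inclusion=1.0) == pytest.approx(21 / 25)
        # inclusion 0.9 raises the threshold, shrinking the area
        assert mpa(cal, presences, inclusion=0.9) <= 21 / 25

    def test_monotone_as_threshold_rises(self):
        rng = np.random.default_rng(2)
        cal = rng.random(200)
        pres = rng.random(20)
        assert mpa(cal, pres, 1.0) >= mpa(cal, pres, 0.9)


class TestRepresentativeReplicate:
    def test_identical_and_single(self):
        M = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], (6, 1))
        assert select_representative_replicate(M) == 0
        assert select_representative_replicate(M[:1]) == 0

    def test_matches_brute_force_distance_to_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            M = rng.normal(size=(10, 5))
            mean = M.mean(axis=0)
            sd = M.std(axis=0)
            Xs = (M - mean) / sd
            expected = int(np.argmin(np.linalg.norm(Xs - Xs.mean(axis=0), axis=1)))
            # full component space (cutoff 1.0): PCA preserves distances
            assert select_representative_replicate(M, variance_cutoff=1.0) == expected


class TestRankCandidates:
    def _cand(self, auc_, aicc_, mpa_):
        return CandidateResult(variables=["V"], beta=1.0, auc_test=auc_,
                               aicc=aicc_, mpa=mpa_, representative_id=0)

    def test_single_and_dominant(self):
        only = [self._cand(0.8, 100.0, 0.3)]
        assert rank_candidates(only)[0] is only[0]
        cands = [self._cand(0.9, 90.0, 0.1), self._cand(0.8, 100.0, 0.3)]
        assert rank_candidates(cands)[0].auc_test == 0.9

    def test_hand_traced_rank_sums_and_aicc_tiebreak(self):
        # all three tie on rank sum 6; AICc breaks the tie
        c1 = self._cand(0.90, 120.0, 0.2)
        c2 = self._cand(0.85, 100.0, 0.3)
        c3 = self._cand(0.80, 110.0, 0.1)
        out = rank_candidates([c1, c2, c3])
        assert [c.rank_sum for c in out] == [6.0, 6.0, 6.0]
        assert [c.aicc for c in out] == [100.0, 110.0, 120.0]

    def test_missing_aicc_ranked_last_on_that_metric(self):
        good = self._cand(0.8, 100.0, 0.2)
        bad = self._cand(0.8, float("nan"), 0.2)
        out = rank_candidates([good, bad])
        assert out[0] is good


def _fitted_model_on(stack, terms_cells=200, seed=0, classes=None):
    rng = np.random.default_rng(seed)
    shape = stack.reference.shape
    idx = rng.choice(shape[0] * shape[1], size=terms_cells, replace=False)
    bg = (idx // shape[1], idx % shape[1])
    # presences concentrated where the first variable is high
    first = stack.grids[stack.names[0]].values
    flat = np.argsort(np.nan_to_num(first, nan=-np.inf).ravel())[-400:]
    pick = rng.choice(flat, size=30, replace=False)
    pres = (pick // shape[1], pick % shape[1])
    fs = build_features(stack, bg, pres, classes=classes or {"linear", "quadratic"})
    F_bg, F_p = fs.at_cells(*bg), fs.at_cells(*pres)
    X = np.vstack([F_bg, F_p])
    model = fit_maxent(fs, X, np.arange(len(F_bg), len(X)), beta=1.0)
    return model, fs, pres, bg


class TestImportance:
    def _stack(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 40
        return PredictorStack(grids={
            "SIG": Grid(np.tile(np.linspace(0, 100, n), (n, 1)), cell_size=1.0),
            "N1": Grid(rng.normal(size=(n, n)), cell_size=1.0),
            "N2": Grid(rng.normal(size=(n, n)), cell_size=1.0),
        })

    def test_single_variable_gets_full_contribution(self):
        assert percent_contribution({"A": 2.5}) == {"A": 100.0}

    def test_unused_variable_gets_zero(self):
        out = percent_contribution({"A": 3.0, "B": 0.0})
        assert out["B"] == 0.0 and out["A"] == 100.0

    def test_zero_gain_warns_uniform(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = percent_contribution({"A": 0.0, "B": 0.0})
        assert out == {"A": 50.0, "B": 50.0}

    def test_signal_variable_dominates_contribution(self):
        model, fs, pres, bg = _fitted_model_on(self._stack())
        out = percent_contribution(model.contribution)
        assert max(out, key=out.get) == "SIG"

    def test_permutation_importance_sums_and_zero_coef(self):
        model, fs, pres, bg = _fitted_model_on(self._stack(), seed=1)
        rows = np.concatenate([pres[0], bg[0]])
        cols = np.concatenate([pres[1], bg[1]])
        V = fs.stack.sample(rows, cols)
        imp = permutation_importance(model, V, np.arange(len(pres[0])), seed=2)
        assert sum(imp.values()) == pytest.approx(100.0)
        # zero out every coefficient touching N2: its importance must vanish
        for j, d in enumerate(fs.descriptors):
            if d.variable == "N2":
                model.coefs[j] = 0.0
        imp = permutation_importance(model, V, np.arange(len(pres[0])), seed=2)
        assert imp["N2"] == 0.0

    def test_permuting_everything_destroys_discrimination(self):
        model, fs, pres, bg = _fitted_model_on(self._stack(), seed=3)
        rows = np.concatenate([pres[0], bg[0]])
        cols = np.concatenate([pres[1], bg[1]])
        V = fs.stack.sample(rows, cols).copy()
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(30):
            Vp = V.copy()
            for i in range(Vp.shape[1]):
                Vp[:, i] = rng.permutation(Vp[:, i])
            s = fs.transform(Vp) @ model.coefs
            aucs.append(auc(s[:len(pres[0])], s[len(pres[0]):]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_jackknife_identifies_the_sole_driver(self):
        stack = self._stack(seed=5)
        model, fs, pres, bg = _fitted_model_on(stack, seed=5)
        jack = jackknife_gains(stack, pres, bg, beta=1.0,
                               classes={"linear", "quadratic"}).set_index("variable")
        full_gain = o.regularized_gain(model)
        # noise variables alone explain (almost) nothing
        assert jack.loc["N1", "gain_only"] < 0.25 * full_gain
        # dropping the sole informative variable collapses the gain
        assert jack.loc["SIG", "gain_without"] < 0.25 * full_gain
        # the informative variable alone recovers (most of) the full gain
        assert jack.loc["SIG", "gain_only"] > 0.75 * full_gain


class TestResponseCurve:
    def test_single_positive_linear_feature_is_increasing(self):
        n = 30
        stack = PredictorStack(grids={
            "V": Grid(np.tile(np.linspace(0, 10, n), (n, 1)), cell_size=1.0)})
        model, fs, pres, bg = _fitted_model_on(stack, classes={"linear"})
        curve = response_curve(model, "V", n_points=40)
        assert np.all(np.diff(curve["suitability"]) >= -1e-12)
        assert curve["suitability"].iloc[-1] > curve["suitability"].iloc[0]

    def test_flat_model_is_half(self):
        n = 20
        rng = np.random.default_rng(6)
        stack = PredictorStack(grids={"V": Grid(rng.random((n, n)), cell_size=1.0)})
        bg = (np.repeat(np.arange(n), n), np.tile(np.arange(n), n))
        fs = build_features(stack, bg, classes={"linear"})
        X = fs.at_cells(*bg)
        model = fit_maxent(fs, np.vstack([X, X[:5]]), np.arange(len(X), len(X) + 5),
                           beta=1e6)  # huge penalty -> uniform model
        curve = response_curve(model, "V")
        np.testing.assert_allclose(curve["suitability"], 0.5, atol=1e-6)

    def test_gaussian_species_optimum_recovered(self, small_broad_data):
        # species driven only by a gaussian temperature response: the fitted
        # response curve should peak near the generating optimum
        import oroniche as o
        from oroniche.prep import sample_background

        terms = [("B10", "gaussian", {"optimum": 14.0, "width": 3.0})]
        suit = o.build_suitability(small_broad_data["stack"], terms)
        rec = o.sample_virtual_occurrences(
            suit, o.VirtualSpeciesConfig(response_terms=terms, n_presences=200,
                                         seed=21))
        stack = small_broad_data["stack"].subset(["B10"])
        ref = stack.reference
        cal = ref.like(np.ones(ref.shape, bool))
        bg = sample_background(1500, cal, valid=stack.mask, seed=7)
        pr, pc = ref.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
        fs = build_features(stack, bg, (pr, pc), classes={"linear", "quadratic"})
        F_bg, F_p = fs.at_cells(*bg), fs.at_cells(pr, pc)
        X = np.vstack([F_bg, F_p])
        # light regularization: L1 shrinkage of the quadratic coefficient
        # biases the peak location at larger beta
        model = fit_maxent(fs, X, np.arange(len(F_bg), len(X)), beta=0.1,
                           max_iter=10000, tol=1e-10)
        curve = response_curve(model, "B10", n_points=200)
        peak = curve["value"].iloc[int(curve["suitability"].idxmax())]
        grid_step = curve["value"].iloc[1] - curve["value"].iloc[0]
        assert abs(peak - 14.0) < max(1.0, 3 * grid_step)


class TestThresholdAndProfile:
    def test_apply_threshold_counts(self):
        pred = Grid(np.linspace(0, 1, 25).reshape(5, 5), cell_size=1000.0)
        mask, frac, cov = apply_threshold(pred, 0.0)
        assert frac == 1.0
        mask, frac, cov = apply_threshold(pred, 2.0)
        assert frac == 0.0
        # 10 validation points, 7 on suitable cells -> 70%
        thr = 0.5
        vals = pred.values.ravel()
        suitable_cells = np.nonzero(vals >= thr)[0][:7]
        unsuitable_cells = np.nonzero(vals < thr)[0][:3]
        cells = np.concatenate([suitable_cells, unsuitable_cells])
        x, y = pred.xy_of(cells // 5, cells % 5)
        rec = pd.DataFrame({"lon": x, "lat": y})
        _, _, cov = apply_threshold(pred, thr, rec)
        assert cov == pytest.approx(70.0)

    def test_profile_step_function_boundary(self):
        n = 30
        elev = Grid(np.tile(np.linspace(0, 2900, n), (n, 1)), cell_size=1000.0)
        pred = elev.like((elev.values >= 1500).astype(float))
        profile, boundary = suitability_elevation_profile(pred, elev, threshold=0.5,
                                                          bin_width=100.0)
        assert boundary == pytest.approx(1500.0, abs=100.0)
        assert (profile["n_cells"] > 0).all()

    def test_uniformly_suitable_boundary_is_lowest_bin(self):
        n = 10
        elev = Grid(np.tile(np.linspace(200, 900, n), (n, 1)), cell_size=1000.0)
        pred = elev.like(np.full((n, n), 0.9))
        profile, boundary = suitability_elevation_profile(pred, elev, threshold=0.5)
        assert boundary == profile["bin_low"].iloc[0]

    def test_empty_region_gives_missing_profile(self):
        elev = Grid(np.ones((5, 5)), cell_size=1.0)
        pred = elev.like(np.ones((5, 5)))
        profile, boundary = suitability_elevation_profile(
            pred, elev, threshold=0.5, region_mask=np.zeros((5, 5), bool))
        assert profile.empty and np.isnan(boundary)
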