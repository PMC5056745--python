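import numpy as np
import pandas as pd
import pytest

from mesocam.cooccur import (
    DetectionHistoryPair, OccupancyModelSpec, enumerate_model_set,
    build_detection_histories, two_species_neg_log_likelihood, fit_model,
    rank_models_and_sif, fit_model_set, gamma_of_params, lure_age_bin,
    MISSING, NEITHER, A_ONLY, B_ONLY, BOTH, _unpack, _sigmoid,
)
from mesocam.errors import ConfigurationError
from mesocam.synth import simulate_detection_histories

from conftest import make_photos, make_deployments


def simple_hist(states, **kw):
    states = np.asarray(states)
    return DetectionHistoryPair(
        sites=[f"s{i}" for i in range(states.shape[0])], states=states,
        lure_bin=kw.get("lure_bin", np.zeros_like(states)),
        cam_slow=kw.get("cam_slow", np.zeros_like(states)),
        species_a="A", species_b="B")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_nll(params, hist, spec):
    """Exhaustive latent-state enumeration with scalar Python arithmetic."""
    (psi_a, psi_b, psi_ab), (p_a, p_b, r_a, r_b) = _unpack(params, spec, hist)
    state_probs = [psi_ab, psi_a - psi_ab, psi_b - psi_ab,
                   1 - psi_a - psi_b + psi_ab]
    total = 0.0
    for i in range(hist.n_sites):
        site_lik = 0.0
        for state, sp in enumerate(state_probs):     # 0 both, 1 A, 2 B, 3 none
            lik = 1.0
            for j in range(hist.n_occasions):
                obs = hist.states[i, j]
                if obs == MISSING:
                    continue
                pa, pb = p_a[i, j], p_b[i, j]
                ra, rb = r_a[i, j], r_b[i, j]
                if state == 0:
                    da, db = ra, rb
                    here_a, here_b = True, True
                elif state == 1:
                    da, db = pa, 0.0
                    here_a, here_b = True, False
                elif state == 2:
                    da, db = 0.0, pb
                    here_a, here_b = False, True
                else:
                    da, db = 0.0, 0.0
                    here_a, here_b = False, False
                want_a = obs in (A_ONLY, BOTH)
                want_b = obs in (B_ONLY, BOTH)
                if (want_a and not here_a) or (want_b and not here_b):
                    lik = 0.0
                    break
                lik *= (da if want_a else 1 - da) * (db if want_b else 1 - db)
            site_lik += sp * lik
        total += -np.log(max(site_lik, 1e-300))
    return total


def single_species_nll(psi, p, detections):
    """Closed-form single-season single-species occupancy NLL (oracle)."""
    total = 0.0
    for row in detections:
        row = np.asarray(row)
        obs = row[row >= 0]
        lik = psi * np.prod(np.where(obs == 1, p, 1 - p))
        if not (obs == 1).any():
            lik += 1 - psi
        total += -np.log(lik)
    return total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestModelSet:
    def test_sixteen_models(self):
        specs = enumerate_model_set()
        assert len(specs) == 16
        assert len({s.name for s in specs}) == 16

    def test_expected_names_present(self):
        names = {s.name for s in enumerate_model_set()}
        assert "psi(S)p(S)r(S)" in names
        assert "psi(S)gamma(.)p(S+Lr+Cam)r(S+Lr+Cam)" in names

    def test_half_have_free_gamma(self):
        assert sum(s.gamma_free for s in enumerate_model_set()) == 8

    def test_parameter_counts(self):
        by_name = {s.name: s.k for s in enumerate_model_set()}
        assert by_name["psi(S)p(S)"] == 4                       # 2 psi + 2 ints
        assert by_name["psi(S)p(S)r(S)"] == 6
        assert by_name["psi(S)gamma(.)p(S+Lr+Cam)r(S+Lr+Cam)"] == 15


class TestLikelihood:
    def test_forced_occupancy_hand_product(self):
        # psi_A = psi_B = 1, p = 0.5, one A-only occasion: L = 0.5*0.5
        hist = simple_hist([[A_ONLY]])
        spec = OccupancyModelSpec(False, (), False)
        params = np.array([30.0, 30.0, 0.0, 0.0, 0.0, 0.0])
        nll = two_species_neg_log_likelihood(params, hist, spec)
        assert nll == pytest.approx(-np.log(0.25), abs=1e-9)

    def test_four_state_hand_sum(self):
        # psi = 0.5 each, gamma = 1, p = r = 0.5, obs neither:
        # 0.25*0.25 + 0.25*0.5 + 0.25*0.5 + 0.25*1 = 0.5625
        hist = simple_hist([[NEITHER]])
        spec = OccupancyModelSpec(False, (), True)
        params = np.array([0.0, 0.0, 0.0, 0.0])
        nll = two_species_neg_log_likelihood(params, hist, spec)
        assert nll == pytest.approx(-np.log(0.5625), abs=1e-9)

    @pytest.mark.parametrize("spec", [
        OccupancyModelSpec(False, (), True),
        OccupancyModelSpec(True, (), False),
        OccupancyModelSpec(True, ("Lr",), True),
        OccupancyModelSpec(True, ("Lr", "Cam"), False),
    ])
    def test_matches_enumeration_oracle(self, spec):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n_sites, n_occ = rng.integers(1, 7), rng.integers(1, 5)
            states = rng.integers(-1, 4, size=(n_sites, n_occ))
            hist = simple_hist(states,
                               lure_bin=rng.integers(0, 4, (n_sites, n_occ)),
                               cam_slow=rng.integers(0, 2, (n_sites, n_occ)))
            params = rng.normal(0, 1.5, spec.k)
            mine = two_species_neg_log_likelihood(params, hist, spec)
            assert mine == pytest.approx(oracle_nll(params, hist, spec), abs=1e-10)

    def test_factorizes_when_independent(self):
        # gamma = 1 and r = p: joint likelihood = product of single-species ones
        rng = np.random.default_rng(3)
        hist, _ = simulate_detection_histories(0.6, 0.5, 1.0, 0.4, 0.4,
                                               40, 5, seed=rng)
        spec = OccupancyModelSpec(False, (), True)
        psi_a, psi_b, p_a, p_b = 0.55, 0.45, 0.35, 0.25
        logit = lambda x: np.log(x / (1 - x))
        params = np.array([logit(psi_a), logit(psi_b), logit(p_a), logit(p_b)])
        joint = two_species_neg_log_likelihood(params, hist, spec)
        det_a = np.where(hist.states == MISSING, -1,
                         np.isin(hist.states, [A_ONLY, BOTH]).astype(int))
        det_b = np.where(hist.states == MISSING, -1,
                         np.isin(hist.states, [B_ONLY, BOTH]).astype(int))
        split = (single_species_nll(psi_a, p_a, det_a)
                 + single_species_nll(psi_b, p_b, det_b))
        assert joint == pytest.approx(split, abs=1e-8)

    def test_gamma_transform_respects_simplex(self):
        spec = OccupancyModelSpec(True, (), True)
        hist = simple_hist([[NEITHER]])
        for u in (-20.0, -1.0, 0.0, 1.0, 20.0):
            params = np.array([1.2, -0.5, u, 0.0, 0.0])
            (pa, pb, pab), _ = _unpack(params, spec, hist)
            assert max(0.0, pa + pb - 1) - 1e-12 <= pab <= min(pa, pb) + 1e-12
            assert gamma_of_params(params, spec, hist) >= 0.0

    def test_non_finite_parameters_rejected(self):
        hist = simple_hist([[NEITHER]])
        spec = OccupancyModelSpec(False, (), True)
        with pytest.raises(ValueError):
            two_species_neg_log_likelihood(
                np.array([np.nan, 0, 0, 0]), hist, spec)


class TestHistories:
    def test_45_day_deployment_gives_three_occasions(self):
        deps = make_deployments([("S1", 32.9, 104.1, "2014-05-01", "2014-06-15")])
        ev = make_photos([]).rename(columns={"timestamp": "event_time"})
        ev["species"] = ev.get("species", pd.Series(dtype=object))
        hist = build_detection_histories(
            pd.DataFrame(columns=["station_id", "species", "event_time"]),
            deps, "A", "B")
        assert hist.n_occasions == 3
        assert (hist.states == NEITHER).all()

    def test_event_placed_in_second_occasion(self):
        deps = make_deployments([("S1", 32.9, 104.1, "2014-05-01", "2014-06-15")])
        events = pd.DataFrame([{"station_id": "S1", "species": "A",
                                "event_time": pd.Timestamp("2014-05-18 02:00")}])
        hist = build_detection_histories(events, deps, "A", "B")
        assert list(hist.states[0]) == [NEITHER, A_ONLY, NEITHER]

    def test_trailing_remnant_rule(self):
        # 37 days -> 2 full + 7-day remnant (< 7.5) dropped
        deps = make_deployments([("S1", 32.9, 104.1, "2014-05-01", "2014-06-07")])
        empty = pd.DataFrame(columns=["station_id", "species", "event_time"])
        assert build_detection_histories(empty, deps, "A", "B").n_occasions == 2
        # 38 days -> 8-day remnant kept
        deps = make_deployments([("S1", 32.9, 104.1, "2014-05-01", "2014-06-08")])
        assert build_detection_histories(empty, deps, "A", "B").n_occasions == 3

    def test_winter_occasions_dropped_by_default(self):
        # Nov 10 -> Dec 15: occasions [Nov10, Nov25) warm, [Nov25, Dec10)
        # winter midpoint, 5-day remnant dropped either way
        deps = make_deployments([("S1", 32.9, 104.1, "2014-11-10", "2014-12-15")])
        empty = pd.DataFrame(columns=["station_id", "species", "event_time"])
        hist = build_detection_histories(empty, deps, "A", "B")
        assert hist.n_occasions == 1
        hist_all = build_detection_histories(empty, deps, "A", "B", season=None)
        assert hist_all.n_occasions == 2

    def test_year_filter(self):
        deps = make_deployments([("S1", 32.9, 104.1, "2010-05-01", "2010-06-15"),
                                 ("S2", 32.9, 104.1, "2012-05-01", "2012-06-15")])
        empty = pd.DataFrame(columns=["station_id", "species", "event_time"])
        hist = build_detection_histories(empty, deps, "A", "B",
                                         years=range(2011, 2016))
        assert hist.sites == ["S2"]

    def test_lure_age_bins(self):
        assert [lure_age_bin(d) for d in (0, 15, 16, 30, 31, 45, 46, 90)] == \
            [0, 0, 1, 1, 2, 2, 3, 3]

    def test_unknown_species_raises(self):
        deps = make_deployments([("S1", 32.9, 104.1, "2014-05-01", "2014-06-15")])
        events = pd.DataFrame([{"station_id": "S1", "species": "A",
                                "event_time": pd.Timestamp("2014-05-02")}])
        with pytest.raises(ConfigurationError):
            build_detection_histories(events, deps, "C", "B",
                                      vocabulary=["A", "B"])

    def test_text_round_trip_symbols(self):
        hist = simple_hist([[NEITHER, A_ONLY, B_ONLY, BOTH, MISSING]])
        assert hist.to_text().split("\t")[1].strip() == "0ABX."


class TestFitting:
    def test_parameter_recovery_small(self):
        hist, truth = simulate_detection_histories(0.5, 0.4, 0.6, 0.3, 0.3,
                                                   400, 6, seed=10)
        fit = fit_model(hist, OccupancyModelSpec(True, (), True), seed=1)
        assert fit.converged
        assert fit.psi_a == pytest.approx(0.5, abs=0.1)
        assert fit.psi_b == pytest.approx(0.4, abs=0.1)
        assert fit.gamma == pytest.approx(0.6, abs=2.5 * fit.gamma_se + 1e-6)

    def test_fixed_gamma_reports_sif_one(self):
        hist, _ = simulate_detection_histories(0.5, 0.4, 1.0, 0.3, 0.3,
                                               100, 5, seed=4)
        fit = fit_model(hist, OccupancyModelSpec(False, (), True), seed=2)
        assert fit.gamma == pytest.approx(1.0, abs=1e-12)
        assert fit.gamma_se == 0.0

    def test_aic_is_neg2ll_plus_2k(self):
        hist, _ = simulate_detection_histories(0.5, 0.4, 0.6, 0.3, 0.3,
                                               80, 4, seed=5)
        fit = fit_model(hist, OccupancyModelSpec(True, (), False), seed=3)
        assert fit.aic == pytest.approx(fit.neg2ll + 2 * fit.k)
        assert fit.k == fit.spec.k == 7

    def test_label_swap_invariance(self):
        hist, _ = simulate_detection_histories(0.6, 0.35, 0.7, 0.35, 0.3,
                                               150, 5, seed=6)
        spec = OccupancyModelSpec(True, (), True)
        fit = fit_model(hist, spec, seed=7)
        fit_swapped = fit_model(hist.swapped(), spec, seed=8)
        assert fit_swapped.aic == pytest.approx(fit.aic, abs=1e-3)
        assert fit_swapped.psi_a == pytest.approx(fit.psi_b, abs=1e-3)
        assert fit_swapped.gamma == pytest.approx(fit.gamma, abs=1e-3)

    def test_site_order_invariance(self):
        hist, _ = simulate_detection_histories(0.5, 0.5, 0.8, 0.3, 0.3,
                                               120, 5, seed=9)
        perm = np.random.default_rng(0).permutation(hist.n_sites)
        shuffled = DetectionHistoryPair(
            [hist.sites[i] for i in perm], hist.states[perm],
            hist.lure_bin[perm], hist.cam_slow[perm], "A", "B")
        spec = OccupancyModelSpec(False, (), True)
        f1, f2 = fit_model(hist, spec, seed=1), fit_model(shuffled, spec, seed=1)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-4)


class TestRanking:
    def test_best_model_has_zero_delta_and_sif_semantics(self):
        hist, _ = simulate_detection_histories(0.55, 0.45, 0.5, 0.35, 0.35,
                                               300, 6, seed=21)
        table, sif = fit_model_set(hist, seed=30)
        assert table["delta_aic"].min() == 0.0
        assert len(table) == 16
        assert sif.interpretation in ("avoidance", "independence",
                                      "aggregation", "unclear")
        if sif.interpretation == "avoidance":
            assert sif.gamma_hat < 1.0

    def test_all_fixed_top_set_means_independence(self):
        fits = []
        for name_k, gf, aic in ((4, False, 100.0), (5, True, 104.0)):
            spec = OccupancyModelSpec(gf, (), True)
            fits.append(type("F", (), {})())
            f = fits[-1]
            f.spec, f.converged, f.aic = spec, True, aic
            f.gamma, f.gamma_se = (1.0, 0.0) if not gf else (0.6, 0.2)
            f.neg2ll, f.k = aic - 2 * name_k, name_k
            f.psi_a = f.psi_b = 0.5
            f.param_se = np.zeros(name_k)
            f.delta_aic = None
        table, sif = rank_models_and_sif(fits)
        assert sif.interpretation == "independence"
        assert sif.gamma_hat == 1.0
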