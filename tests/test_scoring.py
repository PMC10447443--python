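"""Probabilistic shift matching: Z scores, p-values, capping, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shiftsel.core import MissingPredictionError, ShiftDistribution
from shiftsel.scoring import (EnsembleSelection, SiteMatchConfig,
                              compute_reference_uncertainties,
                              environment_probability, histogram_overlap_js,
                              per_molecule_rmse, score_all, site_probability,
                              threshold_diagnostics, two_tailed_p, z_score)


class TestZScore:
    def test_equal_shifts_give_zero(self):
        assert z_score(5.0, 0.6, 5.0, 0.8) == 0.0

    def test_unit_denominator(self):
        # widths chosen so sqrt(0.36 + 0.64) = 1
        assert z_score(5.0, 0.6, 6.0, 0.8) == pytest.approx(1.0)

    @given(st.floats(-50, 250), st.floats(0.1, 10), st.floats(-50, 250),
           st.floats(0.1, 10))
    def test_matches_direct_formula(self, de, se, dp, sp):
        want = abs(de - dp) / np.hypot(se, sp)
        assert z_score(de, se, dp, sp) == pytest.approx(want, rel=1e-12)
        assert z_score(de, se, dp, sp) >= 0

    def test_nonpositive_width_raises(self):
        with pytest.raises(ValueError):
            z_score(1.0, 0.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            z_score(1.0, 1.0, 2.0, -0.5)


class TestTwoTailedP:
    def test_zero_gives_one(self):
        assert two_tailed_p(0.0) == 1.0

    def test_large_z_vanishes(self):
        assert two_tailed_p(40.0) == pytest.approx(0.0, abs=1e-300)

    def test_95_percent_point(self):
        assert two_tailed_p(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_decreasing_in_z(self):
        z = np.linspace(0, 8, 100)
        p = two_tailed_p(z)
        assert np.all(np.diff(p) < 0)

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            two_tailed_p(-0.1)


class TestSiteProbability:
    @pytest.mark.parametrize("p,sp,s0,want", [
        (0.8, 1.0, 1.0, 0.8),   # cap active at ratio 1
        (0.8, 2.0, 1.0, 0.4),   # ratio 2 halves the probability
        (0.8, 0.5, 1.0, 0.8),   # ratio below 1 is floored
    ])
    def test_capping(self, p, sp, s0, want):
        assert site_probability(p, sp, s0) == pytest.approx(want)

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            site_probability(0.5, 1.0, 0.0)


class TestEnvironmentProbability:
    def test_idempotent_on_constant(self):
        assert environment_probability([0.5] * 10) == pytest.approx(0.5)

    def test_zero_annihilates(self):
        assert environment_probability([1.0, 1.0, 0.0]) == 0.0

    def test_log_space_matches_direct_product(self):
        p = [0.9, 0.4, 0.1]
        assert environment_probability(p) == pytest.approx(0.036 ** (1 / 3))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            environment_probability([])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_bounded_by_min_and_max(self, probs):
        pj = environment_probability(probs)
        assert min(probs) - 1e-12 <= pj <= max(probs) + 1e-12


class TestReferenceUncertainties:
    def test_first_quartile_linear_interpolation(self):
        df = pd.DataFrame({"site_label": "S1",
                           "uncertainty_ppm": [1.0, 2.0, 3.0, 4.0]})
        assert compute_reference_uncertainties(df)["S1"] == pytest.approx(1.75)

    def test_constant_and_singleton(self):
        df = pd.DataFrame({"site_label": ["A"] * 5 + ["B"],
                           "uncertainty_ppm": [2.5] * 5 + [0.7]})
        q = compute_reference_uncertainties(df)
        assert q["A"] == pytest.approx(2.5)
        assert q["B"] == pytest.approx(0.7)


def _tables(shifts_by_env, centers=(10.0, 50.0, 120.0), widths=(1.0, 2.0, 3.0),
            uncertainty=0.5):
    """Small prediction/distribution tables for explicit scoring cases."""
    sites = [f"S{i}" for i in range(len(centers))]
    rows = []
    for env_id, shifts in shifts_by_env.items():
        for site, shift in zip(sites, shifts):
            rows.append((0, env_id, 0, site, "C", shift, uncertainty))
    preds = pd.DataFrame(rows, columns=["trajectory", "frame", "molecule_id",
                                        "site_label", "element", "shift_ppm",
                                        "uncertainty_ppm"])
    dists = pd.DataFrame({"site_label": sites, "element": "C",
                          "center_ppm": centers, "width_ppm": widths})
    return preds, dists


class TestScoreAll:
    def test_perfect_predictions_probability_one(self):
        preds, dists = _tables({0: (10.0, 50.0, 120.0)})
        cfg = SiteMatchConfig.from_data(preds, dists)
        sel = score_all(preds, dists, cfg)
        assert sel.probabilities.iloc[0] == pytest.approx(1.0)
        assert len(sel.selected_ids) == 1

    def test_far_outlier_rejected(self):
        # one site 10 joint-sigma away annihilates the geometric mean
        joint = np.hypot(1.0, 0.5)
        preds, dists = _tables({0: (10.0 + 10 * joint, 50.0, 120.0)})
        cfg = SiteMatchConfig.from_data(preds, dists)
        sel = score_all(preds, dists, cfg)
        assert sel.probabilities.iloc[0] < 1e-5
        assert len(sel.selected_ids) == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        envs = {i: tuple(rng.normal((10, 50, 120), 2)) for i in range(20)}
        preds, dists = _tables(envs)
        cfg = SiteMatchConfig.from_data(preds, dists)
        ref = score_all(preds, dists, cfg).probabilities
        shuffled = preds.sample(frac=1.0, random_state=1).reset_index(drop=True)
        got = score_all(shuffled, dists, cfg).probabilities
        pd.testing.assert_series_equal(ref, got)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        envs = {i: tuple(rng.normal((10, 50, 120), 3)) for i in range(50)}
        preds, dists = _tables(envs)
        probs = score_all(preds, dists,
                          SiteMatchConfig.from_data(preds, dists)).probabilities
        previous = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            sel = set(EnsembleSelection.by_threshold(probs, thr).selected_ids)
            if previous is not None:
                assert sel <= previous
            previous = sel

    def test_top_fraction_mode(self):
        rng = np.random.default_rng(2)
        envs = {i: tuple(rng.normal((10, 50, 120), 3)) for i in range(100)}
        preds, dists = _tables(envs)
        cfg = SiteMatchConfig.from_data(preds, dists, top_fraction=0.1)
        sel = score_all(preds, dists, cfg)
        assert len(sel.selected_ids) == 10
        chosen = sel.probabilities.loc[sel.selected_ids]
        others = sel.probabilities.drop(sel.selected_ids)
        assert chosen.min() >= others.max()

    def test_missing_prediction_raises_then_skips(self):
        preds, dists = _tables({0: (10.0, 50.0, 120.0), 1: (10.0, 50.0, 120.0)})
        preds = preds.drop(preds.index[-1])  # env 1 loses site S2
        cfg = SiteMatchConfig.from_data(preds, dists)
        with pytest.raises(MissingPredictionError):
            score_all(preds, dists, cfg)
        cfg.on_missing = "skip"
        sel = score_all(preds, dists, cfg)
        assert len(sel.probabilities) == 1

    def test_equivalent_proton_averaging(self):
        """Averaging two equivalent sites equals scoring their mean shift."""
        sites = ["Ha", "Hb"]
        rows = [(0, 0, 0, "Ha", "H", 3.0, 0.4), (0, 0, 0, "Hb", "H", 5.0, 0.4)]
        preds = pd.DataFrame(rows, columns=["trajectory", "frame",
                                            "molecule_id", "site_label",
                                            "element", "shift_ppm",
                                            "uncertainty_ppm"])
        dists = pd.DataFrame({"site_label": ["H2"], "element": ["H"],
                              "center_ppm": [4.0], "width_ppm": [0.8]})
        cfg = SiteMatchConfig.from_data(preds, dists,
                                        equivalent_groups={"H2": sites})
        sel = score_all(preds, dists, cfg)
        # mean shift 4.0 hits the center exactly
        assert sel.probabilities.iloc[0] == pytest.approx(1.0)


class TestPerMoleculeRMSE:
    def test_perfect_predictions_zero(self):
        preds, dists = _tables({0: (10.0, 50.0, 120.0)})
        rmse = per_molecule_rmse(preds, dists, "C")
        assert rmse.iloc[0] == pytest.approx(0.0)

    def test_single_site_offset(self):
        preds, dists = _tables({0: (12.0,)}, centers=(10.0,), widths=(1.0,))
        assert per_molecule_rmse(preds, dists, "C").iloc[0] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        shifts = rng.normal((10, 50, 120), 5)
        preds, dists = _tables({0: tuple(shifts)})
        want = np.sqrt(np.mean((shifts - np.array([10, 50, 120.0])) ** 2))
        assert per_molecule_rmse(preds, dists, "C").iloc[0] == \
            pytest.approx(want)

    def test_no_matching_sites_raises(self):
        preds, dists = _tables({0: (10.0,)}, centers=(10.0,), widths=(1.0,))
        with pytest.raises(ValueError):
            per_molecule_rmse(preds, dists, "H")


class TestThresholdDiagnostics:
    def test_identical_masses(self):
        q = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        overlap, js = histogram_overlap_js(q, q)
        assert overlap == pytest.approx(1.0)
        assert js == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        p = np.array([1.0, 0.0, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.0, 1.0])
        overlap, js = histogram_overlap_js(p, q)
        assert overlap == 0.0
        assert js == pytest.approx(1.0)

    def test_half_overlapping_toy_case_matches_direct_sum(self):
        dist = ShiftDistribution("S", 0.0, 1.0)
        rng = np.random.default_rng(4)
        shifts = rng.uniform(-1, 3, size=500)
        edges = np.linspace(-4, 4, 41)
        overlap, js = threshold_diagnostics(shifts, dist, bins=edges)
        from scipy.stats import norm
        p = np.histogram(shifts, bins=edges)[0] / 500
        q = np.diff(norm.cdf(edges))
        q = q / q.sum()
        assert overlap == pytest.approx(np.minimum(p, q).sum())
        m = (p + q) / 2

        def _kl(a, b):
            mask = a > 0
            return np.sum(a[mask] * np.log2(a[mask] / b[mask]))

        assert js == pytest.approx((_kl(p, m) + _kl(q, m)) / 2, abs=1e-12)
        assert 0.0 < overlap < 1.0

    def test_gaussian_sample_scores_well(self):
        dist = ShiftDistribution("S", 5.0, 0.8)
        rng = np.random.default_rng(5)
        overlap, js = threshold_diagnostics(rng.normal(5.0, 0.8, 2000), dist)
        assert overlap > 0.9
        assert js < 0.05

    def test_too_few_predictions_raise(self):
        with pytest.raises(ValueError):
            threshold_diagnostics([1.0], ShiftDistribution("S", 0.0, 1.0))
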